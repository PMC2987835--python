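"""Statistics for the leaf-disc fecundity assay and the ROS burst assay.

Fecundity: four first-instar nymphs are placed per well; adults are
counted on days 6, 12 and 14 and newly produced nymphs on days 12, 14
and 17.  The per-well statistic is the chained production rate

    R = N12/A6 + N14/A12 + N17/A14   (nymphs per adult),

computed per well and then averaged per construct.  Wells where a
denominator is zero (all adults dead by that count day) are excluded.
Construct effects are screened liberally (mean differs from the
empty-vector control by at least one standard error) and confirmed with
a one-way ANOVA blocked on experiment repeat.

ROS: per leaf disc the maximum photon count over the time course is
taken; construct means are compared to the control with a Welch
two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

INITIAL_NYMPHS = 4


@dataclass(frozen=True)
class WellCounts:
    """Observed counts for one well of the 24-well plate assay."""

    construct: str
    replicate: str
    A6: int
    A12: int
    A14: int
    N12: int
    N14: int
    N17: int
    initial_n: int = INITIAL_NYMPHS
    well: str = ""

    def __post_init__(self) -> None:
        counts = (self.A6, self.A12, self.A14, self.N12, self.N14, self.N17)
        if any(c < 0 for c in counts):
            raise ValueError(f"{self.construct}/{self.well}: negative count")
        if any(int(c) != c for c in counts):
            raise ValueError(f"{self.construct}/{self.well}: non-integer count")
        if self.A6 > self.initial_n:
            raise ValueError(
                f"{self.construct}/{self.well}: more adults on day 6 than placed")
        if not self.A6 >= self.A12 >= self.A14:
            raise ValueError(
                f"{self.construct}/{self.well}: adult counts must be non-increasing")


def production_rate(well: WellCounts) -> Optional[float]:
    """Per-well nymphs-per-adult statistic; ``None`` marks an excluded well.

    R = N12/A6 + N14/A12 + N17/A14.  A zero denominator (no surviving
    adults at that count day) excludes the well, generalising the
    stated all-four-died exclusion.
    """
    if 0 in (well.A6, well.A12, well.A14):
        return None
    return well.N12 / well.A6 + well.N14 / well.A12 + well.N17 / well.A14


@dataclass(frozen=True)
class ConstructSummary:
    construct: str
    n_wells: int
    mean_rate: float
    se: float
    single_well: bool = False  # SE = 0 by convention, flagged

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ValueError("summary needs at least one well")
        if self.se < 0:
            raise ValueError("standard error cannot be negative")


def summarize_construct(wells: Sequence[WellCounts],
                        construct: str) -> ConstructSummary:
    """Mean and SE of the per-well rates for one construct (excluded
    wells dropped)."""
    rates = [r for w in wells if w.construct == construct
             if (r := production_rate(w)) is not None]
    if not rates:
        raise ValueError(f"{construct}: no data (all wells excluded)")
    n = len(rates)
    mean = float(np.mean(rates))
    if n == 1:
        return ConstructSummary(construct=construct, n_wells=1,
                                mean_rate=mean, se=0.0, single_well=True)
    se = float(np.std(rates, ddof=1) / math.sqrt(n))
    return ConstructSummary(construct=construct, n_wells=n,
                            mean_rate=mean, se=se)


@dataclass(frozen=True)
class ScreenHit:
    construct: str
    direction: str  # "enhanced" | "reduced"
    difference: float
    threshold: float


def initial_screen(summaries: Sequence[ConstructSummary],
                   ev_summary: ConstructSummary,
                   se_basis: str = "difference") -> List[ScreenHit]:
    """The deliberately liberal one-standard-error screening rule.

    A construct is a hit when |mean − mean_EV| ≥ 1 × SE.  Which standard
    error plays the role of the yardstick is configurable: the default
    is the SE of the observed difference, sqrt(SE_c² + SE_EV²), under
    which a null construct is flagged with probability 2Φ(−1) ≈ 32% —
    the liberal behaviour the screen is designed for; ``candidate``
    (the per-construct error bar) and ``control`` are also available.
    """
    hits = []
    for s in summaries:
        if s.construct == ev_summary.construct:
            continue
        if se_basis == "candidate":
            threshold = s.se
        elif se_basis == "control":
            threshold = ev_summary.se
        elif se_basis == "difference":
            threshold = math.hypot(s.se, ev_summary.se)
        else:
            raise ValueError(f"unknown se_basis {se_basis!r}")
        diff = s.mean_rate - ev_summary.mean_rate
        if abs(diff) >= threshold:
            hits.append(ScreenHit(
                construct=s.construct,
                direction="enhanced" if diff > 0 else "reduced",
                difference=diff, threshold=threshold))
    return hits


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_treatment: int
    df_residual: int
    p: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    undefined: bool = False


def blocked_anova(wells: Sequence[WellCounts]) -> AnovaResult:
    """One-way ANOVA with construct as treatment and replicate as block.

    Additive two-way decomposition (treatment + block) on the per-well
    rates; F tests the treatment term against the residual.  Every
    construct must appear in every block (after well exclusion),
    otherwise the design is declared singular.
    """
    rows = []
    for w in wells:
        r = production_rate(w)
        if r is not None:
            rows.append((w.construct, w.replicate, r))
    df = pd.DataFrame(rows, columns=["construct", "replicate", "rate"])
    constructs = df["construct"].unique()
    blocks = df["replicate"].unique()
    if len(constructs) < 2 or len(blocks) < 2:
        raise ValueError("blocked ANOVA needs >= 2 constructs and >= 2 blocks")
    cell_counts = df.groupby(["construct", "replicate"]).size()
    for c in constructs:
        for b in blocks:
            if (c, b) not in cell_counts.index:
                raise ValueError(
                    f"singular design: construct {c!r} has no wells in block {b!r}")

    df_treat = len(constructs) - 1
    df_resid = len(df) - len(constructs) - len(blocks) + 1
    if df["rate"].nunique() == 1:  # no variance at all: F = 0 by convention
        return AnovaResult(F=0.0, df_treatment=df_treat,
                           df_residual=df_resid, p=1.0)

    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    fit = ols("rate ~ C(construct) + C(replicate)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    f_val = float(table.loc["C(construct)", "F"])
    if math.isnan(f_val):  # zero residual variance and zero treatment SS
        f_val = 0.0
    p_val = float(table.loc["C(construct)", "PR(>F)"])
    if math.isnan(p_val):
        p_val = 1.0
    return AnovaResult(F=f_val,
                       df_treatment=int(table.loc["C(construct)", "df"]),
                       df_residual=int(table.loc["Residual", "df"]),
                       p=p_val)


@dataclass(frozen=True)
class RosSeries:
    """Photon counts over time for one leaf disc."""

    disc_id: str
    construct: str
    times: Tuple[float, ...]
    counts: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError(f"{self.disc_id}: empty series")
        if len(self.times) != len(self.counts):
            raise ValueError(f"{self.disc_id}: times/counts length mismatch")
        if any(c < 0 for c in self.counts):
            raise ValueError(f"{self.disc_id}: negative photon count")

    @property
    def max_count(self) -> float:
        return max(self.counts)


@dataclass(frozen=True)
class RosConstructSummary:
    construct: str
    n_discs: int
    mean_max: float
    se: float


def _welch(x: np.ndarray, y: np.ndarray) -> TTestResult:
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return TTestResult(t=0.0, df=float(len(x) + len(y) - 2), p=1.0,
                               undefined=True)
        return TTestResult(t=math.copysign(math.inf, x.mean() - y.mean()),
                           df=float(len(x) + len(y) - 2), p=0.0, undefined=True)
    t, p = stats.ttest_ind(x, y, equal_var=False)
    sx, sy = vx / len(x), vy / len(y)
    df = (sx + sy) ** 2 / (sx ** 2 / (len(x) - 1) + sy ** 2 / (len(y) - 1))
    return TTestResult(t=float(t), df=float(df), p=float(p))


def ros_summary(series_by_construct: Dict[str, Sequence[RosSeries]],
                control: str = "EV"
                ) -> Tuple[Dict[str, RosConstructSummary], Dict[str, TTestResult]]:
    """Per-construct max-photon summaries and Welch t-tests vs control.

    Per disc the maximum photon count over the time course is taken;
    discs are then averaged per construct.
    """
    if control not in series_by_construct:
        raise ValueError(f"control construct {control!r} absent")
    summaries: Dict[str, RosConstructSummary] = {}
    maxima: Dict[str, np.ndarray] = {}
    for construct, series in series_by_construct.items():
        if len(series) < 2:
            raise ValueError(f"{construct}: need >= 2 discs")
        m = np.array([s.max_count for s in series], dtype=float)
        maxima[construct] = m
        summaries[construct] = RosConstructSummary(
            construct=construct, n_discs=len(m), mean_max=float(m.mean()),
            se=float(m.std(ddof=1) / math.sqrt(len(m))))
    tests = {c: _welch(maxima[c], maxima[control])
             for c in series_by_construct if c != control}
    return summaries, tests


# ---------------------------------------------------------------------------
# tabular I/O

PLATE_COLUMNS = ("construct", "replicate", "well",
                 "A6", "A12", "A14", "N12", "N14", "N17")


def read_plate_tsv(path) -> List[WellCounts]:
    df = pd.read_csv(path, sep="\t", dtype={"construct": str, "replicate": str,
                                            "well": str})
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [WellCounts(construct=r.construct, replicate=r.replicate,
                       well=r.well, A6=int(r.A6), A12=int(r.A12),
                       A14=int(r.A14), N12=int(r.N12), N14=int(r.N14),
                       N17=int(r.N17))
            for r in df.itertuples()]


def write_plate_tsv(wells: Sequence[WellCounts], path) -> None:
    pd.DataFrame(
        [(w.construct, w.replicate, w.well, w.A6, w.A12, w.A14,
          w.N12, w.N14, w.N17) for w in wells],
        columns=PLATE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ros_tsv(path) -> Dict[str, List[RosSeries]]:
    """Long-format TSV (construct, disc, time, counts) → series by construct."""
    df = pd.read_csv(path, sep="\t", dtype={"construct": str, "disc": str})
    out: Dict[str, List[RosSeries]] = {}
    for (construct, disc), grp in df.groupby(["construct", "disc"], sort=False):
        grp = grp.sort_values("time")
        out.setdefault(construct, []).append(RosSeries(
            disc_id=disc, construct=construct,
            times=tuple(grp["time"]), counts=tuple(grp["counts"])))
    return out


def write_ros_tsv(series_by_construct: Dict[str, Sequence[RosSeries]], path) -> None:
    rows = []
    for construct, series in series_by_construct.items():
        for s in series:
            for t, c in zip(s.times, s.counts):
                rows.append((construct, s.disc_id, t, c))
    pd.DataFrame(rows, columns=["construct", "disc", "time", "counts"]).to_csv(
        path, sep="\t", index=False)
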