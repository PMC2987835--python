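"""The secretion gate: signal-peptide scoring, TM detection, cleavage.

A translated ORF is called a predicted secreted protein when

* its signal-peptide score exceeds 0.9 (strict inequality),
* the predicted cleavage site lies within residues 1-30, and
* no transmembrane segment ends after the cleavage site (signal
  peptides are themselves hydrophobic and must not count as TM).

Scores and topology normally come from parsed external predictor
reports.  A builtin heuristic scorer and hydropathy-window TM detector
are provided so the pipeline runs self-contained; the builtin scorer is
a deliberately simple classical-signal-peptide model (charged n-region,
hydrophobic h-region, small residues at the (-3,-1) cleavage positions)
and makes no claim of equivalence to a trained predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from .records import PredictorReportRow, ProteinRecord

# Kyte-Doolittle hydropathy scale (standard published values).
KYTE_DOOLITTLE: Dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0, "*": 0.0,
}

SMALL_RESIDUES = frozenset("AGSCT")  # tolerated at the -3 and -1 cleavage positions

SP_SCORE_CUTOFF = 0.9       # strict > comparison
CLEAVAGE_WINDOW = (1, 30)   # 1-based inclusive
TM_WINDOW = 19              # residues per hydropathy window
TM_THRESHOLD = 1.6          # mean hydropathy above which a window seeds a helix
TM_MIN_SEGMENT = 15         # merged segments shorter than this are discarded
_MIN_BUILTIN_LEN = 25       # below this the builtin scorer reports score 0

# Candidate cleavage positions scanned by the builtin scorer (1-based index
# of the last signal-peptide residue).
_CLEAVAGE_SCAN = (16, 30)

_NREGION_SLOPE = 3.0  # logistic steepness of the n-region charge sub-score


@dataclass(frozen=True)
class SignalPeptideCall:
    protein_id: str
    score: float
    cleavage_site: int  # 1-based index of the last signal-peptide residue
    source: str  # "parsed_report" | "builtin_heuristic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"{self.protein_id}: score {self.score} outside [0, 1]")
        if self.cleavage_site < 1:
            raise ValueError(f"{self.protein_id}: cleavage site must be >= 1")


@dataclass(frozen=True)
class TopologyCall:
    protein_id: str
    tm_segments: Tuple[Tuple[int, int], ...]  # 1-based inclusive intervals
    has_tm_in_mature: bool


@dataclass(frozen=True)
class MatureProtein:
    """The secreted product left after signal-peptide cleavage."""

    protein_id: str
    full_seq: str
    cleavage_site: int
    mature_seq: str

    def __post_init__(self) -> None:
        if not self.mature_seq:
            raise ValueError(f"{self.protein_id}: empty mature protein")
        if self.full_seq[self.cleavage_site:] != self.mature_seq:
            raise ValueError(f"{self.protein_id}: mature sequence inconsistent with cleavage site")


def _kd_mean(seq: str) -> float:
    return sum(KYTE_DOOLITTLE[c] for c in seq) / len(seq)


def signal_peptide_subscores(seq: str) -> Tuple[float, float, float, int]:
    """Compute the three builtin sub-scores and the best cleavage position.

    (i)  n-region charge: net #{K,R} − #{D,E} over residues 1-5, through a
         logistic centred at +1 (slope 3).
    (ii) h-region hydrophobicity: max over all 8-residue windows within
         residues 3-25 of mean Kyte-Doolittle hydropathy, linearly
         rescaled so 1.6 → 0.5 and 3.0 → 1.0, clamped to [0, 1].
    (iii) cleavage: small residues {A,G,S,C,T} at the −1 and −3 positions
         of the best candidate site in 16-30: 1.0 both, 0.6 one, 0.2 none.
    """
    n_region = seq[:5]
    net = sum(c in "KR" for c in n_region) - sum(c in "DE" for c in n_region)
    s_charge = 1.0 / (1.0 + math.exp(-_NREGION_SLOPE * (net - 1)))

    # 8-residue windows fully inside residues 3..25 (1-based)
    best_h = -math.inf
    hi = min(25, len(seq))
    for start in range(3, hi - 8 + 2):  # 1-based window start
        window = seq[start - 1:start + 7]
        if len(window) == 8:
            best_h = max(best_h, _kd_mean(window))
    if best_h == -math.inf:
        s_hydro = 0.0
    else:
        s_hydro = min(1.0, max(0.0, 0.5 + (best_h - 1.6) * (0.5 / 1.4)))

    best_site, best_sc = _CLEAVAGE_SCAN[0], -1.0
    for k in range(_CLEAVAGE_SCAN[0], min(_CLEAVAGE_SCAN[1], len(seq) - 1) + 1):
        n_small = (seq[k - 1] in SMALL_RESIDUES) + (seq[k - 3] in SMALL_RESIDUES)
        sc = {2: 1.0, 1: 0.6, 0: 0.2}[n_small]
        if sc > best_sc:
            best_sc, best_site = sc, k
    return s_charge, s_hydro, best_sc, best_site


def predict_signal_peptide(
    protein: ProteinRecord,
    backend: str = "builtin",
    report: Optional[Dict[str, PredictorReportRow]] = None,
) -> SignalPeptideCall:
    """Score the N-terminus of a protein for a cleavable signal peptide.

    ``backend="parsed_report"`` copies score and cleavage site verbatim
    from the loaded report (``report`` maps protein id → row) and raises
    ``KeyError`` naming the id when absent.
    """
    if backend == "parsed_report":
        if report is None or protein.id not in report:
            raise KeyError(f"no signal-peptide report entry for {protein.id!r}")
        row = report[protein.id]
        return SignalPeptideCall(protein_id=protein.id, score=row.score,
                                 cleavage_site=row.cleavage_site,
                                 source="parsed_report")
    if backend != "builtin":
        raise ValueError(f"unknown signal-peptide backend {backend!r}")

    seq = protein.residues
    if len(seq) < _MIN_BUILTIN_LEN:
        return SignalPeptideCall(protein_id=protein.id, score=0.0,
                                 cleavage_site=1, source="builtin_heuristic")
    s1, s2, s3, site = signal_peptide_subscores(seq)
    return SignalPeptideCall(protein_id=protein.id, score=s1 * s2 * s3,
                             cleavage_site=site, source="builtin_heuristic")


def detect_tm_builtin(protein: ProteinRecord, cleavage_site: int) -> TopologyCall:
    """Hydropathy-window TM detection restricted to the mature region.

    Windows of 19 residues over positions strictly after the cleavage
    site; any window with mean Kyte-Doolittle hydropathy > 1.6 seeds a
    segment, overlapping seeds are merged and merged segments shorter
    than 15 residues discarded.
    """
    seq = protein.residues
    if cleavage_site >= len(seq):
        raise ValueError(f"{protein.id}: cleavage site beyond protein end")
    mature = seq[cleavage_site:]
    seeds = []
    for i in range(len(mature) - TM_WINDOW + 1):
        if _kd_mean(mature[i:i + TM_WINDOW]) > TM_THRESHOLD:
            # 1-based inclusive coordinates on the full protein
            start = cleavage_site + i + 1
            seeds.append((start, start + TM_WINDOW - 1))
    merged = []
    for start, end in seeds:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    segments = tuple((s, e) for s, e in merged if e - s + 1 >= TM_MIN_SEGMENT)
    return TopologyCall(protein_id=protein.id, tm_segments=segments,
                        has_tm_in_mature=bool(segments))


def topology_from_report(row: PredictorReportRow, cleavage_site: int) -> TopologyCall:
    """Interpret a parsed topology row relative to a cleavage site.

    A TM segment counts as "in the mature protein" when it ends strictly
    after the cleavage site; helices confined to the signal region are
    the signal peptide itself.
    """
    in_mature = any(end > cleavage_site for _, end in row.tm_segments)
    return TopologyCall(protein_id=row.protein_id, tm_segments=row.tm_segments,
                        has_tm_in_mature=in_mature)


def passes_secretion_gate(
    call: SignalPeptideCall,
    topo: TopologyCall,
    score_cutoff: float = SP_SCORE_CUTOFF,
    cleavage_window: Tuple[int, int] = CLEAVAGE_WINDOW,
) -> Tuple[bool, str]:
    """Apply the secretion gate; returns (passed, reason).

    ``reason`` is ``"ok"`` on success, otherwise the first failing
    clause: ``"score"`` (score must strictly exceed the cutoff),
    ``"cleavage"`` or ``"tm"``.
    """
    if call.protein_id != topo.protein_id:
        raise ValueError(
            f"gate inputs disagree: {call.protein_id!r} vs {topo.protein_id!r}")
    if not call.score > score_cutoff:
        return False, "score"
    if not cleavage_window[0] <= call.cleavage_site <= cleavage_window[1]:
        return False, "cleavage"
    if topo.has_tm_in_mature:
        return False, "tm"
    return True, "ok"


def cleave(protein: ProteinRecord, call: SignalPeptideCall) -> MatureProtein:
    """Cut the signal peptide off, yielding the mature protein."""
    seq = protein.residues
    if call.cleavage_site >= len(seq):
        raise ValueError(f"{protein.id}: empty mature protein")
    return MatureProtein(protein_id=protein.id, full_seq=seq,
                         cleavage_site=call.cleavage_site,
                         mature_seq=seq[call.cleavage_site:])
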