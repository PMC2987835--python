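"""Ground-truth-labelled synthetic inputs for every pipeline stage.

:func:`simulate_library` builds two-species EST libraries with implanted
candidate structure: secreted, full-length, polymorphic true candidates;
TM-anchored decoys; non-secreted decoys; monomorphic conserved decoys;
redundant near-copies; diverged orthologs in the second species; UTRs,
reverse-complemented reads and 5'/3' truncations; plus matching
signal-peptide and topology report files emitted from the builtin
predictors, and a truth table mapping every EST back to its implanted
protein.  :func:`simulate_plate` and :func:`simulate_ros` generate
fecundity plates and ROS time courses with stated per-construct effects.

All generators are pure functions of their configuration: the same seed
yields byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .assays import RosSeries, WellCounts
from .orfs import call_orfs, reverse_complement
from .records import ESTRecord, PredictorReportRow
from .secretion import detect_tm_builtin, predict_signal_peptide

# one fixed codon per amino acid (lexicographically first of the standard
# code); nucleotide-level realism is irrelevant to every stage except
# ATG/stop placement, which this preserves exactly
_CODON = {
    "A": "GCA", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC",
    "G": "GGA", "H": "CAC", "I": "ATA", "K": "AAA", "L": "CTA",
    "M": "ATG", "N": "AAC", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "AGC", "T": "ACA", "V": "GTA", "W": "TGG", "Y": "TAC",
}
_STOP = "TAA"

# hydrophilic-biased residue pool for mature regions: long hydrophobic
# runs (which would read as TM helices) are vanishingly unlikely
_MATURE_POOL = list("DDEEKKNNQQRRHHPPYYGGSSTTAAVLIF")
# early-mature pool excludes the small residues {A,G,S,C,T} so the
# builtin scorer's (-3,-1) scan finds a unique best cleavage position
_EARLY_MATURE_POOL = list("DEKNQRHPYVLIF")
_EARLY_MATURE_LEN = 16


@dataclass(frozen=True)
class LibrarySimConfig:
    """Shape of the simulated two-species EST experiment."""

    seed: int
    n_true_candidates: int = 20
    n_tm_decoys: int = 10
    n_nonsecreted_decoys: int = 10
    n_monomorphic_decoys: int = 10
    redundancy_multiplicity: int = 3   # ESTs per implanted first-species protein
    polymorphism_rate: int = 2         # aa substitutions per mature among copies
    ortholog_fraction: float = 1.0     # share of true candidates with an ortholog
    ortholog_divergence: float = 15.0  # % mature residues differing in the ortholog
    utr5_len: int = 40
    utr3_len: int = 120
    truncation_prob: float = 0.3
    revcomp_prob: float = 0.5
    mature_len_range: Tuple[int, int] = (80, 160)
    n_background_salivary: int = 40
    n_background_all: int = 60         # extra whole-body reads in the full EST set
    n_background_gut: int = 30
    n_gut_contaminants: int = 2        # true candidates also present in gut reads
    n_other_only: int = 0              # other-species-only candidates recoverable
                                       # from the first species' full EST set

    def __post_init__(self) -> None:
        for p in (self.truncation_prob, self.revcomp_prob, self.ortholog_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.ortholog_divergence <= 100.0:
            raise ValueError("ortholog divergence is a percentage in [0, 100]")
        if min(self.n_true_candidates, self.n_tm_decoys, self.n_nonsecreted_decoys,
               self.n_monomorphic_decoys, self.redundancy_multiplicity) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class ImplantedProtein:
    protein_id: str
    class_label: str  # true_candidate | tm_decoy | nonsecreted_decoy | monomorphic_decoy
    species: str
    aa_seq: str
    signal_len: int               # 0 for non-secreted decoys
    ortholog_partner: Optional[str] = None
    redundancy_group: str = ""
    est_ids: List[str] = field(default_factory=list)
    est_full_length: List[bool] = field(default_factory=list)


@dataclass
class LibraryTruth:
    """Maps every generated EST to its implanted protein (or background)."""

    proteins: Dict[str, ImplantedProtein]
    est_to_protein: Dict[str, Optional[str]]

    def ids_of_class(self, label: str, species: str = "mp") -> List[str]:
        return [pid for pid, p in self.proteins.items()
                if p.class_label == label and p.species == species]

    def to_json(self) -> str:
        return json.dumps({
            "proteins": {pid: asdict(p) for pid, p in self.proteins.items()},
            "est_to_protein": self.est_to_protein,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LibraryTruth":
        raw = json.loads(text)
        return cls(
            proteins={pid: ImplantedProtein(**p)
                      for pid, p in raw["proteins"].items()},
            est_to_protein=raw["est_to_protein"])


@dataclass
class SimulatedLibrary:
    config: LibrarySimConfig
    mp_salivary: List[ESTRecord]
    mp_gut: List[ESTRecord]
    mp_all: List[ESTRecord]
    ap_salivary: List[ESTRecord]
    sp_report: Dict[str, PredictorReportRow]
    tm_report: Dict[str, PredictorReportRow]
    truth: LibraryTruth


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _signal_peptide(rng: np.random.Generator) -> str:
    """A signal peptide the builtin scorer accepts by construction:
    positive n-region, a strongly hydrophobic h-region, A at the -3 and
    -1 positions of the cleavage site."""
    k = int(rng.integers(18, 25))  # length incl. the initiator Met
    h_region = "".join(rng.choice(list("LIV"), size=k - 6))  # KD >= 3.8 each
    return "MKR" + h_region + "A" + "L" + "A"


def _mature(rng: np.random.Generator, length: int) -> str:
    head = "".join(rng.choice(_EARLY_MATURE_POOL, size=_EARLY_MATURE_LEN))
    tail = "".join(rng.choice(_MATURE_POOL, size=length - _EARLY_MATURE_LEN))
    return head + tail


def _mutate_mature(rng: np.random.Generator, aa: str, signal_len: int,
                   n_subs: int, min_offset: int = 0) -> str:
    """Substitute ``n_subs`` mature residues (never touching the signal
    peptide or the first ``min_offset`` mature positions)."""
    seq = list(aa)
    lo = signal_len + min_offset
    if n_subs == 0 or lo >= len(seq):
        return aa
    positions = rng.choice(np.arange(lo, len(seq)), size=min(n_subs, len(seq) - lo),
                           replace=False)
    for pos in positions:
        choices = [c for c in _EARLY_MATURE_POOL if c != seq[pos]]
        seq[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(seq)


def back_translate(aa: str) -> str:
    return "".join(_CODON[c] for c in aa)


def _protein_to_est(rng: np.random.Generator, est_id: str, aa: str,
                    species: str, tissue: str, cfg: LibrarySimConfig,
                    truncate: bool) -> Tuple[ESTRecord, bool]:
    """Assemble an EST read for one protein copy; returns (read, full_length).

    The last 5'-UTR codon is an in-frame stop, as in most real
    transcripts, so the called ORF starts at the true initiator Met.
    """
    utr5 = _random_nt(rng, max(cfg.utr5_len - 3, 0)) + _STOP
    utr3 = _random_nt(rng, cfg.utr3_len)
    seq = utr5 + back_translate(aa) + _STOP + utr3
    full = True
    if truncate:
        cut = int(len(seq) * rng.uniform(0.1, 0.5))
        if rng.random() < 0.5:
            seq = seq[cut:]
        else:
            seq = seq[:len(seq) - cut]
        full = False
    if rng.random() < cfg.revcomp_prob:
        seq = reverse_complement(seq)
    return ESTRecord(id=est_id, seq=seq, species=species, tissue=tissue), full


def _implant(rng, truth: LibraryTruth, library: List[ESTRecord],
             protein: ImplantedProtein, n_copies: int, cfg: LibrarySimConfig,
             tissue: str, polymorphic_copies: bool) -> None:
    for copy_idx in range(n_copies):
        aa = protein.aa_seq
        if polymorphic_copies and copy_idx > 0:
            aa = _mutate_mature(rng, aa, protein.signal_len,
                                cfg.polymorphism_rate,
                                min_offset=_EARLY_MATURE_LEN)
        est_id = f"{protein.protein_id}_est{copy_idx + 1}"
        truncate = bool(rng.random() < cfg.truncation_prob)
        est, full = _protein_to_est(rng, est_id, aa, protein.species, tissue,
                                    cfg, truncate)
        library.append(est)
        protein.est_ids.append(est_id)
        protein.est_full_length.append(full)
        truth.est_to_protein[est_id] = protein.protein_id


def simulate_library(config: LibrarySimConfig) -> SimulatedLibrary:
    """Generate the four EST libraries, predictor reports and truth."""
    rng = np.random.default_rng(config.seed)
    truth = LibraryTruth(proteins={}, est_to_protein={})
    mp_sal: List[ESTRecord] = []
    ap_sal: List[ESTRecord] = []
    mp_gut: List[ESTRecord] = []
    mp_extra: List[ESTRecord] = []

    def new_protein(label: str, species: str, pid: str,
                    with_sp: bool = True, tm: bool = False) -> ImplantedProtein:
        lo, hi = config.mature_len_range
        mature = _mature(rng, int(rng.integers(lo, hi + 1)))
        if tm:
            mid = len(mature) // 2
            mature = mature[:mid] + "L" * 21 + mature[mid:]
        if with_sp:
            sp = _signal_peptide(rng)
            aa = sp + mature
            signal_len = len(sp)
        else:
            aa = "M" + mature
            signal_len = 0
        p = ImplantedProtein(protein_id=pid, class_label=label, species=species,
                             aa_seq=aa, signal_len=signal_len,
                             redundancy_group=pid)
        truth.proteins[pid] = p
        return p

    def make_ortholog(parent: ImplantedProtein, pid: str, n_subs: int
                      ) -> ImplantedProtein:
        aa = _mutate_mature(rng, parent.aa_seq, parent.signal_len, n_subs,
                            min_offset=_EARLY_MATURE_LEN)
        p = ImplantedProtein(protein_id=pid, class_label=parent.class_label,
                             species="ap", aa_seq=aa,
                             signal_len=parent.signal_len,
                             ortholog_partner=parent.protein_id,
                             redundancy_group=pid)
        parent.ortholog_partner = pid
        truth.proteins[pid] = p
        return p

    def divergence_subs(mature_len: int) -> int:
        return max(2, round(mature_len * config.ortholog_divergence / 100.0))

    for i in range(config.n_true_candidates):
        p = new_protein("true_candidate", "mp", f"mp_true{i + 1}")
        _implant(rng, truth, mp_sal, p, config.redundancy_multiplicity, config,
                 "salivary_gland", polymorphic_copies=True)
        if rng.random() < config.ortholog_fraction:
            mature_len = len(p.aa_seq) - p.signal_len
            o = make_ortholog(p, f"ap_true{i + 1}", divergence_subs(mature_len))
            _implant(rng, truth, ap_sal, o, config.redundancy_multiplicity,
                     config, "salivary_gland", polymorphic_copies=False)

    for i in range(config.n_tm_decoys):
        p = new_protein("tm_decoy", "mp", f"mp_tm{i + 1}", tm=True)
        _implant(rng, truth, mp_sal, p, 1, config, "salivary_gland",
                 polymorphic_copies=False)

    for i in range(config.n_nonsecreted_decoys):
        p = new_protein("nonsecreted_decoy", "mp", f"mp_nosec{i + 1}",
                        with_sp=False)
        _implant(rng, truth, mp_sal, p, 1, config, "salivary_gland",
                 polymorphic_copies=False)

    for i in range(config.n_monomorphic_decoys):
        p = new_protein("monomorphic_decoy", "mp", f"mp_mono{i + 1}")
        _implant(rng, truth, mp_sal, p, config.redundancy_multiplicity, config,
                 "salivary_gland", polymorphic_copies=False)
        # conserved ortholog: exactly one mature-region difference
        o = make_ortholog(p, f"ap_mono{i + 1}", 1)
        _implant(rng, truth, ap_sal, o, config.redundancy_multiplicity, config,
                 "salivary_gland", polymorphic_copies=False)

    # other-species-only candidates: absent from the first species'
    # salivary library but present (polymorphic) in its full EST set
    for i in range(config.n_other_only):
        p = new_protein("true_candidate", "mp", f"mp_hidden{i + 1}")
        _implant(rng, truth, mp_extra, p, config.redundancy_multiplicity,
                 config, "whole", polymorphic_copies=True)
        mature_len = len(p.aa_seq) - p.signal_len
        o = make_ortholog(p, f"ap_only{i + 1}", divergence_subs(mature_len))
        _implant(rng, truth, ap_sal, o, config.redundancy_multiplicity, config,
                 "salivary_gland", polymorphic_copies=False)

    # gut contamination: verbatim re-reads of the first true candidates
    gut_sources = truth.ids_of_class("true_candidate", "mp")[:config.n_gut_contaminants]
    for j, pid in enumerate(gut_sources):
        p = truth.proteins[pid]
        est_id = f"{pid}_gut{j + 1}"
        est, full = _protein_to_est(rng, est_id, p.aa_seq, "mp", "gut", config,
                                    truncate=False)
        mp_gut.append(est)
        p.est_ids.append(est_id)
        p.est_full_length.append(full)
        truth.est_to_protein[est_id] = pid

    def background(n: int, species: str, tissue: str, tag: str) -> List[ESTRecord]:
        out = []
        for i in range(n):
            est_id = f"{species}_{tag}{i + 1}"
            length = int(rng.integers(300, 901))
            est = ESTRecord(id=est_id, seq=_random_nt(rng, length),
                            species=species, tissue=tissue)
            out.append(est)
            truth.est_to_protein[est_id] = None
        return out

    mp_sal.extend(background(config.n_background_salivary, "mp",
                             "salivary_gland", "bgsal"))
    mp_gut.extend(background(config.n_background_gut, "mp", "gut", "bggut"))
    mp_extra.extend(background(config.n_background_all, "mp", "whole", "bgall"))
    ap_sal.extend(background(config.n_background_salivary, "ap",
                             "salivary_gland", "bgsal"))
    mp_all = mp_sal + mp_extra

    sp_report, tm_report = predictor_reports(mp_all + mp_gut + ap_sal)
    return SimulatedLibrary(config=config, mp_salivary=mp_sal, mp_gut=mp_gut,
                            mp_all=mp_all, ap_salivary=ap_sal,
                            sp_report=sp_report, tm_report=tm_report,
                            truth=truth)


def predictor_reports(ests: Sequence[ESTRecord], min_orf_len: int = 70
                      ) -> Tuple[Dict[str, PredictorReportRow],
                                 Dict[str, PredictorReportRow]]:
    """Run the builtin predictors over every ORF of a library and emit
    report rows in the external dialects (so the parsed-report path can
    be exercised against the same evidence)."""
    sp_rows: Dict[str, PredictorReportRow] = {}
    tm_rows: Dict[str, PredictorReportRow] = {}
    for est in ests:
        if len(est.seq) < 3:
            continue
        for orf in call_orfs(est, min_len=min_orf_len):
            protein = orf.to_protein()
            call = predict_signal_peptide(protein, backend="builtin")
            sp_rows[protein.id] = PredictorReportRow(
                protein_id=protein.id, kind="signal_peptide",
                score=call.score, cleavage_site=call.cleavage_site)
            topo = detect_tm_builtin(protein, call.cleavage_site)
            tm_rows[protein.id] = PredictorReportRow(
                protein_id=protein.id, kind="topology",
                tm_segments=topo.tm_segments)
    return sp_rows, tm_rows


def write_library(sim: SimulatedLibrary, outdir) -> None:
    """Write the simulated experiment as plain-text files."""
    from .io import write_fasta, write_predictor_report
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.mp_salivary, outdir / "mp_salivary.fasta")
    write_fasta(sim.mp_gut, outdir / "mp_gut.fasta")
    write_fasta(sim.mp_all, outdir / "mp_all.fasta")
    write_fasta(sim.ap_salivary, outdir / "ap_salivary.fasta")
    write_predictor_report(list(sim.sp_report.values()),
                           outdir / "signalp3_short.txt", "signalp3_short")
    write_predictor_report(list(sim.tm_report.values()),
                           outdir / "tmhmm_short.txt", "tmhmm_short")
    (outdir / "truth.json").write_text(sim.truth.to_json())


# ---------------------------------------------------------------------------
# fecundity plates


@dataclass(frozen=True)
class PlateSimConfig:
    """Leaf-disc plate simulation: 6 wells x 3 replicates per construct,
    4 first-instar nymphs per well."""

    seed: int
    constructs: Tuple[Tuple[str, float], ...] = (("EV", 1.0),)
    baseline_rate: float = 1.0        # nymphs per adult per count interval
    death_prob: float = 0.05          # per adult per interval
    wells_per_construct: int = 6
    replicates: int = 3
    initial_n: int = 4

    def __post_init__(self) -> None:
        if any(m < 0 for _, m in self.constructs):
            raise ValueError("rate multipliers must be >= 0")
        if not 0.0 <= self.death_prob <= 1.0:
            raise ValueError("death probability must lie in [0, 1]")


def simulate_plate(config: PlateSimConfig) -> List[WellCounts]:
    """Simulate well counts: adults survive each inter-count interval as
    independent coin flips; nymphs are Poisson with mean = surviving
    adults x baseline x construct multiplier.  Wells where every adult
    dies are still emitted — exclusion is the analysis module's job."""
    rng = np.random.default_rng(config.seed)
    p_live = 1.0 - config.death_prob
    wells: List[WellCounts] = []
    for rep in range(1, config.replicates + 1):
        for construct, mult in config.constructs:
            for w in range(1, config.wells_per_construct + 1):
                a6 = int(rng.binomial(config.initial_n, p_live))
                a12 = int(rng.binomial(a6, p_live))
                a14 = int(rng.binomial(a12, p_live))
                lam = config.baseline_rate * mult
                n12 = int(rng.poisson(a6 * lam))
                n14 = int(rng.poisson(a12 * lam))
                n17 = int(rng.poisson(a14 * lam))
                wells.append(WellCounts(
                    construct=construct, replicate=f"rep{rep}",
                    well=f"{construct}_r{rep}_w{w}", A6=a6, A12=a12, A14=a14,
                    N12=n12, N14=n14, N17=n17, initial_n=config.initial_n))
    return wells


# ---------------------------------------------------------------------------
# ROS time courses


def ros_curve(times: np.ndarray, peak: float, t_peak: float = 10.0) -> np.ndarray:
    """Smooth unimodal burst: gamma-shaped rise and decay, maximum
    ``peak`` at ``t_peak``."""
    x = np.clip(times / t_peak, 0.0, None)
    return peak * (x ** 2) * np.exp(2.0 * (1.0 - x))


def simulate_ros(n_discs: int = 8, peak_mean: float = 4000.0,
                 suppression_factor: float = 0.5, noise_sd: float = 400.0,
                 seed: int = 0, t_max: float = 30.0, dt: float = 1.0
                 ) -> Dict[str, List[RosSeries]]:
    """Two-group ROS experiment: an ``EV`` control at full amplitude and
    a ``candidate`` group scaled by ``suppression_factor``; additive
    Gaussian noise truncated at zero."""
    if n_discs < 1:
        raise ValueError("need at least one disc")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max + dt / 2, dt)
    out: Dict[str, List[RosSeries]] = {}
    for construct, factor in (("EV", 1.0), ("candidate", suppression_factor)):
        series = []
        for d in range(1, n_discs + 1):
            clean = ros_curve(times, peak_mean * factor)
            noisy = np.clip(clean + rng.normal(0.0, noise_sd, size=times.shape),
                            0.0, None) if noise_sd > 0 else clean
            series.append(RosSeries(disc_id=f"{construct}_disc{d}",
                                    construct=construct, times=tuple(times),
                                    counts=tuple(float(c) for c in noisy)))
        out[construct] = series
    return out


# ---------------------------------------------------------------------------
# recovery metrics


@dataclass(frozen=True)
class RecoveryMetrics:
    sensitivity: float
    precision: float
    rejection: Dict[str, float]  # per decoy class
    n_true: int
    n_final: int


def evaluate_screen(final_candidates, truth: LibraryTruth,
                    species: str = "mp") -> RecoveryMetrics:
    """Sensitivity/precision of a final candidate set against the truth.

    A candidate maps to its implanted protein through the EST its ORF
    was called on; candidates from background reads count as false
    positives.
    """
    recovered: Dict[str, bool] = {}
    n_true_hits = 0
    for cand in final_candidates:
        est_id = cand.protein.source.est_id if cand.protein.source else None
        pid = truth.est_to_protein.get(est_id)
        label = truth.proteins[pid].class_label if pid else None
        if label == "true_candidate":
            n_true_hits += 1
            recovered[truth.proteins[pid].redundancy_group] = True
    true_ids = truth.ids_of_class("true_candidate", species)
    sensitivity = (sum(1 for pid in true_ids
                       if recovered.get(truth.proteins[pid].redundancy_group))
                   / len(true_ids)) if true_ids else float("nan")
    precision = n_true_hits / len(final_candidates) if final_candidates else float("nan")

    rejection = {}
    final_pids = set()
    for cand in final_candidates:
        est_id = cand.protein.source.est_id if cand.protein.source else None
        pid = truth.est_to_protein.get(est_id)
        if pid:
            final_pids.add(pid)
    for label in ("tm_decoy", "nonsecreted_decoy", "monomorphic_decoy"):
        ids = truth.ids_of_class(label, species)
        if ids:
            rejection[label] = sum(1 for pid in ids if pid not in final_pids) / len(ids)
    return RecoveryMetrics(sensitivity=sensitivity, precision=precision,
                           rejection=rejection, n_true=len(true_ids),
                           n_final=len(final_candidates))
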