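"""The candidate-selection cascade.

Starting from called ORFs, the cascade keeps a translated ORF as a
candidate effector when it

1. carries a signal peptide (score strictly > 0.9, cleavage within
   residues 1-30),
2. is non-redundant (single-linkage clustering of near-identical
   sequences; one representative per cluster),
3. has no transmembrane segment in the mature region,
4. is judged full-length from EST alignment evidence, and
5. shows amino-acid polymorphism consistent with diversifying
   selection (monomorphic sequences whose other-species ortholog is
   near-identical are removed).

Candidates from a second species are then reconciled: overlapping pairs
are recorded, and unmatched other-species candidates are searched back
against the first species' full EST set to recover candidates the
salivary-gland library missed.  Gut-library matches are flagged (not
removed) as possible dissection contaminants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .align import (
    DEFAULT_MATRIX,
    AlignmentResult,
    SubstitutionMatrix,
    align_local,
    align_strings,
    evalue as _evalue,
    translated_search,
)
from .records import ESTRecord, ProteinRecord
from .secretion import MatureProtein, SignalPeptideCall, TopologyCall


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable threshold of the mining cascade.

    ``homolog_evalue`` governs translated homolog searches (1e-5);
    a stricter 1e-15 is used for gut-contamination matches.  The
    full-length rule combines the three criteria as
    ``c1 or (c2 and c3)`` by default ("start/stop directly confirmed, or
    no upstream start plus a full-length ortholog"); ``any_of`` and
    ``all_of`` are available.
    """

    min_orf_len: int = 70
    sp_score_cutoff: float = 0.9          # strict >
    cleavage_window: Tuple[int, int] = (1, 30)
    redundancy_identity: float = 95.0     # strict >, percent
    redundancy_evalue: float = 1e-10
    redundancy_coverage: float = 0.8      # fraction of the shorter sequence
    overlap_evalue: float = 1e-5
    homolog_evalue: float = 1e-5
    gut_evalue: float = 1e-15
    max_ap_mature_diff: int = 1
    fulllength_rule: str = "c1_or_c2c3"   # | "any_of" | "all_of"
    min_start_stop_support: int = 2       # ESTs confirming start+stop for criterion 1
    ortholog_fulllength_coverage: float = 0.9
    polymorphism_min_identity: float = 90.0  # hits below this are paralogs, not copies
    filter_added_candidates: bool = True  # re-added candidates face the same gates

    def __post_init__(self) -> None:
        if self.redundancy_evalue <= 0 or self.homolog_evalue <= 0 \
                or self.overlap_evalue <= 0 or self.gut_evalue <= 0:
            raise ValueError("E-value thresholds must be positive")
        if not 0 < self.redundancy_coverage <= 1:
            raise ValueError("redundancy_coverage must be in (0, 1]")
        if self.cleavage_window[0] < 1 or self.cleavage_window[1] < self.cleavage_window[0]:
            raise ValueError("invalid cleavage window")


DEFAULT_CONFIG = PipelineConfig()


@dataclass(frozen=True)
class Cluster:
    representative: ProteinRecord
    members: Tuple[ProteinRecord, ...]

    def __post_init__(self) -> None:
        if self.representative.id not in {m.id for m in self.members}:
            raise ValueError("cluster representative must be a member")


@dataclass(frozen=True)
class FullLengthCall:
    protein_id: str
    criterion1_start_stop: bool
    criterion2_no_upstream_met: bool
    criterion3_ortholog_support: bool
    is_full_length: bool


@dataclass
class CandidateEffector:
    """A named candidate with full provenance through the cascade."""

    protein: ProteinRecord          # full ORF translation (signal peptide included)
    mature: MatureProtein
    sp_call: SignalPeptideCall
    topology: TopologyCall
    species: str
    cluster: Optional[Cluster] = None
    name: str = ""
    full_length: Optional[FullLengthCall] = None
    polymorphic: Optional[bool] = None
    polymorphism_reason: str = ""
    shared_with_other_species: bool = False
    added_from_other_species: bool = False
    gut_match: bool = False
    csp_motif: Optional[Tuple[int, ...]] = None

    @property
    def id(self) -> str:
        return self.protein.id


FUNNEL_STAGES = (
    "ests_in",
    "orfs_called",
    "with_signal_peptide_nonredundant",
    "with_tm_removed",
    "predicted_secreted",
    "full_length",
    "after_polymorphism_filter",
    "added_cross_species",
    "final_candidates",
)


@dataclass(frozen=True)
class FunnelReport:
    """Ordered per-stage candidate counts of the mining cascade.

    Counts never increase from one stage to the next, with two
    exceptions: the EST → ORF transition (one read can yield several
    ORFs) and the cross-species addition stage.
    """

    stages: Tuple[Tuple[str, int], ...]

    _MAY_INCREASE = ("orfs_called", "added_cross_species")

    def __post_init__(self) -> None:
        prev = None
        for name, count in self.stages:
            if count < 0:
                raise ValueError(f"negative count at stage {name}")
            if prev is not None and name not in self._MAY_INCREASE and count > prev:
                raise ValueError(
                    f"stage {name} increased the candidate count ({prev} -> {count})")
            prev = count

    def as_dict(self) -> Dict[str, int]:
        return dict(self.stages)

    def to_json(self) -> str:
        return json.dumps([{"stage": s, "count": c} for s, c in self.stages])

    def to_text(self) -> str:
        width = max(len(s) for s, _ in self.stages)
        return "\n".join(f"{s:<{width}}  {c}" for s, c in self.stages)


def build_funnel_report(counts: Dict[str, int]) -> FunnelReport:
    missing = [s for s in FUNNEL_STAGES if s not in counts]
    if missing:
        raise ValueError(f"missing funnel stages: {', '.join(missing)}")
    return FunnelReport(tuple((s, counts[s]) for s in FUNNEL_STAGES))


# ---------------------------------------------------------------------------
# redundancy clustering


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def redundancy_edge(result: AlignmentResult, len_a: int, len_b: int,
                    config: PipelineConfig = DEFAULT_CONFIG) -> bool:
    """Two sequences are redundant copies when they align at > 95%
    identity with E < 1e-10 over at least 80% of the shorter sequence."""
    shorter_cov = result.coverage_query if len_a <= len_b else result.coverage_subject
    return (result.identity_pct > config.redundancy_identity
            and result.evalue < config.redundancy_evalue
            and shorter_cov >= config.redundancy_coverage)


def cluster_redundant(proteins: Sequence[ProteinRecord],
                      config: PipelineConfig = DEFAULT_CONFIG,
                      matrix: SubstitutionMatrix = DEFAULT_MATRIX) -> List[Cluster]:
    """Single-linkage clustering under the redundancy edge predicate.

    Clusters partition the input; the representative is the longest
    member, ties broken by lexicographically smallest id.  Cluster order
    follows the input order of each cluster's first member.
    """
    if not proteins:
        raise ValueError("cannot cluster an empty protein set")
    from .align import _aligner_for  # score-only prefilter
    aligner = _aligner_for(matrix)
    uf = _UnionFind(len(proteins))
    seqs = [p.residues for p in proteins]
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            if uf.find(i) == uf.find(j):
                continue
            score = aligner.score(seqs[i], seqs[j])
            if score <= 0:
                continue
            # E-value is monotone in score: skip traceback for hopeless pairs
            if _evalue(score, len(seqs[i]), len(seqs[j])) >= config.redundancy_evalue:
                continue
            res = align_strings(proteins[i].id, seqs[i], proteins[j].id, seqs[j],
                                matrix)
            if redundancy_edge(res, len(seqs[i]), len(seqs[j]), config):
                uf.union(i, j)
    groups: Dict[int, List[int]] = {}
    for i in range(len(proteins)):
        groups.setdefault(uf.find(i), []).append(i)
    clusters = []
    for root in sorted(groups, key=lambda r: min(groups[r])):
        members = tuple(proteins[i] for i in groups[root])
        rep = max(members, key=lambda p: (len(p), _neg_lex(p.id)))
        clusters.append(Cluster(representative=rep, members=members))
    return clusters


def _neg_lex(s: str):
    # max() helper: prefer lexicographically smaller id on length ties
    return tuple(-ord(c) for c in s)


# ---------------------------------------------------------------------------
# full-length assessment


def _supports_start_stop(hit: AlignmentResult, query_len: int) -> bool:
    if hit.query_span != (1, query_len) or not hit.query_aln:
        return False
    if hit.subject_aln[0] != "M":
        return False
    trans = hit.subject_translation
    if trans is None:
        return False
    s_end = hit.subject_span[1]  # 1-based inclusive on the frame translation
    return s_end < len(trans) and trans[s_end] == "*"


def _upstream_met(hit: AlignmentResult) -> bool:
    """True when the subject read carries an in-frame Met upstream of the
    residue aligned to the candidate start, with no intervening stop."""
    if hit.query_span[0] != 1 or hit.subject_translation is None:
        return False
    for c in reversed(hit.subject_translation[: hit.subject_span[0] - 1]):
        if c == "*":
            return False
        if c == "M":
            return True
    return False


def assess_full_length(protein: ProteinRecord,
                       est_hits: Sequence[AlignmentResult],
                       ortholog_hits: Sequence[AlignmentResult],
                       config: PipelineConfig = DEFAULT_CONFIG) -> FullLengthCall:
    """Judge whether a candidate ORF encodes a complete protein.

    ``est_hits`` are translated-search hits against all same-species
    ESTs; ``ortholog_hits`` are alignments against other-species proteins
    already annotated full-length.  Criterion 1: at least
    ``min_start_stop_support`` ESTs align over the entire candidate with
    the start Met and the stop position conserved.  Criterion 2: no
    supporting EST shows an in-frame Met upstream of the candidate start.
    Criterion 3: some full-length ortholog is covered to >= 90%.
    """
    qlen = len(protein)
    supporting = [h for h in est_hits if h.evalue < config.homolog_evalue]
    n_start_stop = sum(_supports_start_stop(h, qlen) for h in supporting)
    c1 = n_start_stop >= config.min_start_stop_support
    c2 = not any(_upstream_met(h) for h in supporting)
    c3 = any(h.evalue < config.homolog_evalue
             and h.coverage_subject >= config.ortholog_fulllength_coverage
             for h in ortholog_hits)
    if config.fulllength_rule == "c1_or_c2c3":
        full = c1 or (c2 and c3)
    elif config.fulllength_rule == "any_of":
        full = c1 or c2 or c3
    elif config.fulllength_rule == "all_of":
        full = c1 and c2 and c3
    else:
        raise ValueError(f"unknown full-length rule {config.fulllength_rule!r}")
    return FullLengthCall(protein_id=protein.id, criterion1_start_stop=c1,
                          criterion2_no_upstream_met=c2,
                          criterion3_ortholog_support=c3, is_full_length=full)


# ---------------------------------------------------------------------------
# polymorphism (diversifying-selection) filter


def polymorphism_filter(candidate: CandidateEffector,
                        same_species_hits: Sequence[AlignmentResult],
                        ortholog_best: Optional[AlignmentResult],
                        config: PipelineConfig = DEFAULT_CONFIG) -> Tuple[bool, str]:
    """Keep candidates showing evidence of diversifying selection.

    A candidate is dropped when its same-species EST alignments show no
    amino-acid variation AND its best other-species mature-region
    alignment differs by at most ``max_ap_mature_diff`` residues (or no
    ortholog alignment exists at all).  Only near-identical hits
    spanning most of the candidate count as copies of the same
    transcript; short or weak hits are paralogs (or shared signal
    peptides) and say nothing about polymorphism.
    Returns (keep, reason).
    """
    copies = [h for h in same_species_hits
              if h.evalue < config.homolog_evalue
              and h.identity_pct >= config.polymorphism_min_identity
              and h.coverage_query >= config.redundancy_coverage]
    variation = any(h.n_mismatches > 0 for h in copies)
    if variation:
        return True, "same_species_variation"
    if ortholog_best is None:
        return False, "monomorphic_no_ortholog"
    diffs = ortholog_best.n_columns - ortholog_best.n_identities
    if diffs <= config.max_ap_mature_diff:
        return False, "monomorphic_conserved_ortholog"
    return True, "ortholog_diverged"


# ---------------------------------------------------------------------------
# motif scan, gut flags, cross-species reconciliation, naming


CSP_GAPS = (6, 18, 2)  # the chemosensory-protein cysteine spacing C-x6-C-x18-C-x2-C


def scan_csp_motif(mature_seq: str, all_occurrences: bool = False):
    """Scan for the conserved chemosensory-protein cysteine pattern
    C-x(6)-C-x(18)-C-x(2)-C.

    Returns the 1-based start position of the first occurrence (or a
    tuple of all occurrences when requested), else ``None``/empty tuple.
    """
    span = 4 + sum(CSP_GAPS)  # 30 residues
    offsets = (0, 1 + CSP_GAPS[0], 2 + CSP_GAPS[0] + CSP_GAPS[1],
               3 + CSP_GAPS[0] + CSP_GAPS[1] + CSP_GAPS[2])
    matches = []
    for i in range(len(mature_seq) - span + 1):
        if all(mature_seq[i + off] == "C" for off in offsets):
            if not all_occurrences:
                return i + 1
            matches.append(i + 1)
    return tuple(matches) if all_occurrences else None


def flag_gut_matches(candidates: Sequence[CandidateEffector],
                     gut_ests: Sequence[ESTRecord],
                     config: PipelineConfig = DEFAULT_CONFIG,
                     matrix: SubstitutionMatrix = DEFAULT_MATRIX) -> List[bool]:
    """Flag candidates whose protein matches the gut EST library.

    Gut matches suggest salivary-gland dissection contaminants; flagged,
    never removed.  The flag is the max over the library, hence
    invariant to record order.
    """
    flags = []
    for cand in candidates:
        hit = False
        for est in gut_ests:
            res = translated_search(cand.protein, est, matrix,
                                    evalue_cutoff=config.gut_evalue)
            if not res.degenerate and res.evalue < config.gut_evalue:
                hit = True
                break
        cand.gut_match = hit
        flags.append(hit)
    return flags


def reconcile_cross_species(
    first_candidates: Sequence[CandidateEffector],
    other_candidates: Sequence[CandidateEffector],
    first_all_ests: Sequence[ESTRecord],
    config: PipelineConfig = DEFAULT_CONFIG,
    matrix: SubstitutionMatrix = DEFAULT_MATRIX,
    sp_backend: str = "builtin",
    sp_report: Optional[Dict] = None,
    tm_report: Optional[Dict] = None,
) -> Tuple[List[Tuple[CandidateEffector, CandidateEffector]], List[CandidateEffector]]:
    """Reconcile candidate sets from the two species.

    Candidate pairs whose *mature* proteins align below
    ``overlap_evalue`` are shared (signal peptides are compositionally
    constrained — one hydrophobic core looks much like another — so they
    are excluded from the overlap decision).  Each unmatched
    other-species candidate is translated-searched against the first
    species' full EST set; an EST hit whose ORF passes the secretion
    gate yields an added first-species candidate (unless it is redundant
    with an existing one).
    """
    from .pipeline import gate_orfs_of_est  # late import; no cycle at call time

    shared: List[Tuple[CandidateEffector, CandidateEffector]] = []
    unmatched: List[CandidateEffector] = []
    for other in other_candidates:
        best: Optional[Tuple[float, CandidateEffector, AlignmentResult]] = None
        for mine in first_candidates:
            res = align_strings(other.id, other.mature.mature_seq,
                                mine.id, mine.mature.mature_seq, matrix)
            if res.degenerate or res.evalue >= config.overlap_evalue:
                continue
            if best is None or res.score > best[0]:
                best = (res.score, mine, res)
        if best is not None:
            mine = best[1]
            mine.shared_with_other_species = True
            other.shared_with_other_species = True
            shared.append((mine, other))
        else:
            unmatched.append(other)

    added: List[CandidateEffector] = []
    existing = [c.protein for c in first_candidates]
    for other in unmatched:
        est_best: Optional[Tuple[float, ESTRecord]] = None
        for est in first_all_ests:
            res = translated_search(other.protein, est, matrix,
                                    evalue_cutoff=config.homolog_evalue)
            if res.degenerate or res.evalue >= config.homolog_evalue:
                continue
            if est_best is None or res.score > est_best[0]:
                est_best = (res.score, est)
        if est_best is None:
            continue
        gated = gate_orfs_of_est(est_best[1], config, sp_backend=sp_backend,
                                 sp_report=sp_report, tm_report=tm_report)
        if not gated:
            continue
        # among the EST's gated ORFs take the one most similar to the probe
        new = max(gated, key=lambda c: align_local(other.protein, c.protein,
                                                   matrix).score)
        dup = any(
            redundancy_edge(align_local(new.protein, p, matrix),
                            len(new.protein), len(p), config)
            for p in existing)
        if dup:
            continue
        new.added_from_other_species = True
        new.shared_with_other_species = True
        existing.append(new.protein)
        added.append(new)
    return shared, added


def name_candidates(candidates: Sequence[CandidateEffector],
                    legacy_names: Optional[Dict[str, str]] = None) -> List[str]:
    """Assign serial names (Mp1, Mp2, ... / Ap1, ...) in input order.

    ``legacy_names`` maps a candidate's protein id to an externally
    supplied historical name (e.g. ``MpC002``), which is honoured
    verbatim.  Names must come out unique.
    """
    legacy_names = legacy_names or {}
    counters: Dict[str, int] = {}
    names = []
    for cand in candidates:
        if cand.id in legacy_names:
            cand.name = legacy_names[cand.id]
        else:
            prefix = cand.species.capitalize() if cand.species else "X"
            counters[prefix] = counters.get(prefix, 0) + 1
            cand.name = f"{prefix}{counters[prefix]}"
        names.append(cand.name)
    if len(set(names)) != len(names):
        raise ValueError("candidate names are not unique")
    return names


def candidate_table(candidates: Sequence[CandidateEffector]) -> str:
    """Render the final candidate set as a TSV table."""
    header = ("name", "protein_id", "length", "cleavage_site", "full_length",
              "polymorphic", "shared_with_other_species",
              "added_from_other_species", "gut_match", "csp_motif")
    lines = ["\t".join(header)]
    for c in candidates:
        lines.append("\t".join(str(v) for v in (
            c.name, c.id, len(c.protein), c.sp_call.cleavage_site,
            c.full_length.is_full_length if c.full_length else "",
            c.polymorphic, c.shared_with_other_species,
            c.added_from_other_species, c.gut_match,
            c.csp_motif if c.csp_motif is not None else "-")))
    return "\n".join(lines) + "\n"
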