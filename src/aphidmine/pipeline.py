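"""End-to-end orchestration of the mining cascade.

:func:`mine_secreted` takes one EST library to the predicted-secretome
stage (ORFs → signal peptide → non-redundant → no TM).
:func:`run_screen` runs the full two-species screen: both secretomes,
full-length assessment, the polymorphism filter, cross-species
reconciliation, gut flagging, motif annotation, naming, and the funnel
report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .align import DEFAULT_MATRIX, AlignmentResult, SubstitutionMatrix, \
    align_strings, translated_search
from .orfs import ORFCandidate, call_orfs
from .records import ESTRecord, PredictorReportRow, ProteinRecord
from .secretion import (
    cleave,
    detect_tm_builtin,
    passes_secretion_gate,
    predict_signal_peptide,
    topology_from_report,
)
from .selection import (
    DEFAULT_CONFIG,
    CandidateEffector,
    Cluster,
    FunnelReport,
    PipelineConfig,
    assess_full_length,
    build_funnel_report,
    cluster_redundant,
    flag_gut_matches,
    name_candidates,
    polymorphism_filter,
    reconcile_cross_species,
    scan_csp_motif,
)

ReportDict = Dict[str, PredictorReportRow]


def _candidate_from_protein(protein: ProteinRecord, species: str,
                            config: PipelineConfig,
                            sp_backend: str, sp_report: Optional[ReportDict],
                            tm_report: Optional[ReportDict]
                            ) -> Optional[CandidateEffector]:
    """Gate one ORF protein through the secretion criteria."""
    call = predict_signal_peptide(protein, backend=sp_backend, report=sp_report)
    if not (call.score > config.sp_score_cutoff
            and config.cleavage_window[0] <= call.cleavage_site
            <= config.cleavage_window[1]):
        return None
    if call.cleavage_site >= len(protein):
        return None
    if tm_report is not None and protein.id in tm_report:
        topo = topology_from_report(tm_report[protein.id], call.cleavage_site)
    else:
        topo = detect_tm_builtin(protein, call.cleavage_site)
    passed, _reason = passes_secretion_gate(
        call, topo, config.sp_score_cutoff, config.cleavage_window)
    if not passed:
        return None
    return CandidateEffector(protein=protein, mature=cleave(protein, call),
                             sp_call=call, topology=topo, species=species)


def gate_orfs_of_est(est: ESTRecord, config: PipelineConfig = DEFAULT_CONFIG,
                     sp_backend: str = "builtin",
                     sp_report: Optional[ReportDict] = None,
                     tm_report: Optional[ReportDict] = None
                     ) -> List[CandidateEffector]:
    """Call ORFs on one EST and return those passing the secretion gate."""
    out = []
    for orf in call_orfs(est, min_len=config.min_orf_len):
        cand = _candidate_from_protein(orf.to_protein(), est.species, config,
                                       sp_backend, sp_report, tm_report)
        if cand is not None:
            out.append(cand)
    return out


@dataclass
class MiningResult:
    """One library taken to the predicted-secretome stage."""

    species: str
    ests: List[ESTRecord]
    orfs: List[ORFCandidate]
    sp_positive: List[ProteinRecord]
    clusters: List[Cluster]
    secreted: List[CandidateEffector]  # non-redundant, signal peptide, no TM
    n_tm_removed: int = 0

    @property
    def counts(self) -> Dict[str, int]:
        return {
            "ests_in": len(self.ests),
            "orfs_called": len(self.orfs),
            "with_signal_peptide_nonredundant": len(self.clusters),
            "with_tm_removed": len(self.secreted),
            "predicted_secreted": len(self.secreted),
        }


def mine_secreted(ests: Sequence[ESTRecord],
                  config: PipelineConfig = DEFAULT_CONFIG,
                  sp_backend: str = "builtin",
                  sp_report: Optional[ReportDict] = None,
                  tm_report: Optional[ReportDict] = None,
                  matrix: SubstitutionMatrix = DEFAULT_MATRIX) -> MiningResult:
    """ESTs → ORFs → signal-peptide positive → non-redundant → no TM.

    Clustering happens among signal-peptide-positive ORFs (so each
    secreted protein is counted once) and the TM filter is applied to
    cluster representatives, mirroring the cascade order of the screen.
    """
    ests = list(ests)
    if not ests:
        raise ValueError("empty EST library")
    species = ests[0].species
    orfs: List[ORFCandidate] = []
    for est in ests:
        if len(est.seq) >= 3:
            orfs.extend(call_orfs(est, min_len=config.min_orf_len))

    backend = "parsed_report" if sp_report is not None else sp_backend
    sp_calls = {}
    sp_positive: List[ProteinRecord] = []
    for orf in orfs:
        protein = orf.to_protein()
        call = predict_signal_peptide(protein, backend=backend, report=sp_report)
        sp_calls[protein.id] = call
        if (call.score > config.sp_score_cutoff
                and config.cleavage_window[0] <= call.cleavage_site
                <= config.cleavage_window[1]
                and call.cleavage_site < len(protein)):
            sp_positive.append(protein)

    secreted: List[CandidateEffector] = []
    clusters: List[Cluster] = []
    n_tm = 0
    if sp_positive:
        clusters = cluster_redundant(sp_positive, config, matrix)
        for cluster in clusters:
            rep = cluster.representative
            call = sp_calls[rep.id]
            if tm_report is not None and rep.id in tm_report:
                topo = topology_from_report(tm_report[rep.id], call.cleavage_site)
            else:
                topo = detect_tm_builtin(rep, call.cleavage_site)
            if topo.has_tm_in_mature:
                n_tm += 1
                continue
            secreted.append(CandidateEffector(
                protein=rep, mature=cleave(rep, call), sp_call=call,
                topology=topo, species=species, cluster=cluster))
    return MiningResult(species=species, ests=ests, orfs=orfs,
                        sp_positive=sp_positive, clusters=clusters,
                        secreted=secreted, n_tm_removed=n_tm)


def _est_hits(candidate: CandidateEffector, ests: Sequence[ESTRecord],
              config: PipelineConfig, matrix: SubstitutionMatrix
              ) -> List[AlignmentResult]:
    hits = []
    for est in ests:
        res = translated_search(candidate.protein, est, matrix,
                                evalue_cutoff=config.homolog_evalue)
        if not res.degenerate and res.evalue < config.homolog_evalue:
            hits.append(res)
    return hits


def _ortholog_hits(candidate: CandidateEffector,
                   full_length_orthologs: Sequence[CandidateEffector],
                   config: PipelineConfig, matrix: SubstitutionMatrix
                   ) -> List[AlignmentResult]:
    hits = []
    for other in full_length_orthologs:
        res = align_strings(candidate.id, candidate.protein.residues,
                            other.id, other.protein.residues, matrix)
        if not res.degenerate and res.evalue < config.homolog_evalue:
            hits.append(res)
    return hits


def _best_mature_alignment(candidate: CandidateEffector,
                           others: Sequence[CandidateEffector],
                           config: PipelineConfig, matrix: SubstitutionMatrix
                           ) -> Optional[AlignmentResult]:
    best: Optional[AlignmentResult] = None
    for other in others:
        res = align_strings(candidate.id, candidate.mature.mature_seq,
                            other.id, other.mature.mature_seq, matrix)
        if res.degenerate or res.evalue >= config.homolog_evalue:
            continue
        if best is None or res.score > best.score:
            best = res
    return best


@dataclass
class ScreenResult:
    """Everything the two-species screen produces."""

    candidates: List[CandidateEffector]       # final first-species set
    other_candidates: List[CandidateEffector]  # other-species full-length set
    shared_pairs: List[Tuple[CandidateEffector, CandidateEffector]]
    funnel: FunnelReport
    mining: MiningResult
    other_mining: MiningResult
    full_length: List[CandidateEffector] = field(default_factory=list)
    after_polymorphism: List[CandidateEffector] = field(default_factory=list)
    added: List[CandidateEffector] = field(default_factory=list)


def run_screen(salivary_ests: Sequence[ESTRecord],
               other_salivary_ests: Sequence[ESTRecord],
               all_ests: Optional[Sequence[ESTRecord]] = None,
               gut_ests: Optional[Sequence[ESTRecord]] = None,
               config: PipelineConfig = DEFAULT_CONFIG,
               sp_report: Optional[ReportDict] = None,
               tm_report: Optional[ReportDict] = None,
               other_sp_report: Optional[ReportDict] = None,
               other_tm_report: Optional[ReportDict] = None,
               legacy_names: Optional[Dict[str, str]] = None,
               matrix: SubstitutionMatrix = DEFAULT_MATRIX) -> ScreenResult:
    """Run the complete two-species candidate-effector screen.

    ``all_ests`` is the first species' full EST collection (defaults to
    the salivary library) used for full-length support, polymorphism
    evidence and cross-species homolog recovery.  The polymorphism
    filter applies to the first species only; the second species
    contributes ortholog evidence, overlap pairs and recovered
    candidates, mirroring the asymmetric design of the screen.
    """
    all_ests = list(all_ests) if all_ests is not None else list(salivary_ests)
    mining = mine_secreted(salivary_ests, config, sp_report=sp_report,
                           tm_report=tm_report, matrix=matrix)
    other_mining = mine_secreted(other_salivary_ests, config,
                                 sp_report=other_sp_report,
                                 tm_report=other_tm_report, matrix=matrix)

    # other-species full-length set: same rule, judged from its own ESTs
    other_full: List[CandidateEffector] = []
    for cand in other_mining.secreted:
        hits = _est_hits(cand, other_mining.ests, config, matrix)
        cand.full_length = assess_full_length(cand.protein, hits, [], config)
        if cand.full_length.is_full_length:
            other_full.append(cand)

    # first species: full-length assessment with ortholog support
    full_length: List[CandidateEffector] = []
    est_hit_cache: Dict[str, List[AlignmentResult]] = {}
    for cand in mining.secreted:
        hits = _est_hits(cand, all_ests, config, matrix)
        est_hit_cache[cand.id] = hits
        orth = _ortholog_hits(cand, other_full, config, matrix)
        cand.full_length = assess_full_length(cand.protein, hits, orth, config)
        if cand.full_length.is_full_length:
            full_length.append(cand)

    # polymorphism filter (first species only)
    kept: List[CandidateEffector] = []
    for cand in full_length:
        ap_best = _best_mature_alignment(cand, other_mining.secreted, config,
                                         matrix)
        keep, reason = polymorphism_filter(cand, est_hit_cache[cand.id],
                                           ap_best, config)
        cand.polymorphic, cand.polymorphism_reason = keep, reason
        if keep:
            kept.append(cand)

    # cross-species reconciliation
    shared, added = reconcile_cross_species(
        kept, other_full, all_ests, config, matrix,
        sp_backend="builtin", sp_report=sp_report, tm_report=tm_report)
    if config.filter_added_candidates:
        screened_added = []
        for cand in added:
            hits = _est_hits(cand, all_ests, config, matrix)
            orth = _ortholog_hits(cand, other_full, config, matrix)
            cand.full_length = assess_full_length(cand.protein, hits, orth,
                                                  config)
            if not cand.full_length.is_full_length:
                continue
            ap_best = _best_mature_alignment(cand, other_mining.secreted,
                                             config, matrix)
            keep, reason = polymorphism_filter(cand, hits, ap_best, config)
            cand.polymorphic, cand.polymorphism_reason = keep, reason
            if keep:
                screened_added.append(cand)
        added = screened_added
    final = kept + added

    if gut_ests:
        flag_gut_matches(final, gut_ests, config, matrix)
    for cand in final + other_full:
        cand.csp_motif = scan_csp_motif(cand.mature.mature_seq,
                                        all_occurrences=True) or None
    name_candidates(final, legacy_names)
    name_candidates(other_full)

    counts = dict(mining.counts)
    counts["full_length"] = len(full_length)
    counts["after_polymorphism_filter"] = len(kept)
    counts["added_cross_species"] = len(final)
    counts["final_candidates"] = len(final)
    funnel = build_funnel_report(counts)
    return ScreenResult(candidates=final, other_candidates=other_full,
                        shared_pairs=shared, funnel=funnel, mining=mining,
                        other_mining=other_mining, full_length=full_length,
                        after_polymorphism=kept, added=added)
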