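"""Local protein alignment and translated search.

All-vs-all Smith-Waterman (affine gaps, BLOSUM62, 11/1 by default)
replaces heuristic database search: at the scale of a few thousand
translated ORFs exhaustive alignment is tractable and removes an
external binary.  Alignment itself is delegated to Biopython's
``PairwiseAligner`` (C implementation); this module adds the identity /
coverage statistics the selection cascade filters on and a
Karlin-Altschul E-value surrogate

    E = K * m * n * exp(-lambda * S)

with the published gapped-BLOSUM62 constants (lambda = 0.267,
K = 0.041), so E-value thresholds keep their conventional meaning.
The surrogate approximates, it does not equal, database-search E-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .orfs import reverse_complement, translate_frame
from .records import ESTRecord, ProteinRecord


@dataclass(frozen=True)
class KarlinAltschulParams:
    """Constants of the extreme-value score distribution (gapped BLOSUM62/11,1)."""

    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")


DEFAULT_KA = KarlinAltschulParams()


def _blosum62_star_patched():
    m = substitution_matrices.load("BLOSUM62").copy()
    # stop sentinel scores -4 against everything, including itself
    for c in m.alphabet:
        m["*", c] = -4.0
        m[c, "*"] = -4.0
    return m


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A scoring matrix plus affine gap penalties (BLAST-style: a gap of
    length g costs gap_open + g * gap_extend)."""

    name: str = "BLOSUM62"
    scores: object = field(default_factory=_blosum62_star_patched)
    gap_open: int = 11
    gap_extend: int = 1

    def score(self, a: str, b: str) -> float:
        return float(self.scores[a, b])


DEFAULT_MATRIX = SubstitutionMatrix()

_ALIGNER_CACHE: dict = {}


def _aligner_for(matrix: SubstitutionMatrix) -> Align.PairwiseAligner:
    key = id(matrix)
    aligner = _ALIGNER_CACHE.get(key)
    if aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = matrix.scores
        # first gap residue costs open+extend, each further residue extend
        aligner.open_gap_score = -(matrix.gap_open + matrix.gap_extend)
        aligner.extend_gap_score = -matrix.gap_extend
        _ALIGNER_CACHE[key] = aligner
    return aligner


def evalue(score: float, m: int, n: int,
           params: KarlinAltschulParams = DEFAULT_KA) -> float:
    """Expected number of chance local alignments scoring >= S."""
    if score < 0:
        raise ValueError("score must be non-negative")
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return params.K * m * n * math.exp(-params.lam * score)


@dataclass(frozen=True)
class AlignmentResult:
    """One local alignment with the statistics the cascade filters on.

    ``identity_pct`` counts identities over *all* alignment columns, gaps
    included; coverages are aligned-span length over sequence length.
    Spans are 1-based inclusive; a (0, 0) span marks a degenerate (empty)
    alignment.
    """

    query_id: str
    subject_id: str
    score: float
    identity_pct: float
    coverage_query: float
    coverage_subject: float
    query_span: Tuple[int, int]
    subject_span: Tuple[int, int]
    evalue: float
    n_columns: int = 0
    n_identities: int = 0
    n_mismatches: int = 0
    query_aln: str = ""
    subject_aln: str = ""
    degenerate: bool = False
    strand: Optional[str] = None           # set by translated_search
    frame: Optional[int] = None            # set by translated_search
    subject_translation: Optional[str] = None

    def as_tabular(self) -> str:
        """BLAST outfmt-6-like row."""
        return "\t".join(str(v) for v in (
            self.query_id, self.subject_id, f"{self.identity_pct:.2f}",
            self.n_columns, f"{self.score:g}", f"{self.evalue:.3g}",
            self.query_span[0], self.query_span[1],
            self.subject_span[0], self.subject_span[1]))


def _degenerate_result(qid: str, qseq: str, sid: str, n_for_e: int,
                       params: KarlinAltschulParams) -> AlignmentResult:
    return AlignmentResult(
        query_id=qid, subject_id=sid, score=0.0, identity_pct=0.0,
        coverage_query=0.0, coverage_subject=0.0,
        query_span=(0, 0), subject_span=(0, 0),
        evalue=evalue(0.0, max(len(qseq), 1), max(n_for_e, 1), params),
        degenerate=True)


def align_strings(qid: str, qseq: str, sid: str, sseq: str,
                  matrix: SubstitutionMatrix = DEFAULT_MATRIX,
                  params: KarlinAltschulParams = DEFAULT_KA,
                  n_for_evalue: Optional[int] = None) -> AlignmentResult:
    """Smith-Waterman on raw strings (the engine behind align_local).

    ``n_for_evalue`` overrides the subject length entering the E-value
    (used by translated search, where n is the nucleotide length).
    """
    if not qseq or not sseq:
        raise ValueError("cannot align empty sequences")
    n_e = n_for_evalue if n_for_evalue is not None else len(sseq)
    aligner = _aligner_for(matrix)
    score = aligner.score(qseq, sseq)
    if score <= 0:
        return _degenerate_result(qid, qseq, sid, n_e, params)

    alignment = next(iter(aligner.align(qseq, sseq)))
    q_aln, s_aln = str(alignment[0]), str(alignment[1])
    n_cols = len(q_aln)
    n_ident = sum(1 for a, b in zip(q_aln, s_aln) if a == b and a != "-")
    n_mis = sum(1 for a, b in zip(q_aln, s_aln)
                if a != "-" and b != "-" and a != b)
    (q_blocks, s_blocks) = alignment.aligned
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    s_start, s_end = int(s_blocks[0][0]), int(s_blocks[-1][1])
    return AlignmentResult(
        query_id=qid, subject_id=sid, score=float(score),
        identity_pct=100.0 * n_ident / n_cols,
        coverage_query=(q_end - q_start) / len(qseq),
        coverage_subject=(s_end - s_start) / len(sseq),
        query_span=(q_start + 1, q_end),
        subject_span=(s_start + 1, s_end),
        evalue=evalue(float(score), len(qseq), n_e, params),
        n_columns=n_cols, n_identities=n_ident, n_mismatches=n_mis,
        query_aln=q_aln, subject_aln=s_aln)


def align_local(a: ProteinRecord, b: ProteinRecord,
                matrix: SubstitutionMatrix = DEFAULT_MATRIX,
                params: KarlinAltschulParams = DEFAULT_KA) -> AlignmentResult:
    """Optimal local alignment between two proteins."""
    return align_strings(a.id, a.residues, b.id, b.residues, matrix, params)


FRAME_ORDER = tuple((strand, offset) for strand in "+-" for offset in range(3))


def translated_search(query: ProteinRecord, subject: ESTRecord,
                      matrix: SubstitutionMatrix = DEFAULT_MATRIX,
                      params: KarlinAltschulParams = DEFAULT_KA,
                      evalue_cutoff: Optional[float] = None) -> AlignmentResult:
    """Best local alignment of a protein against the six frame
    translations of a nucleotide read (a TBLASTN stand-in).

    Stop codons translate to a sentinel scoring -4 against everything;
    the E-value uses the subject's nucleotide length.  Frame ties
    resolve to the first frame in (+0, +1, +2, -0, -1, -2) order.
    When ``evalue_cutoff`` is given, hits at or above it are returned as
    degenerate score-only results (their alignment statistics are never
    consumed), which skips the traceback.
    """
    if len(subject.seq) < 3:
        raise ValueError(f"{subject.id}: subject shorter than one codon")
    qseq = query.residues
    aligner = _aligner_for(matrix)
    rc = reverse_complement(subject.seq)
    best_frame: Optional[Tuple[str, int, str]] = None
    best_score = -math.inf
    for strand, offset in FRAME_ORDER:
        aa = translate_frame(subject.seq if strand == "+" else rc, offset)
        if not aa:
            continue
        score = aligner.score(qseq, aa)
        if score > best_score:
            best_score, best_frame = score, (strand, offset, aa)
    if best_frame is None or best_score <= 0:
        return _degenerate_result(query.id, qseq, subject.id,
                                  len(subject.seq), params)
    if evalue_cutoff is not None and \
            evalue(best_score, len(qseq), len(subject.seq), params) >= evalue_cutoff:
        return _degenerate_result(query.id, qseq, subject.id,
                                  len(subject.seq), params)
    strand, offset, aa = best_frame
    res = align_strings(query.id, qseq, subject.id, aa, matrix, params,
                        n_for_evalue=len(subject.seq))
    return AlignmentResult(
        **{**res.__dict__, "strand": strand, "frame": offset,
           "subject_translation": aa})
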