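"""Core record types shared by every pipeline stage.

The mining cascade moves through three in-memory currencies: nucleotide
EST reads (:class:`ESTRecord`), translated open reading frames exposed as
proteins (:class:`ProteinRecord`), and externally supplied predictor
evidence (:class:`PredictorReportRow`).  Everything downstream — the
secretion gate, redundancy clustering, full-length assessment — consumes
these three types only, so swapping a real predictor report for the
builtin heuristic never changes downstream behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Tuple

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
AA_ALPHABET_EXT = AA_ALPHABET | {"X", "*"}

Species = Literal["mp", "ap", "other"]
Tissue = Literal["salivary_gland", "gut", "whole", "unknown"]


@dataclass(frozen=True)
class ESTRecord:
    """A single-pass cDNA read with library provenance tags.

    ESTs are single reads: they may be truncated at either end and lie on
    either strand, which is why ORF calling scans all six frames.
    """

    id: str
    seq: str
    species: str = "other"
    tissue: str = "unknown"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ESTRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"ESTRecord {self.id!r}: empty sequence")
        bad = next(
            ((i, c) for i, c in enumerate(self.seq) if c not in NUCLEOTIDE_ALPHABET),
            None,
        )
        if bad is not None:
            raise ValueError(
                f"ESTRecord {self.id!r}: illegal nucleotide {bad[1]!r} at position {bad[0] + 1}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence, usually the translation of one ORF.

    At most one trailing ``*`` (stop) is tolerated and never counted in
    :func:`len`.
    """

    id: str
    seq: str
    source: Optional[object] = None  # typically an ORFCandidate
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ProteinRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"ProteinRecord {self.id!r}: empty sequence")
        body = self.seq[:-1] if self.seq.endswith("*") else self.seq
        if "*" in body:
            raise ValueError(f"ProteinRecord {self.id!r}: internal stop codon")
        bad = next(
            ((i, c) for i, c in enumerate(self.seq) if c not in AA_ALPHABET_EXT),
            None,
        )
        if bad is not None:
            raise ValueError(
                f"ProteinRecord {self.id!r}: illegal residue {bad[1]!r} at position {bad[0] + 1}"
            )

    @property
    def residues(self) -> str:
        """Sequence without the optional trailing stop."""
        return self.seq[:-1] if self.seq.endswith("*") else self.seq

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PredictorReportRow:
    """One parsed line of an external predictor report.

    ``kind == "signal_peptide"`` rows carry a score in [0, 1] and a 1-based
    cleavage site (index of the last signal-peptide residue).
    ``kind == "topology"`` rows carry sorted, non-overlapping 1-based
    inclusive transmembrane-segment intervals.
    """

    protein_id: str
    kind: Literal["signal_peptide", "topology"]
    score: Optional[float] = None
    cleavage_site: Optional[int] = None
    tm_segments: Tuple[Tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind == "signal_peptide":
            if self.score is None or not (0.0 <= self.score <= 1.0):
                raise ValueError(
                    f"{self.protein_id}: signal-peptide score {self.score!r} outside [0, 1]"
                )
            if self.cleavage_site is None or self.cleavage_site < 1:
                raise ValueError(
                    f"{self.protein_id}: cleavage site must be a positive integer"
                )
        elif self.kind == "topology":
            prev_end = 0
            for start, end in self.tm_segments:
                if start < 1 or end < start:
                    raise ValueError(
                        f"{self.protein_id}: malformed TM segment {start}-{end}"
                    )
                if start <= prev_end:
                    raise ValueError(
                        f"{self.protein_id}: TM segments overlap or are unsorted"
                    )
                prev_end = end
        else:
            raise ValueError(f"unknown predictor report kind {self.kind!r}")


def check_unique_ids(records: Sequence) -> None:
    """Raise if any record id appears more than once."""
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
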