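"""Six-frame ORF calling on EST reads.

An ORF is an ATG-to-stop or ATG-to-sequence-end stretch of at least
``min_len`` residues, scanned on both strands in all three frame offsets.
Because nested in-frame ATGs share a stop, the default reports one ORF
per stop-free stretch, anchored at its 5'-most ATG (the longest-ORF
convention); ``all_starts=True`` reports one ORF per in-frame ATG
instead.

Coordinates are 0-based half-open on the EST's *forward* strand
regardless of ORF strand, covering coding codons only (the terminating
stop codon, when present, is excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

from Bio.Data import CodonTable

from .records import ESTRecord, ProteinRecord

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP = dict(_STANDARD.forward_table)
STOP_CODONS = frozenset(_STANDARD.stop_codons)  # TAA, TAG, TGA

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_MIN_ORF_LEN = 70


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon; any codon containing N yields X.

    X never counts as a start or a stop, so ambiguous sequence can
    neither open nor close an ORF.
    """
    if "N" in codon:
        return "X"
    if codon in STOP_CODONS:
        return "*"
    return _CODON_MAP[codon]


def translate_frame(seq: str, offset: int) -> str:
    """Translate a single frame; stops appear as ``*``."""
    out = []
    for i in range(offset, len(seq) - 2, 3):
        out.append(translate_codon(seq[i:i + 3]))
    return "".join(out)


@dataclass(frozen=True)
class ORFCandidate:
    """One called ORF, with provenance back to its EST.

    ``start_nt``/``end_nt`` are 0-based half-open on the forward strand
    of the EST; ``frame`` is the offset (0-2) on the reported strand.
    """

    est_id: str
    strand: str  # "+" or "-"
    frame: int
    start_nt: int
    end_nt: int
    aa_seq: str
    terminated_by_stop: bool
    min_len: int = DEFAULT_MIN_ORF_LEN

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.aa_seq.startswith("M"):
            raise ValueError("ORF amino-acid sequence must start with M")
        if len(self.aa_seq) < self.min_len:
            raise ValueError("ORF shorter than min_len")
        if (self.end_nt - self.start_nt) % 3 != 0:
            raise ValueError("ORF nucleotide span not a multiple of 3")

    @property
    def id(self) -> str:
        return (f"{self.est_id}|{self.strand}|{self.frame}|"
                f"{self.start_nt}-{self.end_nt}|complete:{int(self.terminated_by_stop)}")

    def to_protein(self, species: str = "other", tissue: str = "unknown") -> ProteinRecord:
        return ProteinRecord(id=self.id, seq=self.aa_seq, source=self)


def _scan_strand(seq: str, strand: str, seq_len: int, min_len: int,
                 all_starts: bool) -> List[dict]:
    """Scan the three frames of one strand (seq is already oriented 5'→3')."""
    found = []
    for offset in range(3):
        aa = translate_frame(seq, offset)
        if not aa:
            continue
        # split into stop-free stretches; each stretch [lo, hi) in aa coords
        lo = 0
        positions = [i for i, c in enumerate(aa) if c == "*"]
        stretches = []
        for p in positions:
            stretches.append((lo, p, True))
            lo = p + 1
        if lo < len(aa):
            stretches.append((lo, len(aa), False))
        for lo, hi, has_stop in stretches:
            starts = [i for i in range(lo, hi) if aa[i] == "M"]
            if not all_starts:
                starts = starts[:1]
            for s in starts:
                length = hi - s
                if length < min_len:
                    continue
                # nt coords on the reported strand
                nt_start = offset + 3 * s
                nt_end = offset + 3 * hi
                if strand == "+":
                    f_start, f_end = nt_start, nt_end
                else:
                    f_start, f_end = seq_len - nt_end, seq_len - nt_start
                found.append(dict(
                    strand=strand, frame=offset, start_nt=f_start,
                    end_nt=f_end, aa_seq=aa[s:hi], terminated_by_stop=has_stop,
                ))
    return found


def call_orfs(est: ESTRecord, min_len: int = DEFAULT_MIN_ORF_LEN,
              all_starts: bool = False) -> List[ORFCandidate]:
    """Enumerate ORFs of at least ``min_len`` residues in all six frames.

    Returns candidates sorted by (strand, frame, start_nt); '+' sorts
    before '-'.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if len(est.seq) < 3:
        raise ValueError(f"{est.id}: sequence shorter than one codon")

    hits = _scan_strand(est.seq, "+", len(est.seq), min_len, all_starts)
    hits += _scan_strand(reverse_complement(est.seq), "-", len(est.seq),
                         min_len, all_starts)
    hits.sort(key=lambda h: (h["strand"] == "-", h["frame"], h["start_nt"]))
    return [ORFCandidate(est_id=est.id, min_len=min_len, **h) for h in hits]


def write_orfs_fasta(orfs: List[ORFCandidate], path) -> None:
    """Write called ORFs as amino-acid FASTA with provenance headers."""
    from .io import write_fasta
    write_fasta([o.to_protein() for o in orfs], path)
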