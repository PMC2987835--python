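"""FASTA and predictor-report I/O.

FASTA parsing itself is delegated to :mod:`Bio.SeqIO`; this module adds
the project's ingest policy (uppercasing, U→T, IUPAC ambiguity codes →
N with a logged warning, alphabet auto-detection) and the two predictor
report dialects:

``signalp3_short``
    whitespace-delimited ``protein_id score cleavage_site`` with ``#``
    comment lines; score in [0, 1], cleavage site 1-based.

``tmhmm_short``
    whitespace-delimited ``protein_id n_segments start1-end1[,start2-end2...]``
    with ``-`` standing for an empty segment list.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Sequence, Union

from Bio import SeqIO

from .records import (
    AA_ALPHABET_EXT,
    NUCLEOTIDE_ALPHABET,
    ESTRecord,
    PredictorReportRow,
    ProteinRecord,
)

logger = logging.getLogger(__name__)

# IUPAC nucleotide ambiguity codes collapsed to N on ingest.
_AMBIGUITY_CODES = set("RYSWKMBDHV")

_NT_DETECT = set("ACGTNU")


def _looks_nucleotide(seq: str) -> bool:
    if not seq:
        return False
    hits = sum(1 for c in seq if c in _NT_DETECT)
    return hits / len(seq) >= 0.95


def read_fasta(
    path: Union[str, Path],
    species: str = "other",
    tissue: str = "unknown",
) -> List[Union[ESTRecord, ProteinRecord]]:
    """Read a FASTA file into EST or protein records.

    The alphabet is auto-detected per file: if at least 95% of all
    sequence characters fall in {A, C, G, T, N, U} the file is treated as
    nucleotide (U mapped to T, other IUPAC ambiguity codes mapped to N
    with a warning), otherwise as amino acid.  Species/tissue tags apply
    to every record of the file; headers are not parsed for them, since
    public EST headers are not uniform.
    """
    path = Path(path)
    raw = [(r.id, str(r.seq).upper(), r.description) for r in SeqIO.parse(str(path), "fasta")]
    if not raw:
        raise ValueError(f"{path}: no records")

    seen = set()
    for rid, _, _ in raw:
        if rid in seen:
            raise ValueError(f"{path}: duplicate id {rid!r}")
        seen.add(rid)

    all_chars = "".join(seq for _, seq, _ in raw)
    nucleotide = _looks_nucleotide(all_chars)

    records: List[Union[ESTRecord, ProteinRecord]] = []
    for rid, seq, desc in raw:
        desc = desc[len(rid):].strip() if desc.startswith(rid) else desc
        if nucleotide:
            cleaned = []
            for i, c in enumerate(seq):
                if c == "U":
                    c = "T"
                elif c in _AMBIGUITY_CODES:
                    logger.warning(
                        "%s: ambiguity code %r at position %d in %s mapped to N",
                        path.name, c, i + 1, rid,
                    )
                    c = "N"
                elif c not in NUCLEOTIDE_ALPHABET:
                    raise ValueError(
                        f"{path}: illegal character {c!r} at position {i + 1} in {rid!r}"
                    )
                cleaned.append(c)
            records.append(
                ESTRecord(id=rid, seq="".join(cleaned), species=species,
                          tissue=tissue, description=desc)
            )
        else:
            for i, c in enumerate(seq):
                if c not in AA_ALPHABET_EXT:
                    raise ValueError(
                        f"{path}: illegal character {c!r} at position {i + 1} in {rid!r}"
                    )
            records.append(ProteinRecord(id=rid, seq=seq, description=desc))
    return records


def write_fasta(records: Sequence[Union[ESTRecord, ProteinRecord]],
                path: Union[str, Path], width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            seq = rec.seq
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _parse_segments(token: str, line_no: int, path: Path):
    if token == "-":
        return ()
    segments = []
    for part in token.split(","):
        try:
            start_s, end_s = part.split("-")
            segments.append((int(start_s), int(end_s)))
        except ValueError:
            raise ValueError(
                f"{path}:{line_no}: malformed TM segment token {part!r}"
            ) from None
    return tuple(segments)


def read_predictor_report(path: Union[str, Path],
                          dialect: str) -> List[PredictorReportRow]:
    """Parse a signal-peptide or topology report in one of the two dialects."""
    path = Path(path)
    if dialect not in ("signalp3_short", "tmhmm_short"):
        raise ValueError(f"unknown predictor report dialect {dialect!r}")

    rows: List[PredictorReportRow] = []
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if dialect == "signalp3_short":
                    if len(fields) != 3:
                        raise ValueError("expected 3 fields")
                    pid, score_s, cleave_s = fields
                    score = float(score_s)
                    if not 0.0 <= score <= 1.0:
                        raise ValueError(f"score {score} outside [0, 1]")
                    rows.append(PredictorReportRow(
                        protein_id=pid, kind="signal_peptide",
                        score=score, cleavage_site=int(cleave_s)))
                else:
                    if len(fields) != 3:
                        raise ValueError("expected 3 fields")
                    pid, n_seg_s, seg_s = fields
                    segments = _parse_segments(seg_s, line_no, path)
                    if len(segments) != int(n_seg_s):
                        raise ValueError(
                            f"segment count {n_seg_s} does not match {len(segments)} parsed")
                    rows.append(PredictorReportRow(
                        protein_id=pid, kind="topology", tm_segments=segments))
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: {exc}") from None
    return rows


def write_predictor_report(rows: Sequence[PredictorReportRow],
                           path: Union[str, Path], dialect: str) -> None:
    """Write rows in the given dialect (inverse of :func:`read_predictor_report`)."""
    path = Path(path)
    if dialect not in ("signalp3_short", "tmhmm_short"):
        raise ValueError(f"unknown predictor report dialect {dialect!r}")
    with path.open("w") as fh:
        if dialect == "signalp3_short":
            fh.write("# protein_id score cleavage_site\n")
            for row in rows:
                fh.write(f"{row.protein_id} {row.score:.6f} {row.cleavage_site}\n")
        else:
            fh.write("# protein_id n_segments segments\n")
            for row in rows:
                seg = ",".join(f"{s}-{e}" for s, e in row.tm_segments) or "-"
                fh.write(f"{row.protein_id} {len(row.tm_segments)} {seg}\n")
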