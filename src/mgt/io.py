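"""Shared format readers/writers and small sequence utilities.

Standard formats go through the standard libraries (Biopython for
FASTA/FASTQ, pysam for SAM); the wrappers here only add record-numbered
error messages and deterministic writing (fixed line wrapping, fixed
sort orders) so that identical inputs always produce byte-identical
output files.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte -> 0..3 for ACGT (case-insensitive), 4 for anything else
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


class FormatError(ValueError):
    """Malformed input record (carries file/record context in the message)."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict (uppercased)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def read_fasta_with_desc(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTA returning (id, description, sequence) triples in file order."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, rec.description, str(rec.seq).upper()))
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    """Write (id-or-header, sequence) records with fixed 60-column wrapping."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality-string) with record-numbered errors."""
    n = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            n += 1
            yield rec.id, str(rec.seq).upper(), "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
    except ValueError as exc:  # Biopython's length-mismatch / truncation errors
        raise FormatError(f"{path}: malformed FASTQ at record {n + 1}: {exc}") from exc


def read_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[tuple[str, str, str], tuple[str, str, str]]]:
    """Yield synchronized mate pairs from two FASTQ files."""
    it1, it2 = read_fastq(r1_path), read_fastq(r2_path)
    for n, (rec1, rec2) in enumerate(zip(it1, it2, strict=False), 1):
        yield rec1, rec2
    leftover = next(it1, None) or next(it2, None)
    if leftover is not None:
        raise FormatError(f"{r1_path}/{r2_path}: unequal number of mates (record {n + 1})")


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in records:
            if len(seq) != len(qual):
                raise FormatError(f"{path}: seq/qual length mismatch for {read_id}")
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# TSV helpers


def write_tsv(path: str | Path, header: list[str], rows: Iterable[list]) -> None:
    """Write a TSV with deterministic formatting (floats via %.6g)."""
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    if isinstance(v, (np.floating,)):
        return f"{float(v):.6g}"
    if isinstance(v, (np.integer,)):
        return str(int(v))
    return str(v)
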