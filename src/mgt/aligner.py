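"""Internal read aligner and the alignment record shared across the pipeline.

The pipeline's filtering/pileup contract is backend-independent: alignments
can come from any SAM-producing aligner (a documented bowtie2 invocation
is in the README) or from the exact-seed (k=21) gapless seed-and-extend
aligner implemented here, which is sufficient for substitution-only reads.
Both paths produce the same :class:`Alignment` records.

The internal aligner is gapless by design: candidate placements come from
exact 21-mer seed hits, each candidate is scored by identical bases over
the full read/target overlap, and the best placement wins. Reads whose
best score ties across distinct placements are treated as non-unique and
either dropped or resolved lexicographically, depending on the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .io import encode_seq, revcomp

DEFAULT_K = 21
MAPQ_UNIQUE = 60


@dataclass
class Alignment:
    """A gapless-or-SAM alignment of one read against one target contig.

    ``seq``/``qual`` are oriented to the forward strand of the target
    (reverse-strand alignments store the reverse complement), matching
    SAM conventions. ``cigar`` is a list of (op, length) with ops among
    M/I/D/S/=/X/N/H/P.
    """

    read_id: str
    contig: str
    pos: int  # 0-based leftmost reference position
    cigar: list[tuple[str, int]]
    seq: str
    qual: np.ndarray  # phred scores, same orientation as seq
    mapq: int = MAPQ_UNIQUE
    nm: int = 0
    is_reverse: bool = False
    is_read1: bool = True
    is_proper_pair: bool = False
    template_len: int = 0
    is_unmapped: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False

    @property
    def read_length(self) -> int:
        return len(self.seq)

    @property
    def aligned_read_bases(self) -> int:
        return sum(n for op, n in self.cigar if op in "MI=X")

    @property
    def aligned_columns(self) -> int:
        return sum(n for op, n in self.cigar if op in "MID=X")

    @property
    def reference_end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op in "MD=XN")

    def reference_positions(self) -> dict[int, tuple[str, int]]:
        """Map reference position -> (base, quality) for aligned columns.

        Insertion and soft-clipped bases consume read only; deletions
        consume reference only and contribute nothing (SNV-only scope).
        """
        out: dict[int, tuple[str, int]] = {}
        r = 0
        t = self.pos
        for op, n in self.cigar:
            if op in "M=X":
                for i in range(n):
                    out[t + i] = (self.seq[r + i], int(self.qual[r + i]))
                r += n
                t += n
            elif op in "IS":
                r += n
            elif op in "DN":
                t += n
            # H/P consume nothing
        return out


@dataclass
class _Hit:
    contig: str
    pos: int  # leftmost ref position of the aligned block
    strand: str
    identical: int
    mismatches: int
    read_start: int  # first aligned read offset (in strand orientation)
    read_end: int


class GaplessAligner:
    """Exact-seed gapless aligner over a set of target sequences."""

    def __init__(self, targets: dict[str, str], k: int = DEFAULT_K):
        self.k = k
        self.targets = dict(targets)
        self.encoded = {tid: encode_seq(s) for tid, s in targets.items()}
        self.index: dict[str, list[tuple[str, int]]] = {}
        for tid in sorted(targets):
            seq = targets[tid]
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((tid, i))

    # -- candidate generation -------------------------------------------------

    def _candidates(self, seq: str) -> set[tuple[str, int, str]]:
        cands: set[tuple[str, int, str]] = set()
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            L = len(s)
            offsets = list(range(0, L - self.k + 1, self.k))
            if offsets and offsets[-1] != L - self.k:
                offsets.append(L - self.k)
            for off in offsets:
                for tid, tpos in self.index.get(s[off : off + self.k], ()):
                    cands.add((tid, tpos - off, strand))
        return cands

    def _score(self, seq: str, cand: tuple[str, int, str]) -> Optional[_Hit]:
        tid, start, strand = cand
        s = seq if strand == "+" else revcomp(seq)
        tlen = len(self.targets[tid])
        r0 = max(0, -start)
        r1 = min(len(s), tlen - start)
        if r1 - r0 < self.k:
            return None
        q = encode_seq(s[r0:r1])
        t = self.encoded[tid][start + r0 : start + r1]
        mm = int(np.count_nonzero(q != t))
        return _Hit(tid, start + r0, strand, (r1 - r0) - mm, mm, r0, r1)

    def hits(self, seq: str) -> list[_Hit]:
        """All scored candidate placements, best identical-base count first.

        Deterministic order: (-identical, contig, pos, strand).
        """
        scored = []
        for cand in self._candidates(seq):
            h = self._score(seq, cand)
            if h is not None:
                scored.append(h)
        scored.sort(key=lambda h: (-h.identical, h.contig, h.pos, h.strand))
        return scored

    # -- read-level API -------------------------------------------------------

    def align_read(
        self,
        read_id: str,
        seq: str,
        qual: str,
        on_tie: str = "drop",
        is_read1: bool = True,
    ) -> Optional[Alignment]:
        """Best gapless placement of one read, or None.

        ``on_tie`` controls reads whose top score is shared by several
        placements: "drop" discards the read (unique-best mapping);
        "lexi" keeps the lexicographically first placement.
        """
        hits = self.hits(seq)
        if not hits:
            return None
        best = hits[0]
        if len(hits) > 1 and hits[1].identical == best.identical:
            if on_tie == "drop":
                return None
            mapq = 3
        else:
            mapq = MAPQ_UNIQUE
        return self._to_alignment(read_id, seq, qual, best, mapq, is_read1)

    def _to_alignment(
        self,
        read_id: str,
        seq: str,
        qual: str,
        hit: _Hit,
        mapq: int,
        is_read1: bool,
    ) -> Alignment:
        s = seq if hit.strand == "+" else revcomp(seq)
        q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(int) - 33
        if hit.strand == "-":
            q = q[::-1]
        cigar: list[tuple[str, int]] = []
        if hit.read_start:
            cigar.append(("S", hit.read_start))
        cigar.append(("M", hit.read_end - hit.read_start))
        if hit.read_end < len(s):
            cigar.append(("S", len(s) - hit.read_end))
        return Alignment(
            read_id=read_id,
            contig=hit.contig,
            pos=hit.pos,
            cigar=cigar,
            seq=s,
            qual=q,
            mapq=mapq,
            nm=hit.mismatches,
            is_reverse=hit.strand == "-",
            is_read1=is_read1,
        )

    def align_pair(
        self,
        read_id: str,
        r1: tuple[str, str],
        r2: tuple[str, str],
        max_template_len: int = 1000,
        on_tie: str = "drop",
    ) -> list[Alignment]:
        """Align both mates and annotate proper-pair status.

        A pair is proper when both mates map to the same contig in FR
        orientation (opposite strands, forward mate leftmost) with a
        template no longer than ``max_template_len``.
        """
        a1 = self.align_read(read_id, r1[0], r1[1], on_tie=on_tie, is_read1=True)
        a2 = self.align_read(read_id, r2[0], r2[1], on_tie=on_tie, is_read1=False)
        mates = [a for a in (a1, a2) if a is not None]
        if a1 is not None and a2 is not None and a1.contig == a2.contig:
            if a1.is_reverse != a2.is_reverse:
                fwd, rev = (a1, a2) if a2.is_reverse else (a2, a1)
                tlen = max(a1.reference_end, a2.reference_end) - min(a1.pos, a2.pos)
                if fwd.pos <= rev.pos and tlen <= max_template_len:
                    a1.is_proper_pair = a2.is_proper_pair = True
                    a1.template_len = a2.template_len = tlen
        return mates


def from_pysam(rec, contig_name: str | None = None) -> Alignment:
    """Convert a pysam AlignedSegment to the pipeline's Alignment record.

    Requires the NM tag (or raises). pysam already orients query sequence
    and qualities to the forward strand of the reference.
    """
    _OPS = "MIDNSHP=XB"
    cigar = [(_OPS[op], n) for op, n in (rec.cigartuples or [])]
    if rec.is_unmapped:
        nm = 0
    elif rec.has_tag("NM"):
        nm = int(rec.get_tag("NM"))
    else:
        raise ValueError(f"alignment {rec.query_name}: missing NM tag")
    qual = np.array(rec.query_qualities or [], dtype=int)
    return Alignment(
        read_id=rec.query_name,
        contig=contig_name or (rec.reference_name or "*"),
        pos=rec.reference_start if not rec.is_unmapped else -1,
        cigar=cigar,
        seq=(rec.query_sequence or "").upper(),
        qual=qual,
        mapq=rec.mapping_quality,
        nm=nm,
        is_reverse=rec.is_reverse,
        is_read1=not rec.is_read2,
        is_proper_pair=rec.is_proper_pair,
        template_len=abs(rec.template_length),
        is_unmapped=rec.is_unmapped,
        is_secondary=rec.is_secondary,
        is_supplementary=rec.is_supplementary,
    )


def read_sam(path: str) -> Iterable[Alignment]:
    """Stream Alignment records from a SAM/BAM file via pysam."""
    import pysam

    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            yield from_pysam(rec)
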