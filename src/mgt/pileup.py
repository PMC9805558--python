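"""Single-sample SNV step: post-alignment filters, mate-overlap
resolution, per-site pileup and per-sample SNV calls.

No single-strain assumption is made: the full A/C/G/T count vector is
kept at every site so within-sample strain mixtures remain visible.

Paired-end handling is the accuracy-critical part. Mates of one
fragment are resolved jointly before counting so a fragment never
contributes more than one observation to any site: where mates overlap
and agree the base is counted once with the higher quality; where they
disagree the higher-quality base wins; quality ties contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np

from .aligner import Alignment, GaplessAligner
from .io import BASES, BASE_INDEX, read_fastq_pairs, write_tsv


@dataclass
class FilterParams:
    """Post-alignment filter thresholds (all CLI-exposed).

    Defaults follow the MIDAS lineage: MAPQ >= 10, read identity >= 0.90,
    aligned fraction >= 0.75, base quality >= 30, proper pairs only with
    template <= 1000 bp.
    """

    min_mapq: int = 10
    min_read_identity: float = 0.90
    min_aln_cov: float = 0.75
    min_baseq: int = 30
    require_proper_pair: bool = True
    max_template_len: int = 1000

    def __post_init__(self):
        if not (0 <= self.min_read_identity <= 1 and 0 <= self.min_aln_cov <= 1):
            raise ValueError("identity/coverage fractions must be in [0, 1]")
        if min(self.min_mapq, self.min_baseq, self.max_template_len) < 0:
            raise ValueError("thresholds must be >= 0")


#: CNV mapping preset: proper pairing is irrelevant for gene targets and
#: the aligned-fraction floor drops to 0.50 so reads straddling a gene
#: boundary still contribute — this keeps gene depth on the same scale
#: as marker depth (screened at a matching 50-base minimum).
CNV_FILTERS = FilterParams(require_proper_pair=False, min_aln_cov=0.50)


@dataclass
class SitePileup:
    species_id: str
    contig_id: str
    position: int  # 0-based
    ref_allele: str
    counts: np.ndarray  # int counts for A,C,G,T

    @property
    def depth(self) -> int:
        return int(self.counts.sum())


@dataclass
class SampleSNV:
    species_id: str
    contig_id: str
    position: int
    ref_allele: str
    counts: np.ndarray
    major_allele: str
    minor_allele: Optional[str]
    major_freq: float


def filter_alignment(aln: Alignment, params: FilterParams) -> Optional[str]:
    """Return None to keep the record, else the first failing reason.

    Reasons in test order: unmapped, secondary, supplementary, mapq,
    identity (1 - NM/aligned columns), aln_cov (aligned read bases /
    read length), improper_pair, template_len.
    """
    if aln.is_unmapped:
        return "unmapped"
    if aln.is_secondary:
        return "secondary"
    if aln.is_supplementary:
        return "supplementary"
    if aln.mapq < params.min_mapq:
        return "mapq"
    cols = aln.aligned_columns
    if cols == 0 or 1.0 - aln.nm / cols < params.min_read_identity:
        return "identity"
    if aln.read_length == 0 or aln.aligned_read_bases / aln.read_length < params.min_aln_cov:
        return "aln_cov"
    if params.require_proper_pair:
        if not aln.is_proper_pair:
            return "improper_pair"
        if aln.template_len > params.max_template_len:
            return "template_len"
    return None


def resolve_mate_overlap(mates: list[Alignment]) -> dict[int, tuple[str, int]]:
    """Per-reference-position (base, quality) consensus for one fragment.

    Positions covered by a single mate take that mate's base. Overlap
    positions: agreement -> counted once at the higher quality;
    disagreement -> higher-quality base; quality tie -> position dropped
    for this fragment. Depth contribution is therefore <= 1 per site.
    """
    if len(mates) == 1:
        return mates[0].reference_positions()
    m1, m2 = mates[0].reference_positions(), mates[1].reference_positions()
    out = dict(m1)
    for pos, (b2, q2) in m2.items():
        if pos not in out:
            out[pos] = (b2, q2)
            continue
        b1, q1 = out[pos]
        if b1 == b2:
            out[pos] = (b1, max(q1, q2))
        elif q1 == q2:
            del out[pos]
        else:
            out[pos] = (b1, q1) if q1 > q2 else (b2, q2)
    return out


def group_fragments(alignments: Iterable[Alignment]) -> Iterator[list[Alignment]]:
    """Group primary alignments by read id into 1- or 2-mate fragments."""
    frags: dict[str, list[Alignment]] = {}
    for a in alignments:
        frags.setdefault(a.read_id, []).append(a)
    for rid in frags:
        yield frags[rid]


def compute_pileup(
    fragments: Iterable[list[Alignment]],
    target_seqs: dict[str, str],
    params: FilterParams,
) -> dict[str, np.ndarray]:
    """Count fragment bases into per-contig (L, 4) allele-count arrays.

    Filters are applied per record; surviving mates of each fragment are
    overlap-resolved jointly; bases below ``min_baseq`` and non-ACGT
    bases contribute nothing. Alignment columns past the contig end
    raise (malformed alignment).
    """
    counts = {cid: np.zeros((len(seq), 4), dtype=np.int32) for cid, seq in target_seqs.items()}
    for mates in fragments:
        kept = [m for m in mates if filter_alignment(m, params) is None]
        if not kept:
            continue
        by_contig: dict[str, list[Alignment]] = {}
        for m in kept:
            by_contig.setdefault(m.contig, []).append(m)
        for cid, group in by_contig.items():
            if cid not in counts:
                raise KeyError(f"alignment to unknown contig {cid!r}")
            arr = counts[cid]
            L = arr.shape[0]
            for m in group:
                if m.reference_end > L:
                    raise ValueError(
                        f"{m.read_id}: alignment exceeds contig {cid!r} length {L}"
                    )
            for pos, (base, qual) in resolve_mate_overlap(group[:2]).items():
                if qual >= params.min_baseq:
                    idx = BASE_INDEX.get(base)
                    if idx is not None:
                        arr[pos, idx] += 1
    return counts


def iter_sites(
    counts: dict[str, np.ndarray],
    target_seqs: dict[str, str],
    species_of: Optional[dict[str, str]] = None,
) -> Iterator[SitePileup]:
    """Stream nonzero-depth sites in (contig, position) order.

    Contig ids of the customized target are ``species|contig``; if
    ``species_of`` is not given the species is parsed from the id.
    """
    for cid in sorted(counts):
        arr = counts[cid]
        seq = target_seqs[cid]
        if species_of and cid in species_of:
            sid = species_of[cid]
        else:
            sid = cid.split("|", 1)[0] if "|" in cid else cid
        for pos in np.flatnonzero(arr.sum(axis=1)):
            pos = int(pos)
            yield SitePileup(sid, cid, pos, seq[pos], arr[pos].copy())


def call_sample_snv(
    site: SitePileup, min_depth: int = 2, max_depth: int = 10_000
) -> Optional[SampleSNV]:
    """Major/minor call at one site; None outside the depth window.

    Major = argmax count (ties to the lexicographically smallest base);
    minor = second-largest nonzero count under the same tie rule.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    depth = site.depth
    if depth < min_depth or depth > max_depth:
        return None
    ranked = sorted(range(4), key=lambda i: (-site.counts[i], BASES[i]))
    major = BASES[ranked[0]]
    minor = BASES[ranked[1]] if site.counts[ranked[1]] > 0 else None
    return SampleSNV(
        site.species_id,
        site.contig_id,
        site.position,
        site.ref_allele,
        site.counts,
        major,
        minor,
        float(site.counts[ranked[0]] / depth),
    )


PILEUP_COLUMNS = [
    "species_id",
    "contig_id",
    "position",
    "ref_allele",
    "depth",
    "count_A",
    "count_C",
    "count_G",
    "count_T",
    "major_allele",
    "minor_allele",
    "major_freq",
]


def write_pileup(path: str | Path, sites: Iterable[SitePileup]) -> None:
    """Write the per-sample pileup TSV (1-based positions)."""
    rows = []
    for s in sites:
        call = call_sample_snv(s, min_depth=1)
        rows.append(
            [
                s.species_id,
                s.contig_id,
                s.position + 1,
                s.ref_allele,
                s.depth,
                *[int(c) for c in s.counts],
                call.major_allele if call else "",
                (call.minor_allele or "") if call else "",
                call.major_freq if call else 0.0,
            ]
        )
    write_tsv(path, PILEUP_COLUMNS, rows)


def single_sample(
    target_seqs: dict[str, str],
    read_pairs=None,
    alignments: Optional[Iterable[Alignment]] = None,
    params: Optional[FilterParams] = None,
    aligner: Optional[GaplessAligner] = None,
) -> dict[str, np.ndarray]:
    """Run the single-sample step from reads (internal aligner) or SAM.

    Exactly one of ``read_pairs`` / ``alignments`` must be given.
    Returns per-contig count arrays; use :func:`iter_sites` /
    :func:`write_pileup` to serialize.
    """
    params = params or FilterParams()
    if (read_pairs is None) == (alignments is None):
        raise ValueError("provide exactly one of read_pairs or alignments")
    if read_pairs is not None:
        if aligner is None:
            aligner = GaplessAligner(target_seqs)
        frags = (
            aligner.align_pair(
                rec1[0], (rec1[1], rec1[2]), (rec2[1], rec2[2]),
                max_template_len=params.max_template_len,
            )
            for rec1, rec2 in read_pairs
        )
        fragments = (f for f in frags if f)
    else:
        fragments = group_fragments(alignments)
    return compute_pileup(fragments, target_seqs, params)


def single_sample_from_fastq(
    target_seqs: dict[str, str],
    r1_path,
    r2_path,
    params: Optional[FilterParams] = None,
    aligner: Optional[GaplessAligner] = None,
) -> dict[str, np.ndarray]:
    return single_sample(
        target_seqs,
        read_pairs=read_fastq_pairs(r1_path, r2_path),
        params=params,
        aligner=aligner,
    )
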