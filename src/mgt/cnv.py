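"""Pangenome gene copy-number estimation.

Reads are aligned to the species' pangenome centroids; per-centroid
vertical coverage (mapped bases / centroid length) is normalized by the
species' median marker coverage from the screening step — the same
depth scale on both sides — giving copy number ≈ 1 for single-copy
genes, ≈ 2 for duplications and ≈ 0 for deletions.

Mapping uses the SNV filter set minus the proper-pair requirement and
with the aligned-fraction floor at 0.50 (see pileup.CNV_FILTERS):
genes are short relative to fragments, so boundary-straddling reads
must still count or gene depth would be biased low relative to markers.
Cross-mapping between near-identical centroids is a known limitation;
reads are assigned unique-best and ties are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .aligner import GaplessAligner
from .io import write_tsv
from .pileup import CNV_FILTERS, FilterParams, filter_alignment, resolve_mate_overlap

DEFAULT_PRESENCE_THRESHOLD = 0.35


@dataclass
class GeneCoverage:
    species_id: str
    centroid_gene_id: str
    mapped_bases: int
    centroid_length: int
    vertical_coverage: float
    copy_number: float = 0.0
    present: bool = False


def gene_coverage(
    fragments,
    centroid_seqs: dict[str, str],
    species_of: dict[str, str],
    params: Optional[FilterParams] = None,
) -> list[GeneCoverage]:
    """Accumulate mapped bases per centroid from kept fragments.

    ``fragments`` yields lists of Alignment mates (one fragment each);
    mate overlaps are deduplicated, so a fragment contributes each
    covered centroid position at most once.
    """
    params = params or CNV_FILTERS
    mapped: dict[str, int] = {cid: 0 for cid in centroid_seqs}
    for mates in fragments:
        kept = [m for m in mates if filter_alignment(m, params) is None]
        if not kept:
            continue
        by_centroid: dict[str, list] = {}
        for m in kept:
            if m.contig not in mapped:
                raise KeyError(f"alignment to unknown centroid {m.contig!r}")
            by_centroid.setdefault(m.contig, []).append(m)
        for cid, group in by_centroid.items():
            mapped[cid] += len(resolve_mate_overlap(group[:2]))
    out = []
    for cid in sorted(centroid_seqs):
        L = len(centroid_seqs[cid])
        out.append(
            GeneCoverage(species_of[cid], cid, mapped[cid], L, mapped[cid] / L)
        )
    return out


def estimate_copy_number(
    coverages: list[GeneCoverage],
    median_marker_coverage: float,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> list[GeneCoverage]:
    """Normalize vertical coverage into copy number and call presence."""
    if median_marker_coverage <= 0:
        raise ValueError(
            "median marker coverage must be > 0 (species with zero marker "
            "depth are skipped upstream: copy number is undefined)"
        )
    for gc in coverages:
        gc.copy_number = gc.vertical_coverage / median_marker_coverage
        gc.present = gc.copy_number >= presence_threshold
    return coverages


def run_cnv(
    read_pairs,
    centroid_seqs: dict[str, str],
    species_of: dict[str, str],
    median_marker_coverage: dict[str, float],
    params: Optional[FilterParams] = None,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    out_path: str | Path | None = None,
) -> list[GeneCoverage]:
    """Reads -> per-centroid copy number, via the internal aligner.

    ``median_marker_coverage`` maps species id to the screening step's
    median marker coverage for this sample; species with zero marker
    coverage are skipped (their centroids are dropped from the output).
    """
    params = params or CNV_FILTERS
    aligner = GaplessAligner(centroid_seqs)
    frags = (
        aligner.align_pair(
            rec1[0], (rec1[1], rec1[2]), (rec2[1], rec2[2]),
            max_template_len=params.max_template_len,
        )
        for rec1, rec2 in read_pairs
    )
    covs = gene_coverage((f for f in frags if f), centroid_seqs, species_of, params)
    out: list[GeneCoverage] = []
    for sid in sorted({c.species_id for c in covs}):
        mmc = median_marker_coverage.get(sid, 0.0)
        sp = [c for c in covs if c.species_id == sid]
        if mmc <= 0:
            continue  # CNV undefined without a marker depth scale
        out.extend(estimate_copy_number(sp, mmc, presence_threshold))
    if out_path is not None:
        write_tsv(
            out_path,
            ["species_id", "gene_id", "vertical_coverage", "copy_number", "present"],
            [
                [c.species_id, c.centroid_gene_id, c.vertical_coverage, c.copy_number, int(c.present)]
                for c in out
            ],
        )
    return out
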