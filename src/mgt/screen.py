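"""Sample-customized species screening via marker-gene coverage.

Reads are mapped to the database's universal single-copy marker genes;
per-species depth is summarized as the median marker coverage over the
full panel (families without an extracted marker count as 0, which makes
the median robust to marker dropout). Species at or above the coverage
threshold form the sample-customized SNV alignment target: their
representative genomes concatenated with contig ids rewritten as
``<species_id>|<contig_id>``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .aligner import GaplessAligner
from .db import MidasDB
from .io import read_fastq_pairs, write_fasta, write_tsv
from .sim import MARKER_PANEL

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_ALN_LEN = 50
DEFAULT_MIN_COV = 2.0


@dataclass
class MarkerHit:
    read_id: str
    species_id: str
    marker_family: str
    gene_id: str
    aligned_bases: int
    identical_bases: int


@dataclass
class SpeciesProfile:
    species_id: str
    median_marker_coverage: float
    relative_abundance: float
    n_markers_covered: int


def map_to_markers(
    read_pairs,
    marker_seqs: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aln_len: int = DEFAULT_MIN_ALN_LEN,
    aligner: GaplessAligner | None = None,
) -> list[MarkerHit]:
    """Assign each read to at most one marker gene.

    Each mate is mapped independently; the winning hit has the most
    identical bases among placements meeting the identity and length
    floors. Ties within one species resolve lexicographically by gene
    id; ties across species discard the read (unique-best screening).
    Marker FASTA ids are ``species|family|gene_id``.
    """
    if not marker_seqs:
        raise ValueError("marker set is empty")
    if aligner is None:
        aligner = GaplessAligner(marker_seqs)
    hits: list[MarkerHit] = []
    for rec1, rec2 in read_pairs:
        for read_id, seq, _qual in (rec1, rec2):
            h = _best_marker_hit(aligner, seq, min_identity, min_aln_len)
            if h is None:
                continue
            marker_id, aligned, identical = h
            sid, fam, gid = marker_id.split("|", 2)
            hits.append(MarkerHit(read_id, sid, fam, gid, aligned, identical))
    return hits


def _best_marker_hit(aligner, seq, min_identity, min_aln_len):
    best = None
    ties = []
    for h in aligner.hits(seq):
        aligned = h.read_end - h.read_start
        if aligned < min_aln_len or h.identical / aligned < min_identity:
            continue
        if best is None or h.identical > best.identical:
            best, ties = h, [h]
        elif h.identical == best.identical:
            ties.append(h)
    if best is None:
        return None
    species = {t.contig.split("|", 1)[0] for t in ties}
    if len(species) > 1:
        return None  # ambiguous across species: discard read
    win = min(ties, key=lambda t: (t.contig.split("|", 2)[2], t.contig))  # by gene id
    return win.contig, win.read_end - win.read_start, win.identical


def profile_species(hits: list[MarkerHit], db: MidasDB) -> list[SpeciesProfile]:
    """Summarize marker hits into per-species coverage and relative abundance.

    Marker coverage = mapped (aligned) bases / marker length; species
    depth = median over the full panel with missing families as 0;
    relative abundance normalizes the medians over species with nonzero
    median. Species with zero coverage everywhere are omitted.
    """
    mapped: dict[tuple[str, str], int] = {}
    for h in hits:
        key = (h.species_id, h.marker_family)
        mapped[key] = mapped.get(key, 0) + h.aligned_bases

    marker_len = {(m.species_id, m.marker_family): m.length for m in db.markers}
    panel = sorted({m.marker_family for m in db.markers}) or list(MARKER_PANEL)

    profiles: list[SpeciesProfile] = []
    for sid in db.species_ids:
        covs = []
        n_covered = 0
        for fam in panel:
            length = marker_len.get((sid, fam))
            bases = mapped.get((sid, fam), 0)
            cov = bases / length if length else 0.0
            covs.append(cov)
            n_covered += int(cov > 0)
        med = float(np.median(covs)) if covs else 0.0
        if n_covered == 0:
            continue
        profiles.append(SpeciesProfile(sid, med, 0.0, n_covered))

    total = sum(p.median_marker_coverage for p in profiles)
    if total > 0:
        for p in profiles:
            p.relative_abundance = p.median_marker_coverage / total
    profiles.sort(key=lambda p: p.species_id)
    return profiles


def select_species(
    profiles: list[SpeciesProfile], min_median_coverage: float = DEFAULT_MIN_COV
) -> list[str]:
    """Species whose median marker coverage meets the threshold, sorted."""
    if min_median_coverage < 0:
        raise ValueError("min_median_coverage must be >= 0")
    return sorted(
        p.species_id for p in profiles if p.median_marker_coverage >= min_median_coverage
    )


def build_custom_target(
    selected: list[str], db: MidasDB, out_path: str | Path
) -> dict[str, str]:
    """Concatenate selected representatives into the SNV alignment target.

    Contig ids become ``<species_id>|<contig_id>``; species and contigs
    are written in sorted order so rebuilds are byte-identical. Returns
    the target as an id->sequence dict.
    """
    target: dict[str, str] = {}
    for sid in sorted(selected):
        if sid not in db.representatives:
            raise KeyError(f"species {sid!r} has no representative in the database")
        for cid, seq in sorted(db.representative_seqs(sid).items()):
            target[f"{sid}|{cid}"] = seq
    if not selected:
        logger.warning("no species selected; writing empty target %s", out_path)
    write_fasta(out_path, list(target.items()))
    return target


def profile_sample(
    r1_path,
    r2_path,
    db: MidasDB,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aln_len: int = DEFAULT_MIN_ALN_LEN,
) -> list[SpeciesProfile]:
    """FASTQ pair -> species profiles (convenience wrapper)."""
    hits = map_to_markers(
        read_fastq_pairs(r1_path, r2_path),
        db.marker_seqs(),
        min_identity=min_identity,
        min_aln_len=min_aln_len,
    )
    return profile_species(hits, db)


def write_profile(path, profiles: list[SpeciesProfile]) -> None:
    write_tsv(
        path,
        ["species_id", "median_marker_coverage", "relative_abundance", "n_markers_covered"],
        [
            [p.species_id, p.median_marker_coverage, p.relative_abundance, p.n_markers_covered]
            for p in profiles
        ],
    )
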