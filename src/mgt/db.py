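"""Reference database construction.

A database has three parts per species: universal single-copy marker
genes (screening / depth normalization), one representative genome (the
SNV coordinate system) and a pangenome of gene-cluster centroids (CNV
targets). The input is a genome collection described by a
table-of-contents TSV assigning genomes to species and flagging exactly
one representative per species.

Markers are declared by ``marker_family=<label>`` tags in the gene FASTA
description line (the simulator plants them; an external HMM-search hit
table can populate the same tags). Pangenomes use single-tier greedy
length-sorted centroid clustering: genes are visited longest-first (ties
lexicographic by gene id) and join the first centroid they match at or
above the identity threshold under global alignment, where identity is
matches / alignment columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import edlib

from .io import (
    read_fasta,
    read_fasta_with_desc,
    sha256_file,
    write_fasta,
    write_tsv,
)
from .sim import MARKER_PANEL

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY = 0.95


class ValidationError(ValueError):
    """Table-of-contents or collection invariant violation."""


@dataclass
class GenomeRecord:
    genome_id: str
    species_id: str
    is_representative: bool
    genome_path: Path
    genes_path: Path


@dataclass
class GenomeCollection:
    records: list[GenomeRecord]

    @property
    def species_ids(self) -> list[str]:
        return sorted({r.species_id for r in self.records})

    def genomes_of(self, species_id: str) -> list[GenomeRecord]:
        return [r for r in self.records if r.species_id == species_id]

    def representative(self, species_id: str) -> GenomeRecord:
        return next(
            r for r in self.records if r.species_id == species_id and r.is_representative
        )


@dataclass
class MarkerGene:
    species_id: str
    marker_family: str
    gene_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PangenomeCluster:
    species_id: str
    centroid_gene_id: str
    centroid_sequence: str
    member_gene_ids: list[str]
    identity_threshold: float


@dataclass
class MidasDB:
    """In-memory handle over a built database directory."""

    root: Path
    markers: list[MarkerGene]
    representatives: dict[str, Path]  # species_id -> representative FASTA
    pangenomes: dict[str, list[PangenomeCluster]]
    manifest: "object"  # pandas.DataFrame

    @property
    def species_ids(self) -> list[str]:
        return sorted(self.representatives)

    def markers_of(self, species_id: str) -> list[MarkerGene]:
        return [m for m in self.markers if m.species_id == species_id]

    def marker_seqs(self) -> dict[str, str]:
        """Marker FASTA records keyed ``species|family|gene_id``."""
        return {
            f"{m.species_id}|{m.marker_family}|{m.gene_id}": m.sequence
            for m in self.markers
        }

    def representative_seqs(self, species_id: str) -> dict[str, str]:
        return read_fasta(self.representatives[species_id])

    def genome_length(self, species_id: str) -> int:
        return sum(len(s) for s in self.representative_seqs(species_id).values())

    def centroid_seqs(self, species_id: str) -> dict[str, str]:
        return {
            c.centroid_gene_id: c.centroid_sequence
            for c in self.pangenomes.get(species_id, [])
        }


# ---------------------------------------------------------------------------


def parse_toc(toc_path: str | Path) -> GenomeCollection:
    """Parse and validate the table-of-contents TSV."""
    import pandas as pd

    toc_path = Path(toc_path)
    df = pd.read_csv(toc_path, sep="\t", dtype=str)
    required = ["genome_id", "species_id", "is_representative", "genome_path", "genes_path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{toc_path}: missing columns {missing}")

    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.genome_id in seen:
            raise ValidationError(f"duplicate genome_id {row.genome_id!r}")
        seen.add(row.genome_id)
        rec = GenomeRecord(
            genome_id=row.genome_id,
            species_id=row.species_id,
            is_representative=str(row.is_representative).strip().lower()
            in ("1", "true", "yes"),
            genome_path=Path(row.genome_path),
            genes_path=Path(row.genes_path),
        )
        for p in (rec.genome_path, rec.genes_path):
            if not p.exists():
                raise FileNotFoundError(f"{toc_path}: referenced file missing: {p}")
        records.append(rec)

    by_species: dict[str, int] = {}
    for r in records:
        by_species[r.species_id] = by_species.get(r.species_id, 0) + int(r.is_representative)
    for sid, n_rep in sorted(by_species.items()):
        if n_rep != 1:
            raise ValidationError(
                f"species {sid!r} has {n_rep} representatives (exactly 1 required)"
            )
    return GenomeCollection(records)


def extract_markers(
    collection: GenomeCollection, panel: list[str] | None = None
) -> list[MarkerGene]:
    """Collect panel-tagged genes from each species' representative genome.

    At most one marker per (species, family); two genes tagged with the
    same family in one representative violate the single-copy assumption
    and raise. Species with no tagged genes are permitted (logged).
    """
    panel = list(panel) if panel is not None else list(MARKER_PANEL)
    panel_set = set(panel)
    markers: list[MarkerGene] = []
    for sid in collection.species_ids:
        rep = collection.representative(sid)
        seen: dict[str, str] = {}
        for gene_id, desc, seq in read_fasta_with_desc(rep.genes_path):
            fam = _marker_tag(desc)
            if fam is None or fam not in panel_set:
                continue
            if fam in seen:
                raise ValidationError(
                    f"species {sid!r}: marker family {fam!r} tagged on both "
                    f"{seen[fam]!r} and {gene_id!r} (single-copy violation)"
                )
            seen[fam] = gene_id
            markers.append(MarkerGene(sid, fam, gene_id, seq))
        if not seen:
            logger.warning("species %s: no marker-tagged genes in representative", sid)
    markers.sort(key=lambda m: (m.species_id, m.marker_family, m.gene_id))
    return markers


def _marker_tag(description: str) -> str | None:
    for token in description.split():
        if token.startswith("marker_family="):
            return token.split("=", 1)[1]
    return None


# ---------------------------------------------------------------------------
# Pangenome clustering


def global_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    cols = sum(int(n) for n, _ in _parse_cigar(res["cigar"]))
    return 1.0 - res["editDistance"] / cols if cols else 0.0


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


def build_pangenome(
    species_genes: list[tuple[str, str]],
    identity_threshold: float = DEFAULT_IDENTITY,
    species_id: str = "",
) -> list[PangenomeCluster]:
    """Greedy length-sorted centroid clustering of one species' genes.

    Genes are processed by descending length (ties lexicographic by id);
    each joins the first existing cluster whose centroid it matches at
    >= identity_threshold, else founds a new cluster. Clusters partition
    the input, and the centroid is the longest member by construction.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    for gid, seq in species_genes:
        if not seq:
            raise ValueError(f"gene {gid!r} has empty sequence")
    ordered = sorted(species_genes, key=lambda g: (-len(g[1]), g[0]))
    clusters: list[PangenomeCluster] = []
    for gid, seq in ordered:
        placed = False
        for cl in clusters:
            if global_identity(seq, cl.centroid_sequence) >= identity_threshold:
                cl.member_gene_ids.append(gid)
                placed = True
                break
        if not placed:
            clusters.append(
                PangenomeCluster(species_id, gid, seq, [gid], identity_threshold)
            )
    for cl in clusters:
        cl.member_gene_ids.sort()
    clusters.sort(key=lambda c: c.centroid_gene_id)
    return clusters


# ---------------------------------------------------------------------------


def build_db(
    collection: GenomeCollection,
    out_dir: str | Path,
    panel: list[str] | None = None,
    identity_threshold: float = DEFAULT_IDENTITY,
    collection_name: str = "collection",
) -> MidasDB:
    """Build the three database components and write them under out_dir.

    Layout: ``markers.fa``, ``<species>/representative.fa``,
    ``<species>/centroids.fa`` and ``manifest.tsv`` (one row per species
    with component counts and per-file sha256 checksums). All orderings
    are fixed, so identical inputs give byte-identical outputs.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    markers = extract_markers(collection, panel)
    marker_recs = [
        (f"{m.species_id}|{m.marker_family}|{m.gene_id}", m.sequence) for m in markers
    ]
    markers_fa = out / "markers.fa"
    write_fasta(markers_fa, marker_recs)

    representatives: dict[str, Path] = {}
    pangenomes: dict[str, list[PangenomeCluster]] = {}
    rows = []
    for sid in collection.species_ids:
        sp_dir = out / sid
        sp_dir.mkdir(exist_ok=True)
        rep = collection.representative(sid)
        rep_fa = sp_dir / "representative.fa"
        rep_seqs = read_fasta(rep.genome_path)
        write_fasta(rep_fa, sorted(rep_seqs.items()))
        representatives[sid] = rep_fa

        genes: list[tuple[str, str]] = []
        for grec in collection.genomes_of(sid):
            for gid, _desc, seq in read_fasta_with_desc(grec.genes_path):
                genes.append((gid, seq))
        clusters = build_pangenome(genes, identity_threshold, species_id=sid)
        pangenomes[sid] = clusters
        cent_fa = sp_dir / "centroids.fa"
        write_fasta(
            cent_fa, [(c.centroid_gene_id, c.centroid_sequence) for c in clusters]
        )

        rows.append(
            [
                sid,
                len(collection.genomes_of(sid)),
                rep.genome_id,
                sum(1 for m in markers if m.species_id == sid),
                len(clusters),
                sha256_file(rep_fa),
                sha256_file(cent_fa),
            ]
        )

    manifest_path = out / "manifest.tsv"
    header = [
        "species_id",
        "n_genomes",
        "rep_genome_id",
        "n_markers",
        "n_centroids",
        "sha256_representative",
        "sha256_centroids",
    ]
    write_tsv(manifest_path, header, rows)
    # global provenance footer file: build parameters + markers checksum
    write_tsv(
        out / "build_info.tsv",
        ["key", "value"],
        [
            ["collection_name", collection_name],
            ["identity_threshold", identity_threshold],
            ["panel", ",".join(panel or MARKER_PANEL)],
            ["sha256_markers", sha256_file(markers_fa)],
        ],
    )
    manifest = pd.read_csv(manifest_path, sep="\t", dtype={"species_id": str})
    return MidasDB(out, markers, representatives, pangenomes, manifest)


def load_db(db_dir: str | Path) -> MidasDB:
    """Re-open a database directory written by :func:`build_db`."""
    import pandas as pd

    root = Path(db_dir)
    manifest = pd.read_csv(root / "manifest.tsv", sep="\t", dtype={"species_id": str})
    markers = []
    for mid, seq in read_fasta(root / "markers.fa").items():
        sid, fam, gid = mid.split("|", 2)
        markers.append(MarkerGene(sid, fam, gid, seq))
    representatives = {}
    pangenomes = {}
    for sid in manifest["species_id"]:
        representatives[sid] = root / sid / "representative.fa"
        clusters = [
            PangenomeCluster(sid, gid, seq, [gid], float("nan"))
            for gid, seq in read_fasta(root / sid / "centroids.fa").items()
        ]
        pangenomes[sid] = clusters
    return MidasDB(root, markers, representatives, pangenomes, manifest)
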