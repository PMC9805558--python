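"""Synthetic-community generator with exact ground truth.

Every downstream stage (database build, species screening, SNV pileup,
population SNV calling, CNV estimation, strain-mixture detection) is
validated against communities produced here: toy genomes with annotated
genes and a universal single-copy marker panel, strains derived from a
reference by independent per-site point mutation, planted tandem gene
duplications and deletions, and paired-end reads drawn with uniform
fragment starts and a constant per-base error rate.

The model is deliberately simple — i.i.d. bases, no indels, no GC bias,
constant base quality — which is sufficient to exercise every filter in
the pipeline while keeping every expectation analytically checkable.
All randomness flows from explicit integer seeds; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import BASES, revcomp, write_fasta, write_fastq, write_tsv

#: Universal single-copy marker families of the PhyEco panel used by the
#: MIDAS lineage; the simulator tags the first 15 genes of every genome
#: with these so marker extraction and screening are exercised end to end.
MARKER_PANEL = [
    "B000032", "B000039", "B000041", "B000062", "B000063",
    "B000065", "B000071", "B000079", "B000080", "B000081",
    "B000082", "B000086", "B000096", "B000103", "B000114",
]

GENE_LENGTH = 300  # fixed gene span in simulated genomes (bases)


@dataclass
class Gene:
    gene_id: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str = "+"
    marker_family: str | None = None


@dataclass
class Genome:
    """A single-contig genome with gene annotation."""

    genome_id: str
    contig_id: str
    seq: str
    genes: list[Gene] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)

    def gene_seq(self, gene: Gene) -> str:
        s = self.seq[gene.start : gene.end]
        return revcomp(s) if gene.strand == "-" else s


@dataclass
class CnvEvent:
    gene_id: str
    copies: int  # 0 (deletion), 2 or 3 (tandem duplication)


def make_genome(
    genome_id: str,
    length: int,
    gc: float = 0.5,
    n_genes: int = 30,
    seed: int = 0,
    contig_id: str | None = None,
) -> Genome:
    """Generate an i.i.d.-base genome with evenly spaced non-overlapping genes.

    Bases are drawn independently with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2.
    ``n_genes`` 300-bp genes are placed deterministically with uniform
    spacing; the first 15 are tagged with the universal marker panel.
    """
    if n_genes > 0 and length < n_genes * GENE_LENGTH + (n_genes + 1):
        raise ValueError(
            f"cannot pack {n_genes} genes of {GENE_LENGTH} bp into {length} bp"
        )
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    seq = "".join(BASES[c] for c in codes)

    genes: list[Gene] = []
    if n_genes > 0:
        gap = (length - n_genes * GENE_LENGTH) // (n_genes + 1)
        pos = gap
        for i in range(n_genes):
            fam = MARKER_PANEL[i] if i < len(MARKER_PANEL) else None
            genes.append(
                Gene(f"{genome_id}_g{i + 1:04d}", pos, pos + GENE_LENGTH, "+", fam)
            )
            pos += GENE_LENGTH + gap
    return Genome(genome_id, contig_id or f"{genome_id}_c1", seq, genes)


def mutate_strain(
    genome: Genome, divergence: float, seed: int, strain_id: str | None = None
) -> tuple[Genome, list[tuple[int, str, str]]]:
    """Derive a strain by independent per-site substitution.

    Each site mutates with probability ``divergence`` to a uniformly chosen
    different base. Returns the strain genome and the exact truth list of
    (position, ref_base, alt_base), 0-based positions on the reference.
    """
    if not 0 <= divergence <= 0.1:
        raise ValueError("divergence must be in [0, 0.1]")
    rng = np.random.default_rng(seed)
    L = len(genome.seq)
    hit = np.flatnonzero(rng.random(L) < divergence)
    seq = list(genome.seq)
    truth: list[tuple[int, str, str]] = []
    for pos in hit:
        ref = seq[pos]
        alt = rng.choice([b for b in BASES if b != ref])
        seq[pos] = alt
        truth.append((int(pos), ref, str(alt)))
    sid = strain_id or f"{genome.genome_id}_mut"
    return Genome(sid, genome.contig_id, "".join(seq), list(genome.genes)), truth


def plant_cnv(
    genome: Genome,
    gene_id: str,
    copies: int,
    truth_snvs: list[tuple[int, str, str]] | None = None,
) -> tuple[Genome, CnvEvent, list[tuple[int, str, str]]]:
    """Plant a tandem duplication (copies 2 or 3) or deletion (copies 0).

    Deletion removes the gene span; duplication appends copies-1 tandem
    repeats immediately after the gene. Downstream gene coordinates and
    truth SNV positions are remapped; SNVs inside a deleted span are
    dropped from the truth list.
    """
    if copies not in (0, 2, 3):
        raise ValueError("copies must be 0, 2 or 3")
    target = next((g for g in genome.genes if g.gene_id == gene_id), None)
    if target is None:
        raise ValueError(f"gene {gene_id!r} not in genome {genome.genome_id}")
    span = target.end - target.start
    shift = (copies - 1) * span  # negative span for deletions handled below

    if copies == 0:
        new_seq = genome.seq[: target.start] + genome.seq[target.end :]
        shift = -span
    else:
        dup = genome.seq[target.start : target.end] * (copies - 1)
        new_seq = genome.seq[: target.end] + dup + genome.seq[target.end :]

    new_genes = []
    for g in genome.genes:
        if g.gene_id == gene_id and copies == 0:
            continue
        if g.start >= target.end:
            g = replace(g, start=g.start + shift, end=g.end + shift)
        new_genes.append(g)

    new_truth = []
    for pos, ref, alt in truth_snvs or []:
        if copies == 0 and target.start <= pos < target.end:
            continue
        new_truth.append((pos + shift if pos >= target.end else pos, ref, alt))
    return (
        Genome(genome.genome_id, genome.contig_id, new_seq, new_genes),
        CnvEvent(gene_id, copies),
        new_truth,
    )


# ---------------------------------------------------------------------------
# Read simulation


def quality_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, round(-10 * math.log10(error_rate)))
    return chr(q + 33)


def simulate_reads(
    community: list[tuple[Genome, float]],
    coverage: float,
    read_len: int = 100,
    frag_mean: int = 300,
    frag_sd: int = 30,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], "np.ndarray"]:
    """Simulate paired-end reads from a strain mixture.

    The fragment count is ``coverage × effective_length / (2·read_len)``
    where effective_length is the proportion-weighted strain length;
    fragments are allocated to strains multinomially by proportion×length,
    start positions are uniform, and each base errs independently with
    probability ``error_rate`` to a uniform different base. Base quality
    is the constant Phred score matching the error rate. Read ids encode
    ``strain:contig:start:end:index`` so every read is traceable.

    Returns (R1 records, R2 records, per-strain fragment counts).
    """
    props = np.array([p for _, p in community], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("community proportions must sum to 1")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(g) for g, _ in community], dtype=float)
    eff_len = float(props @ lengths)
    n_frags = int(round(coverage * eff_len / (2 * read_len)))
    weights = props * lengths
    weights = weights / weights.sum()
    alloc = rng.multinomial(n_frags, weights)

    qchar = quality_char(error_rate)
    r1_out: list[tuple[str, str, str]] = []
    r2_out: list[tuple[str, str, str]] = []
    idx = 0
    for (genome, _), n in zip(community, alloc):
        L = len(genome)
        for _ in range(int(n)):
            flen = int(np.clip(round(rng.normal(frag_mean, frag_sd)), read_len, L))
            start = int(rng.integers(0, L - flen + 1))
            frag = genome.seq[start : start + flen]
            fwd = frag[:read_len]
            rev = revcomp(frag[-read_len:])
            fwd = _apply_errors(fwd, error_rate, rng)
            rev = _apply_errors(rev, error_rate, rng)
            rid = f"{genome.genome_id}:{genome.contig_id}:{start}:{start + flen}:{idx}"
            # mate roles swap at random so both orientations are exercised
            if rng.random() < 0.5:
                r1_out.append((rid, fwd, qchar * read_len))
                r2_out.append((rid, rev, qchar * read_len))
            else:
                r1_out.append((rid, rev, qchar * read_len))
                r2_out.append((rid, fwd, qchar * read_len))
            idx += 1
    return r1_out, r2_out, alloc


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    hit = np.flatnonzero(rng.random(len(seq)) < error_rate)
    if hit.size == 0:
        return seq
    out = list(seq)
    for pos in hit:
        out[pos] = rng.choice([b for b in BASES if b != out[pos]])
    return "".join(out)


def validate_reads(
    records: list[tuple[str, str, str]], genomes: dict[str, Genome]
) -> int:
    """Check error-free reads re-extract exactly from their source strain.

    Returns the number of reads whose sequence matches neither the forward
    fragment prefix nor the reverse-complemented fragment suffix (0 for
    error-free simulations).
    """
    bad = 0
    for rid, seq, _ in records:
        strain, _contig, start, end, _i = rid.rsplit(":", 4)
        frag = genomes[strain].seq[int(start) : int(end)]
        if seq != frag[: len(seq)] and seq != revcomp(frag[-len(seq) :]):
            bad += 1
    return bad


# ---------------------------------------------------------------------------
# On-disk collection layout (table-of-contents + FASTA) for the DB builder


def gene_records(genome: Genome) -> list[tuple[str, str]]:
    """FASTA records for a genome's genes, marker families tagged in the header."""
    recs = []
    for g in genome.genes:
        header = g.gene_id
        if g.marker_family:
            header += f" marker_family={g.marker_family}"
        recs.append((header, genome.gene_seq(g)))
    return recs


def write_collection(
    out_dir: str | Path, species: dict[str, list[tuple[Genome, bool]]]
) -> Path:
    """Write genome FASTAs, gene FASTAs and the table-of-contents TSV.

    ``species`` maps species_id to a list of (genome, is_representative).
    Returns the path of the TOC file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid in sorted(species):
        for genome, is_rep in species[sid]:
            gpath = out / f"{genome.genome_id}.fa"
            write_fasta(gpath, [(genome.contig_id, genome.seq)])
            gene_path = out / f"{genome.genome_id}.genes.fa"
            write_fasta(gene_path, gene_records(genome))
            rows.append(
                [genome.genome_id, sid, int(is_rep), str(gpath), str(gene_path)]
            )
    toc = out / "toc.tsv"
    write_tsv(
        toc,
        ["genome_id", "species_id", "is_representative", "genome_path", "genes_path"],
        rows,
    )
    return toc


def write_truth(
    out_dir: str | Path,
    snvs: dict[str, list[tuple[int, str, str]]] | None = None,
    cnvs: dict[str, list[CnvEvent]] | None = None,
    composition: dict[str, dict[str, float]] | None = None,
) -> None:
    """Write truth_snvs / truth_cnvs / truth_composition TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if snvs is not None:
        rows = [
            [strain, pos + 1, ref, alt]
            for strain in sorted(snvs)
            for pos, ref, alt in snvs[strain]
        ]
        write_tsv(out / "truth_snvs.tsv", ["strain_id", "position", "ref", "alt"], rows)
    if cnvs is not None:
        rows = [
            [strain, ev.gene_id, ev.copies]
            for strain in sorted(cnvs)
            for ev in cnvs[strain]
        ]
        write_tsv(out / "truth_cnvs.tsv", ["strain_id", "gene_id", "copies"], rows)
    if composition is not None:
        rows = [
            [sample, strain, composition[sample][strain]]
            for sample in sorted(composition)
            for strain in sorted(composition[sample])
        ]
        write_tsv(
            out / "truth_composition.tsv", ["sample_id", "strain_id", "proportion"], rows
        )
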