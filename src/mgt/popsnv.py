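"""Across-samples step: chunked scan of per-sample pileups into
population SNVs.

Each genomic site is visited exactly once, inside exactly one chunk
(a half-open interval of contig positions). A site enters the output
when it is *relevant* — within the depth window — in a sufficient
fraction of samples; relevant samples' allele counts are pooled and the
pooled major/minor alleles computed. Chunks are self-contained work
units: the merged output is, by construction, byte-identical for any
chunk size and any worker count, which is the testable contract behind
chunk-parallel execution.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import BASES, write_tsv

DEFAULT_CHUNK_SIZE = 100_000
#: an allele counts toward the site's allele class (mono/bi/tri/quad)
#: only with pooled frequency >= ALLELE_FREQ_MIN and pooled count >=
#: ALLELE_MIN_COUNT; either floor alone lets a single stray error read
#: relabel a bi-allelic site tri-allelic (at low pooled depth the count
#: floor matters, at high pooled depth the frequency floor does)
ALLELE_FREQ_MIN = 0.01
ALLELE_MIN_COUNT = 2
ALLELE_CLASS = {0: "none", 1: "mono", 2: "bi", 3: "tri", 4: "quad"}


@dataclass
class SiteFilters:
    """Per-site relevance and prevalence thresholds (all CLI-exposed)."""

    site_min_depth: int = 5
    site_max_depth_fold: float = 3.0
    min_sample_prevalence: float = 0.8

    def __post_init__(self):
        if min(self.site_min_depth, self.site_max_depth_fold) < 0:
            raise ValueError("depth thresholds must be >= 0")
        if not 0 <= self.min_sample_prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")


@dataclass(frozen=True)
class Chunk:
    species_id: str
    contig_id: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    chunk_id: int


@dataclass
class PooledSite:
    species_id: str
    contig_id: str
    position: int  # 0-based
    ref_allele: str
    n_relevant_samples: int
    pooled_counts: np.ndarray  # summed over relevant samples
    pooled_major: str
    pooled_minor: Optional[str]
    allele_class: str
    sample_minor_freq: dict[str, float]  # relevant samples only
    sample_depth: dict[str, int]


def make_chunks(
    contig_lengths: dict[str, int], chunk_size: int = DEFAULT_CHUNK_SIZE
) -> list[Chunk]:
    """Tile every contig with consecutive [i·c, min((i+1)·c, L)) chunks.

    ``contig_lengths`` is keyed by the customized-target contig id
    ``species|contig``; ids are assigned in (species, contig, start)
    order.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    chunks: list[Chunk] = []
    cid_counter = 0
    for contig in sorted(contig_lengths):
        L = contig_lengths[contig]
        species = contig.split("|", 1)[0]
        for start in range(0, L, chunk_size):
            chunks.append(Chunk(species, contig, start, min(start + chunk_size, L), cid_counter))
            cid_counter += 1
    return chunks


def site_relevance(depth: int, sample_mean_depth: float, filters: SiteFilters) -> bool:
    """Depth-window test for one site in one sample."""
    return (
        depth >= filters.site_min_depth
        and depth <= filters.site_max_depth_fold * sample_mean_depth
    )


def pool_site(
    count_matrix: np.ndarray, method: str = "counts"
) -> tuple[int, Optional[int], np.ndarray]:
    """Pool one site's (n_relevant, 4) count matrix.

    "counts": pooled major = argmax of summed counts. "prevalence":
    each sample votes its own major allele; the most-voted allele wins.
    Ties break lexicographically (A<C<G<T). The minor allele is the
    runner-up by the same statistic with nonzero support; under
    "prevalence", sites whose runner-up collects no votes fall back to
    the pooled-count runner-up so bi-allelic sites keep their minor.

    Returns (major index, minor index or None, pooled count vector).
    """
    pooled = count_matrix.sum(axis=0)
    if method == "counts":
        ranked = sorted(range(4), key=lambda i: (-pooled[i], i))
        major = ranked[0]
        minor = ranked[1] if pooled[ranked[1]] > 0 else None
    elif method == "prevalence":
        votes = np.zeros(4, dtype=int)
        for row in count_matrix:
            votes[min(range(4), key=lambda i: (-row[i], i))] += 1
        ranked = sorted(range(4), key=lambda i: (-votes[i], i))
        major = ranked[0]
        if votes[ranked[1]] > 0:
            minor = ranked[1]
        else:
            fallback = sorted(
                (i for i in range(4) if i != major), key=lambda i: (-pooled[i], i)
            )
            minor = fallback[0] if pooled[fallback[0]] > 0 else None
    else:
        raise ValueError(f"unknown pooling method {method!r}")
    return major, minor, pooled


# ---------------------------------------------------------------------------
# Sample pileup loading


class SamplePileup:
    """Per-sample allele counts as dense per-contig arrays."""

    def __init__(self, counts: dict[str, np.ndarray], species_mean_depth: dict[str, float]):
        self.counts = counts
        self.species_mean_depth = species_mean_depth


def load_sample_pileup(
    path: str | Path, contig_lengths: dict[str, int]
) -> SamplePileup:
    """Load a single-sample pileup TSV into dense count arrays.

    Validates that positions are strictly increasing within each contig
    (the single-sample step writes them sorted); violations raise with
    the file and position named.
    """
    df = pd.read_csv(str(path), sep="\t", dtype={"species_id": str, "contig_id": str})
    counts: dict[str, np.ndarray] = {}
    last: dict[str, int] = {}
    col = df[["count_A", "count_C", "count_G", "count_T"]].to_numpy()
    for i, (contig, pos1) in enumerate(zip(df["contig_id"], df["position"])):
        if contig not in contig_lengths:
            raise KeyError(f"{path}: pileup contig {contig!r} not in database target")
        if contig not in counts:
            counts[contig] = np.zeros((contig_lengths[contig], 4), dtype=np.int64)
        pos = int(pos1) - 1
        if pos <= last.get(contig, -1):
            raise ValueError(f"{path}: unsorted pileup at {contig}:{pos1}")
        last[contig] = pos
        counts[contig][pos] = col[i]

    species_depth: dict[str, float] = {}
    species_len: dict[str, int] = {}
    for contig, L in contig_lengths.items():
        sid = contig.split("|", 1)[0]
        species_len[sid] = species_len.get(sid, 0) + L
        if contig in counts:
            species_depth[sid] = species_depth.get(sid, 0.0) + float(counts[contig].sum())
    mean = {sid: species_depth.get(sid, 0.0) / L for sid, L in species_len.items()}
    return SamplePileup(counts, mean)


# ---------------------------------------------------------------------------
# Chunk processing and merge


def process_chunk(
    chunk: Chunk,
    samples: dict[str, SamplePileup],
    filters: SiteFilters,
    ref_seq: str,
    method: str = "counts",
) -> list[PooledSite]:
    """Pool every qualifying site of one chunk; no cross-chunk state."""
    sample_ids = sorted(samples)
    n_samples = len(sample_ids)
    width = chunk.end - chunk.start
    depth_mat = np.zeros((n_samples, width), dtype=np.int64)
    count_mats = np.zeros((n_samples, width, 4), dtype=np.int64)
    means = np.zeros(n_samples)
    for si, sid in enumerate(sample_ids):
        sp = samples[sid]
        means[si] = sp.species_mean_depth.get(chunk.species_id, 0.0)
        arr = sp.counts.get(chunk.contig_id)
        if arr is not None:
            count_mats[si] = arr[chunk.start : chunk.end]
            depth_mat[si] = count_mats[si].sum(axis=1)

    relevant = (depth_mat >= filters.site_min_depth) & (
        depth_mat <= filters.site_max_depth_fold * means[:, None]
    )
    n_relevant = relevant.sum(axis=0)
    keep = np.flatnonzero(
        (n_relevant >= 1) & (n_relevant / n_samples >= filters.min_sample_prevalence)
    )

    out: list[PooledSite] = []
    for off in keep:
        rel_idx = np.flatnonzero(relevant[:, off])
        cmat = count_mats[rel_idx, off, :]
        major, minor, pooled = pool_site(cmat, method)
        depth_pooled = pooled.sum()
        n_alleles = int(
            np.count_nonzero(
                (pooled / depth_pooled >= ALLELE_FREQ_MIN) & (pooled >= ALLELE_MIN_COUNT)
            )
        )
        minor_freqs = {}
        depths = {}
        for si in rel_idx:
            d = int(depth_mat[si, off])
            depths[sample_ids[si]] = d
            mf = float(count_mats[si, off, minor] / d) if minor is not None else 0.0
            minor_freqs[sample_ids[si]] = mf
        out.append(
            PooledSite(
                chunk.species_id,
                chunk.contig_id,
                chunk.start + int(off),
                ref_seq[chunk.start + int(off)],
                int(n_relevant[off]),
                pooled,
                BASES[major],
                BASES[minor] if minor is not None else None,
                ALLELE_CLASS[n_alleles],
                minor_freqs,
                depths,
            )
        )
    return out


def merge_chunks(accumulators: list[list[PooledSite]]) -> list[PooledSite]:
    """Order-independent merge: concatenate and sort by genomic position.

    Accumulators must cover disjoint chunks; a duplicated site indicates
    overlapping chunks and raises.
    """
    merged = [s for acc in accumulators for s in acc]
    merged.sort(key=lambda s: (s.species_id, s.contig_id, s.position))
    for a, b in zip(merged, merged[1:]):
        if (a.species_id, a.contig_id, a.position) == (b.species_id, b.contig_id, b.position):
            raise ValueError(
                f"overlapping chunks: site {a.contig_id}:{a.position + 1} pooled twice"
            )
    return merged


def merge_samples(
    sample_pileups: dict[str, str | Path],
    contig_lengths: dict[str, int],
    ref_seqs: dict[str, str],
    filters: SiteFilters | None = None,
    method: str = "counts",
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    workers: int = 1,
    out_dir: str | Path | None = None,
) -> list[PooledSite]:
    """Full across-samples step over per-sample pileup TSVs.

    ``contig_lengths``/``ref_seqs`` describe the customized target
    (contig ids ``species|contig``). When ``out_dir`` is given, writes
    per-species snps_info / snps_freq / snps_depth TSVs.
    """
    filters = filters or SiteFilters()
    samples = {
        sid: load_sample_pileup(p, contig_lengths) for sid, p in sample_pileups.items()
    }
    chunks = make_chunks(contig_lengths, chunk_size)

    def work(chunk: Chunk) -> list[PooledSite]:
        return process_chunk(chunk, samples, filters, ref_seqs[chunk.contig_id], method)

    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            accumulators = list(pool.map(work, chunks))
    else:
        accumulators = [work(c) for c in chunks]
    merged = merge_chunks(accumulators)
    if out_dir is not None:
        write_matrices(out_dir, merged, sorted(samples))
    return merged


def write_matrices(
    out_dir: str | Path, sites: list[PooledSite], sample_ids: list[str]
) -> None:
    """Write per-species snps_info.tsv, snps_freq.tsv and snps_depth.tsv.

    The frequency matrix holds each relevant sample's frequency of the
    pooled minor allele (NA where the sample was not relevant); the
    depth matrix holds raw site depth per sample.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_species: dict[str, list[PooledSite]] = {}
    for s in sites:
        by_species.setdefault(s.species_id, []).append(s)
    for sid in sorted(by_species):
        sp_dir = out / sid
        sp_dir.mkdir(exist_ok=True)
        rows_info, rows_freq, rows_depth = [], [], []
        for s in by_species[sid]:
            site_id = f"{s.contig_id}|{s.position + 1}"
            rows_info.append(
                [
                    site_id,
                    s.ref_allele,
                    s.pooled_major,
                    s.pooled_minor or "",
                    s.n_relevant_samples,
                    s.allele_class,
                    *[int(c) for c in s.pooled_counts],
                ]
            )
            rows_freq.append(
                [site_id]
                + [
                    f"{s.sample_minor_freq[x]:.6g}" if x in s.sample_minor_freq else "NA"
                    for x in sample_ids
                ]
            )
            rows_depth.append(
                [site_id]
                + [str(s.sample_depth[x]) if x in s.sample_depth else "NA" for x in sample_ids]
            )
        write_tsv(
            sp_dir / "snps_info.tsv",
            [
                "site_id",
                "ref_allele",
                "pooled_major",
                "pooled_minor",
                "n_relevant_samples",
                "allele_class",
                "pooled_count_A",
                "pooled_count_C",
                "pooled_count_G",
                "pooled_count_T",
            ],
            rows_info,
        )
        write_tsv(sp_dir / "snps_freq.tsv", ["site_id", *sample_ids], rows_freq)
        write_tsv(sp_dir / "snps_depth.tsv", ["site_id", *sample_ids], rows_depth)
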