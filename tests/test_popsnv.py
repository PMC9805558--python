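"""Across-samples step: chunking, site relevance, pooling (against a
brute-force oracle) and the chunk/worker-invariant merge."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mgt.io import BASES, sha256_file, write_tsv
from mgt.pileup import PILEUP_COLUMNS
from mgt.popsnv import (
    Chunk,
    SiteFilters,
    load_sample_pileup,
    make_chunks,
    merge_chunks,
    merge_samples,
    pool_site,
    process_chunk,
    site_relevance,
)


class TestMakeChunks:
    def test_tiling_with_remainder(self):
        chunks = make_chunks({"s1|c1": 10}, 4)
        assert [(c.start, c.end) for c in chunks] == [(0, 4), (4, 8), (8, 10)]
        assert [c.chunk_id for c in chunks] == [0, 1, 2]

    def test_oversized_chunk_is_whole_contig(self):
        chunks = make_chunks({"s1|c1": 10}, 1000)
        assert [(c.start, c.end) for c in chunks] == [(0, 10)]

    @given(L=st.integers(1, 500), c=st.integers(1, 64))
    def test_chunks_partition_contig(self, L, c):
        chunks = make_chunks({"s1|c1": L}, c)
        assert sum(ch.end - ch.start for ch in chunks) == L
        assert chunks[0].start == 0 and chunks[-1].end == L
        for a, b in zip(chunks, chunks[1:]):
            assert a.end == b.start


class TestSiteRelevance:
    def test_depth_window(self):
        f = SiteFilters(site_min_depth=5, site_max_depth_fold=3.0)
        assert site_relevance(10, 10.0, f)
        assert not site_relevance(100, 10.0, f)  # repeat guard
        assert not site_relevance(4, 10.0, f)


def brute_force_pool(count_matrix, method):
    """Independent pooling over the explicit n x 4 matrix."""
    if method == "counts":
        stat = [sum(row[i] for row in count_matrix) for i in range(4)]
    else:
        stat = [0] * 4
        for row in count_matrix:
            best = max(range(4), key=lambda i: (row[i], -i))
            stat[best] += 1
    order = sorted(range(4), key=lambda i: (-stat[i], BASES[i]))
    pooled = [sum(row[i] for row in count_matrix) for i in range(4)]
    major = order[0]
    if stat[order[1]] > 0:
        minor = order[1]
    else:
        rest = sorted((i for i in range(4) if i != major), key=lambda i: (-pooled[i], i))
        minor = rest[0] if pooled[rest[0]] > 0 else None
    return major, minor


class TestPoolSite:
    def test_counts_method_sums_samples(self):
        mat = np.array([[9, 1, 0, 0], [8, 2, 0, 0]])
        major, minor, pooled = pool_site(mat, "counts")
        assert (major, minor) == (0, 1)
        assert pooled.tolist() == [17, 3, 0, 0]

    def test_prevalence_method_votes(self):
        mat = np.array([[9, 1, 0, 0], [6, 4, 0, 0], [1, 9, 0, 0]])
        major, _, _ = pool_site(mat, "prevalence")
        assert major == 0  # two samples' major is A

    def test_tie_breaks_lexicographic(self):
        mat = np.array([[0, 5, 5, 0]])
        major, minor, _ = pool_site(mat, "counts")
        assert (BASES[major], BASES[minor]) == ("C", "G")

    @pytest.mark.parametrize("method", ["counts", "prevalence"])
    def test_matches_brute_force_on_random_matrices(self, method):
        rng = np.random.default_rng(71)
        for _ in range(50):
            mat = rng.integers(0, 20, size=(5, 4))
            mat[mat.sum(axis=1) == 0, 0] = 1
            major, minor, pooled = pool_site(mat, method)
            want_major, want_minor = brute_force_pool(mat.tolist(), method)
            assert major == want_major and minor == want_minor
            assert pooled.tolist() == mat.sum(axis=0).tolist()


def _write_pileup(path, contig, rows):
    """rows: (pos0, ref, a, c, g, t)"""
    out = []
    for pos, ref, a, c, g, t in rows:
        depth = a + c + g + t
        out.append(["s1", contig, pos + 1, ref, depth, a, c, g, t, "A", "", 1.0])
    write_tsv(path, PILEUP_COLUMNS, out)


class TestProcessChunk:
    def _samples(self, tmp_path, coverage_rows):
        paths = {}
        for sid, rows in coverage_rows.items():
            p = tmp_path / f"{sid}.tsv"
            _write_pileup(p, "s1|c1", rows)
            paths[sid] = p
        return {
            sid: load_sample_pileup(p, {"s1|c1": 100}) for sid, p in paths.items()
        }

    def test_full_prevalence_keeps_all_sites(self, tmp_path):
        rows = [(i, "A", 10, 0, 0, 0) for i in range(100)]
        samples = self._samples(tmp_path, {"x": rows, "y": rows})
        filters = SiteFilters(5, 1000.0, 1.0)
        sites = process_chunk(Chunk("s1", "s1|c1", 0, 100, 0), samples, filters, "A" * 100)
        assert len(sites) == 100
        assert all(s.n_relevant_samples == 2 for s in sites)

    def test_prevalence_threshold_excludes_half_covered(self, tmp_path):
        rows = [(i, "A", 10, 0, 0, 0) for i in range(100)]
        samples = self._samples(tmp_path, {"x": rows, "y": []})
        strict = SiteFilters(5, 1000.0, 1.0)
        loose = SiteFilters(5, 1000.0, 0.5)
        assert process_chunk(Chunk("s1", "s1|c1", 0, 100, 0), samples, strict, "A" * 100) == []
        sites = process_chunk(Chunk("s1", "s1|c1", 0, 100, 0), samples, loose, "A" * 100)
        assert len(sites) == 100 and all(s.n_relevant_samples == 1 for s in sites)

    def test_pooled_counts_conserve_depth(self, tmp_path):
        rng = np.random.default_rng(73)
        rows_x = [(i, "A", *rng.integers(2, 10, 4)) for i in range(50)]
        rows_y = [(i, "A", *rng.integers(2, 10, 4)) for i in range(50)]
        samples = self._samples(tmp_path, {"x": rows_x, "y": rows_y})
        filters = SiteFilters(5, 1000.0, 1.0)
        sites = process_chunk(Chunk("s1", "s1|c1", 0, 100, 0), samples, filters, "A" * 100)
        for s in sites:
            assert s.pooled_counts.sum() == sum(s.sample_depth.values())

    def test_unsorted_pileup_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        _write_pileup(p, "s1|c1", [(5, "A", 9, 0, 0, 0), (3, "A", 9, 0, 0, 0)])
        with pytest.raises(ValueError, match="unsorted"):
            load_sample_pileup(p, {"s1|c1": 100})

    def test_unknown_contig_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        _write_pileup(p, "sX|weird", [(5, "A", 9, 0, 0, 0)])
        with pytest.raises(KeyError, match="weird"):
            load_sample_pileup(p, {"s1|c1": 100})


class TestMergeChunks:
    def test_order_independent(self):
        from mgt.popsnv import PooledSite

        def site(pos):
            return PooledSite("s1", "c", pos, "A", 1, np.array([5, 0, 0, 0]), "A", None, "mono", {}, {})

        a, b = [site(0), site(1)], [site(2)]
        fwd = merge_chunks([a, b])
        rev = merge_chunks([b, a])
        assert [s.position for s in fwd] == [s.position for s in rev] == [0, 1, 2]

    def test_overlapping_chunks_rejected(self):
        from mgt.popsnv import PooledSite

        s = PooledSite("s1", "c", 5, "A", 1, np.array([5, 0, 0, 0]), "A", None, "mono", {}, {})
        with pytest.raises(ValueError, match="overlap"):
            merge_chunks([[s], [s]])

    def test_empty_accumulators_give_empty_output(self, tmp_path):
        from mgt.popsnv import write_matrices

        write_matrices(tmp_path, [], ["x"])
        assert list(tmp_path.iterdir()) == []  # no species, no files
        assert merge_chunks([]) == []


class TestMergeInvariance:
    """The chunk-parallel contract: output invariant to chunk size and
    worker count, proven on the 10-sample two-strain scenario."""

    def test_chunk_size_and_workers_do_not_change_output(self, two_strain_run, tmp_path):
        _, run_dir, _ = two_strain_run
        pileups = {
            p.parent.name: p for p in sorted(run_dir.glob("samples/*/snps_pileup.tsv"))
        }
        ref = pd.read_csv(run_dir / "db" / "manifest.tsv", sep="\t")
        from mgt.db import load_db

        db = load_db(run_dir / "db")
        ref_seqs = {
            f"s1|{cid}": seq for cid, seq in db.representative_seqs("s1").items()
        }
        lengths = {k: len(v) for k, v in ref_seqs.items()}
        digests = set()
        for chunk_size, workers in [(1, 1), (7, 1), (100_000, 1), (7, 8)]:
            out = tmp_path / f"m_{chunk_size}_{workers}"
            merge_samples(
                pileups, lengths, ref_seqs,
                chunk_size=chunk_size, workers=workers, out_dir=out,
            )
            digests.add(
                tuple(
                    sha256_file(out / "s1" / name)
                    for name in ("snps_info.tsv", "snps_freq.tsv", "snps_depth.tsv")
                )
            )
        assert len(digests) == 1

    def test_prevalence_monotonicity(self, two_strain_run):
        _, run_dir, _ = two_strain_run
        from mgt.db import load_db

        db = load_db(run_dir / "db")
        ref_seqs = {f"s1|{c}": s for c, s in db.representative_seqs("s1").items()}
        lengths = {k: len(v) for k, v in ref_seqs.items()}
        pileups = {
            p.parent.name: p for p in sorted(run_dir.glob("samples/*/snps_pileup.tsv"))
        }
        n_sites = []
        for prev in (0.5, 0.8, 1.0):
            sites = merge_samples(
                pileups, lengths, ref_seqs,
                filters=SiteFilters(min_sample_prevalence=prev),
            )
            n_sites.append(len(sites))
        assert n_sites[0] >= n_sites[1] >= n_sites[2]
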