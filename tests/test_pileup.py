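"""Single-sample step: post-alignment filters, mate-overlap resolution,
pileup (against a brute-force column-count oracle) and SNV calls."""

import numpy as np
import pytest

from mgt.aligner import Alignment
from mgt.io import BASE_INDEX, revcomp
from mgt.pileup import (
    FilterParams,
    SitePileup,
    call_sample_snv,
    compute_pileup,
    filter_alignment,
    resolve_mate_overlap,
    single_sample,
)
from mgt.sim import make_genome, simulate_reads


def _aln(seq, pos, contig="c1", qual=40, mapq=60, nm=0, cigar=None, **kw):
    q = np.full(len(seq), qual, dtype=int)
    return Alignment(
        read_id=kw.pop("read_id", "r"),
        contig=contig,
        pos=pos,
        cigar=cigar or [("M", len(seq))],
        seq=seq,
        qual=q,
        mapq=mapq,
        nm=nm,
        **kw,
    )


PARAMS_UNPAIRED = FilterParams(require_proper_pair=False)


class TestFilterAlignment:
    def test_low_mapq_dropped(self):
        a = _aln("ACGT" * 25, 0, mapq=5)
        assert filter_alignment(a, PARAMS_UNPAIRED) == "mapq"

    def test_identity_arithmetic(self):
        a = _aln("ACGT" * 25, 0, nm=12)  # 0.88 < 0.90
        assert filter_alignment(a, PARAMS_UNPAIRED) == "identity"
        a = _aln("ACGT" * 25, 0, nm=10)  # 0.90 passes
        assert filter_alignment(a, PARAMS_UNPAIRED) is None

    def test_aligned_fraction_boundary(self):
        cigar = [("M", 80), ("S", 20)]
        a = _aln("ACGT" * 25, 0, cigar=cigar)  # 0.80 >= 0.75
        assert filter_alignment(a, PARAMS_UNPAIRED) is None
        cigar = [("M", 70), ("S", 30)]
        a = _aln("ACGT" * 25, 0, cigar=cigar)
        assert filter_alignment(a, PARAMS_UNPAIRED) == "aln_cov"

    def test_proper_pair_requirement(self):
        strict = FilterParams()
        a = _aln("ACGT" * 25, 0)
        assert filter_alignment(a, strict) == "improper_pair"
        a = _aln("ACGT" * 25, 0, is_proper_pair=True, template_len=1500)
        assert filter_alignment(a, strict) == "template_len"
        a = _aln("ACGT" * 25, 0, is_proper_pair=True, template_len=300)
        assert filter_alignment(a, strict) is None

    def test_unmapped_secondary_supplementary(self):
        for attr in ("is_unmapped", "is_secondary", "is_supplementary"):
            a = _aln("ACGT" * 25, 0, **{attr: True})
            assert filter_alignment(a, PARAMS_UNPAIRED) == attr.removeprefix("is_")


class TestMateOverlap:
    def test_agreement_counted_once_higher_quality(self):
        m1 = _aln("AAAA", 0, qual=30)
        m2 = _aln("AAAA", 2, qual=20)
        frag = resolve_mate_overlap([m1, m2])
        assert frag[2] == ("A", 30) and frag[3] == ("A", 30)
        assert frag[4] == ("A", 20) and frag[5] == ("A", 20)
        assert len(frag) == 6

    def test_disagreement_higher_quality_wins(self):
        m1 = _aln("A", 0, qual=30)
        m2 = _aln("C", 0, qual=20)
        assert resolve_mate_overlap([m1, m2]) == {0: ("A", 30)}
        assert resolve_mate_overlap([m2, m1]) == {0: ("A", 30)}

    def test_quality_tie_contributes_nothing(self):
        m1 = _aln("A", 0, qual=30)
        m2 = _aln("C", 0, qual=30)
        assert resolve_mate_overlap([m1, m2]) == {}


def brute_force_pileup(fragments, contig_len, min_baseq=30):
    """Independent oracle: lay every fragment into a position x fragment
    matrix and count each column."""
    matrix = []
    for mates in fragments:
        row = {}
        for m in mates:
            for pos, (base, q) in sorted(m.reference_positions().items()):
                if pos in row and row[pos][0] != base:
                    row[pos] = None if row[pos][1] == q else max(row[pos], (base, q), key=lambda x: x[1])
                elif pos in row:
                    row[pos] = (base, max(q, row[pos][1]))
                else:
                    row[pos] = (base, q)
        matrix.append(row)
    counts = np.zeros((contig_len, 4), dtype=int)
    for row in matrix:
        for pos, cell in row.items():
            if cell is not None and cell[1] >= min_baseq and cell[0] in BASE_INDEX:
                counts[pos, BASE_INDEX[cell[0]]] += 1
    return counts


class TestComputePileup:
    def test_single_perfect_fragment(self):
        ref = "ACGTACGTAC" * 10
        a = _aln(ref, 0, is_proper_pair=True, template_len=100)
        counts = compute_pileup([[a]], {"c1": ref}, FilterParams())
        assert counts["c1"].sum() == 100
        for i, b in enumerate(ref):
            assert counts["c1"][i, BASE_INDEX[b]] == 1

    def test_low_quality_base_excluded(self):
        ref = "ACGT" * 25
        a = _aln(ref, 0, is_proper_pair=True, template_len=100)
        a.qual[5] = 10
        counts = compute_pileup([[a]], {"c1": ref}, FilterParams())
        assert counts["c1"][5].sum() == 0 and counts["c1"].sum() == 99

    def test_matches_brute_force_oracle_on_random_fragments(self):
        rng = np.random.default_rng(23)
        g = make_genome("g", 1000, n_genes=0, seed=23)
        fragments = []
        for i in range(50):
            start = int(rng.integers(0, 800))
            flen = int(rng.integers(150, 200))
            frag = g.seq[start : start + flen]
            m1 = _aln(frag[:100], start, contig="g_c1", read_id=f"f{i}", is_proper_pair=True, template_len=flen)
            m2 = _aln(
                frag[-100:], start + flen - 100, contig="g_c1", read_id=f"f{i}",
                is_proper_pair=True, template_len=flen, is_read1=False, is_reverse=True,
            )
            fragments.append([m1, m2])
        got = compute_pileup(fragments, {"g_c1": g.seq}, FilterParams())["g_c1"]
        want = brute_force_pileup(fragments, 1000)
        assert np.array_equal(got, want)

    def test_fully_overlapping_pairs_count_once(self):
        ref = "ACGT" * 25
        frags = []
        for i in range(10):
            m1 = _aln(ref, 0, read_id=f"f{i}", is_proper_pair=True, template_len=100)
            m2 = _aln(ref, 0, read_id=f"f{i}", is_proper_pair=True, template_len=100,
                      is_read1=False, is_reverse=True)
            frags.append([m1, m2])
        counts = compute_pileup(frags, {"c1": ref}, FilterParams())
        assert counts["c1"].sum(axis=1).max() == 10  # never 2 x 10

    def test_alignment_past_contig_end_rejected(self):
        a = _aln("ACGT" * 25, 950, is_proper_pair=True, template_len=100)
        with pytest.raises(ValueError, match="exceeds contig"):
            compute_pileup([[a]], {"c1": "A" * 1000}, FilterParams())

    def test_unknown_contig_rejected(self):
        a = _aln("ACGT" * 25, 0, contig="mystery", is_proper_pair=True, template_len=100)
        with pytest.raises(KeyError, match="mystery"):
            compute_pileup([[a]], {"c1": "A" * 100}, FilterParams())


class TestCallSampleSnv:
    def _site(self, a, c, g, t):
        return SitePileup("s", "c", 0, "A", np.array([a, c, g, t]))

    def test_major_minor_and_freq(self):
        snv = call_sample_snv(self._site(8, 2, 0, 0), min_depth=2)
        assert (snv.major_allele, snv.minor_allele) == ("A", "C")
        assert snv.major_freq == pytest.approx(0.8)

    def test_tie_breaks_lexicographically(self):
        snv = call_sample_snv(self._site(5, 5, 0, 0), min_depth=2)
        assert (snv.major_allele, snv.minor_allele) == ("A", "C")
        snv = call_sample_snv(self._site(0, 0, 3, 3), min_depth=2)
        assert (snv.major_allele, snv.minor_allele) == ("G", "T")

    def test_depth_window(self):
        assert call_sample_snv(self._site(1, 0, 0, 0), min_depth=2) is None
        assert call_sample_snv(self._site(9000, 2000, 0, 0), max_depth=10_000) is None

    def test_monomorphic_site_has_no_minor(self):
        snv = call_sample_snv(self._site(7, 0, 0, 0), min_depth=2)
        assert snv.minor_allele is None and snv.major_freq == 1.0


class TestEndToEndPileup:
    def test_error_free_tiling_matches_reference(self):
        g = make_genome("g", 3000, n_genes=0, seed=31)
        r1, r2, _ = simulate_reads([(g, 1.0)], 10.0, seed=31)
        reads = [((f"{rid}", s1, q1), (rid, s2, q2)) for (rid, s1, q1), (rid2, s2, q2) in zip(r1, r2)]
        counts = single_sample({"g_c1": g.seq}, read_pairs=reads)["g_c1"]
        # every counted base agrees with the reference at q40, no errors
        for pos in np.flatnonzero(counts.sum(axis=1)):
            nz = np.flatnonzero(counts[pos])
            assert len(nz) == 1 and "ACGT"[nz[0]] == g.seq[pos]
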