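"""Concordance statistics, count trees, GAF summaries, binomial imbalance."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import graphloci as gl
from graphloci.metrics import GafRecord, GafSummary


def _matrix(data, assemblies=("a", "b", "c")):
    return pd.DataFrame(data, columns=list(assemblies), dtype=float)


class TestAgreement:
    def test_all_methods_identical(self):
        m = _matrix([[1, 2, 3], [4, 5, 6]])
        summary = gl.agreement_summary({"p": m, "c": m.copy(), "m": m.copy()})
        assert summary.identical_in_all == 2
        assert summary.identical_in_at_least_two == 2
        assert summary.identical_in_none == 0

    def test_single_cell_difference_demotes_locus(self):
        m1 = _matrix([[1, 2, 3], [4, 5, 6]])
        m3 = m1.copy()
        m3.iloc[0, 0] = 9  # method m differs at locus 0, assembly a
        summary = gl.agreement_summary({"p": m1, "c": m1.copy(), "m": m3})
        assert summary.identical_in_all == 1
        assert summary.identical_in_at_least_two == 2  # p-c still agree at locus 0

    def test_missing_value_excludes_locus(self):
        m1 = _matrix([[1, 2, 3], [4, 5, 6]])
        m2 = m1.copy()
        m2.iloc[1, 1] = np.nan
        summary = gl.agreement_summary({"p": m1, "c": m2})
        assert summary.n_common == 1

    def test_empty_intersection(self):
        m1 = _matrix([[1, 2, 3]])
        m2 = _matrix([[1, 2, 3]])
        m2.index = [99]
        summary = gl.agreement_summary({"p": m1, "c": m2})
        assert summary.as_dict() == {
            "common_loci": 0,
            "identical_in_all": 0,
            "identical_in_at_least_two": 0,
            "identical_in_none": 0,
        }


class TestCorrelation:
    def test_identity_is_one(self):
        x = [1, 2, 3, 4]
        assert gl.correlation(x, x, "pearson") == pytest.approx(1.0)
        assert gl.correlation(x, x, "spearman") == pytest.approx(1.0)

    def test_affine_invariance(self):
        x = np.array([1, 2, 3, 4])
        assert gl.correlation(x, 2 * x + 3, "pearson") == pytest.approx(1.0)

    def test_spearman_hand_example(self):
        # ranks of y=[1,3,2,4] vs x=[1,2,3,4]: rho = 0.8, rho^2 = 0.64
        assert gl.correlation([1, 2, 3, 4], [1, 3, 2, 4], "spearman") == pytest.approx(0.64)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            gl.correlation([1, 1, 1, 1], [1, 2, 3, 4], "pearson")

    def test_pairwise_deletion(self):
        x = [1, 2, np.nan, 3, 4]
        y = [1, 2, 5, 3, 4]
        assert gl.correlation(x, y, "pearson") == pytest.approx(1.0)

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(4)
        x = rng.permutation(20).astype(float)  # tie-free
        y = rng.permutation(20).astype(float)
        from scipy.stats import rankdata

        expected = gl.correlation(rankdata(x), rankdata(y), "pearson")
        assert gl.correlation(x, y, "spearman") == pytest.approx(expected)


class TestCountTree:
    def test_identical_vectors_zero_cherry(self):
        m = _matrix([[1, 1, 5], [2, 2, 9], [3, 3, 1]])
        newick = gl.count_tree(m)
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        a = tree.find_node_with_taxon_label("a")
        b = tree.find_node_with_taxon_label("b")
        assert a.edge.length == pytest.approx(0.0)
        assert b.edge.length == pytest.approx(0.0)

    def test_additive_distances_recover_topology(self):
        # ((a,b),(c,d)) with pendant lengths 1,2,3,4 and internal branch 10,
        # embedded in Manhattan space with one locus per tree edge (scaled by
        # the number of loci, since count_tree normalizes by shared loci)
        counts = {
            "a": [5, 0, 0, 0, 0],
            "b": [0, 10, 0, 0, 0],
            "c": [0, 0, 15, 0, 50],
            "d": [0, 0, 0, 20, 50],
        }
        m = pd.DataFrame(counts, dtype=float)
        newick = gl.count_tree(m)
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in tree.taxon_namespace}

        def d(x, y):
            return pdm.patristic_distance(tax[x], tax[y])

        # NJ on an additive matrix reproduces the metric exactly...
        expected = {("a", "b"): 3, ("a", "c"): 14, ("a", "d"): 15,
                    ("b", "c"): 15, ("b", "d"): 16, ("c", "d"): 7}
        for (x, y), dist in expected.items():
            assert d(x, y) == pytest.approx(dist)
        # ...and hence the generating topology by the four-point condition
        assert d("a", "b") + d("c", "d") < d("a", "c") + d("b", "d")
        assert d("a", "b") + d("c", "d") < d("a", "d") + d("b", "c")

    def test_locus_order_invariance(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(
            rng.integers(0, 30, size=(12, 4)), columns=list("abcd"), dtype=float
        )
        perm = m.sample(frac=1.0, random_state=1)
        assert gl.count_tree(m) == gl.count_tree(perm)

    def test_all_missing_assembly_excluded(self):
        m = _matrix([[1, 2, 3], [4, 5, 6], [7, 8, 9]], assemblies=("a", "b", "c"))
        m["d"] = np.nan
        with pytest.warns(UserWarning, match="'d'"):
            newick = gl.count_tree(m)
        assert "d" not in newick


class TestGaf:
    def _record(self, name="q1", qlen=1000, qstart=0, qend=1000, block=1000, nm=0):
        return GafRecord(
            query_name=name,
            query_length=qlen,
            query_start=qstart,
            query_end=qend,
            matches=block - (nm or 0),
            block_length=block,
            edit_distance=nm,
        )

    def test_zero_edits(self):
        s = gl.gaf_summary([self._record(nm=0)])["all"]
        assert s.edit_rate == 0.0

    def test_half_percent_edit_rate(self):
        s = gl.gaf_summary([self._record(nm=5)])["all"]
        assert s.edit_rate == pytest.approx(0.005)

    def test_double_coverage_from_multiple_alignments(self):
        records = [self._record(), self._record()]
        s = gl.gaf_summary(records)["all"]
        assert s.query_coverage == pytest.approx(2.0)

    def test_missing_nm_flagged_and_coverage_only(self):
        records = [self._record(nm=None), self._record(nm=10)]
        s = gl.gaf_summary(records)["all"]
        assert s.records_without_nm == 1
        assert s.total_block == 1000  # only the NM-bearing record
        assert s.edit_rate == pytest.approx(0.01)

    def test_summary_additive_over_concatenation(self):
        rng = np.random.default_rng(2)
        records = [
            self._record(name=f"q{i}", nm=int(rng.integers(0, 20)))
            for i in range(20)
        ]
        whole = gl.gaf_summary(records)["all"]
        parts = gl.gaf_summary(records[:7])["all"], gl.gaf_summary(records[7:])["all"]
        assert whole.total_edit == sum(p.total_edit for p in parts)
        assert whole.total_block == sum(p.total_block for p in parts)
        assert whole.aligned_query_bases == sum(p.aligned_query_bases for p in parts)

    def test_parse_gaf_with_tags(self):
        line = (
            "chr1:100-200\t100\t0\t100\t+\t>s1>s2\t150\t10\t110\t95\t100\t60"
            "\tNM:i:5\tAS:f:90\n"
        )
        (rec,) = gl.parse_gaf(io.StringIO(line))
        assert rec.edit_distance == 5
        assert rec.path == ">s1>s2"

    def test_partition_grouping_by_query_name(self):
        part = gl.classify_genome(
            [gl.RegionTrack("satellite", [("chr1", 0, 150)])], {"chr1": 1000}
        )
        records = [
            self._record(name="chr1:100-200", qlen=100, qend=100, block=100, nm=1),
            self._record(name="chr1:500-600", qlen=100, qend=100, block=100, nm=0),
        ]
        groups = gl.gaf_summary(records, partition=part)
        assert set(groups) == {"satellite", "normal"}
        assert groups["satellite"].edit_rate == pytest.approx(0.01)

    def test_invalid_query_interval_rejected(self):
        with pytest.raises(ValueError, match="bad query interval"):
            GafRecord("q", 100, 50, 200, matches=0, block_length=10)


class TestBinomImbalance:
    def test_paper_snp_pairs_three_sig_figs(self):
        assert gl.binom_imbalance(96, 135) == pytest.approx(1.01e-6, rel=5e-3)
        assert gl.binom_imbalance(94, 137) == pytest.approx(1.57e-5, rel=5e-3)

    def test_mode_observation_is_one(self):
        assert gl.binom_imbalance(5, 10) == pytest.approx(1.0)

    def test_symmetric_extreme(self):
        assert gl.binom_imbalance(10, 10) == pytest.approx(2 * 0.5**10)

    def test_matches_independent_minlike_summation(self):
        # oracle: sum all pmf values not exceeding pmf(k), computed from
        # binomial coefficients directly
        def oracle(k, n):
            pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
            return sum(p for p in pmf if p <= pmf[k] * (1 + 1e-7))

        for k, n in [(96, 135), (94, 137), (0, 7), (3, 11), (20, 40), (17, 23)]:
            assert gl.binom_imbalance(k, n) == pytest.approx(oracle(k, n), rel=1e-9)

    @given(st.integers(min_value=0, max_value=200), st.integers(min_value=1, max_value=200))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetry_and_range(self, k, n):
        k = min(k, n)
        p = gl.binom_imbalance(k, n)
        assert 0 < p <= 1
        assert p == pytest.approx(gl.binom_imbalance(n - k, n), rel=1e-12)

    def test_monotone_in_distance_from_null(self):
        n = 41
        pvals = [gl.binom_imbalance(k, n) for k in range(21, n + 1)]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gl.binom_imbalance(5, 0)
        with pytest.raises(ValueError):
            gl.binom_imbalance(11, 10)
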