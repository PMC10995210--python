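"""LIONESS scoring, thresholding and PPI intersection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssnflight import ssn


def _expr(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestPearsonMatrix:
    def test_identical_genes_score_one(self):
        x = np.arange(5.0)
        expr = _expr([x, x, x[::-1]], genes=["a", "b", "c"])
        out = ssn.pearson_matrix(expr, [("a", "b"), ("a", "c")])
        assert out[("a", "b")] == pytest.approx(1.0)
        assert out[("a", "c")] == pytest.approx(-1.0)

    def test_constant_gene_scores_zero(self):
        expr = _expr([[1, 1, 1, 1], [1, 2, 3, 4]], genes=["const", "var"])
        out = ssn.pearson_matrix(expr, [("const", "var")])
        assert out[("const", "var")] == 0.0

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(7)
        expr = _expr(rng.standard_normal((3, 5)))
        pairs = [("g0", "g1"), ("g0", "g2"), ("g1", "g2")]
        out = ssn.pearson_matrix(expr, pairs)
        for a, b in pairs:
            expected = stats.pearsonr(expr.loc[a], expr.loc[b]).statistic
            assert out[(a, b)] == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            ssn.pearson_matrix(_expr(np.ones((2, 2))), [("g0", "g1")])


class TestLionessScores:
    def test_equation_fixed_point_and_substitution(self):
        # If pcc_all == pcc_without_s == c the interpolation returns c;
        # generally score = N*(pcc_all - pcc_loo) + pcc_loo.
        rng = np.random.default_rng(0)
        expr = _expr(rng.standard_normal((4, 10)))
        pair = ("g0", "g1")
        sid = "s3"
        score = ssn.lioness_scores(expr, sid, [pair]).as_dict()[pair]
        n = 10
        r_all = stats.pearsonr(expr.loc["g0"], expr.loc["g1"]).statistic
        loo = expr.drop(columns=[sid])
        r_loo = stats.pearsonr(loo.loc["g0"], loo.loc["g1"]).statistic
        assert score == pytest.approx(n * (r_all - r_loo) + r_loo, abs=1e-10)
        assert n * (0.5 - 0.4) + 0.4 == pytest.approx(1.4)

    def test_leave_one_out_oracle_random_matrix(self):
        """Every score equals an explicit sample-deletion recomputation."""
        rng = np.random.default_rng(11)
        expr = _expr(rng.standard_normal((6, 8)))
        genes = list(expr.index)
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        for sid in expr.columns:
            scores = ssn.lioness_scores(expr, sid, pairs).as_dict()
            loo = expr.drop(columns=[sid])
            for a, b in pairs:
                r_all = stats.pearsonr(expr.loc[a], expr.loc[b]).statistic
                r_loo = stats.pearsonr(loo.loc[a], loo.loc[b]).statistic
                expected = 8 * (r_all - r_loo) + r_loo
                assert scores[(a, b)] == pytest.approx(expected, abs=1e-10)

    def test_minimum_background(self):
        expr = _expr(np.random.default_rng(1).standard_normal((3, 3)))
        with pytest.raises(ValueError):
            ssn.lioness_scores(expr, "s0")


class TestEdgeThreshold:
    def _set(self, values):
        pairs = [(f"a{i}", f"b{i}") for i in range(len(values))]
        return ssn.EdgeScoreSet("s", pairs, np.asarray(values, dtype=float), 10)

    def test_equal_scores_retain_nothing(self):
        stats_, retained = ssn.edge_threshold(self._set([0.7] * 8))
        assert stats_.w == pytest.approx(0.7)
        assert retained == set()

    def test_hand_computed_outlier(self):
        values = [0.0] * 9 + [10.0]
        stats_, retained = ssn.edge_threshold(self._set(values))
        # mu = 1, sigma = sqrt(sum((x-1)^2)/9) = sqrt(90/9) = sqrt(10)
        assert stats_.mu == pytest.approx(1.0)
        assert stats_.sigma == pytest.approx(np.sqrt(10.0))
        assert retained == {("a9", "b9")}

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_five_or_fewer_pairs_retain_nothing(self, n):
        # max z with sample sd is (n-1)/sqrt(n) < 2 for n <= 5
        rng = np.random.default_rng(n)
        for _ in range(20):
            stats_, retained = ssn.edge_threshold(self._set(rng.standard_normal(n)))
            assert retained == set()


class TestIntersectPpi:
    def test_empty_ppi(self):
        out = ssn.intersect_ppi({("A", "B")}, ssn.PPINetwork(frozenset()), "s")
        assert out.edges == frozenset()
        assert out.nodes == frozenset()

    def test_superset_identity(self):
        pairs = {("A", "B"), ("B", "C")}
        ppi = ssn.PPINetwork(frozenset(pairs | {("C", "D")}))
        out = ssn.intersect_ppi(pairs, ppi, "s")
        assert out.edges == frozenset(pairs)

    def test_hand_intersection(self):
        thresholded = {("A", "B"), ("B", "C"), ("C", "D")}
        ppi = ssn.PPINetwork(frozenset({("B", "C"), ("C", "D"), ("D", "E")}))
        out = ssn.intersect_ppi(thresholded, ppi, "s")
        assert out.edges == frozenset({("B", "C"), ("C", "D")})
        assert out.nodes == {"B", "C", "D"}


class TestBuildAllSsns:
    def test_one_network_per_sample(self, small_pipeline):
        ssns = small_pipeline["ssns"]
        expr = small_pipeline["expr"]
        assert len(ssns) == expr.shape[1]
        assert [s.sample_id for s in ssns] == list(expr.columns)

    def test_edges_subset_of_ppi(self, small_pipeline):
        ppi = small_pipeline["ppi"]
        for s in small_pipeline["ssns"]:
            assert s.edges <= ppi.edges

    def test_matches_componentwise_path(self, small_pipeline):
        """The batch builder agrees with score -> threshold -> intersect."""
        expr, ppi = small_pipeline["expr"], small_pipeline["ppi"]
        sample = expr.columns[3]
        scores = ssn.lioness_scores(expr, sample)
        stats_, retained = ssn.edge_threshold(scores)
        manual = ssn.intersect_ppi(retained, ppi, sample, stats_)
        batch = small_pipeline["ssns"][3]
        assert batch.edges == manual.edges
        assert batch.threshold.w == pytest.approx(stats_.w, abs=1e-12)

    def test_gene_relabeling_preserves_structure(self):
        rng = np.random.default_rng(3)
        expr = _expr(rng.standard_normal((12, 8)))
        ppi_pairs = {("g0", "g1"), ("g2", "g5"), ("g3", "g9"), ("g4", "g7")}
        ppi = ssn.PPINetwork(frozenset(ppi_pairs))
        ssns = ssn.build_all_ssns(expr, ppi)

        mapping = {g: f"z{i:02d}" for i, g in enumerate(expr.index)}
        expr2 = expr.rename(index=mapping)
        ppi2 = ssn.PPINetwork(
            frozenset(tuple(sorted((mapping[a], mapping[b]))) for a, b in ppi_pairs)
        )
        ssns2 = ssn.build_all_ssns(expr2, ppi2)
        for s1, s2 in zip(ssns, ssns2):
            assert len(s1.edges) == len(s2.edges)
            assert s1.threshold.w == pytest.approx(s2.threshold.w, abs=1e-10)
            relabeled = {tuple(sorted((mapping[a], mapping[b]))) for a, b in s1.edges}
            assert relabeled == set(s2.edges)

    def test_ppi_pairs_scope_recovers_planted(self, small_pipeline, small_spec):
        expr, ppi = small_pipeline["expr"], small_pipeline["ppi"]
        narrow = ssn.build_all_ssns(expr, ppi, pair_scope="ppi_pairs")
        planted = {
            tuple(sorted((f"G{p.a:04d}", f"G{p.b:04d}")))
            for p in small_spec.perturbed_pairs
        }
        wide_hits = set().union(*(s.edges for s in small_pipeline["ssns"])) & planted
        narrow_hits = set().union(*(s.edges for s in narrow)) & planted
        assert wide_hits and narrow_hits  # both scopes see planted edges


def test_stratified_background_equals_per_stratum_builds(small_pipeline):
    expr, ppi = small_pipeline["expr"], small_pipeline["ppi"]
    strata = pd.Series(
        ["A"] * 8 + ["B"] * 8, index=expr.columns
    )
    combined = ssn.build_all_ssns_stratified(expr, ppi, strata)
    assert [s.sample_id for s in combined] == list(expr.columns)
    direct_a = ssn.build_all_ssns(expr.loc[:, strata[strata == "A"].index], ppi)
    for got, want in zip(combined[:8], direct_a):
        assert got.edges == want.edges
        assert got.threshold.w == pytest.approx(want.threshold.w)


def test_ppi_symbol_matching_is_case_insensitive(caplog):
    table = pd.DataFrame({"a": [" g0 ", "G1", "gX"], "b": ["g1", "g2 ", "g0"]})
    net = ssn.PPINetwork.from_edge_list(table, gene_ids=["g0", "g1", "g2"])
    assert net.edges == frozenset({("g0", "g1"), ("g1", "g2")})
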