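"""Differential-interaction statistics on degree vectors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssnflight import digstats, synthetic_data as sd
from ssnflight.digstats import StratumSpec, identify_digs, stratified_digs


def _degrees(gc_rows, sf_rows, genes=None):
    """Degree matrix from per-gene (gc_vector, sf_vector) rows."""
    gc_rows, sf_rows = np.atleast_2d(gc_rows), np.atleast_2d(sf_rows)
    genes = genes or [f"g{i}" for i in range(gc_rows.shape[0])]
    gc_ids = [f"GC{i}" for i in range(gc_rows.shape[1])]
    sf_ids = [f"SF{i}" for i in range(sf_rows.shape[1])]
    df = pd.DataFrame(
        np.hstack([gc_rows, sf_rows]), index=genes, columns=gc_ids + sf_ids
    )
    return df, StratumSpec("t", tuple(sf_ids), tuple(gc_ids))


def test_identical_groups_not_significant():
    deg, stratum = _degrees([[1, 2, 3, 4]], [[1, 2, 3, 4]])
    (res,) = identify_digs(deg, stratum)
    assert res.t_stat == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert not res.is_dig


def test_pooled_t_matches_textbook_formula():
    gc = np.array([1, 2, 3, 4, 5], dtype=float)
    sf = np.array([6, 7, 8, 9, 10], dtype=float)
    deg, stratum = _degrees([gc], [sf])
    (res,) = identify_digs(deg, stratum)
    # equal variances -> pooled t = (mean_sf - mean_gc) / (s_p * sqrt(2/n))
    sp = np.sqrt(((gc.var(ddof=1) + sf.var(ddof=1)) / 2))
    expected_t = (sf.mean() - gc.mean()) / (sp * np.sqrt(2 / 5))
    assert res.t_stat == pytest.approx(expected_t, abs=1e-12)
    assert res.t_stat == pytest.approx(5.0)
    assert res.p_value < 0.05 and res.is_dig


def test_two_sidedness_label_swap():
    rng = np.random.default_rng(2)
    a = rng.poisson(3, size=8).astype(float)
    b = rng.poisson(5, size=8).astype(float)
    deg1, s1 = _degrees([a], [b])
    deg2, s2 = _degrees([b], [a])
    (r1,) = identify_digs(deg1, s1)
    (r2,) = identify_digs(deg2, s2)
    assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
    assert r1.t_stat == pytest.approx(-r2.t_stat, abs=1e-12)


def test_levene_gate_selects_welch():
    """With grossly unequal spreads, the reported p matches scipy's Welch
    t-test; with equal spreads it matches the pooled test."""
    rng = np.random.default_rng(3)
    tight = rng.normal(10, 0.1, size=20)
    wide = rng.normal(10, 5.0, size=20)
    deg, stratum = _degrees([tight], [wide])
    (res,) = identify_digs(deg, stratum)
    assert res.levene_p < 0.05
    expected = stats.ttest_ind(wide, tight, equal_var=False)
    assert res.p_value == pytest.approx(expected.pvalue, abs=1e-12)

    same1 = rng.normal(5, 1, size=20)
    same2 = rng.normal(5, 1, size=20)
    deg2, s2 = _degrees([same1], [same2])
    (res2,) = identify_digs(deg2, s2)
    assert res2.levene_p >= 0.05
    expected2 = stats.ttest_ind(same2, same1, equal_var=True)
    assert res2.p_value == pytest.approx(expected2.pvalue, abs=1e-12)


def test_degenerate_zero_variance_rules():
    deg, stratum = _degrees([[2, 2, 2], [2, 2, 2]], [[2, 2, 2], [5, 5, 5]])
    res = {r.gene_id: r for r in identify_digs(deg, stratum)}
    assert res["g0"].p_value == 1.0 and not res["g0"].is_dig
    assert res["g1"].p_value == 0.0 and res["g1"].is_dig


def test_monte_carlo_type_one_error():
    """1000 null genes drawn from one Poisson degree law: the DIG
    fraction at alpha = 0.05 stays within 0.05 +/- 0.015."""
    rng = np.random.default_rng(17)
    gc = rng.poisson(4, size=(1000, 30)).astype(float)
    sf = rng.poisson(4, size=(1000, 30)).astype(float)
    deg, stratum = _degrees(gc, sf)
    res = identify_digs(deg, stratum)
    rate = np.mean([r.is_dig for r in res])
    assert 0.035 <= rate <= 0.065


def test_bh_correction_is_more_conservative():
    rng = np.random.default_rng(5)
    gc = rng.poisson(4, size=(200, 15)).astype(float)
    sf = rng.poisson(4, size=(200, 15)).astype(float)
    deg, stratum = _degrees(gc, sf)
    raw = sum(r.is_dig for r in identify_digs(deg, stratum))
    bh = sum(r.is_dig for r in identify_digs(deg, stratum, bh_correct=True))
    assert bh <= raw


def test_group_too_small():
    deg, _ = _degrees([[1, 2]], [[3, 4]])
    bad = StratumSpec("t", ("SF0",), ("GC0", "GC1"))
    with pytest.raises(ValueError):
        identify_digs(deg, bad)


class TestStratified:
    def test_none_equals_global(self, hub_pipeline):
        deg, md = hub_pipeline["degrees"], hub_pipeline["metadata"]
        out = stratified_digs(deg, md, "none")
        assert set(out) == {"all"}
        sf = tuple(md[md["condition"] == "SF"]["sample_id"])
        gc = tuple(md[md["condition"] == "GC"]["sample_id"])
        direct = identify_digs(deg, StratumSpec("all", sf, gc))
        assert [r.p_value for r in out["all"]] == [r.p_value for r in direct]

    def test_tissue_strata_recover_their_own_perturbations(self):
        """Two tissues with disjoint tissue-gated perturbed blocks: with a
        per-tissue network background, each tissue's DIG ranking is
        enriched only for its own planted genes."""
        from sklearn.metrics import roc_auc_score

        from ssnflight import features, preprocess, ssn

        pairs = tuple(
            p
            for blk, tissue in ((range(0, 25), "liver"), (range(25, 50), "spleen"))
            for p in sd._block_pairs(blk, 0.95, tissue=tissue)
        )
        spec = sd.CohortSpec(
            n_genes=150,
            n_gc=600,
            n_sf=600,
            n_datasets=2,
            tissue_labels=("liver", "spleen"),
            perturbed_pairs=pairs,
            mean_log2_range=(4.0, 9.0),
            seed=8,
        )
        counts, md, truth = sd.generate_cohort(spec)
        expr, _ = preprocess.normalize_counts(preprocess.filter_low_expression(counts))
        ppi = ssn.PPINetwork.from_edge_list(sd.generate_ppi(spec), gene_ids=list(expr.index))
        strata = md.set_index("sample_id")["tissue"]
        deg = features.degree_matrix(ssn.build_all_ssns_stratified(expr, ppi, strata))
        out = stratified_digs(deg, md, "tissue")
        planted = {
            "liver": {f"G{i:04d}" for i in range(0, 25)},
            "spleen": {f"G{i:04d}" for i in range(25, 50)},
        }
        for tissue, results in out.items():
            p = pd.Series({r.gene_id: r.p_value for r in results})
            y = p.index.isin(planted[tissue])
            assert roc_auc_score(y, -p) >= 0.8
            # the other tissue's planted genes are not preferentially called
            other = {"liver": "spleen", "spleen": "liver"}[tissue]
            y_other = p.index.isin(planted[other])
            assert roc_auc_score(y_other, -p) <= 0.7

    def test_dose_strata_dig_counts_grow_with_dose(self):
        """Nested dispersion tiers: higher dose groups carry more
        differential genes against their matched controls."""
        import dataclasses

        from ssnflight import features, preprocess, ssn

        spec = dataclasses.replace(
            sd.dose_recovery_spec(seed=4),
            regime_variance_markers=(
                tuple(range(0, 40)),
                tuple(range(40, 80)),
                tuple(range(80, 120)),
            ),
            marker_mode="nested",
        )
        counts, md, truth = sd.generate_cohort(spec)
        expr, _ = preprocess.normalize_counts(preprocess.filter_low_expression(counts))
        ppi = ssn.PPINetwork.from_edge_list(sd.generate_ppi(spec), gene_ids=list(expr.index))
        deg = features.degree_matrix(ssn.build_all_ssns(expr, ppi))
        md = md.copy()
        md["dose_group"] = ""
        md.loc[md["condition"] == "SF", "dose_group"] = truth.dose_labels.reindex(
            md.loc[md["condition"] == "SF", "sample_id"]
        ).to_numpy()
        out = stratified_digs(deg, md, "dose_group")
        counts_by_group = {k: sum(r.is_dig for r in v) for k, v in out.items()}
        assert counts_by_group["L"] <= counts_by_group["M"] <= counts_by_group["H"]

    def test_unknown_stratifier(self, hub_pipeline):
        with pytest.raises(ValueError):
            stratified_digs(hub_pipeline["degrees"], hub_pipeline["metadata"], "diet")
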