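import pytest

from ssnflight import features, preprocess, ssn, synthetic_data as sd


@pytest.fixture(scope="session")
def small_spec():
    """A tiny but structured cohort: one SF-only correlated block."""
    return sd.CohortSpec(
        n_genes=50,
        n_gc=8,
        n_sf=8,
        n_datasets=2,
        tissue_labels=("liver",),
        baseline_modules=(sd.GeneBlock(tuple(range(30, 36)), 0.6),),
        perturbed_pairs=sd._block_pairs(range(6), 0.9),
        mean_log2_range=(4.0, 9.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    counts, metadata, truth = sd.generate_cohort(small_spec)
    return counts, metadata, truth


@pytest.fixture(scope="session")
def small_pipeline(small_spec, small_cohort):
    """Everything up to the degree matrix for the tiny cohort."""
    counts, metadata, truth = small_cohort
    expr, _ = preprocess.normalize_counts(preprocess.filter_low_expression(counts))
    ppi = ssn.PPINetwork.from_edge_list(sd.generate_ppi(small_spec, 0.05), gene_ids=list(expr.index))
    ssns = ssn.build_all_ssns(expr, ppi)
    degrees = features.degree_matrix(ssns)
    return {
        "counts": counts,
        "metadata": metadata,
        "truth": truth,
        "expr": expr,
        "ppi": ppi,
        "ssns": ssns,
        "degrees": degrees,
    }


@pytest.fixture(scope="session")
def hub_pipeline():
    """Hub-recovery cohort taken through SSN construction and degrees."""
    spec = sd.hub_recovery_spec(seed=1)
    counts, metadata, truth = sd.generate_cohort(spec)
    expr, _ = preprocess.normalize_counts(preprocess.filter_low_expression(counts))
    ppi = ssn.PPINetwork.from_edge_list(sd.generate_ppi(spec), gene_ids=list(expr.index))
    ssns = ssn.build_all_ssns(expr, ppi)
    degrees = features.degree_matrix(ssns)
    return {
        "spec": spec,
        "counts": counts,
        "metadata": metadata,
        "truth": truth,
        "expr": expr,
        "ppi": ppi,
        "ssns": ssns,
        "degrees": degrees,
    }
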