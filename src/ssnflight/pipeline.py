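"""End-to-end orchestration of the SSN analysis.

Stages: preprocess -> single-sample networks -> degree features (+ MDS)
-> dose grouping -> DIG statistics (global and per stratum) -> differential
network & hubs -> enrichment & disease degrees. Every stage writes TSV
outputs under the configured output directory, and a run manifest
summarizes row/edge counts per stage. All randomness flows from the one
root seed in the config, fanned out per stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffnet, digstats, dosegroup, enrich, features, io, preprocess, ssn, synthetic_data
from .config import ConfigError, RunConfig

logger = logging.getLogger(__name__)

__all__ = ["simulate", "run_full"]

_PRESETS = {
    "default": synthetic_data.default_cohort_spec,
    "null": synthetic_data.null_cohort_spec,
    "dose_recovery": synthetic_data.dose_recovery_spec,
    "hub_recovery": synthetic_data.hub_recovery_spec,
    "two_tissue": synthetic_data.two_tissue_spec,
}


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("mds", "dose", "gsea")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def simulate(config: RunConfig) -> dict[str, str]:
    """Generate the synthetic cohort inputs at the configured paths.

    Writes counts, metadata, PPI, GMT gene sets, gene–disease table,
    homolog mapping, and a truth file with the planted structure.
    """
    config.validate_params()
    if config.synthetic_preset not in _PRESETS:
        raise ConfigError(f"unknown synthetic_preset {config.synthetic_preset!r}")
    spec = _PRESETS[config.synthetic_preset](seed=config.seed)
    counts, metadata, truth = synthetic_data.generate_cohort(spec)
    ppi = synthetic_data.generate_ppi(spec, extra_edge_fraction=config.ppi_extra_edge_fraction)
    sets, disease_df, homolog_df = synthetic_data.generate_annotation_fixtures(spec)

    paths = {
        "counts": config.counts,
        "metadata": config.metadata,
        "ppi": config.ppi,
        "gene_sets": config.gene_sets,
        "gene_disease": config.gene_disease,
        "homologs": config.homologs,
    }
    for p in paths.values():
        Path(p).parent.mkdir(parents=True, exist_ok=True)
    io.write_matrix(counts, paths["counts"])
    io.write_table(metadata, paths["metadata"])
    io.write_table(ppi, paths["ppi"])
    io.write_gmt(sets, paths["gene_sets"])
    io.write_table(disease_df, paths["gene_disease"])
    io.write_table(homolog_df, paths["homologs"])
    truth_path = str(Path(paths["counts"]).parent / "truth.json")
    Path(truth_path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))
    paths["truth"] = truth_path
    return paths


def _digs_frame(per_stratum: dict[str, list[digstats.DigResult]], stratify_by: str) -> pd.DataFrame:
    frames = []
    for name, results in sorted(per_stratum.items()):
        df = digstats.dig_table(results)
        df.insert(0, "stratum", name)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    out.insert(0, "stratify_by", stratify_by)
    return out


def run_full(config: RunConfig) -> dict:
    """Execute every stage on the configured inputs; returns the manifest."""
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "warnings": []}

    # -- preprocess -------------------------------------------------------
    counts = io.read_counts(config.counts)
    metadata = io.read_metadata(config.metadata)
    missing = set(counts.columns) - set(metadata["sample_id"])
    if missing:
        raise ConfigError(f"samples missing from metadata: {sorted(missing)}")
    filtered = preprocess.filter_low_expression(counts, config.zero_fraction_threshold)
    expr, size_factors = preprocess.normalize_counts(filtered, config.pseudocount)
    io.write_matrix(expr.round(6), out / "expression.tsv")
    size_factors.round(6).rename_axis("sample_id").reset_index().to_csv(
        out / "size_factors.tsv", sep="\t", index=False
    )
    manifest["stages"]["preprocess"] = {
        "n_genes_raw": int(counts.shape[0]),
        "n_genes_filtered": int(filtered.shape[0]),
        "n_samples": int(counts.shape[1]),
    }

    # -- single-sample networks ------------------------------------------
    ppi = ssn.PPINetwork.from_edge_list(io.read_table(config.ppi), gene_ids=list(expr.index))
    if config.ssn_background == "joint":
        ssns = ssn.build_all_ssns(expr, ppi, pair_scope=config.pair_scope)
    else:
        strata = metadata.set_index("sample_id")[config.ssn_background]
        ssns = ssn.build_all_ssns_stratified(expr, ppi, strata, pair_scope=config.pair_scope)
    edge_rows = [
        {"sample_id": s.sample_id, "gene_a": a, "gene_b": b}
        for s in ssns
        for a, b in sorted(s.edges)
    ]
    io.write_table(pd.DataFrame(edge_rows, columns=["sample_id", "gene_a", "gene_b"]),
                   out / "ssn_edges.tsv")
    io.write_table(
        pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "mu": round(s.threshold.mu, 6),
                    "sigma": round(s.threshold.sigma, 6),
                    "w": round(s.threshold.w, 6),
                    "n_edges": s.n_edges,
                    "pair_scope": s.pair_scope,
                }
                for s in ssns
            ]
        ),
        out / "ssn_thresholds.tsv",
    )
    manifest["stages"]["ssn"] = {
        "n_ssns": len(ssns),
        "n_ppi_edges": len(ppi.edges),
        "total_edges": int(sum(s.n_edges for s in ssns)),
        "pair_scope": config.pair_scope,
    }

    # -- degree features + embedding -------------------------------------
    degrees = features.degree_matrix(ssns)
    io.write_matrix(degrees, out / "degrees.tsv")
    stage = {"n_degree_genes": int(degrees.shape[0])}
    if config.run_mds:
        dist = features.distance_matrix(ssns)
        io.write_matrix(dist.round(6), out / "distances.tsv", index_label="sample_id")
        coords, stress = features.mds_embed(dist, seed=seeds["mds"])
        io.write_matrix(coords.round(6), out / "mds.tsv", index_label="sample_id")
        stage["mds_stress"] = round(stress, 6)
    manifest["stages"]["features"] = stage

    # -- dose grouping ----------------------------------------------------
    best, leaderboard = dosegroup.search_best_partition(
        degrees, metadata, k=config.knn_k, folds=config.folds, seed=seeds["dose"]
    )
    io.write_table(dosegroup.leaderboard_table(leaderboard).round(6), out / "dose_leaderboard.tsv")
    sf_mask = metadata["condition"] == "SF"
    metadata = metadata.copy()
    metadata["dose_group"] = ""
    metadata.loc[sf_mask, "dose_group"] = [
        best.partition.label(d) for d in metadata.loc[sf_mask, "dose_mGy"]
    ]
    io.write_table(metadata, out / "metadata_with_groups.tsv")
    (out / "dose_partition.json").write_text(
        json.dumps(
            {
                "cut_low": best.partition.cut_low,
                "cut_high": best.partition.cut_high,
                "f1_macro": round(best.f1, 6),
                "per_class_auc": {k: round(v, 6) for k, v in best.per_class_auc.items()},
                "group_sizes": best.group_sizes,
            },
            indent=2,
            sort_keys=True,
        )
    )
    manifest["stages"]["dosegroup"] = {
        "n_partitions_scored": len(leaderboard),
        "best_f1_macro": round(best.f1, 6),
        "cut_low": best.partition.cut_low,
        "cut_high": best.partition.cut_high,
    }

    # -- DIG statistics ---------------------------------------------------
    all_digs = digstats.stratified_digs(
        degrees, metadata, "none", alpha=config.alpha, levene_alpha=config.levene_alpha
    )
    frames = [_digs_frame(all_digs, "none")]
    for by in ("tissue", "dose_group"):
        frames.append(
            _digs_frame(
                digstats.stratified_digs(
                    degrees, metadata, by, alpha=config.alpha, levene_alpha=config.levene_alpha
                ),
                by,
            )
        )
    digs_df = pd.concat(frames, ignore_index=True)
    digs_df[["levene_p", "t_stat", "p_value"]] = digs_df[["levene_p", "t_stat", "p_value"]].round(8)
    digs_df[["mean_gc", "mean_sf"]] = digs_df[["mean_gc", "mean_sf"]].round(6)
    io.write_table(digs_df, out / "digs.tsv")
    global_digs = [r.gene_id for r in all_digs["all"] if r.is_dig]
    manifest["stages"]["digstats"] = {
        "n_digs_global": len(global_digs),
        "n_rows": int(digs_df.shape[0]),
    }

    # -- differential network and hubs ------------------------------------
    occurrences = diffnet.edge_occurrences(ssns, metadata)
    n_gc = int((metadata["condition"] == "GC").sum())
    n_sf = int(sf_mask.sum())
    threshold = (
        diffnet.proportional_din_threshold(n_gc, n_sf)
        if config.din_threshold == "auto"
        else int(config.din_threshold)
    )
    din = diffnet.build_din(occurrences, threshold=threshold)
    io.write_table(
        pd.DataFrame(
            [
                {"gene_a": e.pair[0], "gene_b": e.pair[1], "n_gc": e.n_gc,
                 "n_sf": e.n_sf, "diff": e.diff}
                for e in sorted(din.edges, key=lambda e: e.pair)
            ],
            columns=["gene_a", "gene_b", "n_gc", "n_sf", "diff"],
        ),
        out / "din_edges.tsv",
    )
    hubs: list[diffnet.HubGene] = []
    if din.edges:
        hubs = diffnet.hub_genes(din, top_k=config.hub_top_k)
        io.write_table(
            pd.DataFrame([{"gene_id": h.gene_id, "weighted_degree": h.weighted_degree} for h in hubs]),
            out / "hub_genes.tsv",
        )
        ego_rows = []
        for h in hubs:
            for group in ("GC", "SF"):
                try:
                    ego = diffnet.ego_network(ssns, metadata, h.gene_id, group,
                                              rank_cutoff=config.rank_cutoff)
                except ValueError:
                    manifest["warnings"].append(
                        f"hub {h.gene_id} has no incident edge in the {group} group"
                    )
                    continue
                for gene, count in ego.members:
                    ego_rows.append({"hub": h.gene_id, "group": group,
                                     "gene": gene, "connections": count})
        io.write_table(pd.DataFrame(ego_rows, columns=["hub", "group", "gene", "connections"]),
                       out / "ego_networks.tsv")
    else:
        manifest["warnings"].append("differential network is empty at the chosen threshold")
    manifest["stages"]["diffnet"] = {
        "din_threshold": threshold,
        "n_din_edges": len(din.edges),
        "hubs": [h.gene_id for h in hubs],
    }

    # -- enrichment --------------------------------------------------------
    md_idx = metadata.set_index("sample_id")
    sf_ids = tuple(s for s in degrees.columns if md_idx.loc[s, "condition"] == "SF")
    gc_ids = tuple(s for s in degrees.columns if md_idx.loc[s, "condition"] == "GC")
    stratum = digstats.StratumSpec("all", sf_ids, gc_ids)
    ranked = enrich.rank_by_fc(degrees, stratum, epsilon=config.fc_epsilon)
    io.write_table(
        pd.DataFrame({"gene_id": ranked.genes, "fold_change": np.round(ranked.scores, 6)}),
        out / "fc_ranking.tsv",
    )
    gsea_rows = []
    for gs in io.read_gmt(config.gene_sets):
        try:
            res = enrich.gsea(
                ranked, gs,
                n_permutations=config.gsea_permutations,
                weight_exponent=config.gsea_weight_exponent,
                seed=seeds["gsea"],
            )
        except ValueError as exc:
            manifest["warnings"].append(str(exc))
            continue
        gsea_rows.append(
            {"set_name": res.set_name, "es": round(res.es, 6), "p_value": round(res.p_value, 6),
             "n_hits": res.n_hits, "n_permutations": res.n_permutations,
             "leading_edge_size": len(res.leading_edge)}
        )
    io.write_table(pd.DataFrame(gsea_rows), out / "gsea.tsv")

    homologs = io.read_table(config.homologs)
    human_digs = enrich.map_homologs(global_digs, homologs)
    dd, edges = enrich.disease_degrees(
        human_digs, io.read_table(config.gene_disease),
        min_score=config.min_score, min_ei=config.min_ei,
    )
    io.write_table(
        pd.DataFrame([{"disease": d.disease, "degree": d.degree} for d in dd],
                     columns=["disease", "degree"]),
        out / "disease_degrees.tsv",
    )
    io.write_table(edges, out / "disease_edges.tsv")
    manifest["stages"]["enrich"] = {
        "n_gene_sets_tested": len(gsea_rows),
        "n_human_digs": len(human_digs),
        "n_diseases": len(dd),
    }

    manifest["package_version"] = _version()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("ssnflight")
    except PackageNotFoundError:
        return "unknown"
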