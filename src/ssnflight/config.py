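"""Run configuration: one YAML file drives the whole pipeline.

Every stage parameter has a documented default mirroring the analysis it
implements; every key can be overridden from the command line.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # input paths
    counts: str = "inputs/counts.tsv"
    metadata: str = "inputs/metadata.tsv"
    ppi: str = "inputs/ppi.tsv"
    gene_sets: str = "inputs/gene_sets.gmt"
    gene_disease: str = "inputs/gene_disease.tsv"
    homologs: str = "inputs/homologs.tsv"
    out_dir: str = "results"

    # synthetic cohort (simulate stage)
    synthetic_preset: str = "default"  # default | null | dose_recovery | two_tissue
    ppi_extra_edge_fraction: float = 0.01

    # preprocess
    zero_fraction_threshold: float = 0.20
    pseudocount: float = 1.0

    # ssn
    pair_scope: str = "all_pairs"  # all_pairs | ppi_pairs
    ssn_background: str = "joint"  # joint | tissue | dataset (per-stratum, experimental)

    # digstats
    alpha: float = 0.05
    levene_alpha: float = 0.05
    bh_correct: bool = False

    # dosegroup
    knn_k: int = 5
    folds: int = 5

    # diffnet
    din_threshold: int | str = "auto"  # int, or "auto" for the proportional rule
    hub_top_k: int = 10
    rank_cutoff: int = 30

    # enrich
    gsea_permutations: int = 1000
    gsea_weight_exponent: float = 1.0
    fc_epsilon: float = 0.5
    min_score: float = 0.3
    min_ei: float = 0.0

    # embedding
    run_mds: bool = True

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate_params(self) -> None:
        if not (0 <= self.zero_fraction_threshold <= 1):
            raise ConfigError("zero_fraction_threshold must lie in [0, 1]")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be > 0")
        if self.pair_scope not in ("all_pairs", "ppi_pairs"):
            raise ConfigError("pair_scope must be 'all_pairs' or 'ppi_pairs'")
        if self.ssn_background not in ("joint", "tissue", "dataset"):
            raise ConfigError("ssn_background must be 'joint', 'tissue' or 'dataset'")
        if not (0 < self.alpha < 1) or not (0 < self.levene_alpha < 1):
            raise ConfigError("alpha and levene_alpha must lie in (0, 1)")
        if self.knn_k < 1 or self.folds < 2:
            raise ConfigError("knn_k must be >= 1 and folds >= 2")
        if self.din_threshold != "auto" and int(self.din_threshold) < 0:
            raise ConfigError("din_threshold must be >= 0 or 'auto'")
        if self.hub_top_k < 1 or self.rank_cutoff < 1:
            raise ConfigError("hub_top_k and rank_cutoff must be >= 1")
        if self.gsea_permutations < 1:
            raise ConfigError("gsea_permutations must be >= 1")
        if self.fc_epsilon < 0:
            raise ConfigError("fc_epsilon must be >= 0")

    def validate_inputs(self) -> None:
        self.validate_params()
        for name in ("counts", "metadata", "ppi", "gene_sets", "gene_disease", "homologs"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigError(f"input path for {name!r} does not exist: {p}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
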