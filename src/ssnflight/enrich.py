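"""Degree-based enrichment: FC ranking, GSEA, homologs, disease degrees.

Genes are ranked by the fold change of their mean SSN degree between
spaceflight and ground control, FC = (mean d_SF + eps) / (mean d_GC + eps);
gene sets are tested against that ranking with a weighted Kolmogorov–
Smirnov enrichment score and a gene-label permutation p-value. DIG lists
can be mapped to human homologs and scored against a gene–disease
association table: a disease's degree is the number of distinct input
genes linked to it after score/evidence filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .digstats import StratumSpec

logger = logging.getLogger(__name__)

__all__ = [
    "RankedGeneList",
    "GeneSet",
    "GseaResult",
    "DiseaseDegree",
    "rank_by_fc",
    "gsea",
    "curate_union_set",
    "map_homologs",
    "disease_degrees",
]


@dataclass
class RankedGeneList:
    """Gene ids with positive scores, sorted descending (ties broken
    lexicographically on the gene id)."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must have equal length")
        if (np.asarray(self.scores) <= 0).any():
            raise ValueError("ranking scores must be strictly positive")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class GseaResult:
    set_name: str
    es: float
    p_value: float
    n_permutations: int
    n_hits: int
    leading_edge: list[str]


@dataclass(frozen=True)
class DiseaseDegree:
    disease: str
    degree: int


def rank_by_fc(degrees: pd.DataFrame, stratum: StratumSpec, epsilon: float = 0.5) -> RankedGeneList:
    """Rank genes by mean-degree fold change SF/GC.

    ``epsilon`` is added to both means so genes with a zero mean GC degree
    stay rankable; as epsilon -> 0 the plain ratio is recovered wherever
    it is defined.
    """
    stratum.validate()
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    mean_sf = degrees.loc[:, list(stratum.sf_sample_ids)].mean(axis=1)
    mean_gc = degrees.loc[:, list(stratum.gc_sample_ids)].mean(axis=1)
    with np.errstate(divide="ignore"):
        fc = (mean_sf + epsilon) / (mean_gc + epsilon)
    if not np.isfinite(fc).all() or (fc <= 0).any():
        raise ValueError("fold changes are not all positive and finite; "
                         "use a positive epsilon")
    order = sorted(degrees.index, key=lambda g: (-fc[g], g))
    return RankedGeneList(genes=order, scores=fc.loc[order].to_numpy(dtype=float))


def _es_from_hits(scores_w: np.ndarray, hits: np.ndarray) -> tuple[float, int]:
    """Signed extremum of the weighted KS running sum; returns (ES, argmax).

    ``scores_w`` are |score|^exponent values aligned with the ranking;
    ``hits`` is a boolean membership indicator.
    """
    n = len(scores_w)
    nh = int(hits.sum())
    hit_mass = scores_w * hits
    total = hit_mass.sum()
    up = hit_mass / total
    down = (~hits) / (n - nh)
    running = np.cumsum(up - down)
    k = int(np.argmax(np.abs(running)))
    return float(running[k]), k


def gsea(
    ranked: RankedGeneList,
    gene_set: GeneSet,
    n_permutations: int = 1000,
    weight_exponent: float = 1.0,
    seed: int = 0,
) -> GseaResult:
    """Weighted-KS enrichment of a gene set in a ranked list.

    Hit increments are proportional to |score|^weight_exponent normalized
    over the set's hits; misses decrement 1/(n - n_hits). ES is the signed
    extremum of the running sum; the p-value is add-one under gene-label
    permutation: p = (1 + #{|ES*| >= |ES|}) / (1 + n_permutations).
    """
    genes = np.asarray(ranked.genes)
    hits = np.isin(genes, list(gene_set.genes))
    nh = int(hits.sum())
    if nh == 0:
        raise ValueError(f"gene set {gene_set.name!r} shares no gene with the ranking")
    if nh == len(genes):
        raise ValueError(f"gene set {gene_set.name!r} covers the entire ranking")
    w = np.abs(np.asarray(ranked.scores, dtype=float)) ** weight_exponent
    es, k = _es_from_hits(w, hits)
    if es >= 0:
        leading = [g for g, h in zip(genes[: k + 1], hits[: k + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[k:], hits[k:]) if h]

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm_hits = np.zeros(len(genes), dtype=bool)
        perm_hits[rng.choice(len(genes), size=nh, replace=False)] = True
        es_p, _ = _es_from_hits(w, perm_hits)
        if abs(es_p) >= abs(es):
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return GseaResult(
        set_name=gene_set.name,
        es=es,
        p_value=p,
        n_permutations=n_permutations,
        n_hits=nh,
        leading_edge=leading,
    )


def curate_union_set(term_gene_lists: list[GeneSet], name: str) -> GeneSet:
    """Union of several term gene sets (e.g. radiation-response GO terms),
    duplicates collapsed."""
    if not term_gene_lists:
        raise ValueError("curate_union_set needs at least one gene set")
    union: set[str] = set()
    for gs in term_gene_lists:
        union |= gs.genes
    return GeneSet(name=name, genes=frozenset(union))


def map_homologs(genes: list[str], mapping: pd.DataFrame) -> list[str]:
    """Map (mouse) genes to their human homologs via a two-column table.

    One-to-many mappings expand; unmapped genes are dropped with a logged
    count. Output order follows the input order (then the mapping row
    order), de-duplicated.
    """
    if mapping.shape[1] < 2:
        raise ValueError("mapping table needs two columns (source, target)")
    src = mapping.columns[0]
    dst = mapping.columns[1]
    if mapping.duplicated([src, dst]).any():
        raise ValueError("mapping table has duplicate (source, target) rows")
    by_src = mapping.groupby(src, sort=False)[dst].apply(list).to_dict()
    out: list[str] = []
    seen: set[str] = set()
    dropped = 0
    for g in genes:
        targets = by_src.get(g)
        if not targets:
            dropped += 1
            continue
        for t in targets:
            if t not in seen:
                seen.add(t)
                out.append(t)
    if dropped:
        logger.info("map_homologs: %d of %d genes had no homolog", dropped, len(genes))
    return out


def disease_degrees(
    genes: list[str],
    associations: pd.DataFrame,
    min_score: float = 0.3,
    min_ei: float = 0.0,
) -> tuple[list[DiseaseDegree], pd.DataFrame]:
    """Disease degrees on the filtered gene–disease network.

    Associations with score >= min_score, evidence index >= min_ei and
    gene among the inputs are retained; a disease's degree is its count of
    distinct retained genes. Returns the ranked degree list and the
    retained bipartite edge list.
    """
    required = {"gene", "disease", "score", "ei"}
    if not required.issubset(associations.columns):
        raise ValueError(f"associations table needs columns {sorted(required)}")
    if ((associations["score"] < 0) | (associations["score"] > 1)).any():
        raise ValueError("association scores must lie in [0, 1]")
    keep = (
        (associations["score"] >= min_score)
        & (associations["ei"] >= min_ei)
        & associations["gene"].isin(set(genes))
    )
    edges = associations.loc[keep, ["gene", "disease", "score", "ei"]].drop_duplicates(
        ["gene", "disease"]
    )
    counts = edges.groupby("disease")["gene"].nunique()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return (
        [DiseaseDegree(disease=d, degree=int(c)) for d, c in ranked],
        edges.sort_values(["disease", "gene"]).reset_index(drop=True),
    )
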