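"""Single-sample network construction via LIONESS.

For a cohort of N samples, the network of sample s is estimated by linear
interpolation between the aggregate Pearson co-expression network and the
network recomputed with s removed:

    e_ij(s) = N * (e_ij(all) - e_ij(all minus s)) + e_ij(all minus s)

Each sample's edge scores are then thresholded at w = mu(D) + 2*sigma(D),
where D is the distribution of absolute scores over the pair universe, and
intersected with a protein–protein interaction (PPI) network. The surviving
simple undirected graph is that sample's single-sample network (SSN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenePair",
    "ThresholdStats",
    "EdgeScoreSet",
    "PPINetwork",
    "SingleSampleNetwork",
    "canonical_pair",
    "pearson_matrix",
    "lioness_scores",
    "edge_threshold",
    "intersect_ppi",
    "build_all_ssns",
    "build_all_ssns_stratified",
]

GenePair = tuple[str, str]


def canonical_pair(a: str, b: str) -> GenePair:
    if a == b:
        raise ValueError(f"self-pair ({a}, {b}) is not a valid gene pair")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class ThresholdStats:
    """Mean, standard deviation and resulting cut of the |score| distribution."""

    mu: float
    sigma: float

    @property
    def w(self) -> float:
        return self.mu + 2.0 * self.sigma


@dataclass
class EdgeScoreSet:
    """LIONESS edge scores of one sample over a pair universe."""

    sample_id: str
    pairs: list[GenePair]
    values: np.ndarray
    n_background: int

    def as_dict(self) -> dict[GenePair, float]:
        return dict(zip(self.pairs, self.values.tolist()))


@dataclass(frozen=True)
class PPINetwork:
    """Simple undirected PPI graph over canonical gene pairs."""

    edges: frozenset[GenePair]
    name: str = "ppi"

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(g for e in self.edges for g in e)

    @classmethod
    def from_edge_list(
        cls, table: pd.DataFrame, gene_ids: list[str] | None = None, name: str = "ppi"
    ) -> "PPINetwork":
        """Build from a two-column edge list.

        Symbols are matched case-insensitively after whitespace stripping
        against ``gene_ids`` when given; edges touching unmatched genes are
        dropped with a summary count in the log.
        """
        a = table.iloc[:, 0].astype(str).str.strip()
        b = table.iloc[:, 1].astype(str).str.strip()
        if gene_ids is not None:
            lookup = {g.strip().upper(): g for g in gene_ids}
            a_m = a.str.upper().map(lookup)
            b_m = b.str.upper().map(lookup)
            unmatched = int((a_m.isna() | b_m.isna()).sum())
            if unmatched:
                logger.info("PPI: dropped %d edges with unmatched genes", unmatched)
            keep = a_m.notna() & b_m.notna()
            a, b = a_m[keep], b_m[keep]
        edges = frozenset(
            canonical_pair(x, y) for x, y in zip(a, b) if x != y
        )
        return cls(edges=edges, name=name)


@dataclass
class SingleSampleNetwork:
    """Thresholded, PPI-intersected network of one sample."""

    sample_id: str
    edges: frozenset[GenePair]
    threshold: ThresholdStats
    pair_scope: str = "all_pairs"
    ppi_name: str = "ppi"
    nodes: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.nodes is None:
            self.nodes = frozenset(g for e in self.edges for g in e)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# correlation primitives


def _corr_nan_to_zero(values: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of rows; zero-variance rows score 0.

    A pair involving a constant gene has no defined correlation; it is set
    to 0 (no co-variation evidence) so the LIONESS interpolation stays
    total. Diagonal is kept at 1.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(values)
    bad = ~np.isfinite(c)
    if bad.any():
        c[bad] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def _pair_indices(gene_ids: list[str], pairs: list[GenePair]) -> tuple[np.ndarray, np.ndarray]:
    pos = {g: i for i, g in enumerate(gene_ids)}
    try:
        ii = np.fromiter((pos[a] for a, _ in pairs), dtype=np.int64, count=len(pairs))
        jj = np.fromiter((pos[b] for _, b in pairs), dtype=np.int64, count=len(pairs))
    except KeyError as exc:
        raise KeyError(f"gene {exc.args[0]!r} not present in the expression matrix") from exc
    return ii, jj


def pearson_matrix(expr: pd.DataFrame, pairs: list[GenePair]) -> dict[GenePair, float]:
    """Pearson correlation across samples for each requested gene pair."""
    if expr.shape[1] < 3:
        raise ValueError("pearson_matrix needs at least 3 samples")
    genes = sorted({g for p in pairs for g in p})
    sub = expr.loc[genes]
    c = _corr_nan_to_zero(sub.to_numpy(dtype=float))
    pos = {g: i for i, g in enumerate(genes)}
    out = {}
    for a, b in pairs:
        if a not in pos or b not in pos:
            raise KeyError(f"gene pair ({a}, {b}) not present in the expression matrix")
        out[(a, b)] = float(c[pos[a], pos[b]])
    return out


def lioness_scores(
    expr: pd.DataFrame, sample_id: str, pairs: list[GenePair] | None = None
) -> EdgeScoreSet:
    """LIONESS edge scores of ``sample_id`` for the given pairs.

    ``pairs`` defaults to all gene pairs of the expression matrix.
    """
    n = expr.shape[1]
    if n < 4:
        raise ValueError("LIONESS needs at least 4 samples (leave-one-out Pearson needs 3)")
    if sample_id not in expr.columns:
        raise KeyError(f"sample {sample_id!r} not present in the expression matrix")
    gene_ids = list(expr.index)
    if pairs is None:
        iu, ju = np.triu_indices(len(gene_ids), k=1)
        pairs = [(gene_ids[i], gene_ids[j]) for i, j in zip(iu, ju)]
    ii, jj = _pair_indices(gene_ids, pairs)
    values = expr.to_numpy(dtype=float)
    s = expr.columns.get_loc(sample_id)
    c_all = _corr_nan_to_zero(values)
    c_loo = _corr_nan_to_zero(np.delete(values, s, axis=1))
    scores = n * (c_all[ii, jj] - c_loo[ii, jj]) + c_loo[ii, jj]
    return EdgeScoreSet(sample_id=sample_id, pairs=list(pairs), values=scores, n_background=n)


def edge_threshold(score_set: EdgeScoreSet) -> tuple[ThresholdStats, set[GenePair]]:
    """Apply the mu + 2*sigma cut to |scores|; strictly greater survives.

    sigma is the sample standard deviation (ddof=1); for a single pair it
    is 0, so no edge can clear the strict inequality.
    """
    if len(score_set.pairs) == 0:
        raise ValueError("edge_threshold needs a non-empty score set")
    d = np.abs(score_set.values)
    mu = float(d.mean())
    sigma = float(d.std(ddof=1)) if d.size > 1 else 0.0
    stats = ThresholdStats(mu=mu, sigma=sigma)
    mask = d > stats.w
    retained = {score_set.pairs[k] for k in np.nonzero(mask)[0]}
    return stats, retained


def intersect_ppi(
    thresholded_pairs: set[GenePair],
    ppi: PPINetwork,
    sample_id: str = "",
    threshold: ThresholdStats | None = None,
    pair_scope: str = "all_pairs",
) -> SingleSampleNetwork:
    """Keep only edges present in both the thresholded set and the PPI."""
    edges = frozenset(thresholded_pairs & ppi.edges)
    if not edges:
        logger.info("sample %s: empty SSN after PPI intersection", sample_id)
    return SingleSampleNetwork(
        sample_id=sample_id,
        edges=edges,
        threshold=threshold if threshold is not None else ThresholdStats(0.0, 0.0),
        pair_scope=pair_scope,
        ppi_name=ppi.name,
    )


def build_all_ssns(
    expr: pd.DataFrame, ppi: PPINetwork, pair_scope: str = "all_pairs"
) -> list[SingleSampleNetwork]:
    """One SSN per sample of the expression matrix.

    pair_scope:
      * ``all_pairs`` — scores and the threshold distribution D range over
        every gene pair of the matrix (then the PPI intersection is applied);
      * ``ppi_pairs`` — scoring and D are restricted to PPI pairs, a
        tractability mode for large gene universes.
    """
    if pair_scope not in ("all_pairs", "ppi_pairs"):
        raise ValueError("pair_scope must be 'all_pairs' or 'ppi_pairs'")
    n = expr.shape[1]
    if n < 4:
        raise ValueError("LIONESS needs at least 4 samples")
    gene_ids = list(expr.index)
    g = len(gene_ids)
    pos = {gid: i for i, gid in enumerate(gene_ids)}

    ppi_pairs = sorted(e for e in ppi.edges if e[0] in pos and e[1] in pos)
    ppi_i = np.array([pos[a] for a, _ in ppi_pairs], dtype=np.int64)
    ppi_j = np.array([pos[b] for _, b in ppi_pairs], dtype=np.int64)
    ppi_keys = np.sort(ppi_i * g + ppi_j)

    if pair_scope == "all_pairs":
        iu, ju = np.triu_indices(g, k=1)
    else:
        if pair_scope == "ppi_pairs" and len(ppi_pairs) == 0:
            logger.warning("PPI shares no genes with the expression matrix")
        iu, ju = ppi_i, ppi_j
    keys = iu * g + ju

    values = expr.to_numpy(dtype=float)
    c_all = _corr_nan_to_zero(values)
    ssns = []
    for s, sample_id in enumerate(expr.columns):
        c_loo = _corr_nan_to_zero(np.delete(values, s, axis=1))
        scores = n * (c_all[iu, ju] - c_loo[iu, ju]) + c_loo[iu, ju]
        d = np.abs(scores)
        mu = float(d.mean())
        sigma = float(d.std(ddof=1)) if d.size > 1 else 0.0
        stats = ThresholdStats(mu=mu, sigma=sigma)
        mask = d > stats.w
        kept_keys = keys[mask]
        in_ppi = np.isin(kept_keys, ppi_keys, assume_unique=False)
        kept_keys = kept_keys[in_ppi]
        edges = frozenset(
            (gene_ids[k // g], gene_ids[k % g]) for k in kept_keys.tolist()
        )
        ssns.append(
            SingleSampleNetwork(
                sample_id=sample_id,
                edges=edges,
                threshold=stats,
                pair_scope=pair_scope,
                ppi_name=ppi.name,
            )
        )
    return ssns


def build_all_ssns_stratified(
    expr: pd.DataFrame,
    ppi: PPINetwork,
    strata: "pd.Series",
    pair_scope: str = "all_pairs",
) -> list[SingleSampleNetwork]:
    """One SSN per sample with the LIONESS background restricted to the
    sample's stratum (e.g. tissue or dataset).

    ``strata`` maps sample id -> stratum label. Each stratum still needs
    at least 4 samples. Networks are returned in expression-column order.
    The default joint background is usually preferable (the estimator is
    robust to background heterogeneity); per-stratum backgrounds recover
    stratum-private co-expression that a pooled background dilutes.
    """
    missing = set(expr.columns) - set(strata.index)
    if missing:
        raise KeyError(f"samples without a stratum label: {sorted(missing)}")
    by_sample: dict[str, SingleSampleNetwork] = {}
    for level in sorted(strata.loc[list(expr.columns)].unique()):
        cols = [c for c in expr.columns if strata[c] == level]
        for net in build_all_ssns(expr.loc[:, cols], ppi, pair_scope=pair_scope):
            by_sample[net.sample_id] = net
    return [by_sample[c] for c in expr.columns]
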