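"""Differentially interacted genes (DIGs).

A gene is differentially interacted when its SSN degree vector differs
between spaceflight (SF) and ground-control (GC) samples: homogeneity of
variances is checked with Levene's test, which gates the choice between a
pooled-variance and a Welch two-sample t-test; genes with a two-sided
p-value below alpha are DIGs. No multiple-testing correction is applied by
default (a Benjamini–Hochberg option exists behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["DigResult", "StratumSpec", "identify_digs", "stratified_digs", "dig_table"]


@dataclass(frozen=True)
class StratumSpec:
    """A named SF-vs-GC comparison over explicit sample id lists."""

    name: str
    sf_sample_ids: tuple[str, ...]
    gc_sample_ids: tuple[str, ...]

    def validate(self) -> None:
        if len(self.sf_sample_ids) < 2 or len(self.gc_sample_ids) < 2:
            raise ValueError(f"stratum {self.name!r}: each group needs >= 2 samples")
        if set(self.sf_sample_ids) & set(self.gc_sample_ids):
            raise ValueError(f"stratum {self.name!r}: SF and GC sample sets overlap")


@dataclass(frozen=True)
class DigResult:
    gene_id: str
    mean_gc: float
    mean_sf: float
    levene_p: float
    t_stat: float
    p_value: float
    is_dig: bool


def _two_sample_test(gc: np.ndarray, sf: np.ndarray, levene_alpha: float) -> tuple[float, float, float]:
    """Levene-gated two-sided t-test; returns (levene_p, t, p).

    Degenerate zero-variance-in-both-groups vectors get p = 1 when the
    means agree and p = 0 otherwise (a constant shift between groups is
    unambiguous evidence, no sampling variability exists to test against).
    """
    var_gc, var_sf = gc.var(ddof=1), sf.var(ddof=1)
    if var_gc == 0.0 and var_sf == 0.0:
        equal_means = gc.mean() == sf.mean()
        return (np.nan, 0.0 if equal_means else np.inf, 1.0 if equal_means else 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lev_p = float(stats.levene(gc, sf).pvalue)
    if np.isnan(lev_p):
        lev_p = 1.0
    equal_var = lev_p >= levene_alpha
    t, p = stats.ttest_ind(sf, gc, equal_var=equal_var)
    return lev_p, float(t), float(p)


def identify_digs(
    degrees: pd.DataFrame,
    stratum: StratumSpec,
    alpha: float = 0.05,
    levene_alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[DigResult]:
    """Per-gene Levene-gated two-sided t-test on degree vectors.

    Levene p < ``levene_alpha`` selects the unequal-variance (Welch) test,
    otherwise the pooled-variance test is used. ``is_dig`` marks p < alpha
    (on BH-adjusted p-values when ``bh_correct`` is set).
    """
    stratum.validate()
    missing = (set(stratum.sf_sample_ids) | set(stratum.gc_sample_ids)) - set(degrees.columns)
    if missing:
        raise KeyError(f"stratum {stratum.name!r}: samples missing from degree matrix: {sorted(missing)}")
    gc_m = degrees.loc[:, list(stratum.gc_sample_ids)].to_numpy(dtype=float)
    sf_m = degrees.loc[:, list(stratum.sf_sample_ids)].to_numpy(dtype=float)
    rows = []
    degenerate = 0
    for gi, gene in enumerate(degrees.index):
        gc, sf = gc_m[gi], sf_m[gi]
        lev_p, t, p = _two_sample_test(gc, sf, levene_alpha)
        if np.isnan(lev_p):
            degenerate += 1
        rows.append((gene, float(gc.mean()), float(sf.mean()), lev_p, t, p))
    if degenerate:
        logger.info("stratum %s: %d genes with zero variance in both groups",
                    stratum.name, degenerate)
    pvals = np.array([r[5] for r in rows])
    if bh_correct:
        decide = _bh_adjust(pvals)
    else:
        decide = pvals
    return [
        DigResult(gene_id=r[0], mean_gc=r[1], mean_sf=r[2], levene_p=r[3],
                  t_stat=r[4], p_value=r[5], is_dig=bool(q < alpha))
        for r, q in zip(rows, decide)
    ]


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def dig_table(results: list[DigResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "mean_gc": r.mean_gc,
                "mean_sf": r.mean_sf,
                "levene_p": r.levene_p,
                "t_stat": r.t_stat,
                "p_value": r.p_value,
                "is_dig": r.is_dig,
            }
            for r in results
        ]
    )


def _matched_gc(metadata: pd.DataFrame, sf_ids: list[str]) -> list[str]:
    """GC samples sharing a dataset accession with any of the SF samples."""
    md = metadata.set_index("sample_id")
    datasets = set(md.loc[sf_ids, "dataset"])
    gc = md[(md["condition"] == "GC") & md["dataset"].isin(datasets)]
    return list(gc.index)


def stratified_digs(
    degrees: pd.DataFrame,
    metadata: pd.DataFrame,
    stratify_by: str = "none",
    alpha: float = 0.05,
    levene_alpha: float = 0.05,
) -> dict[str, list[DigResult]]:
    """DIG lists per stratum level (dose_group, tissue, or none).

    For each level, the SF samples of that level are paired with the GC
    samples sharing a dataset accession with them. Levels with fewer than
    two samples on either side are skipped with a warning.
    """
    if stratify_by not in ("none", "tissue", "dose_group"):
        raise ValueError("stratify_by must be 'none', 'tissue' or 'dose_group'")
    md = metadata[metadata["sample_id"].isin(degrees.columns)]
    sf = md[md["condition"] == "SF"]
    out: dict[str, list[DigResult]] = {}
    if stratify_by == "none":
        levels = {"all": list(sf["sample_id"])}
    else:
        if stratify_by not in md.columns:
            raise KeyError(f"metadata lacks a {stratify_by!r} column")
        levels = {
            str(level): list(group["sample_id"])
            for level, group in sf.groupby(stratify_by, sort=True)
        }
    for name, sf_ids in levels.items():
        gc_ids = _matched_gc(md, sf_ids)
        if len(sf_ids) < 2 or len(gc_ids) < 2:
            logger.warning("stratum %s skipped: too few matched samples", name)
            continue
        stratum = StratumSpec(name=name, sf_sample_ids=tuple(sf_ids), gc_sample_ids=tuple(gc_ids))
        out[name] = identify_digs(degrees, stratum, alpha=alpha, levene_alpha=levene_alpha)
    return out


def dig_intersections(per_stratum: dict[str, list[DigResult]]) -> dict[tuple[str, str], set[str]]:
    """Pairwise intersections of DIG sets across strata."""
    sets = {k: {r.gene_id for r in v if r.is_dig} for k, v in per_stratum.items()}
    names = sorted(sets)
    return {
        (a, b): sets[a] & sets[b]
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
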