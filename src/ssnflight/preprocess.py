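"""Count filtering and log2 normalization.

Genes with zero counts in more than a fraction of samples (default 20%)
are removed, then counts are normalized with median-of-ratios size factors
and moved to log2 scale with a pseudocount. The transform preserves the two
properties correlation analysis needs — library-size normalization and a
log2 scale — and is pluggable should a different variance-stabilizing
transform be preferred.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["filter_low_expression", "size_factors", "normalize_counts"]


def filter_low_expression(counts: pd.DataFrame, zero_fraction_threshold: float = 0.20) -> pd.DataFrame:
    """Drop genes whose fraction of zero-count samples exceeds the threshold.

    A gene is retained iff its zero fraction is <= ``zero_fraction_threshold``
    (strictly-over is removed). Sample set and gene order are preserved.
    """
    if not (0 <= zero_fraction_threshold <= 1):
        raise ValueError("zero_fraction_threshold must lie in [0, 1]")
    zero_frac = (counts == 0).mean(axis=1)
    keep = zero_frac <= zero_fraction_threshold
    out = counts.loc[keep]
    if out.empty:
        logger.warning("filter_low_expression removed every gene")
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Per sample: median over genes of count / (geometric mean of the gene
    across samples), computed over genes with all-positive counts. Falls
    back to library size / mean library size when no gene is everywhere
    positive.
    """
    values = counts.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        logger.warning(
            "no gene has positive counts in every sample; "
            "falling back to library-size factors"
        )
        lib = values.sum(axis=0)
        sf = lib / lib.mean()
    else:
        pos = values[all_positive]
        geomean = np.exp(np.log(pos).mean(axis=1))
        sf = np.median(pos / geomean[:, None], axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, pseudocount: float = 1.0) -> tuple[pd.DataFrame, pd.Series]:
    """log2(count / size_factor + pseudocount) expression matrix.

    Returns (expression, size_factors); the factors are reported so a run
    log can record them.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    sf = size_factors(counts)
    expr = np.log2(counts.to_numpy(dtype=float) / sf.to_numpy()[None, :] + pseudocount)
    return pd.DataFrame(expr, index=counts.index, columns=counts.columns), sf
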