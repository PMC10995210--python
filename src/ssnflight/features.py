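"""Node features and network geometry of single-sample networks.

Degrees are the node features: each gene gets a degree vector across all
SSNs (0 where absent). Networks are compared with the Jaccard distance on
edge sets, and the resulting distance matrix can be embedded in the plane
with metric MDS for visual inspection of tissue/condition structure.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from sklearn.manifold import MDS

from .ssn import SingleSampleNetwork

logger = logging.getLogger(__name__)

__all__ = ["degree_matrix", "jaccard_distance", "distance_matrix", "mds_embed"]


def degree_matrix(ssns: list[SingleSampleNetwork]) -> pd.DataFrame:
    """Degree of every gene (union over SSN node sets) in every SSN.

    Rows are genes, columns samples; a gene absent from an SSN has degree 0.
    Column sums equal twice the SSN's edge count (handshake lemma).
    """
    if not ssns:
        raise ValueError("degree_matrix needs at least one SSN")
    genes = sorted(set().union(*(s.nodes for s in ssns)))
    pos = {g: i for i, g in enumerate(genes)}
    out = np.zeros((len(genes), len(ssns)), dtype=np.int64)
    for k, s in enumerate(ssns):
        for a, b in s.edges:
            out[pos[a], k] += 1
            out[pos[b], k] += 1
    return pd.DataFrame(out, index=pd.Index(genes, name="gene_id"),
                        columns=[s.sample_id for s in ssns])


def jaccard_distance(a: SingleSampleNetwork, b: SingleSampleNetwork) -> float:
    """1 - |E1 ∩ E2| / |E1 ∪ E2| on canonical edge sets.

    Two empty networks are considered identical (distance 0).
    """
    union = len(a.edges | b.edges)
    if union == 0:
        logger.info("jaccard_distance of two empty networks (%s, %s) -> 0",
                    a.sample_id, b.sample_id)
        return 0.0
    inter = len(a.edges & b.edges)
    return 1.0 - inter / union


def distance_matrix(ssns: list[SingleSampleNetwork]) -> pd.DataFrame:
    """Symmetric Jaccard distance matrix over a list of SSNs."""
    n = len(ssns)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = jaccard_distance(ssns[i], ssns[j])
    ids = [s.sample_id for s in ssns]
    return pd.DataFrame(d, index=ids, columns=ids)


def mds_embed(dist: pd.DataFrame, seed: int = 0) -> tuple[pd.DataFrame, float]:
    """Metric MDS (SMACOF stress majorization) of a distance matrix to 2-D.

    Uses 4 restarts, a 300-iteration cap and tolerance 1e-6; deterministic
    under a fixed seed. Returns (coordinates, final stress).
    """
    values = dist.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T):
        raise ValueError("mds_embed needs a square symmetric distance matrix")
    model = MDS(
        n_components=2,
        metric="precomputed",
        init="random",
        n_init=4,
        max_iter=300,
        eps=1e-9,
        random_state=seed,
        normalized_stress=False,
    )
    coords = model.fit_transform(values)
    out = pd.DataFrame(coords, index=dist.index, columns=["mds1", "mds2"])
    return out, float(model.stress_)
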