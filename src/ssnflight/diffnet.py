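"""Differentially interacted network (DIN) and hub genes.

Each edge's occurrence is counted separately across ground-control and
spaceflight SSNs; edges whose counts differ by strictly more than a
threshold form the DIN, weighted by |n_gc - n_sf|. A gene's weighted
degree is the sum of its incident DIN edge weights; the top genes by
weighted degree are hubs. Per-group hub ego-networks collect the genes
most frequently co-occurring with a hub across that group's SSNs
(tie-inclusive at the rank cutoff).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .ssn import GenePair, SingleSampleNetwork

__all__ = [
    "EdgeOccurrence",
    "DifferentialNetwork",
    "HubGene",
    "EgoNetwork",
    "edge_occurrences",
    "build_din",
    "proportional_din_threshold",
    "hub_genes",
    "ego_network",
    "ego_overlap",
]

# threshold of 20 differential occurrences calibrated against a 290-vs-301
# sample cohort; the proportional mode rescales it by mean group size
REFERENCE_THRESHOLD = 20
REFERENCE_GROUP_SIZE = (290 + 301) / 2


@dataclass(frozen=True)
class EdgeOccurrence:
    pair: GenePair
    n_gc: int
    n_sf: int

    @property
    def diff(self) -> int:
        return abs(self.n_gc - self.n_sf)


@dataclass
class DifferentialNetwork:
    edges: list[EdgeOccurrence]
    threshold: int

    @property
    def genes(self) -> set[str]:
        return {g for e in self.edges for g in e.pair}


@dataclass(frozen=True)
class HubGene:
    gene_id: str
    weighted_degree: int


@dataclass
class EgoNetwork:
    hub: str
    group: str
    members: list[tuple[str, int]]  # (gene, co-occurrence count), descending
    rank_cutoff: int


def _split_groups(ssns: list[SingleSampleNetwork], metadata: pd.DataFrame):
    cond = metadata.set_index("sample_id")["condition"]
    missing = [s.sample_id for s in ssns if s.sample_id not in cond.index]
    if missing:
        raise KeyError(f"SSN samples missing from metadata: {missing}")
    gc = [s for s in ssns if cond[s.sample_id] == "GC"]
    sf = [s for s in ssns if cond[s.sample_id] == "SF"]
    return gc, sf


def edge_occurrences(ssns: list[SingleSampleNetwork], metadata: pd.DataFrame) -> list[EdgeOccurrence]:
    """Count, for each edge seen in at least one SSN, its occurrences in
    the GC and SF groups."""
    gc, sf = _split_groups(ssns, metadata)
    c_gc: Counter[GenePair] = Counter()
    c_sf: Counter[GenePair] = Counter()
    for s in gc:
        c_gc.update(s.edges)
    for s in sf:
        c_sf.update(s.edges)
    pairs = sorted(set(c_gc) | set(c_sf))
    return [EdgeOccurrence(pair=p, n_gc=c_gc.get(p, 0), n_sf=c_sf.get(p, 0)) for p in pairs]


def proportional_din_threshold(n_gc: int, n_sf: int) -> int:
    """Rescale the reference differential-count threshold to a smaller
    cohort, proportionally to the mean group size (minimum 1)."""
    mean_size = (n_gc + n_sf) / 2
    return max(1, round(REFERENCE_THRESHOLD * mean_size / REFERENCE_GROUP_SIZE))


def build_din(occurrences: list[EdgeOccurrence], threshold: int = REFERENCE_THRESHOLD) -> DifferentialNetwork:
    """Retain edges with differential count strictly greater than the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kept = [e for e in occurrences if e.diff > threshold]
    return DifferentialNetwork(edges=kept, threshold=threshold)


def weighted_degrees(din: DifferentialNetwork) -> dict[str, int]:
    wd: Counter[str] = Counter()
    for e in din.edges:
        wd[e.pair[0]] += e.diff
        wd[e.pair[1]] += e.diff
    return dict(wd)


def hub_genes(din: DifferentialNetwork, top_k: int = 10) -> list[HubGene]:
    """Top genes of the DIN by weighted degree.

    Sorted by weighted degree descending; ties (including at rank top_k)
    are broken lexicographically on the gene id, so the cut is
    deterministic. Returns all genes when top_k exceeds the gene count.
    """
    if not din.edges:
        raise ValueError("hub_genes needs a non-empty differential network")
    wd = weighted_degrees(din)
    ranked = sorted(wd.items(), key=lambda kv: (-kv[1], kv[0]))
    return [HubGene(gene_id=g, weighted_degree=w) for g, w in ranked[:top_k]]


def ego_network(
    ssns: list[SingleSampleNetwork],
    metadata: pd.DataFrame,
    hub: str,
    group: str,
    rank_cutoff: int = 30,
) -> EgoNetwork:
    """Genes most connected to a hub within one condition group.

    For every other gene, the connection count is the number of the group's
    SSNs containing the edge (hub, gene). The genes with the top
    ``rank_cutoff`` counts are kept, including every gene tied with the
    count at the cutoff rank.
    """
    if group not in ("GC", "SF"):
        raise ValueError("group must be 'GC' or 'SF'")
    gc, sf = _split_groups(ssns, metadata)
    members_counter: Counter[str] = Counter()
    for s in gc if group == "GC" else sf:
        for a, b in s.edges:
            if a == hub:
                members_counter[b] += 1
            elif b == hub:
                members_counter[a] += 1
    if not members_counter:
        raise ValueError(f"hub {hub!r} has no incident edge in any {group} SSN")
    ranked = sorted(members_counter.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > rank_cutoff:
        cut_count = ranked[rank_cutoff - 1][1]
        ranked = [kv for kv in ranked if kv[1] >= cut_count]
    return EgoNetwork(hub=hub, group=group, members=ranked, rank_cutoff=rank_cutoff)


def ego_overlap(a: EgoNetwork, b: EgoNetwork) -> set[str]:
    """Member-set overlap between two ego-networks of the same hub
    (the GC-NET vs SF-NET Venn comparison)."""
    return {g for g, _ in a.members} & {g for g, _ in b.members}
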