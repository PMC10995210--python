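"""Synthetic spaceflight cohort generator.

Produces a fully labelled cohort — raw counts, sample metadata, a PPI edge
list, gene sets, a gene–disease table and a homolog mapping — whose
statistical structure matches what the single-sample-network pipeline
assumes: two conditions (ground control GC / spaceflight SF) sharing a
baseline gene–gene correlation structure, a planted set of gene pairs whose
correlation differs in SF samples only, three latent absorbed-dose regimes
that scale (and optionally gate) the planted perturbations, tissue blocks,
and paired GC/SF dataset accessions.

Counts are generated through a latent-Gaussian copula: a gene × sample
matrix of standard-normal values with the target correlation structure is
shifted/scaled per gene on the log2 scale, exponentiated and rounded to
nonnegative integers. This gives exact control over the Pearson structure
the LIONESS stage consumes while still looking like an RNA-seq count table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneBlock",
    "PerturbedPair",
    "DoseRegime",
    "CohortSpec",
    "SyntheticTruth",
    "CohortConfigError",
    "generate_cohort",
    "generate_ppi",
    "generate_annotation_fixtures",
    "default_cohort_spec",
    "null_cohort_spec",
    "dose_recovery_spec",
    "hub_recovery_spec",
    "two_tissue_spec",
]


class CohortConfigError(ValueError):
    """A CohortSpec invariant is violated; the message names the field."""


@dataclass(frozen=True)
class GeneBlock:
    """A block of gene indices sharing a within-block correlation."""

    genes: tuple[int, ...]
    rho: float


@dataclass(frozen=True)
class PerturbedPair:
    """A gene pair whose correlation differs in spaceflight samples.

    ``min_regime`` gates the perturbation: it is active only for SF samples
    whose dose regime index is >= min_regime (0 = active in all regimes),
    which lets higher dose regimes carry strictly more differential edges.
    ``tissue`` restricts the perturbation to SF samples of one tissue
    (None = all tissues).
    """

    a: int
    b: int
    rho_sf: float
    min_regime: int = 0
    tissue: str | None = None


@dataclass(frozen=True)
class DoseRegime:
    """A contiguous absorbed-dose interval (mGy) with a perturbation scale.

    The scale multiplies (rho_sf - rho_base) for every active perturbed
    pair of samples in the regime, so higher regimes plant stronger
    differential correlations.
    """

    low: float
    high: float
    scale: float = 1.0


@dataclass(frozen=True)
class CohortSpec:
    n_genes: int = 300
    n_gc: int = 30
    n_sf: int = 30
    n_datasets: int = 6
    tissue_labels: tuple[str, ...] = ("liver", "spleen", "thymus")
    baseline_modules: tuple[GeneBlock, ...] = ()
    tissue_modules: dict[str, tuple[GeneBlock, ...]] = field(default_factory=dict)
    perturbed_pairs: tuple[PerturbedPair, ...] = ()
    dose_regimes: tuple[DoseRegime, ...] = (
        DoseRegime(4.66, 7.14, 0.6),
        DoseRegime(7.592, 8.295, 0.8),
        DoseRegime(8.49, 22.099, 1.0),
    )
    regime_sizes: tuple[int, int, int] | None = None
    # genes whose latent log-scale dispersion is inflated in SF samples;
    # tier r applies to samples of regime >= r ("nested" mode) or exactly
    # regime r ("exclusive" mode). Inflation gives a consistent per-sample
    # degree elevation, the signature KNN dose grouping reads.
    regime_variance_markers: tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]] = ((), (), ())
    marker_mode: str = "nested"
    marker_wiring: str = "cliques"  # "cliques": wire tier quadruples in the PPI; "none"
    variance_inflation: float = 1.6
    hub_gene_indices: tuple[int, ...] = ()
    n_silenced_genes: int = 0
    mean_log2_range: tuple[float, float] = (2.0, 8.0)
    gene_log2_sd: float = 1.0
    seed: int = 0

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.n_genes < 2:
            raise CohortConfigError("n_genes must be >= 2")
        if self.n_gc < 4:
            raise CohortConfigError(
                "n_gc must be >= 4 (leave-one-out correlation needs >= 3 samples)"
            )
        if self.n_sf < 4:
            raise CohortConfigError(
                "n_sf must be >= 4 (leave-one-out correlation needs >= 3 samples)"
            )
        if self.n_datasets < 1:
            raise CohortConfigError("n_datasets must be >= 1")
        if not self.tissue_labels:
            raise CohortConfigError("tissue_labels must be non-empty")
        if len(self.dose_regimes) != 3:
            raise CohortConfigError("dose_regimes must list exactly three regimes")
        prev_high = -math.inf
        for r in self.dose_regimes:
            if not (0 < r.low <= r.high):
                raise CohortConfigError("dose_regimes intervals must be positive")
            if r.low <= prev_high:
                raise CohortConfigError("dose_regimes must be disjoint and ordered")
            prev_high = r.high
        if self.regime_sizes is not None:
            if len(self.regime_sizes) != 3 or any(s < 1 for s in self.regime_sizes):
                raise CohortConfigError("regime_sizes must be three positive counts")
            if sum(self.regime_sizes) != self.n_sf:
                raise CohortConfigError("regime_sizes must sum to n_sf")
        n_active = self.n_genes - self.n_silenced_genes
        if n_active < 2:
            raise CohortConfigError("n_silenced_genes leaves fewer than 2 active genes")
        for blocks in [self.baseline_modules, *self.tissue_modules.values()]:
            for b in blocks:
                if any(g < 0 or g >= n_active for g in b.genes):
                    raise CohortConfigError(
                        "baseline_modules/tissue_modules reference a gene outside "
                        "the expressed range"
                    )
                if not (0 <= b.rho < 1):
                    raise CohortConfigError("module rho must lie in [0, 1)")
        for p in self.perturbed_pairs:
            if p.a == p.b:
                raise CohortConfigError("perturbed_pairs must not be self-pairs")
            if any(g < 0 or g >= n_active for g in (p.a, p.b)):
                raise CohortConfigError("perturbed_pairs reference a missing gene")
            if not (-1 < p.rho_sf < 1):
                raise CohortConfigError("perturbed_pairs rho_sf must satisfy |rho| < 1")
            if not (0 <= p.min_regime <= 2):
                raise CohortConfigError("perturbed_pairs min_regime must be 0, 1 or 2")
            if p.tissue is not None and p.tissue not in self.tissue_labels:
                raise CohortConfigError("perturbed_pairs tissue must be a tissue label")
        for h in self.hub_gene_indices:
            if h < 0 or h >= n_active:
                raise CohortConfigError("hub_gene_indices reference a missing gene")
        if len(self.regime_variance_markers) != 3:
            raise CohortConfigError("regime_variance_markers must have three tiers")
        for tier in self.regime_variance_markers:
            if any(g < 0 or g >= n_active for g in tier):
                raise CohortConfigError("regime_variance_markers reference a missing gene")
        if self.variance_inflation <= 0:
            raise CohortConfigError("variance_inflation must be > 0")
        if self.marker_mode not in ("nested", "exclusive"):
            raise CohortConfigError("marker_mode must be 'nested' or 'exclusive'")
        if self.marker_wiring not in ("cliques", "none"):
            raise CohortConfigError("marker_wiring must be 'cliques' or 'none'")

    # -- naming helpers ---------------------------------------------------
    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def sample_names(self) -> list[str]:
        gc = [f"GC{i:03d}" for i in range(self.n_gc)]
        sf = [f"SF{i:03d}" for i in range(self.n_sf)]
        return gc + sf


@dataclass
class SyntheticTruth:
    """Ground truth labels for a generated cohort."""

    perturbed_genes: set[str]
    planted_hub_genes: list[str]
    dose_boundaries: tuple[float, float]
    dose_labels: pd.Series  # index: SF sample id, values in {"L","M","H"}

    def to_dict(self) -> dict:
        return {
            "perturbed_genes": sorted(self.perturbed_genes),
            "planted_hub_genes": list(self.planted_hub_genes),
            "dose_boundaries": list(self.dose_boundaries),
            "dose_labels": self.dose_labels.to_dict(),
        }


REGIME_NAMES = ("L", "M", "H")


# ---------------------------------------------------------------------------
# correlation machinery


def _nearest_psd_correlation(c: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalues are clipped at ``eps`` and the diagonal rescaled to 1.
    Planted structures such as correlation stars are infeasible as written;
    the projection keeps their qualitative shape while making the target
    drawable.
    """
    vals, vecs = np.linalg.eigh(c)
    if vals.min() >= eps:
        return c
    vals = np.clip(vals, eps, None)
    c2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(c2))
    c2 = c2 / np.outer(d, d)
    np.fill_diagonal(c2, 1.0)
    return c2


def _target_correlation(
    spec: CohortSpec, tissue: str, condition: str, regime: int | None
) -> np.ndarray:
    g = spec.n_genes
    c = np.eye(g)

    def apply_block(block: GeneBlock) -> None:
        idx = np.asarray(block.genes)
        sub = np.full((len(idx), len(idx)), block.rho)
        np.fill_diagonal(sub, 1.0)
        c[np.ix_(idx, idx)] = sub

    for b in spec.baseline_modules:
        apply_block(b)
    for b in spec.tissue_modules.get(tissue, ()):
        apply_block(b)
    if condition == "SF" and regime is not None:
        scale = spec.dose_regimes[regime].scale
        for p in spec.perturbed_pairs:
            if regime >= p.min_regime and (p.tissue is None or p.tissue == tissue):
                base = c[p.a, p.b]
                rho = base + scale * (p.rho_sf - base)
                c[p.a, p.b] = c[p.b, p.a] = rho
    return _nearest_psd_correlation(c)


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw one synthetic cohort.

    Returns ``(counts, metadata, truth)`` where counts is a genes × samples
    integer DataFrame, metadata has one row per sample with columns
    sample_id, condition, tissue, dataset, dose_mGy, and truth records the
    planted perturbed genes, hub genes, dose boundaries and regime labels.
    Identical spec (including seed) gives byte-identical outputs.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_dose, rng_latent, rng_gene = [np.random.default_rng(s) for s in ss.spawn(3)]

    genes = spec.gene_names()
    samples = spec.sample_names()
    n = spec.n_gc + spec.n_sf

    # metadata: dataset accessions pair GC and SF; tissue follows dataset
    conditions = ["GC"] * spec.n_gc + ["SF"] * spec.n_sf
    datasets, tissues = [], []
    for cond_count in (spec.n_gc, spec.n_sf):
        for i in range(cond_count):
            d = i % spec.n_datasets
            datasets.append(f"SYN-{d:02d}")
            tissues.append(spec.tissue_labels[d % len(spec.tissue_labels)])

    # dose regimes for SF samples
    if spec.regime_sizes is not None:
        sizes = list(spec.regime_sizes)
    else:
        base, rem = divmod(spec.n_sf, 3)
        sizes = [base + (1 if i < rem else 0) for i in range(3)]
    regime_idx = np.repeat(np.arange(3), sizes)
    doses = np.zeros(n)
    sf_doses = np.concatenate(
        [
            rng_dose.uniform(r.low, r.high, size=s)
            for r, s in zip(spec.dose_regimes, sizes)
        ]
    )
    doses[spec.n_gc :] = sf_doses

    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "condition": conditions,
            "tissue": tissues,
            "dataset": datasets,
            "dose_mGy": doses,
        }
    )

    # latent Gaussian draws, one cell per (tissue, condition, regime)
    z = np.zeros((spec.n_genes, n))
    cell_of = [
        (tissues[i], conditions[i], int(regime_idx[i - spec.n_gc]) if conditions[i] == "SF" else None)
        for i in range(n)
    ]
    for cell in sorted(set(cell_of), key=lambda t: (t[0], t[1], -1 if t[2] is None else t[2])):
        cols = [i for i, c in enumerate(cell_of) if c == cell]
        corr = _target_correlation(spec, *cell)
        chol = np.linalg.cholesky(corr)
        draw = chol @ rng_latent.standard_normal((spec.n_genes, len(cols)))
        _, condition, regime = cell
        if condition == "SF" and regime is not None:
            inflate = np.ones(spec.n_genes)
            for step, tier in enumerate(spec.regime_variance_markers):
                active = regime >= step if spec.marker_mode == "nested" else regime == step
                if active and tier:
                    inflate[np.asarray(tier)] = spec.variance_inflation
            draw *= inflate[:, None]
        z[:, cols] = draw

    # gene-level count model: log2 mean + constant log2 sd, then 2**x rounded
    lo, hi = spec.mean_log2_range
    mu = rng_gene.uniform(lo, hi, size=spec.n_genes)
    if spec.n_silenced_genes:
        mu[spec.n_genes - spec.n_silenced_genes :] = -2.0
    latent = mu[:, None] + spec.gene_log2_sd * z
    counts = np.rint(np.exp2(latent)).astype(np.int64)
    counts = np.maximum(counts, 0)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)

    # truth
    perturbed_genes = {genes[p.a] for p in spec.perturbed_pairs} | {
        genes[p.b] for p in spec.perturbed_pairs
    }
    hubs = [genes[h] for h in spec.hub_gene_indices]
    sf_samples = samples[spec.n_gc :]
    dose_labels = pd.Series(
        [REGIME_NAMES[r] for r in regime_idx], index=pd.Index(sf_samples, name="sample_id")
    )
    boundaries = (
        float(sf_doses[regime_idx == 0].max()),
        float(sf_doses[regime_idx == 1].max()),
    )
    truth = SyntheticTruth(perturbed_genes, hubs, boundaries, dose_labels)
    return counts_df, metadata, truth


def _planted_pairs(spec: CohortSpec) -> set[tuple[str, str]]:
    genes = spec.gene_names()
    pairs: set[tuple[str, str]] = set()
    for blocks in [spec.baseline_modules, *spec.tissue_modules.values()]:
        for b in blocks:
            for a, c in itertools.combinations(sorted(b.genes), 2):
                pairs.add((genes[a], genes[c]))
    for p in spec.perturbed_pairs:
        a, c = sorted((p.a, p.b))
        pairs.add((genes[a], genes[c]))
    return pairs


def generate_ppi(
    spec: CohortSpec,
    extra_edge_fraction: float = 0.01,
    enriched_degree: int = 0,
) -> pd.DataFrame:
    """Synthetic PPI edge list: all planted pairs plus random extra pairs.

    ``extra_edge_fraction`` is the fraction of all possible gene pairs added
    as random (non-planted) edges. Dispersion-marker genes are additionally
    wired to at least ``enriched_degree`` partners, mimicking the high
    connectivity of well-studied stress-response genes in curated PPI
    resources. The result is a simple undirected edge list with canonically
    ordered columns gene_a < gene_b, deterministic for a given spec.
    """
    spec.validate()
    if not (0 <= extra_edge_fraction <= 1):
        raise CohortConfigError("extra_edge_fraction must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(4)[3])
    genes = spec.gene_names()
    planted = _planted_pairs(spec)
    n_possible = spec.n_genes * (spec.n_genes - 1) // 2
    n_extra = int(round(extra_edge_fraction * n_possible))
    edges = set(planted)
    target = min(len(planted) + n_extra, n_possible)
    while len(edges) < target:
        need = target - len(edges)
        ii = rng.integers(0, spec.n_genes, size=2 * need + 8)
        jj = rng.integers(0, spec.n_genes, size=2 * need + 8)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            a, b = (int(i), int(j)) if i < j else (int(j), int(i))
            edges.add((genes[a], genes[b]))
            if len(edges) >= target:
                break
    # dispersion-marker genes: wire consecutive within-tier quadruples as
    # cliques (co-inflation is only visible to the pipeline where the pair
    # is a PPI edge; three partners per gene average the presence noise)
    if spec.marker_wiring == "cliques":
        for tier in spec.regime_variance_markers:
            for k in range(0, len(tier) - 3, 4):
                for a, b in itertools.combinations(tier[k : k + 4], 2):
                    edges.add((genes[min(a, b)], genes[max(a, b)]))
    enriched = sorted({g for tier in spec.regime_variance_markers for g in tier})
    for g in enriched:
        degree = sum(1 for e in edges if genes[g] in e)
        while degree < min(enriched_degree, spec.n_genes - 1):
            p = int(rng.integers(0, spec.n_genes))
            if p == g:
                continue
            a, b = (g, p) if g < p else (p, g)
            e = (genes[a], genes[b])
            if e not in edges:
                edges.add(e)
                degree += 1
    rows = sorted(edges)
    return pd.DataFrame(rows, columns=["gene_a", "gene_b"])


def generate_annotation_fixtures(
    spec: CohortSpec,
    radiation_set_size: int = 40,
    n_decoy_sets: int = 5,
    decoy_set_size: int = 30,
    n_diseases: int = 8,
    homolog_coverage: float = 0.97,
) -> tuple[dict[str, list[str]], pd.DataFrame, pd.DataFrame]:
    """Annotation fixtures: gene sets (GMT-ready), gene–disease table, homologs.

    The "radiation_response" gene set is enriched for the planted perturbed
    genes (they all belong to it, padded with random genes up to
    ``radiation_set_size``); decoy sets are random draws. The gene–disease
    table carries scores and evidence indices in [0, 1]. The homolog mapping
    is identity-plus-noise: most genes map to an upper-cased human symbol,
    a few are dropped and a few map to two paralogs.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(5)[4])
    genes = spec.gene_names()
    perturbed = sorted(
        {genes[p.a] for p in spec.perturbed_pairs} | {genes[p.b] for p in spec.perturbed_pairs}
    )
    pool = [g for g in genes if g not in set(perturbed)]

    sets: dict[str, list[str]] = {}
    n_pad = max(0, radiation_set_size - len(perturbed))
    pad = list(rng.choice(pool, size=min(n_pad, len(pool)), replace=False))
    sets["radiation_response"] = sorted(perturbed + pad)
    for k in range(n_decoy_sets):
        members = rng.choice(genes, size=min(decoy_set_size, len(genes)), replace=False)
        sets[f"decoy_set_{k:02d}"] = sorted(members)

    diseases = [f"disease_{k:02d}" for k in range(n_diseases)]
    rows = []
    assoc_genes = perturbed + list(rng.choice(pool, size=min(len(pool), 40), replace=False))
    for g in assoc_genes:
        for d in rng.choice(diseases, size=rng.integers(1, 4), replace=False):
            rows.append(
                {
                    "gene": f"H{g}",
                    "disease": d,
                    "score": float(np.round(rng.uniform(0, 1), 4)),
                    "ei": float(np.round(rng.uniform(0, 1), 4)),
                }
            )
    disease_df = pd.DataFrame(rows).sort_values(["gene", "disease"]).reset_index(drop=True)

    hom_rows = []
    for g in genes:
        u = rng.uniform()
        if u > homolog_coverage:
            continue  # unmapped gene
        hom_rows.append({"mouse_gene": g, "human_gene": f"H{g}"})
        if u < 0.02:  # one-to-many paralog expansion
            hom_rows.append({"mouse_gene": g, "human_gene": f"H{g}B"})
    homolog_df = pd.DataFrame(hom_rows)
    return sets, disease_df, homolog_df


# ---------------------------------------------------------------------------
# presets: the study conditions exercised by the test-suite and pipeline


def _block_pairs(
    genes: list[int] | range, rho_sf: float, min_regime: int = 0, tissue: str | None = None
) -> tuple[PerturbedPair, ...]:
    """All pairs of a gene block as perturbed pairs (an SF-only module).

    A uniformly correlated block is always positive semidefinite, so the
    planted correlations are realized exactly; and every member carries
    several differential edges, which is what gives per-sample networks a
    readable degree signal through the mu + 2*sigma cut.
    """
    return tuple(
        PerturbedPair(a, b, rho_sf, min_regime, tissue)
        for a, b in itertools.combinations(genes, 2)
    )


def default_cohort_spec(seed: int = 0, n_gc: int = 30, n_sf: int = 30) -> CohortSpec:
    """Default 300-gene cohort: three SF-only correlated blocks of ten
    genes (30 perturbed genes), two baseline co-expression modules, three
    dose regimes with mild scale differences, 5 silenced genes.

    Per-sample networks retain only |score| > mu + 2*sigma edges, which
    caps per-edge detection at roughly 15% per sample even for near-perfect
    correlations; the 30 planted genes therefore share one block so each
    carries 29 differential edges and a readable degree shift.
    """
    return CohortSpec(
        n_genes=300,
        n_gc=n_gc,
        n_sf=n_sf,
        n_datasets=6,
        baseline_modules=(
            GeneBlock(tuple(range(200, 215)), 0.5),
            GeneBlock(tuple(range(215, 230)), 0.5),
        ),
        perturbed_pairs=_block_pairs(range(30), 0.95),
        dose_regimes=(
            DoseRegime(4.66, 7.14, 0.95),
            DoseRegime(7.592, 8.295, 0.975),
            DoseRegime(8.49, 22.099, 1.0),
        ),
        mean_log2_range=(4.0, 9.0),
        n_silenced_genes=5,
        seed=seed,
    )


def hub_recovery_spec(seed: int = 0, n_gc: int = 30, n_sf: int = 30) -> CohortSpec:
    """Cohort with 10 planted differential hub genes.

    Each hub gene and its ten PPI spokes are dispersion-inflated in every
    SF sample and weakly SF-correlated (rho 0.1 hub-spoke), so the star's
    edges light up through the influence tail in a sizable fraction of SF
    networks and almost never in GC. The PPI wires hub-spoke stars only,
    so the hub collects ten high-differential edges while each spoke
    carries one — the hubs dominate the weighted-degree ranking of the
    differential network. No baseline co-expression modules are planted:
    inflation raises the SF edge threshold, which would otherwise turn
    ordinary module edges into spurious GC-side differential edges.
    """
    pairs: list[PerturbedPair] = []
    markers: list[int] = []
    for h in range(10):
        spokes = tuple(range(10 + 10 * h, 20 + 10 * h))
        pairs.extend(PerturbedPair(h, s, 0.1) for s in spokes)
        markers.extend((h, *spokes))
    return CohortSpec(
        n_genes=300,
        n_gc=n_gc,
        n_sf=n_sf,
        n_datasets=6,
        baseline_modules=(),
        perturbed_pairs=tuple(pairs),
        regime_variance_markers=(tuple(markers), (), ()),
        marker_mode="nested",
        marker_wiring="none",
        variance_inflation=3.5,
        hub_gene_indices=tuple(range(10)),
        dose_regimes=(
            DoseRegime(4.66, 7.14, 0.95),
            DoseRegime(7.592, 8.295, 0.975),
            DoseRegime(8.49, 22.099, 1.0),
        ),
        mean_log2_range=(4.0, 9.0),
        seed=seed,
    )


def null_cohort_spec(seed: int = 0, n_genes: int = 1000, n_gc: int = 40, n_sf: int = 40) -> CohortSpec:
    """Null cohort: no perturbed pairs, so GC and SF are exchangeable."""
    return CohortSpec(
        n_genes=n_genes,
        n_gc=n_gc,
        n_sf=n_sf,
        n_datasets=5,
        baseline_modules=(
            GeneBlock(tuple(range(100, 115)), 0.5),
            GeneBlock(tuple(range(115, 130)), 0.5),
        ),
        perturbed_pairs=(),
        seed=seed,
    )


def dose_recovery_spec(seed: int = 0) -> CohortSpec:
    """Cohort for dose-group recovery: 120 SF samples in 30/40/50 regimes.

    Each regime carries its own tier of dispersion-marker genes (40, 60
    and 80 genes for low, medium and high dose), whose latent log-scale
    variance is inflated in SF samples of exactly that regime. Markers are
    wired as four-gene cliques in the PPI; a co-inflated edge lights in a
    large fraction of its regime's samples (against a few percent
    otherwise), giving every SF sample a low-noise regime signature the
    KNN classifier can read; larger tiers at higher dose mean more
    differential genes with dose.
    """
    return CohortSpec(
        n_genes=300,
        n_gc=40,
        n_sf=120,
        n_datasets=8,
        baseline_modules=(GeneBlock(tuple(range(210, 225)), 0.5),),
        regime_variance_markers=(
            tuple(range(0, 40)),
            tuple(range(40, 100)),
            tuple(range(100, 180)),
        ),
        marker_mode="exclusive",
        variance_inflation=3.0,
        regime_sizes=(30, 40, 50),
        dose_regimes=(
            DoseRegime(4.66, 7.14, 0.95),
            DoseRegime(7.592, 8.295, 0.975),
            DoseRegime(8.49, 22.099, 1.0),
        ),
        mean_log2_range=(4.0, 9.0),
        seed=seed,
    )


def two_tissue_spec(seed: int = 0) -> CohortSpec:
    """Two tissues with strong tissue-specific co-expression modules, for
    embedding / clustering checks (networks should cluster by tissue)."""
    return CohortSpec(
        n_genes=120,
        n_gc=12,
        n_sf=12,
        n_datasets=2,
        tissue_labels=("liver", "spleen"),
        tissue_modules={
            "liver": (GeneBlock(tuple(range(0, 30)), 0.85),),
            "spleen": (GeneBlock(tuple(range(30, 60)), 0.85),),
        },
        seed=seed,
    )
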