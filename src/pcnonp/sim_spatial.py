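"""Spatially structured cohort simulator (grid structured coalescent).

Individuals originate from squares of a ``K0 x K0`` lattice.  Each
variant's genealogy is a backward-in-time structured coalescent: two
lineages in the same square coalesce at rate 1 (coalescent time units),
and each lineage migrates at total rate ``M/2`` split equally among its
rook-adjacent squares (reflecting boundaries).  One mutation dropped on
a branch chosen proportional to branch length yields the variant's
genotypes; each diploid contributes two co-located lineages.

The genealogy engine is msprime's structured-coalescent sampler,
configured so that its rates match the above (per-deme size 1 with
haploid-pair coalescence rate 1).  Mutation dropping, carrier
extraction and genotype construction are implemented here on the
exported node tables.

Nongenetic spatial risk enters the trait as ``y = beta * R_phi + eps``
with three risk surfaces: model 0 (flat zero), model 1 (three sharp
4x4 unit blocks), model 2 (wide smooth Gaussian bump).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .genotypes import GenotypeMatrix
from .sim_subpop import SimCohort, power_trait

#: risk-model-1 block anchors, 1-based (l0, j0) with blocks l0..l0+3
MODEL1_ANCHORS = ((6, 6), (14, 6), (14, 14))


@dataclass
class GridConfig:
    """Grid-simulator parameters (coalescent time units throughout)."""

    K0: int = 20
    M: float = 0.01
    n: int = 500
    beta_risk: float = 2.0
    placement: str = "uniform"  # or "one-per-square"
    seed: int | None = None

    def __post_init__(self):
        if self.K0 < 1:
            raise ValueError("K0 must be >= 1")
        if self.M <= 0:
            raise ValueError("M must be > 0")

    @property
    def n_demes(self) -> int:
        return self.K0 * self.K0


@dataclass
class RiskSurface:
    """Nongenetic risk per grid square; ``R[l-1, j-1]`` in the 1-based
    (l, j) convention."""

    R: np.ndarray
    model: int

    def at(self, phi: np.ndarray) -> np.ndarray:
        """Risk value at flat deme indices (row-major, 0-based)."""
        return self.R.ravel()[np.asarray(phi)]


class Genealogy:
    """A single-variant coalescent tree in compact array form.

    Leaves (two per diploid) occupy a contiguous permutation such that
    every node's descendant leaves form the slice
    ``leaf_order[start[u]:end[u]]``; this makes carrier extraction a
    slice plus a bincount.
    """

    def __init__(self, parent, time, node_individual, individual_map, n):
        self.parent = parent
        self.time = time
        self.n = int(n)
        self.num_nodes = parent.size
        self.num_leaves = 2 * self.n
        # children adjacency (transient) to build contiguous leaf intervals
        order = np.argsort(time, kind="stable")
        children = [[] for _ in range(self.num_nodes)]
        for u in range(self.num_nodes):
            p = parent[u]
            if p >= 0:
                children[p].append(u)
        root = int(order[-1])
        start = np.zeros(self.num_nodes, dtype=np.int32)
        end = np.zeros(self.num_nodes, dtype=np.int32)
        leaf_order = np.empty(self.num_leaves, dtype=np.int32)
        pos = 0
        stack = [(root, False)]
        while stack:
            u, done = stack.pop()
            if done:
                end[u] = pos
                continue
            start[u] = pos
            if not children[u]:
                leaf_order[pos] = u
                pos += 1
                end[u] = pos
            else:
                stack.append((u, True))
                for c in children[u]:
                    stack.append((c, False))
        self.start, self.end = start, end
        # cohort individual index for each position of leaf_order
        self.ind_order = individual_map[node_individual[leaf_order]].astype(np.int32)
        self.num_samples = (end - start).astype(np.int32)
        bl = np.zeros(self.num_nodes)
        has_parent = parent >= 0
        bl[has_parent] = time[parent[has_parent]] - time[has_parent]
        self.branch_lengths = bl

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    @property
    def tmrca(self) -> float:
        return float(self.time.max())

    def genotypes_below(self, node: int) -> np.ndarray:
        """Diploid genotype column for a mutation on the branch above
        ``node`` (carrier lineage count per individual)."""
        carriers = self.ind_order[self.start[node]:self.end[node]]
        return np.bincount(carriers, minlength=self.n).astype(np.int8)

    def folded_maf(self, node: int) -> float:
        c = int(self.num_samples[node])
        return min(c, self.num_leaves - c) / self.num_leaves


def place_samples(cfg: GridConfig, rng: np.random.Generator) -> np.ndarray:
    """Map individuals to grid squares (flat row-major 0-based index).

    ``uniform`` placement is multinomial over the squares;
    ``one-per-square`` requires ``n == K0^2`` and is a bijection.
    """
    if cfg.placement == "one-per-square":
        if cfg.n != cfg.n_demes:
            raise ValueError("one-per-square placement needs n == K0^2")
        return np.arange(cfg.n_demes)
    return rng.integers(0, cfg.n_demes, size=cfg.n)


def phi_to_lj(phi: np.ndarray, K0: int) -> np.ndarray:
    """Flat deme index -> 1-based (l, j) grid coordinates, shape (n, 2)."""
    phi = np.asarray(phi)
    return np.column_stack([phi // K0 + 1, phi % K0 + 1])


@lru_cache(maxsize=8)
def _demography(K0: int, M: float):
    import msprime

    dem = msprime.Demography()
    n_demes = K0 * K0
    # ploidy * size = 1 so two lineages in a deme coalesce at rate 1
    for i in range(n_demes):
        dem.add_population(name=f"d{i}", initial_size=0.5)
    if n_demes > 1:
        rates = np.zeros((n_demes, n_demes))
        for l in range(K0):
            for j in range(K0):
                i = l * K0 + j
                nb = []
                if l > 0:
                    nb.append(i - K0)
                if l < K0 - 1:
                    nb.append(i + K0)
                if j > 0:
                    nb.append(i - 1)
                if j < K0 - 1:
                    nb.append(i + 1)
                for v in nb:
                    rates[i, v] = (M / 2.0) / len(nb)
        dem.migration_matrix = rates
    return dem


def _sample_sets(phi: np.ndarray):
    import msprime

    counts = np.bincount(phi, minlength=int(phi.max()) + 1)
    return [
        msprime.SampleSet(int(c), population=int(d), ploidy=2)
        for d, c in enumerate(counts)
        if c > 0
    ]


def _genealogy_from_ts(ts, individual_map: np.ndarray) -> Genealogy:
    tree = ts.first()
    num_nodes = ts.num_nodes
    parent = tree.parent_array[:num_nodes].astype(np.int32)
    time = ts.tables.nodes.time
    node_ind = ts.tables.nodes.individual
    return Genealogy(parent, time, node_ind, individual_map, ts.num_individuals)


def genealogy_stream(phi: np.ndarray, cfg: GridConfig, rng: np.random.Generator,
                     total: int):
    """Yield ``total`` independent genealogies for the placed sample."""
    import msprime

    phi = np.asarray(phi)
    individual_map = np.argsort(phi, kind="stable").astype(np.int32)
    dem = _demography(cfg.K0, cfg.M)
    samples = _sample_sets(phi)
    seed = int(rng.integers(1, 2**31 - 1))
    reps = msprime.sim_ancestry(
        samples=samples, demography=dem, ploidy=2,
        num_replicates=total, random_seed=seed,
    )
    for ts in reps:
        yield _genealogy_from_ts(ts, individual_map)


def simulate_genealogy(phi: np.ndarray, cfg: GridConfig,
                       rng: np.random.Generator) -> Genealogy:
    """One structured-coalescent genealogy for the placed sample."""
    return next(genealogy_stream(phi, cfg, rng, total=1))


def _check_window(maf_window, num_leaves):
    lo, hi = maf_window
    if hi < 1.0 / num_leaves:
        raise ValueError(
            f"maf_window upper bound {hi} is below the minimum attainable "
            f"MAF 1/{num_leaves}"
        )
    return lo, hi


def drop_mutation(tree: Genealogy, rng: np.random.Generator,
                  maf_window: tuple[float, float] | None = None,
                  tree_source=None) -> np.ndarray:
    """Place one mutation proportional to branch length; return genotypes.

    With ``maf_window = (lo, hi)`` the draw is rejected and a fresh tree
    (from ``tree_source``) plus mutation drawn until the folded sample
    MAF lies in ``[lo, hi)``.
    """
    if maf_window is not None:
        lo, hi = _check_window(maf_window, tree.num_leaves)
        if tree_source is None:
            raise ValueError("maf_window rejection needs a tree_source for redraws")
    while True:
        bl = tree.branch_lengths
        node = int(rng.choice(tree.num_nodes, p=bl / bl.sum()))
        if maf_window is None:
            return tree.genotypes_below(node)
        maf = tree.folded_maf(node)
        if lo <= maf < hi:
            return tree.genotypes_below(node)
        tree = next(tree_source)


def window_mutation(tree: Genealogy, rng: np.random.Generator,
                    maf_window: tuple[float, float]) -> np.ndarray | None:
    """Mutation proportional to branch length among window-compatible
    branches only (conditions the tree on yielding an in-window
    variant); ``None`` if the tree has no compatible branch."""
    lo, hi = _check_window(maf_window, tree.num_leaves)
    c = tree.num_samples
    folded = np.minimum(c, tree.num_leaves - c) / tree.num_leaves
    mask = (folded >= lo) & (folded < hi)
    weights = tree.branch_lengths * mask
    tot = weights.sum()
    if tot <= 0:
        return None
    node = int(rng.choice(tree.num_nodes, p=weights / tot))
    return tree.genotypes_below(node)


def simulate_variants(phi: np.ndarray, cfg: GridConfig, rng: np.random.Generator,
                      count: int, maf_window: tuple[float, float] | None = None,
                      variants_per_tree: int = 1) -> np.ndarray:
    """(n, count) genotype matrix, streaming one tree per
    ``variants_per_tree`` variants.  Window placement is restricted (see
    :func:`window_mutation`); trees with no compatible branch are
    skipped."""
    cols = []
    # generous upper bound on trees needed; the stream is lazy
    budget = 4 * count + 32
    stream = genealogy_stream(phi, cfg, rng, total=budget)
    for tree in stream:
        for _ in range(variants_per_tree):
            if maf_window is None:
                cols.append(drop_mutation(tree, rng))
            else:
                g = window_mutation(tree, rng, maf_window)
                if g is None:
                    break
                cols.append(g)
            if len(cols) == count:
                return np.column_stack(cols)
    raise RuntimeError("genealogy stream exhausted before reaching count")


class TreePool:
    """Cache of independent genealogies reused across replicates.

    Regional experiments draw each region's variants from pool trees
    with fresh mutations, amortizing the coalescent cost over
    replicates.  A tree is chosen with probability proportional to its
    branch length inside the MAF window and the branch then drawn
    proportional to length within the window, which reproduces the
    distribution of a random segregating site (Poisson mutations)
    restricted to the pool.
    """

    def __init__(self, phi, cfg, rng, size: int):
        self.trees = list(genealogy_stream(phi, cfg, rng, total=size))
        self._weights: dict[tuple[float, float], np.ndarray] = {}

    def _window_probs(self, maf_window: tuple[float, float]) -> np.ndarray:
        probs = self._weights.get(maf_window)
        if probs is None:
            lo, hi = maf_window
            lens = np.empty(len(self.trees))
            for t, tree in enumerate(self.trees):
                c = tree.num_samples
                folded = np.minimum(c, tree.num_leaves - c) / tree.num_leaves
                mask = (folded >= lo) & (folded < hi)
                lens[t] = (tree.branch_lengths * mask).sum()
            if lens.sum() <= 0:
                raise ValueError("no pool tree has branches inside the MAF window")
            probs = lens / lens.sum()
            self._weights[maf_window] = probs
        return probs

    def draw_variants(self, rng: np.random.Generator, count: int,
                      maf_window: tuple[float, float]) -> np.ndarray:
        probs = self._window_probs(maf_window)
        idx = rng.choice(len(self.trees), size=count, p=probs)
        cols = [window_mutation(self.trees[t], rng, maf_window) for t in idx]
        return np.column_stack(cols)


def risk_surface(model: int, K0: int = 20, sigma: float = 5.0,
                 anchors=MODEL1_ANCHORS, center=(6, 6)) -> RiskSurface:
    """Nongenetic risk surfaces 0 (flat), 1 (sharp blocks), 2 (smooth).

    Model 1 places unit-height 4x4 blocks at each anchor ``(l0, j0)``
    covering ``l0 <= l <= l0+3``; model 2 is a Gaussian bump of scale
    ``sigma`` centered at ``center`` with unit peak.
    """
    if model == 0:
        return RiskSurface(np.zeros((K0, K0)), 0)
    if model == 1:
        R = np.zeros((K0, K0))
        for l0, j0 in anchors:
            R[l0 - 1:l0 + 3, j0 - 1:j0 + 3] = 1.0
        return RiskSurface(R, 1)
    if model == 2:
        l = np.arange(1, K0 + 1)
        dl = (l[:, None] - center[0]) ** 2 + (l[None, :] - center[1]) ** 2
        return RiskSurface(np.exp(-dl / (2.0 * sigma**2)), 2)
    raise ValueError(f"unknown risk model {model!r}")


def null_trait_spatial(phi: np.ndarray, surface: RiskSurface, cfg: GridConfig,
                       rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Null trait ``y = beta * R_phi + N(0, 1)``; ``size`` gives columns
    of independent replicates."""
    base = cfg.beta_risk * surface.at(phi)
    if size is None:
        return base + rng.standard_normal(base.size)
    return base[:, None] + rng.standard_normal((base.size, size))


def power_trait_spatial(region: np.ndarray, causal_ids: np.ndarray, h2: float,
                        causal_mafs: np.ndarray, null_trait: np.ndarray) -> np.ndarray:
    """Equal-heritability causal effects added to the spatial null trait."""
    return power_trait(region, causal_ids, h2, causal_mafs, null_trait)


def simulate_cohort(cfg: GridConfig, rng: np.random.Generator | None = None,
                    risk_model: int = 0, L: int = 2000, n_T: int = 10,
                    marker_window: tuple[float, float] = (0.01, 0.5),
                    region_window: tuple[float, float] = (0.001, 0.01),
                    h2: float = 0.0, qualitative: bool = False) -> SimCohort:
    """Full spatial cohort: markers, candidate region, trait, origins."""
    from .sim_subpop import dichotomize

    rng = rng or np.random.default_rng(cfg.seed)
    phi = place_samples(cfg, rng)
    # folded MAF upper bound is 0.5 exactly; widen hi so 0.5 is included
    mw = (marker_window[0], np.nextafter(marker_window[1], 1.0))
    markers = GenotypeMatrix(simulate_variants(phi, cfg, rng, L, mw),
                             variant_ids=[f"M{j}" for j in range(L)])
    region_vals = simulate_variants(phi, cfg, rng, n_T, region_window)
    region = GenotypeMatrix(region_vals, variant_ids=[f"R{j}" for j in range(n_T)])
    surface = risk_surface(risk_model, cfg.K0)
    y0 = null_trait_spatial(phi, surface, cfg, rng)
    causal_ids = None
    if h2 > 0:
        n_c = n_T // 2
        causal_ids = rng.choice(n_T, size=n_c, replace=False)
        maf = GenotypeMatrix(region_vals).maf[causal_ids]
        y = power_trait_spatial(region_vals, causal_ids, h2, maf, y0)
    else:
        y = y0
    if qualitative:
        y = dichotomize(y)
    return SimCohort(markers, region, y, phi, causal_ids,
                     truth={"cfg": cfg, "risk_model": risk_model})
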