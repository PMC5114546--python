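"""Type-I-error and power experiments over the two simulation engines.

A calibration run draws batches of cohorts; within a batch the
background (markers, PCs, selected bandwidth h*) is shared and each
replicate is a fresh null trait plus a fresh candidate variant or
region.  Rejection rates at the nominal levels are compared to a 2-SD
binomial band.  Power runs add equal-heritability causal effects over
a grid of regional heritabilities.

All randomness flows from one master seed through per-batch
``numpy.random.SeedSequence`` spawns, so identical configs reproduce
bit-identical tables.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import sim_spatial, sim_subpop
from .association import GC_CHI2_MEDIAN, kernel_score_paired, score_test_paired
from .bandwidth import bandwidth_grid, select_bandwidth
from .genotypes import GenotypeMatrix
from .kernel import KernelSmoother
from .pca import ancestry_pcs
from .sim_spatial import GridConfig, TreePool, risk_surface
from .sim_subpop import SubpopConfig

logger = logging.getLogger(__name__)

ALL_TESTS = ("Uncorrected", "GC", "PC-linear", "PC-nonp")

#: default folded-MAF windows for spatial variants (half-open)
MARKER_WINDOW = (0.01, 0.5000001)
RARE_WINDOW = (0.001, 0.01)


@dataclass
class ExperimentConfig:
    """One calibration or power experiment.

    ``subpop`` or ``grid`` selects the scenario; the other is None.
    ``replicates`` is the total across ``batches`` batches, each with
    its own cohort background.
    """

    replicates: int
    subpop: SubpopConfig | None = None
    grid: GridConfig | None = None
    risk_model: int = 0
    tests: tuple[str, ...] = ALL_TESTS
    mode: str = "single_variant"  # or "regional"
    trait_type: str = "quantitative"  # or "qualitative"
    alphas: tuple[float, ...] = (0.01, 0.001)
    batches: int = 10
    k_pcs: int = 10
    L: int = 2000  # spatial background markers (subpop uses subpop.L)
    n_T: int = 10  # regional candidate size
    h2: float = 0.0
    region_mode: str = "independent"  # spatial regions: independent | shared_tree
    pool_size: int = 300  # cached genealogies for region_mode="independent"
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if (self.subpop is None) == (self.grid is None):
            raise ValueError("exactly one of subpop or grid must be set")
        if any(not 0 < a < 1 for a in self.alphas):
            raise ValueError("alphas must lie in (0, 1)")
        unknown = set(self.tests) - set(ALL_TESTS)
        if unknown:
            raise ValueError(f"unknown tests: {sorted(unknown)}")

    @property
    def scenario(self) -> str:
        return "subpop" if self.subpop is not None else "spatial"


def binomial_band(alpha: float, replicates: int) -> tuple[float, float]:
    """2-SD binomial band around a nominal level, clipped to [0, 1].

    Endpoints are rounded to the second significant digit of the
    half-width, matching the printing convention of reported CIs
    ((0.008, 0.012) and (0.00037, 0.00163) at 10,000 replicates).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    half = 2.0 * math.sqrt(alpha * (1.0 - alpha) / replicates)
    decimals = -math.floor(math.log10(half)) + 1
    lo = round(max(0.0, alpha - half), decimals)
    hi = round(min(1.0, alpha + half), decimals)
    return lo, hi


# ---------------------------------------------------------------------------
# batch background and replicate draws


@dataclass
class _Background:
    """Shared per-batch state."""

    n: int
    markers: GenotypeMatrix | None
    pcs: object | None
    smoother: KernelSmoother | None
    h_star: float | None
    linear_q: np.ndarray | None
    labels: np.ndarray  # subpop labels or flat deme index
    pool: TreePool | None = None
    phi: np.ndarray | None = None
    marker_freqs: np.ndarray | None = None


def _needs(cfg: ExperimentConfig):
    needs_pcs = bool({"PC-linear", "PC-nonp"} & set(cfg.tests))
    needs_markers = needs_pcs or "GC" in cfg.tests
    return needs_pcs, needs_markers


def _null_traits(cfg, bg, rng, size):
    if cfg.scenario == "subpop":
        y = sim_subpop.null_trait_quant(bg.labels, cfg.subpop, rng, size=size)
    else:
        surface = risk_surface(cfg.risk_model, cfg.grid.K0)
        y = sim_spatial.null_trait_spatial(bg.phi, surface, cfg.grid, rng, size=size)
    if cfg.trait_type == "qualitative":
        y = sim_subpop.dichotomize(y).astype(float)
    return y


def _subpop_background(cfg: ExperimentConfig, rng) -> _Background:
    sp = cfg.subpop
    needs_pcs, needs_markers = _needs(cfg)
    labels = np.repeat(np.arange(sp.k0), sp.n_per_subpop)
    markers = pcs = smoother = q = None
    h_star = None
    if needs_markers:
        mfreq = sim_subpop._freq_matrix(sp.L, sp, rng)
        markers = GenotypeMatrix(
            sim_subpop.genotype_matrix(mfreq, labels, rng)
        ).drop_monomorphic()
    if needs_pcs:
        pcs = ancestry_pcs(markers, cfg.k_pcs)
        from .association import linear_residual_basis

        q = linear_residual_basis(pcs)
    if "PC-nonp" in cfg.tests:
        y_cal = _null_traits(cfg, _Background(sp.n, None, None, None, None, None,
                                              labels), rng, None)
        sel = select_bandwidth(y_cal, markers, pcs, bandwidth_grid(k=cfg.k_pcs))
        h_star = sel.h_star
        smoother = KernelSmoother(pcs.coords, h_star)
        logger.info("batch h* = %.4f (s = %d)", h_star, sel.s_star)
    return _Background(sp.n, markers, pcs, smoother, h_star, q, labels)


def _spatial_background(cfg: ExperimentConfig, rng) -> _Background:
    gc = cfg.grid
    needs_pcs, needs_markers = _needs(cfg)
    phi = sim_spatial.place_samples(gc, rng)
    markers = pcs = smoother = q = pool = None
    h_star = None
    if needs_markers:
        vals = sim_spatial.simulate_variants(phi, gc, rng, cfg.L, MARKER_WINDOW)
        markers = GenotypeMatrix(vals).drop_monomorphic()
    if needs_pcs:
        pcs = ancestry_pcs(markers, cfg.k_pcs)
        from .association import linear_residual_basis

        q = linear_residual_basis(pcs)
    if "PC-nonp" in cfg.tests:
        y_cal = _null_traits(cfg, _Background(gc.n, None, None, None, None, None,
                                              phi, phi=phi), rng, None)
        sel = select_bandwidth(y_cal, markers, pcs, bandwidth_grid(k=cfg.k_pcs))
        h_star = sel.h_star
        smoother = KernelSmoother(pcs.coords, h_star)
        logger.info("batch h* = %.4f (s = %d)", h_star, sel.s_star)
    if cfg.mode == "regional" and cfg.region_mode == "independent":
        pool = TreePool(phi, gc, rng, cfg.pool_size)
    return _Background(gc.n, markers, pcs, smoother, h_star, q, phi, pool=pool,
                       phi=phi)


def _subpop_candidates(cfg, bg, rng, size) -> tuple[np.ndarray, np.ndarray]:
    """(n, size) candidate scores plus generating pooled MAFs.

    Single-variant mode draws one spectrum/Balding-Nichols variant per
    replicate; regional mode draws an n_T-variant region and combines
    it with Madsen-Browning weights.  Monomorphic candidates are
    resampled (counted in the log).
    """
    from .association import regional_score

    sp = cfg.subpop
    per = 1 if cfg.mode == "single_variant" else cfg.n_T
    resampled = 0
    X = np.empty((sp.n, size))
    mafs = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        freqs = sim_subpop._freq_matrix(todo.size * per, sp, rng)
        g = sim_subpop.genotype_matrix(freqs, bg.labels, rng)
        if per == 1:
            cols = g.astype(float)
        else:
            cols = np.empty((sp.n, todo.size))
            for i in range(todo.size):
                cols[:, i] = regional_score(g[:, i * per:(i + 1) * per])
        pooled = freqs.mean(axis=1).reshape(todo.size, per)
        X[:, todo] = cols
        mafs[todo] = np.minimum(pooled, 1 - pooled).mean(axis=1)
        bad = cols.std(axis=0) <= 0
        resampled += int(bad.sum())
        todo = todo[bad]
    if resampled:
        logger.info("resampled %d degenerate candidates", resampled)
    return X, mafs


def _spatial_candidates(cfg, bg, rng, size) -> np.ndarray:
    """(n, size) candidate scores for the spatial scenario.

    Single-variant candidates come from independent genealogies.  A
    region's variants are drawn from the cached tree pool by default
    (mutually independent, no LD).  ``region_mode="shared_tree"``
    instead draws all of a region's variants from one fresh genealogy
    per replicate — variants of a real genomic region are in LD
    through their common tree, which concentrates the rare-variant
    burden spatially and makes every adjustment's task harder.
    """
    from .association import regional_score
    from .sim_spatial import genealogy_stream, window_mutation

    if cfg.mode == "single_variant":
        vals = sim_spatial.simulate_variants(bg.phi, cfg.grid, rng, size, RARE_WINDOW)
        return vals.astype(float)
    X = np.empty((cfg.grid.n, size))
    if cfg.region_mode == "independent":
        for i in range(size):
            region = bg.pool.draw_variants(rng, cfg.n_T, RARE_WINDOW)
            X[:, i] = regional_score(region)
        return X
    filled = 0
    stream = genealogy_stream(bg.phi, cfg.grid, rng, total=4 * size + 32)
    for tree in stream:
        cols = [window_mutation(tree, rng, RARE_WINDOW) for _ in range(cfg.n_T)]
        if cols[0] is None:
            continue  # no rare-window branch on this tree
        X[:, filled] = regional_score(np.column_stack(cols))
        filled += 1
        if filled == size:
            return X
    raise RuntimeError("genealogy stream exhausted while building regions")


def _run_tests(cfg, bg, Y, X) -> dict[str, np.ndarray]:
    """Per-replicate p-values for each requested test."""
    n = Y.shape[0]
    out = {}
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    if "Uncorrected" in cfg.tests or "GC" in cfg.tests:
        t_unc, p_unc = score_test_paired(Yc, Xc)
        if "Uncorrected" in cfg.tests:
            out["Uncorrected"] = p_unc
    if "GC" in cfg.tests:
        from scipy import stats

        G = np.asarray(bg.markers.values, float)
        Gc = G - G.mean(axis=0)
        sxx_g = (Gc * Gc).sum(axis=0)
        syy = (Yc * Yc).sum(axis=0)
        U = Gc.T @ Yc  # (L, R)
        with np.errstate(divide="ignore", invalid="ignore"):
            T_marker = np.where(syy > 0, U * U * n / (sxx_g[:, None] * syy[None, :]), 0.0)
        lam = np.maximum(1.0, np.median(T_marker, axis=0) / GC_CHI2_MEDIAN)
        out["GC"] = stats.chi2.sf(t_unc / lam, df=1)
    if "PC-linear" in cfg.tests:
        q = bg.linear_q
        Yl = Y - q @ (q.T @ Y)
        Xl = X - q @ (q.T @ X)
        _, out["PC-linear"] = score_test_paired(Yl, Xl)
    if "PC-nonp" in cfg.tests:
        Yn = bg.smoother.residualize(Y)
        Xn = bg.smoother.residualize(X)
        _, out["PC-nonp"] = kernel_score_paired(
            bg.smoother, Yn, Xn,
            local_variance=(cfg.trait_type == "qualitative"))
    return out


def _batch_sizes(total: int, batches: int) -> list[int]:
    base = total // batches
    sizes = [base] * batches
    for i in range(total - base * batches):
        sizes[i] += 1
    return [s for s in sizes if s > 0]


def run_type1(cfg: ExperimentConfig) -> pd.DataFrame:
    """Empirical type I error per (test, alpha) with 2-SD bands."""
    master = np.random.SeedSequence(cfg.seed)
    counts = {(t, a): 0 for t in cfg.tests for a in cfg.alphas}
    total = 0
    for b, (size, ss) in enumerate(
        zip(_batch_sizes(cfg.replicates, cfg.batches), master.spawn(cfg.batches))
    ):
        rng = np.random.default_rng(ss)
        t0 = time.time()
        bg = (_subpop_background if cfg.scenario == "subpop" else _spatial_background)(
            cfg, rng
        )
        Y = _null_traits(cfg, bg, rng, size)
        if cfg.scenario == "subpop":
            X, _ = _subpop_candidates(cfg, bg, rng, size)
        else:
            X = _spatial_candidates(cfg, bg, rng, size)
        pvals = _run_tests(cfg, bg, Y, X)
        for t in cfg.tests:
            for a in cfg.alphas:
                counts[(t, a)] += int((pvals[t] < a).sum())
        total += size
        logger.info("batch %d/%d (%d replicates) in %.1fs", b + 1, cfg.batches,
                    size, time.time() - t0)
    rows = []
    for t in cfg.tests:
        for a in cfg.alphas:
            lo, hi = binomial_band(a, total)
            rate = counts[(t, a)] / total
            rows.append(
                dict(test=t, alpha=a, count=counts[(t, a)], replicates=total,
                     rate=rate, band_lo=lo, band_hi=hi,
                     in_band=bool(lo <= rate <= hi))
            )
    return pd.DataFrame(rows)


def run_power(cfg: ExperimentConfig, h2_grid) -> pd.DataFrame:
    """Power per (test, alpha, h2) using regional tests.

    Each replicate draws a fresh region; traits at every h2 point reuse
    the replicate's region with fresh causal effects added to the same
    null trait.
    """
    if cfg.mode != "regional":
        cfg = replace(cfg, mode="regional")
    master = np.random.SeedSequence(cfg.seed)
    h2_grid = list(h2_grid)
    counts = {(t, a, h2): 0 for t in cfg.tests for a in cfg.alphas for h2 in h2_grid}
    total = 0
    from .association import regional_score

    for size, ss in zip(_batch_sizes(cfg.replicates, cfg.batches),
                        master.spawn(cfg.batches)):
        rng = np.random.default_rng(ss)
        bg = (_subpop_background if cfg.scenario == "subpop" else _spatial_background)(
            cfg, rng
        )
        # quantitative null traits; dichotomized later if qualitative
        if cfg.scenario == "subpop":
            Y0 = sim_subpop.null_trait_quant(bg.labels, cfg.subpop, rng, size=size)
        else:
            surface = risk_surface(cfg.risk_model, cfg.grid.K0)
            Y0 = sim_spatial.null_trait_spatial(bg.phi, surface, cfg.grid, rng,
                                                size=size)
        n_c = cfg.n_T // 2
        regions, scores, causal, cmafs = [], np.empty((bg.n, size)), [], []
        if cfg.scenario == "spatial" and cfg.region_mode == "shared_tree":
            from .sim_spatial import genealogy_stream, window_mutation

            stream = genealogy_stream(bg.phi, cfg.grid, rng, total=4 * size + 32)
        for i in range(size):
            if cfg.scenario == "subpop":
                freqs = sim_subpop._freq_matrix(cfg.n_T, cfg.subpop, rng)
                g = sim_subpop.genotype_matrix(freqs, bg.labels, rng)
                pooled = freqs.mean(axis=1)
                maf = np.minimum(pooled, 1 - pooled)
            elif cfg.region_mode == "shared_tree":
                cols = None
                for tree in stream:
                    cols = [window_mutation(tree, rng, RARE_WINDOW)
                            for _ in range(cfg.n_T)]
                    if cols[0] is not None:
                        break
                g = np.column_stack(cols)
                maf = GenotypeMatrix(g).maf
            else:
                g = bg.pool.draw_variants(rng, cfg.n_T, RARE_WINDOW)
                maf = GenotypeMatrix(g).maf
            ids = rng.choice(cfg.n_T, size=n_c, replace=False)
            regions.append(g)
            scores[:, i] = regional_score(g)
            causal.append(ids)
            cmafs.append(maf[ids])
        for h2 in h2_grid:
            Y = np.empty((bg.n, size))
            for i in range(size):
                Y[:, i] = sim_subpop.power_trait(regions[i], causal[i], h2,
                                                 cmafs[i], Y0[:, i])
            if cfg.trait_type == "qualitative":
                Y = sim_subpop.dichotomize(Y).astype(float)
            pvals = _run_tests(cfg, bg, Y, scores)
            for t in cfg.tests:
                for a in cfg.alphas:
                    counts[(t, a, h2)] += int((pvals[t] < a).sum())
        total += size
    rows = [
        dict(test=t, alpha=a, h2=h2, count=counts[(t, a, h2)], replicates=total,
             power=counts[(t, a, h2)] / total)
        for t in cfg.tests for a in cfg.alphas for h2 in h2_grid
    ]
    return pd.DataFrame(rows)


def qq_data(pvals) -> pd.DataFrame:
    """Observed vs expected -log10 p for a QQ plot (uniform reference)."""
    p = np.sort(np.asarray(pvals, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p == 0).any():
        logger.warning("clamping %d zero p-values to machine minimum",
                       int((p == 0).sum()))
        p = np.maximum(p, np.finfo(float).tiny)
    L = p.size
    expected = -np.log10((np.arange(1, L + 1) - 0.5) / L)
    return pd.DataFrame({"expected": expected, "observed": -np.log10(p)})
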