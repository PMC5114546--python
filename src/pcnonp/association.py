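"""Score tests on adjusted values and the comparison tests.

The core statistic is ``T = U^2 / V`` with ``U = sum_i y~_i x~_i`` and
``V = (sum_i y~_i^2)(sum_i x~_i^2) / n``, which equals ``n r^2`` on
centered inputs and follows chi-square(1) asymptotically under the
null.  Four variants are provided:

* ``pc_nonp_test``   -- residuals of the kernel regression on PCs (PC-nonp)
* ``uncorrected_test`` -- mean-centered raw values
* ``gc_correct``     -- genomic-control deflation by lambda estimated
  from genome-wide marker statistics (median / 0.456, floored at 1)
* ``pc_linear_test`` -- residuals of linear regression on PCs

Regional tests combine the variants of a region into one genotype score
with Madsen-Browning inverse-variance weights before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotypes import GenotypeMatrix
from .kernel import KernelSmoother
from .pca import PCMatrix

logger = logging.getLogger(__name__)

#: median of the chi-square(1) distribution as used by genomic control
GC_CHI2_MEDIAN = 0.456

_DEGENERATE = 1e-12


@dataclass
class TestResult:
    method: str
    statistic: float
    pvalue: float
    mode: str = "single_variant"
    untestable: bool = False


def _chi2_p(t: np.ndarray) -> np.ndarray:
    return stats.chi2.sf(t, df=1)


def score_test(y_adj, x_adj, method: str = "PC-nonp", mode: str = "single_variant",
               var_inflation: float = 1.0) -> TestResult:
    """Score test on already-adjusted (residualized or centered) vectors.

    ``var_inflation`` is the finite-sample variance factor of the
    adjustment (1 for plain centered inputs; the smoother's
    ``var_inflation`` for kernel residuals), dividing the statistic.
    """
    y = np.asarray(y_adj, dtype=float)
    x = np.asarray(x_adj, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y_adj and x_adj must have the same length")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    sxx = float(x @ x)
    syy = float(y @ y)
    if sxx <= _DEGENERATE or syy <= _DEGENERATE:
        return TestResult(method, 0.0, 1.0, mode, untestable=sxx <= _DEGENERATE)
    u = float(y @ x)
    v = syy * sxx / n
    t = u * u / (v * var_inflation)
    return TestResult(method, t, float(_chi2_p(t)), mode)


def score_test_many(y_adj: np.ndarray, X_adj: np.ndarray,
                    var_inflation: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized score test of one adjusted trait against many columns.

    Returns ``(T, p)`` arrays of length ``X_adj.shape[1]``.  Degenerate
    columns (or a degenerate trait) get ``T = 0, p = 1``.
    """
    y = np.asarray(y_adj, dtype=float)
    X = np.asarray(X_adj, dtype=float)
    n = y.size
    syy = float(y @ y)
    sxx = (X * X).sum(axis=0)
    u = X.T @ y
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            (sxx > _DEGENERATE) & (syy > _DEGENERATE),
            u * u * n / (syy * sxx * var_inflation),
            0.0,
        )
    p = _chi2_p(t)
    p[t == 0.0] = 1.0
    return t, p


def score_test_paired(Y_adj: np.ndarray, X_adj: np.ndarray,
                      var_inflation: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized score test of paired columns: replicate r tests
    ``Y_adj[:, r]`` against ``X_adj[:, r]``."""
    Y = np.asarray(Y_adj, dtype=float)
    X = np.asarray(X_adj, dtype=float)
    n = Y.shape[0]
    syy = (Y * Y).sum(axis=0)
    sxx = (X * X).sum(axis=0)
    u = (Y * X).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where((sxx > _DEGENERATE) & (syy > _DEGENERATE),
                     u * u * n / (syy * sxx * var_inflation), 0.0)
    p = _chi2_p(t)
    p[t == 0.0] = 1.0
    return t, p


def is_binary_trait(y) -> bool:
    """True if the trait is 0/1 affection status."""
    vals = np.unique(np.asarray(y, dtype=float))
    return vals.size <= 2 and np.isin(vals, (0.0, 1.0)).all()


def kernel_score_paired(smoother: KernelSmoother, Y_res: np.ndarray,
                        X_res: np.ndarray,
                        local_variance: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Score test of kernel residuals with the conditional variance.

    ``Var(U | x) = sum_i v_i (A^T x~)_i^2`` (see
    :meth:`KernelSmoother.score_denominator`); exact for arbitrarily
    structured genotype scores.  ``local_variance`` selects the
    kernel-estimated variance function used for 0/1 traits.  Accepts a
    single residual vector pair or matched column matrices; degenerate
    pairs get ``T = 0, p = 1``.
    """
    U = (np.asarray(Y_res, float) * np.asarray(X_res, float)).sum(axis=0)
    denom = smoother.score_denominator(Y_res, X_res, local_variance=local_variance)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > _DEGENERATE, U * U / denom, 0.0)
    p = _chi2_p(t)
    p = np.where(t == 0.0, 1.0, p)
    return t, p


def uncorrected_test(y, x, mode: str = "single_variant") -> TestResult:
    """Score test on mean-centered raw trait and genotype score."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    return score_test(y - y.mean(), x - x.mean(), method="Uncorrected", mode=mode)


def gc_lambda(marker_stats) -> float:
    """Genomic-control inflation factor from marker chi-squares."""
    stats_ = np.asarray(marker_stats, dtype=float)
    if stats_.size == 0:
        raise ValueError("marker_stats must be nonempty")
    return max(1.0, float(np.median(stats_)) / GC_CHI2_MEDIAN)


def gc_correct(candidate: TestResult, marker_stats) -> TestResult:
    """Divide a candidate statistic by the inflation factor lambda.

    lambda is floored at 1, so GC never increases a statistic.
    """
    lam = gc_lambda(marker_stats)
    t = candidate.statistic / lam
    return TestResult("GC", t, float(_chi2_p(t)), candidate.mode, candidate.untestable)


def linear_residual_basis(pcs: PCMatrix | np.ndarray) -> np.ndarray:
    """Orthonormal basis Q of [1, PCs]; residualizing v is v - Q (Q^T v).

    Collinear PC columns are dropped (logged) before the QR step.
    """
    coords = pcs.coords if isinstance(pcs, PCMatrix) else np.asarray(pcs, float)
    n = coords.shape[0]
    A = np.column_stack([np.ones(n), coords])
    q, r = np.linalg.qr(A)
    keep = np.abs(np.diag(r)) > n * np.finfo(float).eps * np.abs(r[0, 0])
    if not keep.all():
        logger.info("dropping %d collinear PC column(s) in linear adjustment", int((~keep).sum()))
        q = np.linalg.qr(A[:, keep])[0]
    return q


def pc_linear_test(y, x, pcs, mode: str = "single_variant") -> TestResult:
    """Score test on least-squares residuals of y and x on intercept + PCs."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    q = linear_residual_basis(pcs)
    if y.size <= q.shape[1]:
        raise ValueError("need n > k + 1 for the linear adjustment")
    y_res = y - q @ (q.T @ y)
    x_res = x - q @ (q.T @ x)
    return score_test(y_res, x_res, method="PC-linear", mode=mode)


def madsen_browning_weights(region: np.ndarray) -> np.ndarray:
    """Inverse-variance rare-variant weights ``1/sqrt(n q(1-q))``.

    ``q`` uses a +1/+2 pseudo-count so monomorphic variants keep a
    finite weight.
    """
    g = np.asarray(region, dtype=float)
    n = g.shape[0]
    q = (g.sum(axis=0) + 1.0) / (2.0 * n + 2.0)
    return 1.0 / np.sqrt(n * q * (1.0 - q))


def regional_score(region: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Weighted combination of a region's genotypes into one score."""
    g = region.values if isinstance(region, GenotypeMatrix) else np.asarray(region, float)
    if g.ndim != 2 or g.shape[1] < 1:
        raise ValueError("region must hold at least one variant")
    return g @ madsen_browning_weights(g)


def pc_nonp_test(y, x, pcs, h_star: float, smoother: KernelSmoother | None = None,
                 mode: str = "single_variant") -> TestResult:
    """PC-nonp: score test on kernel-regression residuals at h*.

    ``x`` is a single variant's genotypes (single-variant mode) or a
    combined regional score.  A cached :class:`KernelSmoother` may be
    passed to amortize the weight matrix across candidates.
    """
    coords = pcs.coords if isinstance(pcs, PCMatrix) else np.asarray(pcs, float)
    sm = smoother if smoother is not None else KernelSmoother(coords, h_star)
    x_res = sm.residualize(x)
    if float(x_res @ x_res) <= _DEGENERATE:
        return TestResult("PC-nonp", 0.0, 1.0, mode, untestable=True)
    t, p = kernel_score_paired(sm, sm.residualize(y), x_res,
                               local_variance=is_binary_trait(y))
    return TestResult("PC-nonp", float(t), float(p), mode)
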