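"""Quartic-product-kernel Nadaraya-Watson smoothing on ancestry PCs.

The regression functions mu(p) of trait and of genotype score on the
rescaled PC coordinates are estimated by a kernel-weighted local mean
with the quartic (biweight) kernel K(u) = (15/16)(1-u^2)^2 on [-1, 1],
a single common bandwidth h across all PC dimensions, and a product
kernel over dimensions.  Residuals from the two fits are the
stratification-adjusted trait and genotype score.

The 1/h normalizing constant of the kernel density is omitted: it
cancels in the Nadaraya-Watson ratio.  The sum includes j = i, so the
denominator is always positive ((15/16)^k self-weight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class KernelConfig:
    """Common smoothing parameter ``h`` (> 0, on the [0,1] PC scale)."""

    h: float
    k: int = 10

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("bandwidth h must be > 0")


@dataclass
class ResidualPair:
    """Adjusted trait and genotype-score vectors under one bandwidth."""

    y_res: np.ndarray
    x_res: np.ndarray
    h_used: float


def quartic_kernel(u):
    """Quartic (biweight) kernel: (15/16)(1-u^2)^2 on |u| <= 1, else 0."""
    u = np.asarray(u, dtype=float)
    out = np.where(np.abs(u) <= 1.0, (15.0 / 16.0) * (1.0 - u**2) ** 2, 0.0)
    return out if out.ndim else float(out)


def pairwise_weights(coords: np.ndarray, h: float) -> np.ndarray:
    """``n x n`` product-kernel weight matrix over PC coordinates.

    ``W[i, j] = prod_d K((p_id - p_jd) / h)``; symmetric, nonnegative,
    with diagonal ``(15/16)^k``.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be > 0")
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n, k = coords.shape
    w = np.ones((n, n))
    for d in range(k):
        col = coords[:, d]
        w *= quartic_kernel((col[:, None] - col[None, :]) / h)
    return w


class KernelSmoother:
    """Caches the weight matrix for one ``(pcs, h)`` pair.

    Fitting ``m`` vectors under one bandwidth then costs a single
    ``n x n`` build plus ``m`` matrix-vector products, which is how the
    bandwidth search and the replicate loops share work.
    """

    def __init__(self, coords: np.ndarray, h: float):
        self.h = float(h)
        self.coords = np.asarray(coords, dtype=float)
        self.weights = pairwise_weights(self.coords, self.h)
        self._rowsum = self.weights.sum(axis=1)
        self._var_inflation = None
        self._smat = None

    @property
    def residual_df(self) -> float:
        """Residual degrees of freedom tr(M), M = (I - S)^T (I - S).

        For residuals r = (I - S)v of white noise v, E[sum r^2] =
        sigma^2 tr(M); dividing by ``residual_df`` instead of n
        unbiases the residual variance estimate.
        """
        self.var_inflation  # populates the trace cache
        return self._tr_m

    def score_denominator(self, y_res: np.ndarray, x_res: np.ndarray,
                          local_variance: bool = False) -> np.ndarray:
        """Conditional variance of U = sum y~ x~ given the genotypes.

        With y = mu(p) + eps, eps independent noise, and residuals
        through A = I - S:  Var(U | x) = sum_i v_i (A^T x~)_i^2 for
        noise variances v_i.  With ``local_variance=False`` the noise
        is taken homoskedastic and v is the pooled estimate
        sum y~^2 / tr(M) (Gaussian traits).  With
        ``local_variance=True`` the variance function is estimated by
        kernel-smoothing the squared residuals, v = S(y~^2) — for a
        0/1 trait the outcome variance genuinely varies with the
        ancestry-dependent prevalence, and pooling it inflates the
        statistic where prevalence and genotype variance co-vary.
        Conditioning on x makes the variance exact for arbitrarily
        structured genotype scores (drifted variants, spatially
        clustered burdens), where a white-noise approximation over- or
        under-corrects.  Accepts column matrices; returns one
        denominator per column pair.
        """
        y_res = np.asarray(y_res, dtype=float)
        x_res = np.asarray(x_res, dtype=float)
        if self._smat is None:
            self._smat = self.weights / self._rowsum[:, None]
        z = x_res - self._smat.T @ x_res  # A^T x~
        if local_variance:
            v = self._smat @ (y_res * y_res)
            return (v * z * z).sum(axis=0)
        sig2 = (y_res * y_res).sum(axis=0) / self.residual_df
        return sig2 * (z * z).sum(axis=0)

    @property
    def var_inflation(self) -> float:
        """Finite-sample variance factor of the residual cross-product.

        For residuals r = (I - S)v of a linear smoother S applied to
        white noise, Var(sum r_y r_x) = sigma^2 tau^2 tr(M^2) with
        M = (I - S)^T (I - S), while the plug-in variance
        (sum r_y^2)(sum r_x^2)/n estimates sigma^2 tau^2 tr(M)^2 / n.
        The ratio c = n tr(M^2) / tr(M)^2 >= 1 corrects the score
        statistic for the degrees of freedom the smoother consumes; it
        tends to n/(n-1) as h grows (pure centering) and grows as h
        shrinks.  Cached per (coords, h).
        """
        if self._var_inflation is None:
            s = self.weights / self._rowsum[:, None]
            n = s.shape[0]
            b = s + s.T - s.T @ s  # M = I - B
            tr_m = n - np.trace(b)
            tr_m2 = n - 2.0 * np.trace(b) + float((b * b).sum())
            self._tr_m = float(tr_m)
            self._var_inflation = float(n * tr_m2 / tr_m**2)
        return self._var_inflation

    def fit(self, values: np.ndarray) -> np.ndarray:
        """Nadaraya-Watson fitted values; accepts (n,) or (n, m)."""
        values = np.asarray(values, dtype=float)
        if values.shape[0] != self.weights.shape[0]:
            raise ValueError("values length does not match the PC matrix")
        num = self.weights @ values
        if values.ndim == 1:
            return num / self._rowsum
        return num / self._rowsum[:, None]

    def residualize(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) - self.fit(values)


def nw_fit(values, coords, h) -> np.ndarray:
    """Nadaraya-Watson fit of ``values`` on PC coordinates at bandwidth h."""
    return KernelSmoother(coords, h).fit(values)


def residualize(values, coords, h) -> np.ndarray:
    """Values minus their Nadaraya-Watson fit (adjusted values)."""
    return KernelSmoother(coords, h).residualize(values)


def residual_pair(y, x, coords, h) -> ResidualPair:
    """Adjust trait and genotype score under the same bandwidth."""
    sm = KernelSmoother(coords, h)
    return ResidualPair(sm.residualize(y), sm.residualize(x), h)
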