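"""Ancestry principal components from background genomic markers.

The top-``k`` left singular vectors of the column-standardized genotype
matrix serve as continuous ancestry coordinates.  Each marker column is
centered by its mean and scaled by ``sqrt(q(1-q))`` with ``q`` the sample
allele frequency (the normalization customary for genotype PCA), and the
resulting sample coordinates are rescaled columnwise to [0, 1] before
being used as kernel-regression covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

#: number of PCs used throughout unless overridden
DEFAULT_K = 10


@dataclass
class PCMatrix:
    """Sample ancestry coordinates.

    ``coords`` is ``(n, k)``; after :func:`rescale_unit_interval` every
    column spans exactly [0, 1].  ``explained`` holds each component's
    share of the total standardized variance.
    """

    coords: np.ndarray
    explained: np.ndarray
    rescaled: bool = False

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def to_tsv(self, path, sample_ids=None) -> None:
        import pandas as pd

        ids = sample_ids or [f"S{i}" for i in range(self.n)]
        df = pd.DataFrame(
            self.coords, index=ids, columns=[f"PC{j+1}" for j in range(self.k)]
        )
        df.to_csv(path, sep="\t", index_label="sample_id")


def _standardize(values: np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        col_mean = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x = x.copy()
        x[idx] = col_mean[idx[1]]
    mean = x.mean(axis=0)
    q = mean / 2.0
    scale = np.sqrt(q * (1.0 - q))
    if (scale == 0).any():
        raise ValueError("monomorphic columns present; drop them before PCA")
    return (x - mean) / scale


def compute_pcs(markers: GenotypeMatrix, k: int = DEFAULT_K) -> PCMatrix:
    """First ``k`` sample principal components (unrescaled).

    Returns the left singular vectors of the standardized marker matrix,
    ordered by decreasing singular value.  Monomorphic markers are
    dropped first (logged).  Sign is fixed so each component's entry of
    largest magnitude is positive, making output deterministic across
    SVD backends.
    """
    markers = markers.drop_monomorphic()
    n, m = markers.values.shape
    if n < 2:
        raise ValueError("need at least 2 samples for PCA")
    if m == 0:
        raise ValueError("all marker columns are monomorphic; nothing to decompose")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(n, m)={min(n, m)}")
    z = _standardize(markers.values)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    rank = int((s > s[0] * max(n, m) * np.finfo(float).eps).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds the matrix rank {rank}")
    coords = u[:, :k] * s[:k]
    # deterministic sign: largest-|entry| positive
    flip = np.sign(coords[np.abs(coords).argmax(axis=0), np.arange(k)])
    coords = coords * flip
    explained = s[:k] ** 2 / (s**2).sum()
    return PCMatrix(coords, explained, rescaled=False)


def rescale_unit_interval(pcs: PCMatrix) -> PCMatrix:
    """Map each coordinate column affinely onto [0, 1].

    Idempotent; preserves within-column order statistics.  A constant
    column cannot be rescaled and raises ``ValueError``.
    """
    c = np.asarray(pcs.coords, dtype=float)
    lo, hi = c.min(axis=0), c.max(axis=0)
    if (hi == lo).any():
        raise ValueError("constant PC column cannot be rescaled to [0, 1]")
    return PCMatrix((c - lo) / (hi - lo), pcs.explained, rescaled=True)


def ancestry_pcs(markers: GenotypeMatrix, k: int = DEFAULT_K) -> PCMatrix:
    """Convenience: compute then rescale to the unit interval."""
    return rescale_unit_interval(compute_pcs(markers, k))
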