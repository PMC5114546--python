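"""Discrete-subpopulation cohort simulator (Balding-Nichols model).

Ancestral minor-allele frequencies are drawn from a synthetic
exome-like spectrum (60% rare in (0.0005, 0.01), 40% common in
(0.01, 0.5)); each subpopulation's frequency is a Beta draw with
parameters ``p(1-Fst)/Fst`` and ``(1-p)(1-Fst)/Fst``; genotypes are
Binomial(2, freq) within subpopulations.  Traits under the null are
subpopulation mean shifts plus standard normal noise; under the
alternative, equal-per-variant-heritability effects of randomly chosen
causal variants are added, so rarer causal variants get larger effects.
Qualitative traits dichotomize the quantitative ones at mean + 1 SD
(16% prevalence for a normal trait).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix


@dataclass
class SubpopConfig:
    """Simulation parameters for the subpopulation model.

    ``mu`` defaults to 5 when ``k0 = 20`` and 2 otherwise (the scale of
    between-subpopulation trait-mean differences).  ``n_c`` causal
    variants default to half the region (``n_T / 2``).
    """

    k0: int = 1
    fst: float = 0.01
    n_per_subpop: int = 1000
    L: int = 10_000
    n_T: int = 20
    n_c: int | None = None
    mu: float | None = None
    h2: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if self.n_c is None:
            self.n_c = self.n_T // 2
        if self.n_c > self.n_T:
            raise ValueError("n_c cannot exceed n_T")
        if self.mu is None:
            self.mu = 5.0 if self.k0 == 20 else 2.0

    @property
    def n(self) -> int:
        return self.k0 * self.n_per_subpop


@dataclass
class SimCohort:
    """Output of either simulator: genotypes, trait, origins, truth."""

    markers: GenotypeMatrix
    region: GenotypeMatrix | None
    trait: np.ndarray
    labels: np.ndarray
    causal_ids: np.ndarray | None = None
    truth: dict = field(default_factory=dict)


def sample_ancestral_maf(rng: np.random.Generator, spectrum=None, size=None):
    """Draw ancestral MAF(s) from the spectrum.

    ``spectrum`` may be an array of frequencies to resample from (e.g.
    loaded from a user file); by default the built-in synthetic
    rare-enriched mixture stand-in is used.
    """
    if spectrum is not None:
        spectrum = np.asarray(spectrum, dtype=float)
        if spectrum.size == 0:
            raise ValueError("empty MAF spectrum")
        out = rng.choice(spectrum, size=size if size is not None else 1)
        return out if size is not None else float(out[0])
    m = size if size is not None else 1
    rare = rng.random(m) < 0.6
    p = np.where(
        rare,
        rng.uniform(0.0005, 0.01, size=m),
        rng.uniform(0.01, 0.5, size=m),
    )
    return p if size is not None else float(p[0])


def balding_nichols_freqs(p, fst: float, k0: int, rng: np.random.Generator,
                          min_freq: float = 0.0) -> np.ndarray:
    """Subpopulation allele frequencies for one variant.

    ``min_freq`` implements the polymorphism acceptance rule: redraw
    until at least one subpopulation frequency reaches it (0 disables).
    """
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    while True:
        freqs = rng.beta(a, b, size=k0)
        if min_freq <= 0.0 or (freqs >= min_freq).any():
            return freqs


def _freq_matrix(L: int, cfg: SubpopConfig, rng: np.random.Generator,
                 spectrum=None) -> np.ndarray:
    """Accepted Balding-Nichols frequencies for L variants, (L, k0)."""
    p = np.asarray(sample_ancestral_maf(rng, spectrum, size=L), dtype=float)
    a = p * (1.0 - cfg.fst) / cfg.fst
    b = (1.0 - p) * (1.0 - cfg.fst) / cfg.fst
    freqs = rng.beta(a[:, None], b[:, None], size=(L, cfg.k0))
    min_freq = 1.0 / (4.0 * cfg.n_per_subpop)
    bad = ~(freqs >= min_freq).any(axis=1)
    while bad.any():
        freqs[bad] = rng.beta(a[bad, None], b[bad, None], size=(int(bad.sum()), cfg.k0))
        bad = ~(freqs >= min_freq).any(axis=1)
    return freqs


def genotypes_from_freqs(freqs: np.ndarray, n_per_subpop: int,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Hardy-Weinberg genotypes for one variant across subpopulations.

    Returns the genotype column and the subpopulation label per sample.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    labels = np.repeat(np.arange(freqs.size), n_per_subpop)
    g = rng.binomial(2, freqs[labels])
    return g, labels


def genotype_matrix(freqs: np.ndarray, labels: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """(n, L) genotypes from an (L, k0) frequency matrix and labels."""
    probs = freqs[:, labels].T  # (n, L)
    return rng.binomial(2, probs)


def subpop_means(cfg: SubpopConfig) -> np.ndarray:
    """Per-subpopulation trait means.

    ``k0 <= 2``: (0, mu).  Otherwise means are evenly spaced on
    [0, mu].
    """
    if cfg.k0 == 1:
        return np.zeros(1)
    if cfg.k0 == 2:
        return np.array([0.0, cfg.mu])
    return cfg.mu * np.arange(cfg.k0) / (cfg.k0 - 1)


def null_trait_quant(labels: np.ndarray, cfg: SubpopConfig,
                     rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Null quantitative trait: subpopulation mean + N(0, 1) noise.

    ``size`` draws that many independent replicates as columns.
    """
    mu = subpop_means(cfg)[labels]
    if size is None:
        return mu + rng.standard_normal(labels.size)
    return mu[:, None] + rng.standard_normal((labels.size, size))


def causal_betas(h2: float, mafs: np.ndarray) -> np.ndarray:
    """Equal-heritability effect sizes: beta = sqrt((h2/nc) / (2 q (1-q)))."""
    if h2 >= 1.0:
        raise ValueError("h2 must be < 1")
    n_c = mafs.size
    q = np.asarray(mafs, dtype=float)
    return np.sqrt((h2 / n_c) / (2.0 * q * (1.0 - q)))


def power_trait(region: np.ndarray, causal_ids: np.ndarray, h2: float,
                causal_mafs: np.ndarray, null_trait: np.ndarray) -> np.ndarray:
    """Alternative trait: sum of causal effects plus the null trait.

    ``causal_mafs`` are the generating (pooled) minor-allele
    frequencies of the causal variants, which set the effect sizes.
    """
    if h2 == 0.0:
        return np.asarray(null_trait, dtype=float)
    betas = causal_betas(h2, causal_mafs)
    g = np.asarray(region, dtype=float)[:, causal_ids]
    return g @ betas + np.asarray(null_trait, dtype=float)


def dichotomize(y: np.ndarray) -> np.ndarray:
    """Liability threshold: affected iff y >= mean(y) + sd(y).

    For columns of a 2-D array the threshold is per column.  A normal
    trait yields ~16% prevalence.
    """
    y = np.asarray(y, dtype=float)
    sd = y.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("trait has zero variance; cannot dichotomize")
    return (y >= y.mean(axis=0) + sd).astype(np.int8)


def simulate_cohort(cfg: SubpopConfig, rng: np.random.Generator | None = None,
                    spectrum=None, qualitative: bool = False) -> SimCohort:
    """Full cohort: markers, candidate region, trait, labels, truth."""
    rng = rng or np.random.default_rng(cfg.seed)
    labels = np.repeat(np.arange(cfg.k0), cfg.n_per_subpop)

    mfreq = _freq_matrix(cfg.L, cfg, rng, spectrum)
    markers = GenotypeMatrix(genotype_matrix(mfreq, labels, rng),
                             variant_ids=[f"M{j}" for j in range(cfg.L)])

    rfreq = _freq_matrix(cfg.n_T, cfg, rng, spectrum)
    region_vals = genotype_matrix(rfreq, labels, rng)
    region = GenotypeMatrix(region_vals, variant_ids=[f"R{j}" for j in range(cfg.n_T)])

    y0 = null_trait_quant(labels, cfg, rng)
    causal_ids = None
    if cfg.h2 > 0:
        causal_ids = rng.choice(cfg.n_T, size=cfg.n_c, replace=False)
        pooled = rfreq.mean(axis=1)
        pooled = np.minimum(pooled, 1 - pooled)
        y = power_trait(region_vals, causal_ids, cfg.h2, pooled[causal_ids], y0)
    else:
        y = y0
    if qualitative:
        y = dichotomize(y)
    return SimCohort(markers, region, y, labels, causal_ids,
                     truth={"cfg": cfg, "marker_freqs": mfreq, "region_freqs": rfreq})
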