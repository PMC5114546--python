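# pcnonp

Kernel-regression correction for population stratification in
rare-variant association studies, with the simulation engines used to
calibrate it.

## The problem

Rare-variant studies pool samples across geographic origins, and
ancestry then confounds genotype–trait associations.  Rare alleles are
young and geographically clustered, so the relationship between trait
values and ancestry principal components (PCs) can be strongly
nonlinear — linear PC adjustment and genomic control, which work for
common variants, can leave the type I error badly inflated.

## The method

**PC-nonp** residualizes *both* the trait `y` and the candidate
genotype score `x` on the top `k = 10` rescaled ancestry PCs
`p_i ∈ [0,1]^k` by Nadaraya–Watson kernel regression with the quartic
(biweight) product kernel,

    ŷ_i = Σ_j w_ij y_j / Σ_j w_ij,   w_ij = Π_d (15/16)(1 − ((p_id − p_jd)/h)²)² · 1{|p_id − p_jd| ≤ h},

and tests association between the residuals with the 1-df score
statistic `T = U²/V̂`, `U = Σ ỹ_i x̃_i`, with the conditional variance
`V̂ = σ̂²‖Aᵀx̃‖²`, `σ̂² = Σỹ²/tr(AᵀA)`, `A = I − S` (S the smoother
matrix), referred to χ²₁ — for pure centering this reduces to the
classical `n·r²` up to the centering degrees-of-freedom factor
`(n−1)/n`.  The bandwidth `h` is chosen on the grid
`h_s = 2^{2(s−23)/(5+k)}`, `s = 1..30`, by minimizing the Kolmogorov
distance between the genome-wide single-variant p-values and the
uniform distribution — if stratification is properly adjusted, null
marker p-values are uniform.  `x` is a single variant's 0/1/2 count or
a Madsen–Browning weighted sum over a region.  The comparison tests
(Uncorrected, genomic control, PC-linear) and two simulators — a
Balding–Nichols discrete-subpopulation model and a structured
coalescent on a migration grid (msprime-backed) — are included.  See
`docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from pcnonp import (SubpopConfig, ancestry_pcs, select_bandwidth,
                    pc_nonp_test, uncorrected_test)
from pcnonp.kernel import KernelSmoother
from pcnonp.sim_subpop import (simulate_cohort, sample_ancestral_maf,
                               balding_nichols_freqs, genotypes_from_freqs)

# 10 subpopulations, Fst = 0.01, trait means differ by subpopulation
cohort = simulate_cohort(SubpopConfig(k0=10, n_per_subpop=100, L=6000, seed=1))
pcs = ancestry_pcs(cohort.markers.drop_monomorphic(), k=10)
sel = select_bandwidth(cohort.trait, cohort.markers, pcs)
print(f"h* = {sel.h_star:.3f} (grid point s = {sel.s_star}, "
      f"Kol = {sel.kol.min():.4f})")

# 500 candidate variants simulated under the null (no association)
rng = np.random.default_rng(2)
sm = KernelSmoother(pcs.coords, sel.h_star)
p_unc, p_nonp = [], []
for _ in range(500):
    freqs = balding_nichols_freqs(sample_ancestral_maf(rng), 0.01, 10, rng)
    x, _ = genotypes_from_freqs(freqs, 100, rng)
    if x.std() == 0:
        continue
    p_unc.append(uncorrected_test(cohort.trait, x.astype(float)).pvalue)
    p_nonp.append(pc_nonp_test(cohort.trait, x.astype(float), pcs,
                               sel.h_star, smoother=sm).pvalue)
print(f"null rejections at 0.05 - Uncorrected: "
      f"{np.mean(np.array(p_unc) < 0.05):.3f}, "
      f"PC-nonp: {np.mean(np.array(p_nonp) < 0.05):.3f}")
```

Output:

```
h* = 0.228 (grid point s = 7, Kol = 0.0055)
null rejections at 0.05 - Uncorrected: 0.096, PC-nonp: 0.047
```

The bandwidth search lands at an interior grid point where the 6,000
marker p-values are nearly uniform (Kol ≈ 0.006).  Subpopulation
trait-mean differences alone roughly double the uncorrected test's
false-positive rate (9.6% at nominal 5%), while the kernel-adjusted
test stays at its nominal level (4.7%).

A command-line interface mirrors the library:

```bash
pcnonp simulate subpop --k0 10 --n-per-subpop 100 --markers 6000 --seed 1 --out cohort/
pcnonp select-h --pheno cohort/phenotype.tsv --markers cohort/markers.tsv --out h.tsv
pcnonp test --pheno cohort/phenotype.tsv --geno cohort/region.tsv \
            --markers cohort/markers.tsv --mode regional --out results.tsv
```

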