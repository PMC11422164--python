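# dyngp

Genetic association mapping for **dynamic** (context-dependent) effects with
sparse Gaussian processes.

Most genetic effects on molecular traits are static, but some manifest only
in particular cellular states — along differentiation, stimulation response,
cell cycle or age. `dyngp` maps such effects for a quantitative phenotype
`y` (e.g. gene expression across cells or repeated measures) measured over a
continuous state `x` per sample, with genotype `g ∈ {0,1,2}`:

```
y = α + β ⊙ g + γ + ε
α ~ N(0, K)          baseline trajectory over x        (K = k(X, X))
β ~ N(0, δ_g K)      dynamic genetic effect β(x)
γ ~ N(0, δ_d K ⊙ R)  donor-specific trajectories       (R: kinship = ZZᵀ)
ε ~ N(0, σ² I)
```

The per-variant null hypothesis is `δ_g = 0`, tested by a variance-component
score statistic

```
S = yᵀ V̂_d⁻¹ G K_NM K_MM⁻¹ K_MN G V̂_d⁻¹ y,   G = diag(g),
```

whose null law is the generalized chi-squared `Σ_m λ_m χ²₁` with weights
from an M×M eigenproblem. Everything runs through inducing-point (Titsias)
bounds and low-rank Woodbury solves — never an N×N matrix — so cost is
linear in the number of cells. The package also provides:

- a three-step null fit (H0: kernel and inducing points; H1: variance
  components; per-variant tests never refit),
- Bayes factors averaged over a `δ_g` grid {0.01, 0.1, 0.5},
- a static/dynamic decomposition with the composite kernel
  `K* = σ²e^{−ρ₀}11ᵀ + K`,
- a GPLVM to infer the state axis `x` (pseudotime, optionally a periodic
  cell-cycle phase) from an expression matrix when it is not observed,
- a Poisson count model via working responses and iterative weights,
- genome-style kinship estimation `R̂ = Σ g̃g̃ᵀ/L`,
- an exact synthetic-data generator for all of the above.

Intended users: statistical geneticists and single-cell folks running
cell-state-resolved eQTL scans, and method developers who want a compact,
fully tested reference implementation of the sparse-GP score test.

## Worked example

Simulate 30 donors × 10 cells with one causal variant (dynamic effect
`δ_g = 0.5`) among 20, then scan:

```python
import numpy as np
from dyngp import (SimulationConfig, simulate_genotypes, simulate_states,
                   simulate_phenotype, map_variants)

cfg = SimulationConfig(n_donors=30, cells_per_donor=10, n_variants=20,
                       delta_g=0.5, maf_range=(0.2, 0.4), seed=7)
rng = np.random.default_rng(7)
dosages, donor, _, _ = simulate_genotypes(cfg, rng)
states = simulate_states(cfg, rng)
y, truth = simulate_phenotype(cfg, dosages[:, 0], donor, X=states, rng=rng)

results, null = map_variants(y, dosages, states, donor, m=10, seed=0,
                             compute_bf=True)
print(results.sort_values("p").head(5))
```

prints

```
variant  score        p  log_bf method flag  fdr_bh
     v0   1139 0.002367   3.757  imhof      0.04734
     v8  513.4  0.04087  0.5023  imhof       0.4087
     v4  220.3   0.0801  0.1075  imhof       0.4656
     v5  393.9  0.09739 -0.2476  imhof       0.4656
    v17  239.4   0.1164  -0.257  imhof       0.4656
```

The causal variant `v0` ranks first: score-test p = 0.0024 (still
significant at FDR 5% after Benjamini–Hochberg across the 20 variants) and
log Bayes factor 3.76, i.e. the dynamic model is ~43× more probable than
the null for this variant. The fitted null for this phenotype had
`δ̂_d = 0.103`, `σ̂² = 0.348`, `ρ̂ = 1.16`. Null variants cluster around
p ≈ uniform, log BF ≈ 0.

The same scan from the shell:

```bash
dyngp simulate --seed 7 --out sim/
dyngp map --pheno sim/phenotype.tsv --geno sim/dosages.tsv \
          --donor sim/donors.tsv --states sim/states.tsv \
          --inducing 10 --bf --seed 0 --out results.tsv
dyngp kinship --geno sim/dosages.tsv --out kinship.tsv
dyngp fit-gplvm --counts expr.tsv --q 1 --m 15 --out latent.tsv
```

`map` also writes `results.tsv.qq.tsv` (expected vs observed −log₁₀p) for a
calibration QQ plot.

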