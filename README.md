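# metabnet

Group-level metabolic brain-network analysis from FDG-PET.

In resting FDG-PET, each subject contributes a single image of regional
glucose uptake, so within-subject connectivity cannot be computed the way it
is for fMRI time series. Instead, **metabolic connectivity** is defined
*across subjects*: for one cohort, the Pearson correlation between the mean
normalized uptake of region *i* and region *j*, taken over the cohort's
subjects. One correlation matrix per group — for the standard AAL
parcellation with the cerebellum removed, a 90 × 90 matrix with
M = N(N−1)/2 = 4005 distinct edges.

`metabnet` implements the full analysis around that metric, for researchers
comparing patient and control cohorts (the motivating application is
early-onset vs late-onset Alzheimer's disease):

- **ROI front end** — registered NIfTI volumes are smoothed (isotropic
  Gaussian kernel, default 16-mm FWHM), intensity-normalized by the mean
  cerebellar uptake (the reference region least affected in AD), and reduced
  to subject × region tables.
- **Edgewise comparison** — the subtracted connectivity matrix
  Δ_ij = r_ij^A − r_ij^B is tested by a non-parametric permutation test:
  group labels are reshuffled over the pooled subjects (10,000 relabelings
  by default, exhaustive enumeration when feasible), with two-tailed
  per-edge p-values and familywise control by the max-statistic null
  p_FWE = (1 + #{max_edges |Δ*| ≥ |Δ_ij|}) / (n_perm + 1).
- **Graph analysis** — matrices are thresholded to fixed densities
  (top k = round(density·M) edges); clustering coefficient
  C = (1/N) Σ C_i, global efficiency E = (1/(N(N−1))) Σ 1/d_ij,
  characteristic path length L, and small-worldness σ = γ/λ with
  γ = C/C_rand and λ = L/L_rand against degree-preserving rewired null
  networks (1000 randomizations by default). Binary and weighted modes are
  both available (weighted clustering is the Onnela form; weighted path
  lengths sum 1/w).
- **Density sweep** — parameters are evaluated over the 10–90% density
  interval in 17 steps of 5%, densities are screened for σ > 1, and
  per-density group differences in C and E are permutation-tested with the
  same relabelings as the edge test.
- **Synthetic cohorts** — multivariate-normal subject × region generators
  with modular covariance, planted edge effects and global attenuation
  stand in for patient data in all tests and examples.

## Worked example

Simulate the default synthetic study — a 74-subject case cohort against 20
controls, with ten cross-module correlations weakened from r = 0.6 to
r = 0.1 — and fit the edgewise comparison:

```python
from metabnet import EdgeComparison
from metabnet.synthetic import default_cohort_spec, simulate_cohort_pair

spec = default_cohort_spec(seed=0)
case, control = simulate_cohort_pair(spec)
fitted = EdgeComparison(case, control).fit(n_permutations=1000, seed=0)
print(fitted.summary(alpha=0.01, correction="uncorrected", max_rows=6))
```

```
Edgewise metabolic connectivity comparison
==========================================================
groups:          EAD (n=74) vs young (n=20)
regions/edges:   90 / 4005
permutations:    1000
scale:           raw correlation
threshold:       p < 0.01 (uncorrected)
significant:     2 edges
----------------------------------------------------------
 region_i  region_j   delta       p
       20        81 -0.5397  0.0070
       24        81 -0.5392  0.0090
```

`delta` is the case-minus-control correlation difference; negative values
mean weaker coupling in the case group. With only 20 control subjects the
sampling noise of each correlation is large (SE ≈ 0.15 at r = 0.6), so at
strict thresholds only the strongest differences surface — the planted
0.5-sized drops hover near the detection limit, which is exactly the power
regime such cohort sizes put you in.

The density-swept network comparison works the same way and shares the
permutation scheme:

```python
import numpy as np
from metabnet import NetworkComparison

net = NetworkComparison(case, control, grid=np.array([0.2, 0.4, 0.6, 0.8]))
res = net.fit(scheme=fitted.scheme, seed=0, n_randomizations=50)
print(res.summary(alpha=0.005))
```

```
Network-parameter comparison over the density grid
==========================================================
groups:        EAD (n=74) vs young (n=20)
grid:          0.20-0.80 (4 levels), mode=weighted
permutations:  1000
small-world screen (sigma > 1):
  EAD          20%-60% (3 levels)
  young        20%-60% (3 levels)
  shared       20%-60% (3 levels)
----------------------------------------------------------
C: significant density ranges at p < 0.005: none
E: significant density ranges at p < 0.005: none
metric  density  observed       p
     C   0.2000    0.0876  0.7483
     C   0.4000   -0.0389  0.4416
     ...
```

A config-driven pipeline (TSV/NIfTI inputs, BrainNet-style `.node`/`.edge`
exports) is available as `metabnet run config.yaml`; `metabnet demo OUTDIR`
generates a synthetic cohort and runs everything end to end.

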