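# Methods

## The model of metabolic connectivity

Each subject contributes one vector of mean normalized FDG uptake over the
90 non-cerebellar AAL regions. Within a group of n subjects, connectivity
between regions i and j is the Pearson correlation of their uptake values
across the n subjects. The object of inference is therefore a *group-level*
matrix: subjects are the sampling unit, and the exchangeability of subjects
under the null ("these two cohorts come from the same population") is what
licenses the permutation tests.

The ROI front end mirrors the standard preprocessing chain for registered
PET volumes: isotropic Gaussian smoothing (FWHM 16 mm by default, applied
as sigma = FWHM/(2√(2 ln 2)) per axis scaled by voxel size, constant-zero
boundary), division of every voxel by the mean intensity over
cerebellar-labelled voxels (the cerebellum is the reference because it is
the region least affected in Alzheimer's disease), then per-region
arithmetic means. Spatial normalization/registration is out of scope —
inputs are assumed already in atlas space. Whether ROI means should be
taken from smoothed or unsmoothed normalized images is not standardized;
the pipeline applies smoothing → normalization → extraction and exposes
smoothing as a config switch (off for precomputed tables).

## Permutation tests

**Edgewise.** For groups A (n_A) and B (n_B), the observed statistic per
edge is Δ_ij = r_ij^A − r_ij^B (a Fisher-z variant is available by flag;
raw differences are the default because the subtracted-matrix formulation
is the method's native scale). Null relabelings assign n_A of the pooled
subjects to A uniformly without replacement; when C(n_A+n_B, n_A) does not
exceed the requested count the scheme enumerates all assignments and the
test is exact. Two-tailed p-values use +1 smoothing,
p = (1 + #{|Δ*| ≥ |Δ|}) / (n_perm + 1), so no p-value is ever zero and the
test remains valid at any permutation count. Familywise error is controlled
by the max-statistic distribution — the maximum |Δ*| over all 4005 edges in
each relabeling — the standard strong-control nonparametric FWE; no
distributional assumption is needed. Permuted statistics are compared with
a 1e-10 tie tolerance: relabelings that reproduce the observed partition
must register as ties even though summation order perturbs floating-point
results. A relabeling that produces a zero-variance column (possible only
for degenerate inputs) contributes +inf for the affected edges,
conservatively inflating their p-values, and is logged.

**Network parameters.** The same relabelings (one `PermutationScheme`
object, checksum-verifiable) drive the per-density tests of C and E: at
each density level the permuted group pair is rebuilt from scratch
(correlation → threshold → metric) and the observed difference is referred
to the permutation distribution, again two-tailed with +1 smoothing. No
across-density multiplicity correction is applied — results are reported
per level with the significant levels merged into maximal consecutive runs
(e.g. "25–90%") — matching the per-density reporting convention of the
analyses this package reproduces; that is a documented limitation, not an
oversight.

## Graphs and metrics

Proportional thresholding retains the k = round(density · M) top-ranked
edges (rounding half away from zero, which lands exactly on the 5% grid
for M = 4005). Ranking is by signed correlation by default — the strongest
positive couplings first — with an absolute-value option; in weighted mode
retained non-positive edges are dropped because w^(1/3) and 1/w lengths are
meaningless for them, while binary mode keeps them as unit edges. Ties at
the cut break deterministically by (i, j) index order.

Metrics come in both modes because the printed formulas of the source
analyses are binary (edge counts) while their text states weighted matrices
were used; the pipeline default is weighted. Binary: C_i = 2t_i/(k_i(k_i−1))
(t_i = triangles at i; C_i = 0 for degree < 2), hop-count shortest paths.
Weighted: Onnela clustering C_i = (1/(k_i(k_i−1))) Σ (ŵ_ij ŵ_ih ŵ_jh)^{1/3}
with weights rescaled by the graph maximum, and path lengths that sum 1/w
per edge. L averages over reachable ordered pairs with the unreachable
fraction reported alongside; E needs no special-casing since 1/∞ = 0.
Implementations are vectorized (matrix powers for triangles,
Dijkstra via `scipy.sparse.csgraph` for paths) and validated exactly
against naive triple-loop and exhaustive-relaxation oracles on every
connected graph with ≤ 6 nodes.

Small-worldness σ = γ/λ uses degree-preserving double-edge-swap nulls
(default 10·|E| accepted swaps per null, 1000 nulls for a full analysis,
100 inside sweeps), which also preserve density; weight multisets are
preserved and reassigned uniformly in weighted mode. Dense graphs are
rewired through their complement — swaps on the complement preserve the
complement's degree sequence and hence the original's — keeping proposal
acceptance workable at high density. The swap kernel is numba-compiled
with a pure-Python fallback. Graphs admitting no valid swap (stars) fall
back to density-only rewiring with a warning; a complete graph is its own
null, making σ = 1 exactly.

## Synthetic cohorts

The generator emulates the study design the package targets: group sizes
default to 74 early-onset cases vs 20 young controls (46/13 for the
late-onset pair), subject rows drawn i.i.d. from a multivariate normal
whose correlation matrix has 6 contiguous modules over 90 regions
(within-module r = 0.75, between-module r = 0.45 — a modular structure in
the range reported for cross-subject metabolic correlations), mean uptake
1.0 and SD 0.1. Planted effects: ten disjoint cross-module edges at
r = 0.6 in controls drop to r = 0.1 in cases; a global attenuation knob
scales every off-diagonal case correlation by (1 − a) (a uniform loss of
metabolic coupling; a convex combination with the identity, so positive
semidefiniteness is free). Planted overrides can break PSD, so matrices are
repaired by eigenvalue clipping (floor 1e-8) with the diagonal rescaled to
1; a repair that moves any entry by more than 0.1 raises "infeasible
structure" rather than silently distorting the design. With the default
background the case-group planted entries land at 0.139 after repair.

What the generator does *not* emulate: PET physics (scatter, attenuation,
partial volume), site or scanner effects, non-Gaussian uptake
distributions, age/sex covariates, and spatially correlated noise. Passing
tests therefore demonstrate the statistical machinery under a clean,
exactly-controlled correlation model — not robustness to real acquisition
artifacts.

## Power at the emulated design, honestly stated

The emulated cohort sizes impose hard limits that the validation suite
deliberately documents rather than hides. With 20 control subjects the
sampling SE of a single correlation near r = 0.6 is ≈ 0.15, so a planted
drop of 0.5 carries an observed-delta SE near 0.19; the max-statistic FWE
threshold over 4005 edges sits near 0.5–0.7 for any background covariance
that is PSD-feasible with the planted values. Consequently the
planted-edge recovery check at FWE 0.05 and the demand that C and E be
significant at p < 0.005 in ≥ 90% of replicates fail at this design size —
the corresponding acceptance tests are expected to be red, and the
acceptance script reports the measured recovery (0% at FWE;
raw-direction checks such as "attenuated case has lower C" pass at
100%). Detecting such effects at familywise significance requires either
larger control groups or larger planted effects than the emulated design
provides.

## Test-suite problem sizes

Simulation-based checks are sized for a single CPU: the familywise-level
check uses 200 replicate null cohorts of 20 vs 20 subjects over 20 regions
at 1000 permutations; the null-uniformity check 100 replicates at 250
permutations over two densities; the planted-effect checks the full
74-vs-20, 90-region design at 1000 permutations (20 replicates for the
attenuated variant, evaluated at densities 0.60/0.75/0.90); small-world
sanity checks use 100 randomizations. The acceptance script uses the same
designs with 100 level-replicates.

## Numerical and design choices

- Region order is ascending AAL code everywhere; edges are canonical
  unordered pairs (i < j), giving deterministic matrix indexing.
- Cerebellar labels are identified by the `Cerebelum`/`Vermis` name
  prefixes of the packaged 116-label table, reproducing the 90-region
  cerebral parcellation.
- The packaged centroid table for viewer exports is synthetic (deterministic
  pseudo-MNI coordinates, hemisphere-signed); it positions nodes for
  BrainNet-style files without claiming anatomical accuracy.
- Density grids are rounded to 4 decimals to keep levels platform-identical.
- The +1-smoothed p-values are conservative by ~1/(n_perm+1); exhaustive
  enumeration removes Monte-Carlo error entirely for small designs.
- All generators and tests are seed-deterministic; cohort specs are echoed
  to JSON alongside outputs, and pipeline runs record a config hash, making
  reruns bit-identical.
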