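# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `vsatnet`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Task model

The visual sustained-attention task is a pure block design: alternating
rest and task blocks (rest first), each block of length

    block_s = cue_s + L·digit_s + break_s + n_seq·(L·digit_s + response_s)

with defaults cue 0.8 s, digit 0.4 s, target length L = 3, break 1.0 s,
nine probe sequences and 1.8 s response windows — 30 s per block, and
5 + 5 blocks give a 5 min run sampled at a 1 s interval (300 volumes).
Durations are held as exact rationals (`fractions.Fraction`) so the design
arithmetic carries no float drift; floats appear only at the regressor
stage.

The hemodynamic response is the canonical double-gamma: a positive gamma
with mode at 6 s minus a 1/6-scaled undershoot with mode at 16 s,
peak-normalized. Gamma shape is delay + 1 at unit rate, which places the
mode exactly on the stated delay. The task regressor is the block boxcar
convolved with this kernel on a 10× oversampled grid, decimated back and
unit-peak-normalized. An identity ("delta") HRF is available for tests.

## Synthetic data generator

The generator produces everything the pipeline consumes; its defaults are
the study conditions the package is designed around (two groups of ~40,
300 volumes at 1 s, 30 s blocks).

**Atlas.** Disjoint box parcels (≥ 150 voxels each) tiled onto a
24×24×16 grid of 2 mm voxels, split into WM "tracts" (labels 1..n_wm) and
GM "regions". The tiling slot shape is chosen deterministically to
maximize slot count; parcel placement is seeded. Real atlases have
irregular, touching, anisotropic parcels — none of that is emulated, so
tests exercise the selection logic, not anatomical realism.

**Cohort.** Per-group Gaussian draws for age, education, parental
education and the two symptom scores, with means/SDs set to the
demographic table being emulated (e.g. inattentive 4.67 ± 2.81 in NC vs
9.31 ± 6.28 in TBI) and male fractions 23/43 and 21/42. Ages are clipped
to 18–27 and scores at 0; the implied truncation is mild, so sample means
are checked against targets within sampling error, never exactly.

**BOLD volumes.** Signals are generated at parcel level and broadcast to
member voxels with independent white voxel noise (default SD 1.0) —
voxel-level signal genesis is deliberately minimal, since only parcel-level
structure is analyzed downstream. The latent parcel series are built by
Cholesky-mixing iid Gaussian series to a target correlation matrix, then
band-limiting to < 0.125 Hz (FFT mask, DC removed). If a group increment
breaks positive semidefiniteness, the matrix is projected to the nearest
valid correlation matrix (eigenvalue clipping + rescaling) with a warning;
the pipeline preconditions its planted increment once up front.

The WM spectral bump multiplies the magnitude of each WM parcel's own
Fourier coefficient at the bin nearest 0.017 Hz by adding
`gain × rms(passband)` (default gain 3), keeping the phase. Because the
operation is per-row and phase-preserving, planted correlations among WM
parcels (and among GM parcels) are preserved exactly; WM–GM cross pairs
are attenuated by a few percent at the default gain. Tests that assert
correlation recovery therefore plant effects within a tissue class. The
bump magnitude is deterministic so the periodogram argmax lands in the
target bin with overwhelming probability at any seed.

GM parcels additionally receive the task regressor at amplitude 1.0
relative to the unit-variance latent (WM task amplitude defaults to 0; the
relative WM/GM amplitude is exposed as a parameter rather than fixed,
since no reference value exists). The shared task drive inflates GM–GM
correlations, which is physiological; correlation-recovery tests disable
it.

The default planted correlation structure (`ring_shortcut_corr`) decays as
rho^d with ring distance plus a few strong shortcuts — binarized over the
cost grid this produces lattice-plus-shortcut graphs, the regime empirical
functional networks occupy.

## Node discovery

**GM.** Per-voxel OLS (intercept + regressor + optional confounds); the
regressor t statistic is Gaussianized to Z by matching tail probability
(via log-survival functions for deep tails) and capped at ±40 so
numerically perfect fits stay finite. Suprathreshold voxels (Z > 2.3) are
grouped into 26-connected components (6/18 configurable; the upstream
convention is unstated) and components of ≤ 100 voxels are discarded.
Random-field cluster p-values are not implemented: the >100-voxel rule is
what actually gates node eligibility. Group maps are averaged per group,
thresholded, and combined as the voxelwise union of surviving masks with
peaks taken on the across-group mean Z — the source procedure does not
specify which map supplies peak values, so the mean is used. A node is
placed per GM parcel whose surviving suprathreshold voxel count exceeds
100 (counted within the parcel, not per overlapping cluster — flagged as
an interpretation), at the parcel's maximum-Z surviving voxel, as a 4 mm
sphere intersected with the parcel.

**WM.** Subject weighted WM masks are binarized strictly above 0.5
("more than 50% probability"), averaged, and the mean is binarized at
≥ 0.8 (ties inclusive; both conventions configurable). Voxel power is the
periodogram of the z-scored series summed over positive bins with
f ≤ 0.017 Hz — the cumulative reading of "under 0.017 Hz"; a
single-nearest-bin mode exists behind a flag. With 300 samples at 1 s
that is bins 1/300…5/300 Hz, i.e. 5 of 150 positive bins. The group power
map is the voxelwise mean of subject maps (combination rule unstated
upstream; the mean is the obvious estimator). One 2 mm sphere per tract
is placed at the in-mask power maximum; argmax ties break to the smallest
C-order voxel index for reproducibility. Sphere membership is by voxel
center distance in mm, intersected with tract and group mask. No fixed
node count is asserted anywhere: how many of the tracts yield nodes is a
property of the data.

## Wavelet denoising

The MODWT is implemented directly (pyramid algorithm with circularly
wrapped filters) because the series length (300) need not be divisible by
2^level, which the SWT in PyWavelets requires; PyWavelets supplies the
filter coefficients, and `pywt.mra(..., transform='swt')` on dyadic-length
inputs is the independent cross-check in the tests. Scale j spans
[fs/2^(j+1), fs/2^j]; scales {3,4,5} at 1 Hz span 0.015625–0.125 Hz.
Denoising reconstructs the MRA detail components of the selected scales
per voxel and then averages voxels within a node — in that order.
Default wavelet is `sym4` (the 8-tap least-asymmetric Daubechies family,
LA8, the common choice for fMRI MODWT); `db4` is a tested alternative.
Boundary handling is periodic by default, which makes additivity, energy
decomposition and circular-shift invariance exact (verified to 1e-10);
a reflection mode halves wrap-around artifacts at the cost of exact shift
invariance. Pearson correlation is scale-invariant, so z-scoring before
versus after filtering does not change FC; series are used as
reconstructed.

## Network topology

FC is the absolute Pearson correlation between node-mean denoised series;
the diagonal is excluded. Binarization at cost C keeps the
K = round(C·N(N−1)/2) strongest weights (round-half-up), with ties at the
cutoff broken by ascending lexicographic pair order so the edge count is
exactly K and runs are reproducible. Efficiencies use inverse shortest
path lengths with unreachable pairs contributing 0; distances come from
all-pairs BFS via boolean matrix products (fast for dense graphs of tens
to hundreds of nodes). Local efficiency of node i is the global efficiency
of the subgraph induced by its neighbors, excluding i; nodes with < 2
neighbors score 0, as do nodes with < 2 neighbors for clustering.
Clustering is exposed both per node and as the network mean (the printed
network formula carries the leading 1/n; the per-node summand is what
feeds nodal statistics). Betweenness is Brandes' algorithm (networkx),
normalized by (N−1)(N−2)/2 to honor the "proportion" reading; raw values
are recoverable by `normalized=False`.

Null models: the regular null is a ring lattice with identical N and K
filled shell by shell in deterministic node order; the random null rewires
by uniform double-edge swaps (20 attempts per edge), preserving the degree
sequence exactly. Small-world evaluation compares the group-averaged FC
matrix at each cost (0.10–0.50, step 0.01) against the lattice and the
mean of several rewired nulls; per-subject metrics are computed on each
subject's own FC matrix over 0.10–0.40 and cost-averaged, since subjects —
not the group average — enter the statistics. The scan reports per-cost
flags and the largest contiguous satisfying interval. Because the partial
shell of the lattice null and of a binarized ring-decay matrix can differ
in arrangement, the strict lattice inequality carries no real margin for a
lattice input; the validation tests therefore classify inputs by the full
criterion (lattice-plus-shortcut matrices satisfy it across essentially
the whole grid, pure lattices and Erdős–Rényi matrices do not).

The benchmark weighted matrices used in the validation are constructed so
that binarization at *every* cost yields the named topology: Watts–
Strogatz edges ranked above a ring-distance-decaying background (giving
lattice-with-shortcuts at all costs), pure ring decay (lattice), and iid
uniform weights (Erdős–Rényi).

## Group inference

The covariate-adjusted comparison is a fixed-effects linear model per
(node, metric): outcome ~ group + sex + age + education + parental
education, F-tested on group. The source describes scalar covariates as
"random effects", which has no identifiable single-observation
interpretation, so fixed effects are used. Stage-1 Bonferroni families are
all (node × metric) outcomes within a network; survivors get plain
two-sample t-tests Bonferroni-corrected within the survivor family. Raw
and adjusted p are always reported side by side with the family size, and
trend-level results (adjusted p below 0.10 by default) are reported, not
gated. The pooled t-test is the default (it reproduces the demographic
table's p-values from rounded summaries better than Welch); a Welch mode
exists. Collinear covariates are dropped with a warning rather than
failing. WM–GM interaction correlates, per diagnostic group, each
significant WM outcome with each significant GM outcome (the significant
metric per node by default; all-metric pairing is a caller choice).
Brain–behavior analysis is a residual-based partial correlation
(df = n − #controls − 2) of significant metrics against the raw symptom
scores, controlling age and the three education covariates.

## Validation design and problem sizes

The statistical validation of the group comparison plants effects at the
metric level: per-subject (node, metric) outcomes load 0.6 on z-scored age
and 0.4 on z-scored education with residual SD 0.7, and the planted shift
is Cohen's d = 0.8 of the total non-group SD at one node/metric, n = 40
per group, family = 6 nodes × 5 metrics. The covariate loadings are the
point of the design: adjusted comparison removes that variance, which is
what gives the procedure its power at this family size. Detection and
familywise-error rates are measured over 20 seeded replicates. The
end-to-end imaging-pipeline version of the same claim is exercised at
reduced scale (8–16 subjects, one seed) by checking that a planted
TBI-only correlation increment reappears in the group FC difference on
the planted pair.

Desk-scale runs use the 24×24×16 toy grid with 6 WM + 10 GM parcels;
oracle equivalence for the graph metrics is exhaustive on 200 random
graphs of up to 8 nodes; the small-world validation uses 64-node
benchmark matrices over 20 seeds with 2 rewired nulls per cost.

## Known limitations

- No head motion, drift, physiological noise, slice timing or
  registration is simulated; the generator produces already-aligned data,
  and motion confounds enter only through the GLM's optional confound
  columns.
- Toy parcels are boxes on a small grid; tract geometry, cortical folding
  and partial-volume effects are absent.
- The absolute-value FC floors null correlations above zero, so planted
  group differences reappear attenuated (see the worked example).
- Weighted-graph metrics, modularity and prewhitening are out of scope.
- The Gaussianized Z cap at ±40 is arbitrary but inert: it only affects
  numerically perfect fits.
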