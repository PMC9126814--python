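# Methods

## Trial-resolved connectivity

Beta-series correlation treats the vector of per-trial GLM amplitudes of a
region as its "signal" and correlates it between regions. To resolve
connectivity *per trial* we combine it with the jackknife-correlation idea:
for each trial *t* the Pearson correlation of every edge is computed over
all trials of the phase except *t* and Fisher-transformed. Removing a trial
that supports the correlation lowers the leave-one-out estimate, so the
sign-flipped value −z(r⁽⁻ᵗ⁾) is a per-trial measure of that trial's
contribution to coupling.

Two variants are exposed:

* `jackknife_zflip` (default): the flipped series is standardized per edge
  across trials (mean 0, SD 1). Units are relative within subject/edge;
  everything downstream that contrasts time-blocks within subject is
  invariant to this per-edge affine rescaling.
* `jackknife_pseudovalue`: classical pseudovalues T·z_all − (T−1)·z⁽⁻ᵗ⁾,
  unstandardized, preserving between-subject amplitude.

Choices and edge cases:

* The leave-one-out pool is **all trials of the phase** (both CS types
  pooled); matrices are afterwards reordered by CS type and presentation
  time. A per-CS pool is a small code change but was not needed.
* Fisher transform before flipping (variance stabilization), toggleable.
* Perfect correlations are capped at |z| = 6 so degenerate edges stay
  finite.
* A zero-variance region across all trials is an error; a zero-variance
  *leave-one-out subsample* zeroes the affected entries and increments a
  quality counter rather than propagating NaN.
* Implementation: sum/outer-product downdates give all T leave-one-out
  covariance matrices in one vectorized O(T·R²) pass; the test suite checks
  it against an explicit per-trial `corrcoef` loop to 1e-10 (both variants),
  which is also re-verified at run time by `scripts/acceptance.py`.

The optional GLM path estimates the beta series from BOLD + events with
least-squares-separate (LSS): per trial, a design with that trial's
regressor, one pooled regressor per condition for the remaining trials, and
Legendre drift up to order 2; HRF is the canonical double-gamma
(`nilearn`'s glover model). Region values come from region-mean time series,
which for a linear model equals averaging voxel coefficients. LSS is
preferred over least-squares-all for stability in short event-related
designs. Noise-free forward simulations are recovered with r > 0.99.

## Time-block dynamics

Trials of each CS type are divided into 4 equal contiguous blocks in
presentation order and averaged. ΔFC is block 4 − block 1 per edge,
vectorized over the strict upper triangle in row-major (i<j) order — one
stated convention everywhere prevents silent edge misalignment. The
differential change ([CS+ − CS−] at block 4) − ([CS+ − CS−] at block 1) is
computed as ΔFC(CS+) − ΔFC(CS−), an algebraic identity that is also tested.
Static FC (one correlation matrix over all trials of a CS type, Fisher z)
exists as the control analysis; an "early/late = first/last 4 trials"
summary is a thin alternative to block means.

## Group inference (NBS)

Edgewise model: OLS of ΔFC on [intercept, group indicator, age, sex];
t statistic on the group coefficient, df = n − 4. The Network-Based
Statistic thresholds edges at a primary directional p (default 0.001,
one-sided per contrast direction, since signed components are reported;
two-sided available), takes connected components over regions, and uses the
component *extent* (edge count; intensity = Σ|t| available) as the
statistic. The null permutes group labels across subjects — covariates stay
attached to their subjects and the GLM is refit each time — recording the
maximal component size. p_FWE = (1 + #{null ≥ obs}) / (1 + n_perm) (add-one,
so p is never 0); when the label-assignment space is at most n_perm the
null is enumerated exactly (p = #{null ≥ obs}/N, observed assignment
included). The component-level t-test on per-subject component-mean
differential change is a plain pooled-variance two-sample t with
df = n₁ + n₂ − 2.

Calibration note: with very sparse supra-threshold graphs (e.g. R = 60,
1770 edges at p < 0.001, ≈ 1.8 expected supra-threshold edges) the null
max-component-size distribution is supported on {0, 1, 2, 3} and the
achievable test levels skip from ≈ 0.10 to ≈ 0.003 — a discrete test cannot
reject at exactly 0.05 and the realized family-wise rate is far below
nominal. The calibration test therefore uses a primary threshold of 0.01 at
that problem size (≈ 18 expected supra edges), where the measured
any-component rate over 200 null cohorts is statistically compatible with
0.05. At realistic scale (R = 432, 93k edges) the p < 0.001 default does not
suffer this collapse.

Power note: component membership requires each edge to pass the primary
threshold individually, so edge-level sensitivity is bounded by the
per-edge power. At an edgewise Cohen's d of 0.8 with 40 subjects per group,
the one-sided p < 0.001 threshold (t₇₆ = 3.19) against a noncentral t with
ncp = 0.8·√20 = 3.58 gives power ≈ 0.63; recovering ≥ 80% of a planted
component's edges needs d ≈ 1 or larger samples. The planted-recovery test
runs at d ≈ 0.8 and documents this bound in its failure message.

## Cross-phase association

The predictor is each subject's mean ΔFC over a fixed component; responses
are recall-phase region signals. Per region: OLS on [1, predictor, age,
sex], partial r = t/√(t² + df). Family-wise error across regions is
controlled with a max-|t| permutation null obtained by shuffling the
covariate-residualized predictor (region-level analogue of a voxelwise
cluster-FWE analysis; voxel-level mapping is out of scope). Recall-phase
edge FC supports the same question at the connectome level through the NBS
engine with a continuous covariate of interest, run separately for positive
and negative couplings. Correlation differences between groups use the
independent-samples Fisher z by default (the groups are disjoint);
Steiger's (1980) dependent test with the non-shared-variable
inter-correlation is provided where correlations share a sample.

## Clinical CCA

Edge counts exceed subject counts, so X is PCA-reduced to
min(⌊n/10⌋, 30) components (logged, overridable) before the first canonical
pair is computed in closed form (QR of both centered blocks, SVD of
QₓᵀQᵧ). Only the first pair is tested; higher correlations are emitted
descriptively. Inference shuffles rows of Y (10000 by default) with the X
reduction held fixed; cross-validation refits reduction + CCA per training
fold, projects held-out subjects with the trained weights, pools held-out
score pairs for cv_r, and re-runs the whole CV loop on shuffled Y for
cv_perm_p (default 1000 re-runs — each is a full 5-fold fit, so the default
is lighter than the in-sample test). Canonical signs are arbitrary; they are
fixed so the connectivity variate correlates non-negatively with the first
X principal component. Loading *products* (clinical × connectivity) are
invariant to the joint sign flip, which is what the directionality analyses
use. Missing clinical values are removed listwise with a logged count;
residualizing X and Y for age/sex before CCA is available as a flag,
default off.

## Synthetic cohorts

`generate_cohort` draws per-trial region vectors from a zero-mean
multivariate normal: identity correlation except on a planted edge set,
where the CS+ correlation at trial *t* (1…T) is baseline_rho +
slope·(t−1)/(T−1); CS− trials stay at baseline. Each subject's slope is the
group slope plus N(0, subject_slope_sd), truncated to the interval in which
I + ρ·A is positive definite (A = planted adjacency; for the default
8-clique + 2 spokes this is ρ ∈ (−0.12, 0.52), computed from A's extreme
eigenvalues). The subject's *true ΔFC proxy* is the planted correlation
difference between block 4 and block 1 implied by that slope. The recall
region's value is recall_link[group]·proxy + N(0, recall_noise_sd);
clinical scores are instrument-scaled linear functions of standardized
negative proxy ("severity") plus noise. CS+/CS− presentation is alternating
by default (blocked/randomized available and recorded in the events files).

Defaults are one fixed set of study conditions: 16 trials/CS in 4 blocks of
4; control slope +0.3 and patient slope −0.1 from baseline 0.1 (an increase
of moderate size that stays well inside the positive-definite range);
subject SD 0.1; recall link 1.0 in control groups and 0 in patient groups;
clinical link weight 0.6 per instrument. Heavier-powered analyses in the
test suite state their own sizes: the planted-recovery conditions use 32
trials/CS with slopes (+0.38, −0.10) — calibrated once so the realized
edgewise d through the full pipeline is ≈ 0.8 — and the cross-phase
conditions use 100 subjects/group, 32 trials/CS, subject SD 0.18 and recall
noise 0.04, because the jackknife estimate of component-mean ΔFC carries
substantial estimation noise (reliability ≈ 0.5 against the true proxy at
32 trials/CS), and the planted link must be strong enough to be detectable
through it.

What the generator does *not* emulate: hemodynamics and scanner noise
(unless the optional BOLD mode is used), spatial autocorrelation between
regions, background connectivity structure (a single-factor background
option exists), motion or physiological artifacts, non-Gaussian clinical
distributions, and site/batch effects. Passing tests therefore demonstrate
the statistical machinery — estimator correctness, FWE control, recovery at
planted effect sizes — not robustness to fMRI artifacts.

## Determinism and sizes

Every stochastic stage takes a seed; pipeline stage seeds are derived from
the top-level seed with fixed offsets, and re-running an identical config
reproduces all statistics bit-identically. Permutation loops are
single-process. Simulation-backed checks use 60-region cohorts (30–100
subjects/group) and 200–1000 permutations; these sizes keep the whole suite
and the acceptance script in the minutes range on one CPU while leaving
every assertion's power comfortable. The packaged 432-region atlas table is
a schematic stand-in (Schaefer-style labels, 7 systems + 32 subcortical
regions, pseudo-coordinates) for the real parcellation files, which are
external resources; any table with the same schema drops in.
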