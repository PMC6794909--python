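# Methods

`morphohybrid` quantifies how hybridization shapes the limb skeleton of
domestic equids: whether F1 hybrids (mules, hinnies) are morphologically
intermediate between donkeys and horses, how far they transgress the
parental axis, which parent dominates their shape, and whether the
covariation structure among bones (morphological integration) differs
between hybrids and parents. This note documents the models, estimators,
numerical conventions and the synthetic study generator, in that order.

## Superimposition and shape variables

Each bone is analysed separately. Configurations of k 3-D landmarks are
centered, scaled to unit centroid size (full Procrustes fit; size is
analysed separately via centroid size) and iteratively rotated to the
running consensus with proper rotations only — reflections are never
absorbed silently; antimeres must be mirrored explicitly via the per-
configuration `reflect` flag. Convergence is declared when the root-mean-
square change of the unit-normalized consensus drops below `tol = 1e-10`
(default `max_iter = 100`); non-convergence warns and reports
`iterations_used`.

GPA is defined only up to a global rotation, so the converged consensus is
oriented along its principal axes with a deterministic sign convention (the
landmark with the largest |projection| scores positive on the first two
axes; the third axis follows the right-hand rule). This makes the output
invariant, to tolerance, under arbitrary rotation, translation and scaling
of any input — a property the acceptance suite checks end to end.

Shape variables are the flattened deviations from the consensus after
orthogonal projection onto the tangent space at the consensus pole (the
convention of the classic morphometrics toolkits); plain Procrustes
residuals are available via `shape_variable_kind="residual"`. For
deviations below ~0.05 the tangent distance tracks the Procrustes distance
to well under 1%.

## Ordination and group tests

PCA is the eigendecomposition of the specimen covariance of the shape
variables (at most `min(n − 1, 3k − 7)` non-null axes for 3-D Procrustes
data). Group tests run on the smallest leading set of PCs explaining 90% of
variance (configurable). Pairwise MANOVAs use Wilks' Λ with the standard F
approximation (delegated to statsmodels; for a single retained PC the test
reduces exactly to the classical one-way F). The two-way species x sex
model excludes geldings from the sex factor; a significant interaction
routes the bone to sex-stratified index computation (no per-sex
significance testing — the per-sex samples are small by design).

Disparity is the Procrustes variance: the mean (divisor n) squared tangent
distance of group members to their group mean. Pairwise comparisons use the
statistic |var_i − var_j| with a residual-randomization null: squared
residual norms from each specimen's own group mean are permuted across
specimens. Residuals — not group labels — are the exchangeable units here;
permuting labels would mix the parent-species mean separation into the
permuted variances and collapse the test's level (measured rejection ~0
instead of 0.05 under label permutation at the default divergence).

## Size and allometry

Size is log10 centroid size: one-way ANOVA plus pooled-variance pairwise
t-tests, Bonferroni-corrected. Allometry is the multivariate regression of
shape variables on log10 size; R² = trace(SS_model)/trace(SS_total), with
significance from permuting the size vector (999 permutations by default,
p with the +1 correction). Slope homogeneity compares the full model
(size + group + size x group) to the reduced model (size + group) by a
pseudo-F on summed squared deviations, with residual randomization of the
reduced model (RRPP): the null datasets are reduced-model fitted values
plus permuted reduced-model residuals. Small p means the slopes are *not*
parallel.

## Transgression and dominance

Group mean shapes are arithmetic means of the full tangent-space shape
variables (not PC subsets); d(·,·) below are Euclidean distances between
them, with D = donkey, Ho = horse, Hy = hybrid:

* transgression % = (dDHy + dHoHy − dDHo) · 100 / dDHo
* dominance % = (m − dDHy) · 100 / m, with m = (dDHy + dHoHy)/2

Transgression is 0 exactly when the hybrid mean lies on the parental
segment; dominance is +100 at the donkey mean, −100 at the horse mean, 0
when equidistant. (Some statements of the dominance formula write the
horse–hybrid distance as dCHy, C for *Equus caballus*; it is the same
quantity as dHoHy.) Uncertainty comes from a within-group nonparametric
bootstrap with percentile intervals.

The plug-in distance between two estimated means of groups of size n has a
noise floor ε ≈ sqrt(2 p σ²/n) for p shape dimensions and per-dimension
noise σ. It matters only where a true distance is ~0 (a hybrid exactly at a
parent mean), where it biases dominance by about 2ε/dDHo · 100 percentage
points; at the generator defaults this is ~1.3 pp at n = 200/group and
shrinks as 1/sqrt(n). Away from those degenerate corners the bias is
second-order.

## Integration

Two-block PLS: SVD of the cross-covariance of two centered blocks of shape
variables; rPLS is the Pearson correlation of the first paired axis scores;
squared singular values normalized to sum 1 give per-axis covariance
fractions. Significance permutes the specimen rows of one block (999 by
default). Each bone keeps its own GPA; a pair is analysed on the specimens
common to both bones, re-centered within the analysed group.

The effect size is z = (t(r_obs) − mean t(r_perm)) / sd t(r_perm) with t
Fisher's transformation. Because z studentizes the observation against its
own permutation null, its null distribution is ~N(0, 1) at any sample size
and block dimension — this is what makes integration strength comparable
across datasets, whereas the null expectation of raw rPLS moves strongly
with n (it is ~0.78 at n = 30 with 17-dimensional blocks under pure noise).
Under a fixed generating coupling z still grows like sqrt(n), as any
consistent standardized test statistic must. The reported standard error
adds the finite-permutation estimation error of the null moments:
se = sqrt(1 + 1/N + z²/(2N)) for N permutations. Two datasets are compared
by |z_a − z_b| / sqrt(se_a² + se_b²) against the standard normal,
Bonferroni-corrected over the comparisons in a report.

Covariation networks evaluate three shipped pair families over the sixteen
bones — serial homologs (scapula–coxal, humerus–femur, radio-ulna–tibia,
metacarpal–metatarsal, three phalanx pairs), within-limb adjacent chains
(with talus and calcaneus each linked to tibia and metatarsal), and
functional equivalents (scapula–femur, humerus–tibia, radio-ulna–
metatarsal) — all overridable in the run config. Multiple testing follows a
per-bone familywise rule: within a group, the family of a bone is every
tested pair containing it; an edge is significant only if its p-value
survives Bonferroni in the families of both of its bones (the reported
`p_adj` is the larger of the two corrected values).

Shape changes along a PLS axis displace each block's consensus by the
first-axis loading vector times the requested score quantiles; per-landmark
displacement norms between the two extremes feed covariation-intensity
visualizations. Mesh warping is out of scope; the numeric tables are the
contract.

## Synthetic study generator

The generator emulates the statistical structure the analysis assumes, with
closed-form ground truth recorded alongside every dataset:

* **Sample.** Defaults mirror a reference museum sample: 42 horses, 38
  donkeys, 21 hybrids (13 mules, 8 hinnies), sixteen bones with 8–12
  landmarks each. An optional `missing_rate` drops configurations to
  emulate sub-complete skeletons.
* **Divergence and placement.** Per bone, parent means sit ± divergence/2
  (default separation 0.1 Procrustes units) along a fixed direction u of
  shape space; the hybrid mean is placed at fraction f along u plus an
  orthogonal offset t·separation (defaults f = 0.45, t = 0.4: expected
  transgression 28.2%, dominance +6.1% toward donkeys, the regime of mild
  donkey dominance with substantial transgression).
* **Noise.** Isotropic Gaussian tangent noise, sd 0.00125 per dimension.
  All planted directions and the noise are confined to the orthogonal
  complement of the similarity subspace (translations, rotations, scaling)
  at the base shape, so GPA neither absorbs nor distorts them and the
  closed-form index expectations stay valid; the noise level keeps the
  plug-in distance floor (see above) around 1% of the parent separation at
  n = 200, i.e. recovery operates in its asymptotic regime while every
  pairwise group MANOVA remains decisively significant — the regime the
  analysed sample sits in.
* **Size and allometry.** log10 centroid size is Gaussian per group
  (donkey 2.20 ± 0.06, horse 2.35 ± 0.10, hybrid 2.30 ± 0.07 — horses the
  largest and most size-diverse, hybrids intermediate-large), with one
  size deviate shared across a specimen's bones. Shape gains
  slope·(log size − group mean) along a fixed direction; a per-group slope
  magnitude breaks parallelism on demand. Note the shared size deviate
  times a common slope is itself a genuine inter-bone coupling and an
  inter-group dispersion difference — null simulations for integration or
  disparity must therefore switch allometry off.
* **Integration.** Each planted edge (bone_a, bone_b, ρ) shares a standard
  normal latent per specimen, mixed as sqrt(ρ)·latent + sqrt(1−ρ)·noise on
  one loading direction per bone, so the realized cross-block correlation
  on that direction is ρ. The loading direction carries 3× the noise sd
  (~9× the per-dimension variance, a dominant share): real within-group
  covariation is concentrated on a few factors, not spread isotropically —
  with isotropic noise the permutation null of rPLS at n = 30 sits near
  0.78 and no realistic coupling would ever be detectable, whereas
  empirical studies detect rPLS ≥ 0.9 at n ≈ 21.
* **Sex.** Sexes are drawn 48/47/5% female/male/gelding; an optional male
  shape offset, restricted to one species on demand, plants a species x sex
  interaction.
* **Emission.** Each configuration is rescaled to its drawn centroid size,
  randomly rotated and translated, so superimposition has real work to do.
  Everything is bit-reproducible from the single spec seed
  (numpy SeedSequence spawning, one stream per bone plus metadata and
  latent streams).

What the generator does *not* emulate: anatomically realistic mean shapes
(base shapes are deterministic non-degenerate helices), measurement error
structure of a digitizer, allometric curvature, breed substructure, or
integration spanning more than one direction per edge. Passing tests
therefore certify the statistical machinery — superimposition, estimators,
permutation engines, report plumbing — not anatomical realism.

## Numerical conventions and degenerate inputs

Permutation and bootstrap p-values use the +1 correction; defaults are 999
draws (199 in the large calibration sweeps, which use 500 simulations per
engine — sizes chosen so the full verification suite runs on one CPU in
minutes). All randomness flows from numpy Generators; the pipeline splits
one global seed into per-bone, per-stage streams, and every table is
byte-reproducible given the config. Degenerate inputs fail loudly:
coincident landmarks, constant size vectors, singleton groups, singular
within-group covariances, empty factor cells and zero permutation spread
raise typed errors naming the offender. PCA axes and PLS axis pairs carry a
deterministic sign convention (largest-|loading| element positive).

## Known limitations

* Tangent-space linearization: index expectations are exact in tangent
  space; through the full GPA path a curvature term O(separation²)
  (~0.03% relative at the default separation) remains. Irrelevant at the
  tested tolerances except for exactness claims, which hold on mean
  vectors.
* The Wilks-based MANOVA assumes within-group multivariate normality on
  the retained PCs; no non-parametric location test is provided.
* The covariation network treats pairs independently apart from the
  familywise correction; no graphical-model conditional independence is
  implied.
* Real TPS dialect variation (curves, scale factors) is not parsed — only
  `LM3=` blocks with `ID=`/`IMAGE=` fields, rectangular NTS, and the long
  CSV format.
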