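# morphohybrid

Geometric-morphometric analysis of how hybridization shapes the limb
skeleton of domestic equids. Mules and hinnies — F1 hybrids of donkeys and
horses — are prized for "hybrid vigor", yet whether their bones are simply
intermediate between the parent species, or transgress the parental range,
is a quantitative question about 3-D landmark data. This package implements
the full analysis chain for that question and a synthetic study generator
with recorded ground truth to validate every step. It is written for
morphometricians and zooarchaeologists working with per-bone landmark
configurations and specimen metadata (species, hybrid class, sex).

## What it computes

For each bone, after generalized Procrustes analysis (GPA) and tangent
projection:

* **Ordination and group structure** — PCA of shape variables, pairwise
  MANOVA (Wilks' Λ) on the PCs explaining 90% of variance, two-way
  species × sex MANOVA with automatic sex-stratified reanalysis when the
  interaction is significant.
* **Disparity** — Procrustes variance per group, with residual-
  randomization permutation tests of pairwise differences.
* **Size and allometry** — ANOVA and pairwise t-tests on log₁₀ centroid
  size; multivariate regression of shape on log size (permutation R²);
  RRPP test of allometric-slope homogeneity among groups.
* **Transgression and dominance** — from the Euclidean distances between
  group mean shapes (D = donkey, Ho = horse, Hy = hybrid):

  transgression % = (d\_DHy + d\_HoHy − d\_DHo) · 100 / d\_DHo

  dominance % = (m − d\_DHy) · 100 / m, m = (d\_DHy + d\_HoHy)/2

  Transgression is 0 when the hybrid mean lies on the parental segment;
  dominance is +100 at the donkey mean and −100 at the horse mean.
  Bootstrap percentile intervals quantify uncertainty.
* **Integration** — two-block PLS between bone pairs (serial homologs,
  within-limb adjacent bones, functional equivalents): rPLS, permutation
  significance with a per-bone familywise Bonferroni rule, standardized
  effect sizes z (Fisher-transformed rPLS studentized against its
  permutation null) and two-sample z comparisons between groups.

The synthetic generator (`morphohybrid.synthetic`) emulates two parent
species plus hybrids with controllable divergence, hybrid placement
(fraction *f* along the parent axis, orthogonal transgressive offset *t*),
noise, allometry, sex effects and planted inter-bone integration — and
records closed-form expected index values for every bone.
`docs/methods.md` documents all models, conventions and limitations.

## Worked example

Generate a study mirroring a museum sample of 101 skeletons (42 horses, 38
donkeys, 21 hybrids) with hybrids placed at *f* = 0.45, *t* = 0.4
(expected transgression 28.2%, dominance +6.1% toward donkeys), then
estimate the indices for one bone:

```python
import morphohybrid as mh

spec = mh.GeneratorSpec(seed=1)
dataset, truth = mh.generate_study(spec)

aligned = mh.gpa(dataset.configurations_for_bone("humerus"), bone_id="humerus")
res = mh.hybrid_indices(aligned.shape_variables,
                        dataset.labels_for_bone("humerus"))
print(f"transgression {res.transgression_pct:.1f}%  "
      f"(expected {truth.expected_transgression['humerus']:.1f}%)")
print(f"dominance    {res.dominance_pct:+.1f}%  "
      f"(expected {truth.expected_dominance['humerus']:+.1f}%)")
```

```
transgression 28.4%  (expected 28.2%)
dominance    +6.3%  (expected +6.1%)
```

The hybrid humerus mean sits ~28% of the inter-parent distance outside the
parental segment (transgressive), slightly closer to the donkey mean than
to the horse mean — recovered within a fraction of a percentage point of
the generating truth at n = 21 hybrids.

The numbered scripts under `analysis/` run the full narrative on the
16-bone reference study (script 01 regenerates the data under `scratch/`,
the rest write tables under `results/`):

```sh
python analysis/01_simulate_study.py   # 101 specimens x 16 bones + truth
python analysis/02_shape_spaces.py     # GPA, PCA, MANOVAs, disparity
python analysis/03_size_allometry.py   # size ANOVA, allometry, slope tests
python analysis/04_transgression_dominance.py
python analysis/05_integration_network.py
```

On the reference study these print, among other things: all pairwise group
MANOVAs significant after Bonferroni; mean |estimate − expectation| of
0.15 pp for transgression across the 16 bones; slope parallelism supported
for 16/16 bones; mean rPLS of 0.86 on serial-homolog pairs.

The same pipeline runs on real data from the command line:

```sh
morphohybrid simulate --seed 1 --out study/        # or your own TPS/NTS/CSV
morphohybrid run --config config.yaml
morphohybrid hybrid-indices study/ --bone humerus --n-boot 999
```

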