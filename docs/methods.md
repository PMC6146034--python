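# Methods

## The design and its analysis model

The package analyses a paired two-compartment design: each of *n* animals
contributes one cecal and one fecal sample, and animals additionally carry
between-animal factors (feeding regime, size class). All per-feature
inference is built on the within-animal differences
`d_i = cecum_i − feces_i`, which removes every animal-level effect —
including the feeding regime, which is constant within an animal and
therefore confounded with the animal block. The pipeline handles that
confounding explicitly rather than silently: the origin test is run
within animals, and the regime main effect is only ever reported from a
between-animal model on animal means, flagged as such.

### Paired bootstrap-F test

For one feature the origin effect is `mean(d)` with standard error
`sd(d)/√n`, and its F statistic is `F = n·mean(d)²/var(d)`. This is
algebraically identical to the extra-sum-of-squares F for the origin term
in the least-squares fit `abundance ~ animal + origin` (verified to 1e-9
against an independent linear-model oracle in the test suite). Instead of
a theoretical F reference distribution, an empirical null is built by
resampling the *centered* differences `{d_i − mean(d)}` with replacement
B times (default 1,000) and recomputing the statistic; the p-value is the
proportion of resamples with `F* ≥ F` (ties count toward the numerator).
Centered-difference resampling is the standard bootstrap null for a
paired mean: it preserves the observed within-pair noise distribution
while imposing a zero origin effect. An alternative `add_one` rule,
`(# + 1)/(B + 1)`, avoids exact-zero p-values.

Degenerate inputs are flagged rather than propagated: zero variance of
the differences yields `F = +inf` when the mean is nonzero (certainty)
and `F = 0` when all differences vanish; the corresponding p-values are 0
and 1 with a warning.

P-values are corrected per feature family (OTU, genus, phylum runs are
separate families) by Benjamini–Hochberg step-up, with significance
declared at FDR 0.05. OTU-level tests run on *linear* CSS abundances —
effect estimates are then in CSS units — and rank-level tests on relative
abundances computed from the raw filtered counts; a log2(x+1) variant of
the CSS table is available behind a flag.

Each feature draws its bootstrap resamples from an RNG substream keyed on
the global seed and a CRC-32 hash of the feature id, so results are
reproducible and independent of feature order.

### CSS normalization

For sample *j* with *m* nonzero counts and quantile level *l*, the
reference quantile `q_j` is the `ceil(l·m)`-th order statistic of the
nonzero counts and the scaling factor `s_j` sums **all** counts ≤ `q_j`;
abundances are `count/s_j × N` with `N = 1000` by default. Quantiles are
taken over nonzero counts only, otherwise sparse samples collapse the
factor to ~0.

The level can be chosen adaptively: scan `l = 0.01 … 0.99` and take the
smallest level at which the per-sample quantiles disagree across samples
(median absolute deviation from the across-sample median, relative to
that median, above 0.1), falling back to 0.5 when no level is unstable.
Because count order statistics are integer-granular at the low tail —
the handful of singleton and doubleton reads can trip the relative
criterion while carrying no information about the heavy tail the method
is guarding against — the selected level is floored at the median level
(0.5, with a warning), mirroring the reference CSS implementation's
behavior of falling back to the median when its instability scan returns
an implausibly low percentile. On depth-heterogeneous tables this floor
is what keeps `s_j` tracking sequencing depth (correlation ≈ 0.94 on
synthetic tables at l = 0.5 versus negative correlation at l ≈ 0.02).

### Alpha diversity

Each sample is rarefied — subsampled without replacement — to a common
depth (default 15,000 reads; one seeded draw per sample, optionally
averaged over R draws), then Shannon diversity `H = −Σ p log2 p` (base 2;
base e available) and observed OTU richness are computed. The paired
ANOVA fits `index ~ animal + origin + origin×regime` with centered ±1/2
codings; origin and interaction are tested against the residual mean
square with `n − 2` residual degrees of freedom. With the interaction
omitted, F(origin) is exactly the squared paired t statistic. When only
one regime is present the interaction column is collinear with origin
and is dropped automatically.

### Ordination

Weighted UniFrac sums branch lengths weighted by the absolute difference
in the fraction of each sample's total abundance descending from the
branch; because it is computed on proportions it is invariant to each
sample's depth and accepts real-valued (CSS) tables. The implementation
accumulates per-branch descendant proportions in one postorder pass and
evaluates all pairs as a branch-length-weighted Manhattan distance; it is
cross-checked in the tests against an exhaustive per-branch oracle and
against scikit-bio on integer tables. The raw (unnormalized) form is the
default, matching the QIIME-1 convention; the normalized variant
(dividing by `Σ b_i(p_A(i)+p_B(i))`) is a flag. By default the pipeline
feeds CSS abundances converted to proportions.

PCoA Gower-centers the squared distances, `B = −½·J·(D∘D)·J`, and
eigendecomposes. Coordinates are eigenvectors scaled by `√λ` for positive
eigenvalues only; negative eigenvalues (non-Euclidean mass) are reported
but never embedded, and explained-variance fractions are computed over
the positive spectrum.

The multilevel decomposition subtracts from each sample its animal's
two-sample mean profile. The deviation is computed directly as
`±(x_C − x_F)/2`, which makes the two rows of an animal cancel *exactly*
in floating point and makes the within/between sum-of-squares split an
identity. Paired PCA is the SVD of this (column-centered) within matrix;
with complete pairs the column means are already zero and the two samples
of an animal score as exact mirror images.

### Multilevel sparse PLS-DA

The origin labels are one-hot encoded into Y; X is the within-animal
deviation matrix, column-centered and (by default) unit-variance scaled,
mixOmics-style. Per component: the leading singular pair (u, v) of
`M = Xᵀ Y` is found by power iteration started from the largest-norm
column of M (deterministic, no random initialization); u is
soft-thresholded so that exactly `keepX` entries survive — the threshold
is the largest excluded magnitude, ranking ties are broken by feature
order, and a survivor tied with the threshold keeps a vanishing nonzero
magnitude so the support size is exact — then renormalized. Variates are
`ξ = X u` and `ω = Y v`; both X and Y are deflated by regressing on ξ
(regression mode, asymmetric). With `keepX = p` the procedure reduces to
dense PLS-DA and matches an independent NIPALS implementation to 1e-6.

Component defaults are `keepX = (70, 50)` over two components. Explained
X-variance per component is `‖ξ c'‖²_F / ‖X₁‖²_F` with
`c = Xᵀξ/(ξᵀξ)`, equal to the drop in residual sum of squares at each
deflation. Selected features are assigned to the class (cecum or feces)
with the larger mean processed abundance. No cross-validated tuning of
`keepX` is performed; classification of new samples is out of scope.

## The synthetic-data generator

`generate_dataset` emulates the processed output of the paired design.
For animal *i*, OTU *k*, origin *o*:

```
eta_ik(o) = base_k + a_ik + delta_k·I(o = cecum) + gamma_k·I(restricted)
```

- `base_k ~ Normal(0, base_log_sd)` on the log scale (log-normal
  baselines). The default `base_log_sd = 2.0` is calibrated against the
  emulated study's per-sample richness: with 596 OTUs it yields ~480–520
  of them detected in a 40,000-read sample and ~430–460 after
  rarefaction to 15,000 reads, matching the reported 482 (range 411–541)
  and ~431.
- `a_ik ~ Normal(0, animal_sd)` is drawn per animal *and* OTU and shared
  by the animal's two samples. A scalar per-animal shift would cancel in
  the compositional allocation below; a per-OTU animal effect is what
  actually induces the within-animal correlation the paired design
  exploits. Default SD 0.25.
- `delta_k` is the planted origin effect: nonzero for a
  `frac_differential` subset (default 30%, the fraction of OTUs the
  emulated study called differential), magnitude `origin_effect_size`
  with random sign so both compartments harbour overrepresented OTUs.
- `gamma_k` is a feeding-regime effect applied to a designated 20% OTU
  subset (recorded in the ground truth). Applied to all OTUs it would
  cancel in the allocation; restricting it to a subset makes the
  confounded regime factor actually visible to the between-animal tests.
- Counts: a library size is drawn uniformly from `depth_range` (default
  16,415–68,080 reads, the emulated study's printed range) and allocated
  by a gamma-multinomial scheme — per-OTU gamma intensities with shape
  `dispersion` around `exp(eta)`, normalized and fed to a multinomial.
  This is negative-binomial-style overdispersion conditioned on the
  library size, so column totals land exactly in range.

The per-sample log-intensity noise SD implied by the gamma shape is
`sqrt(trigamma(dispersion))` (`noise_sd`); the within-pair difference
noise SD is `√2` times that (`paired_noise_sd`). Planted effects are
naturally expressed as multiples of the paired noise SD — the paired
standardized effect (Cohen's d_z for a paired design is the mean
difference over the SD of differences) — and an effect of
`1.5 × paired_noise_sd` is a d_z of 1.5. The default
`origin_effect_size = 0.5` (natural-log scale, ≈ 1.65-fold) is a
moderate effect detectable but not saturating at 21 pairs. The default
`dispersion = 10` (noise SD ≈ 0.32) reflects the residual within-animal
variation left after animal effects are modelled separately.

The phylogeny is a random rooted binary tree over the OTUs (uniform
pairwise joins, Exp(1) branch lengths). Taxonomy strings are synthetic
Greengenes-style lineages assigned by clade — tips in tree order are
sliced into 8 phyla and ~24 genus blocks — with assignment depth
mimicking short-read resolution: ~3% of OTUs entirely unassigned, ~50%
resolved to family, ~20% to genus. Metadata assigns regimes and size
classes at the emulated study's frequencies (11 restricted / 10 ad
libitum at n = 21).

All draws flow from one seeded generator in a fixed documented order, so
a seed pins the dataset bit-exactly.

### What the generator does and does not emulate

It reproduces the design structure (pairing, confounded regime,
depth variation, rank-abundance skew, overdispersed counts, planted
compositional effects) — the features the statistical machinery is
sensitive to. It does **not** emulate taxonomic misassignment, chimeras,
phylogenetic signal in the effects (planted OTUs are not clustered on
the tree), zero-inflation beyond what the gamma-multinomial produces, or
any real community structure. Passing tests therefore demonstrate that
the *pipeline* is correct and calibrated under the design's assumptions,
not that any particular biological conclusion transfers to real data.

## Problem sizes and numerical conventions

The statistical acceptance checks run at the design's own scale: null
calibration with 21 pairs × 500 features × 1,000 resamples; recovery
with 20% of 300 features planted at d_z 1.5 over 10 replicates; sPLS-DA
recovery at 50 pairs × 100 features over 20 replicates; selection/test
overlap at the full 596-OTU scale. These sizes keep every check
statistically meaningful while completing in seconds.

- Filters use strict "less than" for removal (a 5,000-read sample
  survives a 5,000 minimum; an OTU at exactly 0.01% survives), and
  prevalence uses `ceil(fraction × n_samples)` — the conservative
  reading of "at least 5% of samples".
- Rare-OTU filtering is computed after sample filtering (sample level
  first, then OTU level), and prevalence filtering after pairing, only
  for the OTU-level test set.
- Ties in bootstrap resampling (`F* = F`) count as exceedances; BH
  q-values come from statsmodels.
- PCoA treats eigenvalues below `max(λ)·1e-12` as zero; symmetry is
  enforced to 1e-8 on input and exactly thereafter.
- The pipeline's run log contains no wall-clock times (timings go to
  stderr only), which is what makes report bundles byte-reproducible.

## Known limitations

- The bootstrap null resamples centered paired differences; residual
  resampling from the full linear model would coincide asymptotically
  but can differ at very small n.
- With B = 1,000 the smallest attainable p-value under the `proportion`
  rule is 0; the BH step then treats several features as exactly tied at
  zero. The `add_one` rule bounds p away from zero at the cost of a
  slight conservatism.
- The adaptive CSS level on heterogeneous-depth integer tables almost
  always hits the median floor; the adaptivity matters mainly for tables
  with genuinely divergent heavy tails.
- sPLS-DA explained-variance fractions are not monotone across
  components (components maximize covariance with the response, not
  X-variance); this is expected, not a defect.
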