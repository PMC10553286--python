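# Methods

This note documents the models and procedures implemented in
`eatrhythm`, the assumptions behind them, and the choices made where the
underlying methodology left the design open.

## The Eating Regularity Index

Parent-reported meal start times are recorded at 15-minute resolution.
Each assessment day becomes a binary vector of `E = 1440 / 15 = 96`
epochs with a 1 in every epoch containing at least one meal start (the
vector is binary: coincident meals in one epoch still give a 1).  A
simple moving average (SMA) of width `k` epochs is applied twice.  One
pass replaces each entry by the mean of the window
`[t − ⌊(k−1)/2⌋, t + ⌈(k−1)/2⌉]`; two passes turn a single meal into a
triangular bump of width `2k − 1` epochs whose weights decay with
distance from the meal.  Smoothing is *circular*: windows wrap across
midnight, so a meal at 00:00 is a near neighbour of one at 23:45.  Total
mass is conserved (`Σ smoothed = Σ binary`).

For one subject at one assessment with days `d_1 … d_n`, the ERI is the
mean cosine similarity over all `C(n, 2)` pairs of smoothed profiles:

    ERI = (2 / (n(n−1))) Σ_{i<j} ⟨v_i, v_j⟩ / (‖v_i‖ ‖v_j‖)

Because profiles are non-negative, every pairwise cosine — and hence the
ERI — lies in [0, 1]: 1 means identical meal timing on every day, values
near 0 mean no timing overlap beyond the smoothing width.  The ERI is
invariant to day reordering and to a common circular rotation of all
days.

Handling rules:

* days with no recorded meal are dropped (cosine similarity is undefined
  for a zero vector) and the drop is recorded;
* subject × assessments with fewer than `min_days = 5` remaining days
  are excluded from analysis;
* `min_days < 2` is rejected (no pairs exist).

Two meal covariates accompany the index, computed over the retained
days: the mean number of meals per day, and the fraction of meals
starting in the half-open daytime window [07:00, 19:00) (half-open so a
19:00 meal is not counted twice conceptually; the boundary choice moves
the ratio by at most one meal).

**SMA width.**  `k` is a tuning constant.  `select_sma_interval`
reproduces the selection procedure: for every candidate width and age
group, compute all subjects' ERIs and the between-subject standard
deviation; the chosen width is the one attaining the per-age maximum SD
in the most age groups, ties resolving to the smaller width (smaller =
less smoothing = closer to the raw data).  The package default is
`k = 4` (a one-hour window), the width this procedure favours on
realistic cohorts.

Open interpretation points, fixed as follows: smoothing wraps at
midnight (the alternative, zero padding, penalises night feeds
asymmetrically); both SMA passes use the same width; even-width windows
are centred left-biased (⌊·⌋/⌈·⌉ split) — the choice shifts all profiles
of a subject identically and therefore cancels in day-pair comparisons;
"fewer than 5 days" is read as fewer than five *retained* diary days,
not necessarily consecutive calendar days.

## Synthetic cohorts

The generator exists so every downstream stage can be tested against a
known truth.  It emulates a longitudinal infant cohort assessed at 3, 6
and 12 months with 11 diary days per assessment.

* **Latent regularity.**  Each subject has a trait `r ~ Beta(5, 2)`
  (right-shifted: most infants moderately-to-highly regular).  A
  template meal schedule per age (mean meals/day 8.0 → 6.5 → 5.0 from 3
  to 12 months; feeds around the clock at 3 months, within a waking
  window later) is perturbed each day by Gaussian jitter with standard
  deviation `σ(r)` minutes, plus independent meal add/drop events
  (p = 0.05 each), then snapped (floor) to the epoch grid modulo 24 h.
* **Jitter-map calibration.**  The default map `σ(r)` is built by
  estimating `E[pairwise cosine | σ]` by Monte Carlo on a grid of jitter
  SDs — with the very same template/day machinery, including add/drop —
  and inverting the resulting decreasing curve.  Consequently
  `E[ERI | r] ≈ r`: the latent trait and the measured index share one
  scale, which is what makes "the configured slope is recoverable from a
  regression on the ERI" a well-posed statement.  The calibration uses a
  fixed internal seed and is cached; it is a deterministic package
  constant.  On a 300-subject cohort the realised calibration gives
  ERI-on-r slope ≈ 1.00, intercept ≈ 0.00, r ≈ 0.98.
* **Sleep composites.**  Five composites (Sleep Activity, Day, Night,
  Timing, Variability) are linear in `r` with configurable true slopes
  (defaults −1.7, 0, 0, −3.5, −2.0 — regularity-coupled for the three
  composites where an association is plausible, null for the two
  duration composites), a subject random intercept (SD 0.5), residual
  noise (SD 1), small fixed age and Structure-score effects, sex
  ~ Bernoulli(1/2), breastfeeding 1 for everyone at 3 months and
  declining monotonically per subject afterwards, and a parental
  Structure score correlated with `r` (default ρ = 0.3).
* **Microbiota.**  Counts are Dirichlet-multinomial (depth 20 000) over
  a 21-genus panel spanning the four dominant infant phyla.  Two base
  compositions define the enterotypes (A: *Bifidobacterium*-dominated,
  B: *Bacteroides*-dominated); membership shifts from A to B with age
  (P(B) = 0.25/0.45/0.70).  With age the Dirichlet concentration rises
  (25/50/100) and the base mixes towards an even community
  (weight 0.10/0.25/0.45) in which seven "late-colonizer" genera absent
  from the milk-fed gut appear — so richness, Shannon diversity and
  community maturity all increase with age.
* **Mediation modes.**  `none`: community structure depends on age only;
  any marker–sleep association given `r` is spurious.  `full`: the
  evenness weight is driven by `r`, and the designated composite (Sleep
  Variability by default) is generated from the *realised* Shannon
  diversity of the subject's sample rather than from `r` — the marker
  carries the whole effect.  `partial`: half direct, half through the
  marker.
* **Streams.**  Random-number streams are partitioned per subject and
  stage (`SeedSequence((seed, subject, stage))`), so enlarging a cohort
  never changes existing subjects' data.

What the generator does *not* emulate: actigraphy and the derivation of
the composites from raw sleep variables, sequencing noise beyond
multinomial sampling (no chimeras, contamination or compositional
artefacts), diary non-compliance patterns, and any true age-trend in
`r` itself.  Passing tests therefore certify the statistical machinery
under the stated generative assumptions, not the field behaviour of the
instruments.  The meal-time jitter is Gaussian purely as a stand-in; the
diary literature gives no distributional form.

## Maturational markers of the gut microbiota

* **Alpha diversity** per sample: observed species (count of taxa with
  reads), Shannon entropy in *natural* log units (base matters: ln 4 ≈
  1.386 vs log2 4 = 2), and Chao1 in the bias-corrected form
  `S_obs + F1(F1−1)/(2(F2+1))`, which remains defined with no doubletons.
* **Weighted UniFrac** (normalised): `Σ_l b_l |A_l − B_l| / Σ_l b_l
  (A_l + B_l)` over branches `l` with length `b_l` and descending
  relative abundances `A_l`, `B_l`; computed by scikit-bio, checked
  in tests against an explicit branch-enumeration oracle.  Requires a
  rooted tree with branch lengths on every edge.
* **Enterotypes**: deterministic k-medoids (PAM BUILD + SWAP, ties to
  the smaller index) at k = 2 on the UniFrac matrix.  Quality is scored
  by a distance-based Calinski–Harabasz index (within-cluster sums of
  squares via the pairwise-distance identity, so no coordinates are
  needed) and by Tibshirani–Walther prediction strength with one seeded
  two-fold split (worst-cluster co-membership agreement, averaged over
  the two directions).  The cluster with the higher mean
  *Bifidobacterium* relative abundance is labelled A, the other B.
* **Bacterial maturation index**: a random-forest regression
  (500 trees) of chronological age on genus-level relative abundances.
  Predictions for training samples are out-of-bag, so the index
  (predicted − actual age, months) is not inflated by memorisation and
  is approximately centred on zero over the training distribution.
  Positive values = a community more mature than expected for age.
  Genus-level features and OOB evaluation are package choices; the
  marker's provenance does not fix either.
* **Phylum table**: counts collapsed to Firmicutes, Bacteroidetes,
  Actinobacteria, Proteobacteria and "other" (unannotated taxa are
  routed to "other" with a warning), renormalised per sample.

## Association models

For each of the five sleep composites, a linear mixed model regresses
the composite on the ERI plus the control covariates — sex (0/1),
exact age (months), breastfeeding (0/1), mean meals per day, daytime
meal ratio, and the parental Structure score — with a per-subject
random intercept, optionally plus a random ERI slope.  The random
structure is selected by AIC between the two variants fitted by maximum
likelihood (ML, since REML likelihoods are not comparable across fixed
structures and ML AICs are the standard basis for random-structure
comparison); BIC is reported and any disagreement flagged; a
non-converging variant is disqualified.  The chosen model is refit by
REML for inference.

Fixed-effect t-tests use a Satterthwaite-style approximation for the
denominator degrees of freedom: with variance parameters θ = (σ²,
vech G), the df for coefficient i is `2 v_i² / (g_iᵀ W g_i)` where
`v_i = [ (Xᵀ V(θ)⁻¹ X)⁻¹ ]_{ii}`, `g_i = ∂v_i/∂θ` (central
differences), and `W` is the inverse observed information of the REML
log-likelihood in θ (numerical Hessian).  The implementation agrees
with `lmerTest` to about three decimals on estimates, SEs, df and
p-values (cross-checked in the test suite through `Rscript`).  With one
observation per subject the variance components are unidentifiable; the
fit falls back to ordinary least squares with residual df and a warning.

Predictors enter untransformed; rows with any missing model variable
are dropped listwise (counted and logged); a rank-deficient design is
fatal with the aliased columns named.  The significance level is 0.05
throughout.

Per-age analyses use ordinary linear models on single-age slices with
the same fixed effects; breastfeeding is dropped from the 3-month model
where it is constant (all infants primarily breastfed).  The age trend
of the ERI itself is a one-way ANOVA across the three assessment ages
with Tukey HSD post-hoc comparisons at family-wise 95% confidence.

Known limitation: because the ERI estimates `r` from 11 diary days, it
carries measurement error (per-observation SD ≈ 0.037 under default
conditions, reliability ≈ 0.95 against Beta(5, 2) trait variance).
Regression of a composite on the ERI is therefore attenuated by ~5–8%
relative to the configured slope on `r`; the test suite bounds this by
also regressing on the true trait.  No correction (e.g. regression
calibration) is applied, mirroring standard practice for such indices.

## Mediation

Baron & Kenny causal steps, judged at α = 0.05, for every pair of
(marker, sleep composite) with the ERI as exposure:

1. `Y ~ X + covariates` — no association ⇒ verdict `not_computed`
   (nothing to mediate; the full mediation model is not computed);
2. `M ~ X + covariates` — failure ⇒ `no_mediation`;
3. `Y ~ M + X + covariates`, M term — failure ⇒ `no_mediation`;
4. the X term of the same model: non-significant ⇒ `full`; significant
   but attenuated versus step 1 ⇒ `partial`; otherwise `no_mediation`.

All steps include the subject random intercept (the steps are refits of
the same mixed-model machinery; step 1 is numerically identical to the
corresponding association model).  Steps 3 and 4 share one fit.  The
screen caches step-1 fits per composite and step-2 fits per marker, so
its cost is linear rather than quadratic in practice.  No
multiple-testing correction is applied across the screen by default
(matching the single-test α); a Benjamini–Hochberg column is available
on request.  A Sobel z for the indirect effect is attached as a labelled
extra and never influences the verdict.  Binary mediators (enterotype
0/1) are modelled linearly (a linear probability model for step 2);
constant or exposure-collinear mediators are rejected.

## Numerical and testing choices

* Cosines of smoothed profiles are clipped to [0, 1] against −1e−16
  round-off; all closed-form checks run at 1e−10 or tighter.
* Finite-difference steps for the Satterthwaite machinery are
  `max(1e−4 |θ|, 1e−4 σ²)`; a non-positive-definite information matrix
  falls back to residual df.
* The heavy statistical guarantees run at stated sizes chosen as the
  package's simulation budget: slope recovery with 100 replicates of
  300 subjects × 3 ages; type-I error with 1000 fits (40 cohorts of 100
  subjects × 25 independent outcome redraws — valid under the null
  because the outcome is independent of the design); mediation
  discrimination with 15 replicates per generative mode at n = 150.
* Determinism: every stochastic component takes an explicit seed; the
  pipeline writes byte-identical outputs under a fixed seed.
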