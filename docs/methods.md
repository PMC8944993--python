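# Methods

## Scope and purpose

`sgann` implements a first-trimester SGA/AGA prediction pipeline built
around a shallow feed-forward network, together with the synthetic cohort
machinery needed to exercise it end to end.  The original clinical records
are not publicly available, so every quantitative claim the package makes
is computed on synthetic cohorts whose *marginal* structure is calibrated
to the published group statistics of a 77-woman cohort (14 SGA, 63 AGA),
or on *oracle* cohorts whose targets come from a known ground-truth
network.  This section records the model, the generator, the numerical
choices, and what the passing tests do and do not establish.

## The synthetic cohort generator

Each of the 14 maternal features carries per-group (SGA / AGA) parameters:
mean ± SD for continuous features, a "yes" probability for the binary
multivitamin feature (SGA 4/14, AGA 24/63).  Continuous features are drawn
from a **truncated normal** by rejection sampling from the parent normal —
exact, at the cost of speed that is irrelevant at this scale.  The
truncation window of a group is `[mean − 4·SD, mean + 4·SD]` intersected
with hard physiological limits (age ≥ 18 years, pBMI ≥ 13 kg/m², fat mass
in [0, 100] %, concentrations ≥ 0, gestational age at birth in [22, 43]
weeks).  Features are sampled independently by default, because only
marginals are published; a user-supplied correlation matrix induces
dependence through a Gaussian copula (correlated standard normals mapped
through each marginal's truncated-normal quantile function).

Two generator behaviours deserve emphasis:

* **Heavy floors shift moments.**  For most features the ±4 SD window is
  effectively untruncated and the sampled moments match the printed values
  (the calibration tests verify sample moments against the *analytic*
  truncated-normal moments via `scipy.stats.truncnorm`, and additionally
  against the printed means for the mildly truncated features such as age
  and fat mass).  MDA is the exception: its printed SD (≈180 pmol/mg at a
  mean of ≈153) places the zero floor at z ≈ −0.85, so the truncated mean
  sits near 215 and the SD near 140.  This is a property of any
  non-negative sampler honouring those marginal parameters, and is
  documented rather than "corrected": downstream stages are insensitive to
  it, since the network learns whatever distribution it is given.
* **Gestational age at birth** is not printed as mean ± SD.  The package
  uses SGA 38.5 ± 1.4 and AGA 38.7 ± 1.4 weeks, chosen so the implied
  preterm (<37 weeks) probabilities match the printed frequencies
  (SGA 2/14 ≈ 14.3%, AGA 7/63 ≈ 11.1%) in expectation; the preterm
  fraction is honoured in expectation only, never enforced per draw.

### Oracle mode

Oracle cohorts make trainer correctness measurable.  Features are drawn
exactly as above (the config's group counts set the mixture); the cohort
is min–max scaled on all rows; a ground-truth 14–h–1 network produces the
noiseless output; the codified target adds Gaussian noise of configurable
SD, clipped to [0, 1]; the label is the interval classification of the
noiseless output (a value below the AGA band maps to SGA — it is more
SGA-leaning than the SGA band itself).  When no truth is supplied, a
seeded network with weights uniform on [−2, 2] is drawn and its output
layer affinely rescaled so that the 10th/90th percentiles of the
pre-sigmoid activation map to logit(0.48)/logit(0.95).  This guarantees
the noiseless outputs span both classification intervals with substantial
mass in each, so every partition of a ~150-row cohort contains both
classes; because the rescaling only transforms `Wo` and `b2`, the truth
remains a member of the modelled family.

## Preprocessing

Inputs are scaled by `x′ = 0.8·(x − x_min)/(x_max − x_min) + 0.1`.  The
bounds are fitted **on the training partition only** by default, and
held-out values falling outside the fitted range are clipped to
[0.1, 0.9]; this is the leakage-free variant.  Fitting on all rows and
linear extrapolation are both available as flags, since the original
procedure is ambiguous on both points.  The binary multivitamin feature is
normalised with fixed bounds (0, 1), mapping no/yes to 0.1/0.9 regardless
of which categories the fitting rows contained.  A feature that is
constant on the fitting rows makes the map undefined and raises an error
naming the feature.  Outcomes codify as SGA → 0.5, AGA → 1.0.

Splitting assigns each row to exactly one of train / validation /
independent-test by a seeded permutation, with per-partition counts given
by largest-remainder rounding of the fractions.  The published fractions
(75% + 15% + 15%) exceed 100%; the default here is **(0.70, 0.15, 0.15)**,
preserving a majority training share and two 15%-scale held-out sets, with
(0.75, 0.15, 0.10) selectable.

## Training

Levenberg–Marquardt minimises the RMSE between network output and target.
Per epoch: the analytic residual Jacobian (all 14h + 2h + 1 parameters) is
assembled by backpropagation; the damped step solves
`(JᵀJ + μI)δ = −Jᵀr` via least squares on the stacked system
`[J; √μ·I]δ = [−r; 0]` (a QR/SVD route, stable when `JᵀJ` is
ill-conditioned near convergence); an error-reducing step is accepted and
μ is multiplied by 0.1, otherwise μ is multiplied by 10 and the step
retried.  Stopping: RMSE goal (10⁻¹² by default), epoch cap (1000), or
μ exceeding 10¹⁰ (no improving step exists — in practice the usual exit at
a local minimum).  Optional early stopping on validation RMSE exists but
is off by default; the goal + epoch-cap rule is the default because the
original procedure states those two parameters explicitly.

The stated "learning rate of 0.001" is interpreted as the initial damping
μ₀ — the conventional reading for an LM trainer, which has no classical
learning rate.  Weight initialisation is uniform on [−0.5, 0.5] from the
config seed (Nguyen–Widrow available behind a flag); no initialisation
scheme is stated in the source, and the multi-restart selection makes the
choice uncritical.  Residuals are defined on the post-logsig output, since
RMSE is stated on predicted-vs-actual values.  Restart budgets are
desk-scale — 20 restarts of ≤1000 epochs for the headline experiments,
fewer in fast unit tests — the package's position being that the
*selection rule* (best validation RMSE; ties toward smaller hidden layer,
then lower seed) is the method, not the budget.  The architecture search
grows `h` from 1 with that rule.

## Evaluation

Agreement between targets and outputs: Pearson R, R² and the OLS line of
predicted on actual, plus two-sided Student *t*-tests of slope = 1 and
intercept = 0 with n − 2 degrees of freedom at 99.8% confidence (α =
0.002); "pass" means neither null is rejected, i.e. the fit is
statistically indistinguishable from the identity.  Classification takes
**SGA as the positive class** throughout.  Outputs are binarised through
the intervals; because the bands are stated at two-decimal resolution, the
output is rounded to two decimals first (resolving the (0.79, 0.8) gap),
and a value below the SGA band counts as an SGA call.  Ratios with a zero
denominator (PPV with no positive calls) are NaN — "undefined" — and are
excluded from aggregates rather than silently zeroed.  AUROC is the
rank-based (Mann–Whitney) formulation with midrank ties; network outputs
are negated before ranking, since *lower* outputs indicate SGA.  k-fold CV
shuffles rows into folds differing in size by at most one, holds each fold
out exactly once, and aggregates per-fold reports as mean ± SD.

## Garson feature importance

For input *i* and hidden unit *j*, the contribution is
`c_ij = |Wi[j,i]|·|Wo[j]|`; contributions are normalised within each
hidden unit, summed over units, and rescaled to percentages summing
to 100.  Biases are excluded (the classic formulation uses connection
weights only) and signs are discarded, so importances are magnitudes with
no direction.  A hidden unit with all-zero incoming weights contributes
zero shares rather than dividing by zero; the degenerate all-zero network
reports a flat 100/14% per feature.  Ties in ranking break by canonical
feature order, making results stable across runs.  The published ranking
itself (CP 12.7%, GWG 10.8%, …) depends on the unavailable trained weights
and is therefore not a reproducible quantity; the implementation is
instead verified by hand-computed cases, permutation equivariance, and
invariance to positive rescaling of the output weights.

## Simulator

A trained model travels as a JSON bundle — weights, biases, per-feature
normalization bounds, output intervals, feature order — serialised at full
float precision so a load/export round trip reproduces forward outputs
bit-for-bit; a flat CSV of the same numbers supports spreadsheet
embedding.  Scenario scoring is the pure function normalize → forward →
classify.  The SGA band's lower bound defaults to 0.4 (the figure-caption
value; the narrative's 0.45 variant is configurable).  Preset scenarios
fix pBMI at 24 kg/m² and cross three axes: GWG adequate (1.5 kg) vs
excessive (3.5 kg, threshold > 2.0 kg), vitamin D adequate (32 ng/mL,
> 30) vs deficient (15 ng/mL, < 20), and redox balanced (CP/MDA/TAC at
pooled cohort means) vs imbalanced (CP and MDA one pooled SD up, TAC one
SD down); remaining features sit at the pooled cohort means.  Exploratory
pBMI 35 variants exist behind a flag and carry no claims.

## Problem sizes and determinism

The headline recovery experiment uses n = 154 (the published 14:63 mixture
doubled, for stable held-out partitions of ~23 rows), noise SD 0.02,
h = 2, 20 restarts, ≤1000 epochs, 70/15/15 split — it runs in seconds.
Calibration checks use 100,000-row mixtures.  Every random stage (cohort
draw, truth network, split, restart initialisations) derives its sub-seed
from one master seed via `numpy` `SeedSequence`, so all experiments are
exactly reproducible and byte-identical across runs.

## Limitations

* Synthetic cohorts reproduce published *marginals*, not the joint
  distribution of real maternal physiology; feature independence is a
  simplification (the copula hook exists but no published correlations are
  available to drive it).  Passing recovery tests therefore demonstrate
  correctness of the pipeline — generator, scaling, trainer, metrics — not
  clinical validity of any trained model.
* Oracle-recovery performance bounds what the trainer can do when the
  truth is in the model family; real outcome-generating processes are not.
* SGA/AGA labels are generated, never derived from birth-weight
  percentile standards; percentile classification is out of scope.
* MDA's truncated-normal moments deviate from the printed mean ± SD, as
  discussed above.
* No missing-data handling: the modelled cohort is complete-case.
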