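# Methods

This note documents the models and numerical conventions behind
`mitotick`: what each estimator computes, what the synthetic generator
does and does not emulate, and the design choices made where the design
was genuinely open.

## Mitotic-age scoring

The mitotic clock score of a sample is the unweighted mean beta over a
fixed clock CpG set (polycomb-group-target promoter CpGs that start
unmethylated and gain methylation with cell division). Missing clock CpGs
are dropped per sample (available-case mean) and the per-sample coverage
is reported; scoring refuses to run when less than `min_coverage`
(default 0.8) of the clock set is present in the matrix. The packaged
clock file is a clearly-labelled *synthetic* stand-in probe list — the
published 385-probe set ships with its source publication — and any
user-supplied list is accepted in the same format.

Weighted clocks compute `calibration(intercept + Σ w_j β_j)`; the
calibration is either the identity or the standard piecewise
log-linear inverse transform used by pan-tissue clocks
(`horvath:adult_age`), both strictly monotone.

**Acceleration measures.** All accelerations are ordinary-least-squares
residuals fitted on the full analysis sample (cases and controls jointly;
a control-only fit is available but not the default, since the analysis
population is the natural reference when case status is the outcome):

* AccelEpiTOC: mitotic score residualized on age;
* AgeAccel: a linear DNAm age residualized on age;
* IEAA: DNAm age residualized on age *and* cell-composition columns
  (composition-independent aging); zero-variance columns are dropped,
  rank-deficient designs are rejected with the aliased columns named;
* EEAA: an immune-weighted DNAm age (base clock plus configurable
  weighted cell abundances; the weights are recorded with the result and
  default to zero, i.e. a surrogate construction) residualized on age.

SD standardization uses the sample SD (n−1). Per-SD effect estimates are
therefore invariant to positive rescaling of the predictor.

## Reference-based deconvolution

Markers are chosen per cell type by the two-sample t statistic of that
type's purified samples against all others; the `n_per_type` (default 50)
most hyper- and hypomethylated CpGs per type form the union panel, and
the reference matrix holds per-type arithmetic means over that panel.

Proportions solve the constrained projection
`min ‖b − Rw‖² s.t. w ≥ 0` with `Σw = 1` (default) or `Σw ≤ 1`.
The solver is active-set non-negative least squares on an augmented
system: a penalty row of weight 1e4 enforces the sum constraint (the
inequality mode adds a non-negative slack component instead). The penalty
magnitude makes the constraint violation O(residual/1e4²), far below the
1e-6 agreement demanded of the solver in the test suite, where it is
checked against an independent Lawson–Hanson reimplementation and an
exhaustive simplex grid search. Per-sample residual norms are reported as
a fit diagnostic.

Count-style subsets (naive/exhausted CD8, naive CD4, plasmablasts) are
linear predictors `intercept + Σ w_j β_j` with user-supplied coefficient
files, flagged as surrogates: the published coefficients belong to their
source estimators and are not redistributed here.

## Statistical layer

* Complete-case analysis per model; categorical covariates dummy-coded
  against the most frequent level (deterministic tie-break by name).
* Logistic fits are Newton ML with |Δ loglik| < 1e-10; perfect separation
  is detected and raised, never silently diverged.
* Mixed models (cell-type panels, progression) use REML with Wald-z
  p-values — a deliberate simplification (no Satterthwaite df); fits that
  fail or go singular fall back to fixed-effects OLS with a warning.
  Progression models use a random intercept and random slope on time per
  subject by default; the acceleration × time coefficient is the yearly
  change in exam score per SD of acceleration.
* Stepwise selection is bidirectional greedy AIC from a locked model
  (exposure and design covariates are never dropped), ML fits on the
  complete-case intersection of all candidate columns so AICs are
  comparable, ties broken by term name, stopping when no move improves
  AIC by more than 1e-6. Note that with pure-noise candidates AIC admits
  each with probability P(χ²₁ > 2) ≈ 0.16; the selected set should be
  read as "sufficient", not minimal-unique.
* Correlation panels are pairwise-complete Pearson R with p-values from
  the t transform; partial correlations residualize both variables on the
  covariates first.

Technical-variation PCs are the leading SVD scores of the column-centered
sample × control-probe matrix (per-probe mean imputation first). Signs
are fixed by making each component's largest-magnitude loading positive,
so outputs are platform-independent.

## The synthetic generator

The generator exists to exercise the analysis under the structure it
assumes, with known truth. Its default parameters are the package's
study conditions and were fixed once by a documented Monte-Carlo
calibration; they are not test knobs.

**Division model.** Compartment k of a subject aged A has accumulated
`D_k = r_k · (A0 + κ·A) · frailty` effective divisions, with per-type
rates `r_k` (myeloid 0.7–0.9, lymphoid 2.2–2.7 divisions per adult-year
equivalent), a developmental expansion `A0 = 28.5` adult-year
equivalents, adult accrual scale `κ = 0.25`, and a mean-one lognormal
subject frailty (σ = 0.15) multiplying all rates. The developmental
offset is what lets a large purified-cell lineage gap (≈ 0.06–0.08 at
mean donor age 38) coexist with a weak adult age correlation of the
whole-blood score (R ≈ 0.27), as real blood shows; a purely linear-in-age
model cannot produce both. Clock CpGs start at baseline betas ≤ 0.05 and
gain `δ·D` each (δ = 0.001 per division), deterministically in
expectation — ticking noise enters only at measurement, as logit-normal
noise (σ = 0.05) clipped to [0.001, 0.999].

**Profiles and mixtures.** Each cell type carries a baseline methylome
with per-type discriminating marker blocks (granulocyte markers shared by
the neutrophil/eosinophil subtypes) and a genome-wide myeloid
hypomethylation of 0.02. Whole blood mixes the six circulating
populations with granulocyte-dominant Dirichlet proportions (mean ≈ 0.60
granulocytes, SD ≈ 0.13). Cases multiply division counts by 1.092 and
shift mean granulocyte fraction up by 0.088; these two constants were
calibrated jointly so the composition-adjusted association is a log-odds
of ≈ 0.75 per SD of acceleration while the unadjusted estimate is pulled
to null/protective — the confounding-by-composition reversal the analysis
is designed to expose. Two aging-tracker CpG blocks encode an
immune-weighted DNAm age (sharing the frailty factor, so its
acceleration couples to mitotic acceleration at partial R ≈ 0.27) and a
composition-independent DNAm age. Control probes carry batch (wave) and
continuous position structure only.

**Exam scores.** Patient trajectories are linear:
`score_it = β0 + b0i + (β_time + slope_per_sd·accel_i + b1i)·t + ε`,
with Gaussian random intercepts/slopes and residuals whose SDs are chosen
so the interaction SE at ≈ 330 patients × 3 visits matches the reporting
scale of the corresponding clinical instruments (≈ 0.02 for the
cognitive exam and tremor sub-score, ≈ 0.13 for the full motor exam);
slopes per SD default to −0.06 (cognitive), +0.19 (motor), +0.05
(tremor). Baseline scores are drawn as separate noisy measurements so
adjusting for them is well-posed.

**What the generator does not emulate** — and hence what passing tests do
not establish about real arrays: probe-level annotation and type-I/II
chemistry, preprocessing artifacts (the pipeline assumes normalized
betas), genetic-ancestry and smoking biology (those covariates are
independent noise here), progenitor-pool dynamics (the division model is
a reduced-form rate, a limitation the mitotic-clock literature itself
notes), and any cancer-tissue behaviour.

## Problem sizes and determinism

The validation suite runs the recovery analyses at the study scales the
design targets: cohorts of n = 1200 (100 replicates for the
masking-direction property), 50-sample mixtures at logit noise 0.01 for
deconvolution RMSE, 300 patients × 3 visits for progression, and 6 donors
× 8 cell types for lineage separation. `scripts/acceptance.py` reports
replicate-averaged estimates (3 panels, 12 cohorts, 16 visit sets) so
that single-draw Monte-Carlo noise does not dominate the headline
quantities. All randomness flows from one integer seed through named
sub-streams; identical config + seed reproduces outputs byte-for-byte,
and the pipeline manifest records the config hash to make that checkable.

## Known limitations

Wald-z inference for mixed models is anti-conservative at very small
subject counts (the purified-panel contrast has n = 6 subjects; its SE is
reported alongside). The equality-constrained projection is a penalty
approximation, exact to ~1e-8 in practice but not a true QP solve. The
EEAA construction is a configurable surrogate, not a reimplementation of
any published immune-weighted clock. GEO series-matrix support covers
only the data block, by design.
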