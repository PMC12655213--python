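# Methods

`mcubed` implements model-simulated model-based meta-analysis (M-cubed)
for population pharmacokinetics: published popPK analyses are transcribed
into machine-readable study descriptors (side 1), virtual patients and
drug concentrations are simulated from each study's own published model
and design (side 2), and a single integrated population model is
re-estimated on the pooled virtual data, with covariate selection,
replicated many times (side 3).  Vancomycin — a renally cleared antibiotic
under routine therapeutic drug monitoring, with hundreds of published
popPK models that each cover a narrow patient population — is the worked
case.

## Study descriptors and the plausibility screen

A descriptor records what a publication actually prints: per-covariate
summary statistics (mean ± SD, median with range, or median with
interquartile range; a flag marks creatinine clearance reported per
1.73 m² body surface area), the structural model (1–3 compartments,
volumes and inter-compartmental clearances), the clearance formula in
creatinine clearance (linear `a + b·CLcr` or power `a·CLcr^b`), variance
components (exponential between-subject variances ω², residual variance
σ² with kind), the dosing rule (maintenance dose/interval/infusion
duration, optional loading dose and renal-adjustment bands), and the
sampling design (tagged peak/random/trough windows and the average number
of samples per patient).

Every clearance model is screened at a reference CLcr of 50 mL/min, where
a typical vancomycin clearance is about 3 L/h: models yielding more than
6 or less than 1.5 L/h (a two-fold corridor) are classified implausible.
The corridor bounds themselves count as plausible — the published rule is
written with strict inequalities.

The packaged `vancomycin_studies.yaml` encodes the 19-study vancomycin
set: sample sizes, sex counts, covariate summaries, BSA-normalization
flags and disease labels are transcribed from the published demographics
table (sample sizes sum to 2266).  The per-study structural models,
variance components and dosing/sampling designs are **synthetic
stand-ins** (`unverified: true` in the file): their numeric values appear
only in the 19 original publications.  They are calibrated so the
non-elevated consensus clearance is ≈ 2.75 L/h at CLcr 75 mL/min, the
four conditions reported as PK-elevated (hematologic malignancy,
critically ill sepsis, post-craniotomy meningitis, sepsis/septic shock)
carry ≈ 1.88× that clearance, all models pass the plausibility screen,
and the structural mix is 10/8/1 one/two/three-compartment with 11 linear
and 8 power clearance forms.  Analyses that depend only on the covariate
summaries (the pooled-cohort statistics) are insensitive to these
stand-ins; integrated-fit magnitudes are pipeline-consistency checks, not
literature reproductions.

## Virtual cohorts from summary statistics

Published summaries describe the *observed* (range-limited) data, so each
covariate sampler is a truncated parametric distribution whose truncated
moments reproduce the stated ones:

- mean ± SD (± range): truncated normal, with location and scale solved
  numerically so the truncated mean and SD equal the stated values.  When
  the coefficient of variation exceeds 0.5 (or the descriptor hints
  lognormal) a truncated lognormal is used instead, again moment-matched
  on the truncated support.  Where the stated SD is unattainable on the
  bounded support, the best least-squares compromise is kept.
- median [range]: lognormal with `μ = log(median)` and
  `σ = (log hi − log lo)/6` — the stated range is read as roughly the
  central 99.7% interval — truncated to the range.
- median [IQR]: lognormal matched to the quartiles
  (`σ = (log hi − log lo)/1.349`), truncated at the implied 0.1/99.9
  percentiles.
- A missing bound defaults to mean ± 4·SD (normal) or median×4 / median÷4
  (lognormal); ages are clipped to [16, 110] years (several source
  studies enrolled from age 16) and weights/clearances to positive
  values.

Age and creatinine clearance are coupled by a Gaussian copula with a
Spearman rank correlation of −0.58, the value estimated in-house from 246
vancomycin-treated adults; rank correlation is invariant under the
monotone marginal transforms, so the coupling is exact regardless of the
marginal families.  Body weight and sex (Bernoulli from the study's male
fraction) are drawn independently.

Height is never reported, but the Du Bois formula
`BSA = BW^0.425 · height^0.725 · 0.007184` needs it to de-normalize
BSA-indexed creatinine clearance (`CLcr_abs = CLcr_norm · BSA / 1.73`).
Height is therefore imputed by drawing BMI from a truncated normal prior
(mean 23, SD 3.5, bounds [15, 45] kg/m²) and inverting
`height = 100·√(BW/BMI)`.  Studies with an obesity inclusion criterion
override the prior: an explicit BMI ≥ 40 criterion (the extreme-obesity
study) and BMI ≥ 30 for the obese-sepsis study — without the override the
default prior would impute implausible > 2 m heights for 110–150 kg
populations.

### The pooled AGE–CLcr correlation

The pooled Pearson correlation across all 19 cohorts decomposes into the
within-study coupling and the between-study mean structure.  With the
within-study coupling switched off entirely, the between-study means of
the 19-study set already produce a pooled correlation of about −0.19
(young/high-clearance versus geriatric/renal-impairment populations);
with the within-study −0.58 imposed, the pooled value is about −0.56.
The original analysis reported −0.23 pooled, which is only consistent
with a within-study coupling that was effectively near zero after its
(unreported) transformations.  This implementation keeps the stated
within-study target and reports the pooled value it actually produces;
the discrepancy is irreducible without knowing the original generation
mechanism.

## Concentration simulation

Dose schedules follow the descriptor: renal-adjustment bands select
dose/interval by the patient's CLcr; loading doses may be absolute or
per-kg; under steady-state designs the schedule runs for at least 7
dosing intervals or 5 terminal half-lives (whichever is longer) before
the sampled interval.  Individual parameters are the study's typical
values at the patient's CLcr times `exp(η)` for every parameter with a
reported ω².  Central concentrations come from the closed-form solution
of the linear mammillary model (eigen-decomposition, superposition of
zero-order infusions); nearly coincident eigenvalues are separated by a
negligible relative nudge of the micro constants.

Sample counts per patient are zero-truncated Poisson around the study's
stated average; sampling times are uniform within tagged windows.  When
a design names only the window tags, default geometry applies: trough =
the half hour before the next dose, peak = the hour after the end of
infusion, random = the gap between them; designs with no sampling
information default to steady-state trough sampling.  Observations get
proportional (or additive/combined) residual error; non-positive
observed concentrations are excluded — dropped, not clipped — and the
per-replicate exclusion count is logged.  Output is a NONMEM-style long
table (ID, TIME, AMT, RATE, EVID, MDV, DV, covariates, one 0/1 column
per disease label).

## Estimation: FOCE with interaction

The integrated model is a two-compartment IV-infusion model with typical
values (CL, V1, Q2, V2), multiplicative covariate effects on CL — power
effects `(COV/COV_med)^θ` normalized to the population median and
categorical effects `(1+θ)^COV` — exponential between-subject variability
(η on CL by default, optionally V1) and proportional residual error.

The marginal likelihood is approximated per subject: a damped Newton
search (vectorized across all subjects, finite-difference derivatives in
the 1–2-dimensional η, Hessian eigenvalues clipped at the prior
curvature so steps always descend) finds the conditional mode; the model
is linearized there, and the residual variance is evaluated at the
conditional prediction (the interaction term).  With the linearization
`f ≈ f(η̂) + G(η − η̂)` the per-subject contribution is

    OFV_i = n_i log 2π + log|G Ω Gᵀ + V| + rᵀ (G Ω Gᵀ + V)⁻¹ r,
    r = y − f(η̂) + G η̂,   V = diag(σ² f(η̂)²),

evaluated with the Woodbury identity so the cost is linear in the number
of observations.  For a model linear in η with additive error this is
exact and equals the closed-form linear-mixed-model likelihood — the
validation route used in the tests.  A variance floor of 1e-10 on
σ²·pred² guards near-zero predictions.

The outer problem optimizes log-transformed positive parameters (typical
values, ω², σ²) and raw covariate θs by L-BFGS-B, with restart-polish
(re-running from the incumbent until the OFV improvement falls below
0.01) because a single quasi-Newton pass can terminate on a flat
direction, and up to three jittered restarts on failure.  The reported
OFV is recomputed from a cold start so values are comparable across
fits; standard errors come from the finite-difference observed
information (delta method back to the natural scale).  Between-subject
variability is reported both as %CV = 100·√(exp(ω²)−1) and as 100·√ω²,
since published values rarely state their convention.

## Covariate search and the provisional PK cluster

Candidates are AGE, BW and CLcr as power effects on CL, plus disease
indicators.  Against the covariate-free base fit, each disease label is
tested for elevated empirical-Bayes η_CL (one-sided Welch t-test versus
all other subjects, Bonferroni-corrected at α = 0.05, groups under 5
subjects skipped); labels testing elevated merge into one 0/1
"provisional PK cluster" indicator that replaces its constituents in the
candidate pool.  Forward inclusion adds the best candidate per round
while its OFV drop exceeds 3.84 (χ²₁ at p = 0.05); backward elimination
then removes covariates whose deletion raises the OFV by at most 6.63
(χ²₁ at p = 0.01), weakest first, to a fixpoint.  Ties break by larger
drop, then name.  Every decision is reproducible from the recorded ΔOFV
and the two thresholds.

## Replication and aggregation

A replicate is one full generate → simulate → pool → fit (→ search)
pass.  Child seeds are spawned per replicate from one master seed
(numpy `SeedSequence`), so runs are deterministic end to end and
replicates are independent.  Summaries report per-parameter means,
standard errors (the SD over replicates), and 5th/50th/95th percentiles,
plus convergence tallies, per-replicate dataset counts, and the
frequency of each selected covariate structure (replicates can select
different structures; summaries are reported per structure as well as
pooled).  Non-converged replicates are excluded and counted; a run with
more than 20% non-convergence is flagged unreliable.

## Synthetic truth and what the tests show

`synthetic.TruthSpec` defines a known integrated model (clearance 2.75
L/h at CLcr 75, CLcr exponent 0.765, a planted 1.881× two-label disease
cluster, ω² = 0.1, σ² = 0.04) projected into heterogeneous study sets:
alternating power/linear clearance forms, one- and two-compartment
structures, trough-only versus peak+trough designs, and lognormal 10%-CV
between-study clearance jitter.  Projections are chosen to be faithful
on the scale the design observes: linear forms are the least-squares
projection of the power curve over the study's CLcr distribution
(mean-preserving), and one-compartment volumes are solved so the
steady-state trough matches the two-compartment truth at the
study-typical clearance.  Recovery experiments redraw the study set per
replicate, so the jitter averages out as part of the data-generating
process.

Problem sizes in the test suite are chosen for a single-CPU run:
recovery uses 19 studies × 20 patients × 10 replicates; the null
calibration uses 200 simulations of 25 subjects with the structural
volumes held fixed; the scaled integrated fit caps each packaged study
at 8 patients.  Passing these tests shows the machinery is calibrated
and unbiased under the stated generative assumptions; it does not show
that real vancomycin data follow those assumptions, and the integrated
volume terms (V1, Q2, V2) are deliberately *not* recovery targets — with
mixed source structures they are compromise values, exactly as in a real
meta-analysis of structurally heterogeneous models.

## Known limitations

- Between-subject variability is supported on CL (and optionally V1)
  only; Ω is diagonal; no SAEM, bootstrap SEs, or below-quantification
  likelihoods.
- Covariates are searched on CL only; volumes and inter-compartmental
  clearance keep their typical values.
- The correlation structure of the virtual patients is limited to the
  AGE–CLcr copula; BW–CLcr dependence is not modeled directly, so a body
  weight effect present in real data through the Cockcroft–Gault formula
  is not reproduced by the synthetic cohorts.
- The packaged source models and designs are calibrated stand-ins; any
  conclusion about actual published vancomycin parameters requires
  transcribing the original 19 publications into the descriptor schema.
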