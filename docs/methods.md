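# Methods

This note documents the models, the synthetic-data generator, the fitting
machinery and the numerical choices behind `priorcfc`, in the spirit of a
package methods appendix.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Task geometry and conventions

Angles are in degrees relative to the reference separating the orange and
blue choice regions; orange is negative, blue positive.  The decision
region is (−90°, +90°).  The prior over perceived motion direction is a
two-component Gaussian mixture with equal weights and common SD σ_P, means
180° apart: ±90° in the No-Bias condition, and 35°/−145° from the
reference (or the mirror image) in the Bias condition.  Wrapping is
ignored: for the σ_P range the models operate in (roughly 5–200°, with
fits typically near 30°) the mixture components carry negligible mass
beyond ±180°, and decision-relevant integrals are restricted to ±90°
anyway.  Line orientation (10°–80° from vertical, signed for CW/CCW) is
carried as trial metadata only; no model consumes it beyond determining
the preferred direction, which the condition already encodes.

## Decision stage

On each interval the internal signal is r ~ N(θ, σ_L²).  The posterior is
prior × N(x; r, σ_L²) truncated to ±90°, and the observer chooses blue iff
the blue-side mass exceeds the orange-side mass.  The side masses have a
closed form: mixture component k contributes evidence weight
½·N(r; μ_k, σ_P² + σ_L²) times the mass of a Gaussian with
precision-weighted mean (μ_k/σ_P² + r/σ_L²)/(σ_P⁻² + σ_L⁻²) and SD
(σ_P⁻² + σ_L⁻²)^(−1/2) over the side interval.  The test suite checks this
algebra against 0.01°-grid trapezoid quadrature (agreement ≤ 1e−6 across a
100-point sweep including σ_P ∈ {5, 200} and |r| = 80).

Because the blue-side probability is strictly increasing in r, the
decision rule is equivalent to a signal threshold r\*, and the first-order
psychometric function is exactly Φ((θ − r\*)/σ_L).  r\* is located by a
coarse sign-change scan of the normalized mass imbalance on ±300° followed
by Brent refinement; the normalization keeps the sign meaningful where the
raw masses underflow.  If the imbalance never crosses zero (prior so
strong the signal is irrelevant) the threshold saturates at the scan edge,
which correctly degenerates the psychometric function.

Exact ties in the decision or the confidence forced-choice are broken by a
seeded fair coin.  They are measure-zero under the continuous noise but
reachable in floating point.

## Confidence read-outs

- **Bayesian (`bayes`)** — posterior probability of the chosen color,
  in [0.5, 1].
- **Distance-to-criterion (`dist`)** — |r_c| for a single sample r_c from
  the posterior truncated to the chosen side (confidence never opposes the
  decision).  Sampling is by inverse CDF: one uniform picks the mixture
  component by its side mass, a second locates the sample inside the
  truncated component.
- **Decoupled Prior (`dp`)** — the Bayesian read-out recomputed with
  likelihood SD w·σ_L everywhere it appears (evidence weights and
  component posteriors).  w > 1 overweights the prior in confidence;
  values below 0.5 are possible (confidence disagreeing with the choice).
  At w = 1 the computation path is identical to `bayes`, bitwise.
- **Prior-congruent evidence (`pce`)** — |cos(θ_r − θ_P)| with θ_r the
  same internal signal r that feeds the posterior and θ_P the preferred
  direction.  Whether θ_r shares noise with the decision stage is not
  constrained by the design; we use one draw per interval (a single noisy
  measurement feeds both stages), which keeps the observer parsimonious.
  The read-out is invariant to which antipodal mixture mean is used.
- **WPPCE (`wppce`)** — (1 − α)·BPE + α·PCE, α ∈ [0, 1].  Reduces bitwise
  to `bayes` at α = 0 and to `pce` at α = 1.
- **Efficient coding (`ec`)** — the condition's prior, renormalized over
  [−180°, 180°), defines F(θ), its CDF, mapping stimuli to a sensory space
  on [0, 1] where encoding precision is uniform.  This is the standard
  resource-allocation scheme in which the density of Fisher information
  follows the prior (√J ∝ p).  A measurement is
  m ~ N(F(θ) + ε_T, σ_N²) with transduction jitter ε_T ~ N(0, σ_T²), drawn
  independently per interval (each interval is an independent stimulus
  measurement).  Decoding inverts the mapping on a 0.1° grid over the
  decision region: posterior ∝ prior(θ)·N(m; F(θ), σ_N²); the likelihood
  in physical space is narrower where the prior is denser.  Decision and
  confidence then proceed as in the Bayesian observer.  A ×10 grid
  refinement changes the decoded choice probability by < 1e−4 (tested),
  and a monotone interpolation table over m (resolution σ_N/20) serves the
  bulk-simulation paths.

The one nuance worth flagging: Decoupled-Prior confidence is *not*
monotone in w over (0, ∞).  For w ≥ 1 (the prior-overweighting regime)
confidence in a bias-congruent choice is non-decreasing in w, but as
w → 0 the sharpened likelihood drives confidence toward 1 again; tests
assert monotonicity on w ≥ 1 only.

## Synthetic data

The generator reproduces the study design: eight stimulus settings (four
per condition targeting P('Blue') ∈ {0.15, 0.35, 0.65, 0.85}; blue-bias
settings carry the two high targets, orange-bias the two low), all 28
unordered pairings of distinct settings, each repeated an even number of
times split across both interval orders.  Each 56-trial block contains
every ordered pair once, with exactly half the trials tilted CW/CCW and
half with orange counterclockwise of the reference; tilt magnitudes are
drawn from {10°, …, 80°}, excluding cardinals.  24 repetitions give the
study-scale 672 trials.

Stimulus levels come either from exact quantile inversion of the
observer's psychometric function (deterministic; used in recovery studies)
or from the simulated calibration pipeline: a Kesten-style accelerated
stochastic approximation (ASA) staircase.  Three interleaved procedures
(No-Bias, blue-bias, orange-bias) each run four staircases (two per target
probability 0.25/0.75): the level moves by −step·(response − target) with
step = c/n before the first reversal and c/(2 + #reversals) after, c = 40°,
start levels ±40°, levels clipped to ±90° (clipping flagged).  Each
procedure's data are then fit with a two-parameter cumulative normal (no
lapse term) and the eight levels are the fit's target quantiles
θ = μ + σ·Φ⁻¹(target).

The staircase length defaults to 80 trials per staircase.  The selection
step extrapolates to the 0.15/0.85 quantiles from staircases converging at
0.25/0.75, which is the noise bottleneck of the whole calibration; 80
trials keeps the pooled calibration error of the selected levels within
0.03 of the targeted rates (asserted end-to-end in the acceptance tests),
while much shorter staircases leave errors comparable to the binomial
uncertainty of the main task itself.  The count is configurable
(`ASAConfig`).

Reaction times are log-normal (median 0.8 s, σ_log = 0.4) and exist purely
to exercise the exclusion filters; they carry no scientific content.
Trial tables are CSV with a documented column order; a JSON manifest
records the generating model, parameters and seed, and fixed float
formatting makes re-runs byte-identical.

What the generator does **not** emulate: learning, fatigue, serial
dependence, lapses, or any within-session drift — its observers are
stationary by construction.  Tests passing on these observers therefore
certify the machinery (calibration, fitting, recovery), not the behavior
of human data, where staircase miscalibration and non-stationarity are
real possibilities.

## Analyses

Exclusions follow the study's rules: any decision slower than 8 s, any
motion decision faster than 100 ms, and — when calibrated levels are
supplied — all trials presenting a Bias setting whose matched No-Bias
|θ| is not strictly more extreme (the basic bias effect is absent for
that setting).  The filters are idempotent and report per-rule counts.

The symmetric-bias fit models blue-bias trials as Φ((θ + μ_Bias)/σ_Bias)
and orange-bias trials as Φ((θ − μ_Bias)/σ_Bias) — one shared magnitude
shifting the two directions oppositely, shared σ — with the No-Bias
condition fit separately as baseline.

The non-parametric confidence-bias analysis uses cross-condition trials
only.  For each of the 16 Bias × No-Bias setting pairs, each condition's
rate of choosing its expected color (computed within that pair's trials,
both interval orders merged, Haldane–Anscombe 0.5-correction when a cell
is empty or full) is logit transformed and differenced (cp_diff); the rate
of choosing the Bias interval as more confident is regressed on cp_diff
with a two-parameter cumulative normal via trial-weighted Bernoulli ML.
The PSE (μ_cb) and the predicted P("Bias") at cp_diff = 0 summarize the
confidence bias after first-order differences are accounted for.  Pooling
across observers weights setting-pairs by their trial counts through the
likelihood; an unweighted alternative would give sparse pairs equal say
and is not offered.

## Fitting

Fitting is two-stage.  First-order parameters are fit exclusively to the
perceptual decisions; confidence parameters exclusively to the confidence
choices given those decisions.

**Bayesian family first order** — (σ_P, σ_L) by Bernoulli ML over the
closed-form psychometric functions.  The Bias-condition threshold uses the
single-Gaussian simplification of the prior (the −145° component shifts
the choice probability by < 1e−3 near the stimulus range, ≤ ~3e−3 at
extreme signals; tested), while all simulation uses the full mixture.
L-BFGS-B on log parameters, three starts, bounds σ_P ∈ [1, 500],
σ_L ∈ [0.5, 200]; boundary optima flagged.

**Efficient coding first order** — exhaustive grid search over
σ_P ∈ {20, 25, …, 100} × σ_N ∈ {0.02, …, 0.50 step 0.02} ×
σ_T ∈ {0.02, …, 0.10 step 0.02} (17 × 25 × 5 = 2125 points).  Because the
EC decision rule reduces to a measurement threshold m\*, the choice
probability is closed form, 1 − Φ((m\* − F(θ))/√(σ_N² + σ_T²)), so the
grid search needs no simulation; the orange-bias condition is evaluated by
mirror symmetry.

**Confidence likelihood** — simulation-based.  Cells are ordered
setting-pairs × the observed response pair, cross-condition trials only.
Conditioning on the responses is exact: since decision ⇔ signal threshold,
the response-consistent signal distribution is a truncated normal and is
sampled by inverse CDF from frozen per-cell uniforms.  The same frozen
block is reused at every parameter value (common random numbers), making
the simulated likelihood smooth in w and α; a probability floor
ε = 1/(2·n_sim) guards the Bernoulli log-likelihood.  n_sim defaults to
10⁴ per cell (2·10³ in bulk recovery studies).  The Bayesian-family cell
probabilities are validated against deterministic two-dimensional
quadrature in the tests.

**Confidence parameters** — DP: grid over w ∈ {0.1, …, 4.0 step 0.1} (a
0.25 step in bulk studies), best point refined by bounded scalar
minimization; WPPCE: same on α ∈ [0, 1] (step 0.05 / 0.1).  If refinement
fails the grid optimum is returned and flagged.

**Comparison** — AIC = 2k − 2 ln L̂ with k = 2 (bayes, dist, pce) or 3
(dp, wppce, ec), counting first-order parameters; BIC uses the number of
confidence choices in the likelihood.  A model wins conclusively only
with a ≥ 2-point AIC margin.

**Model recovery** — simulate from each of the six observers (reduced
design: 8 repetitions, 224 trials; quantile-exact levels so calibration
noise does not blur the comparison), fit all six, tabulate winners.
Because the model set contains exact nestings (DP ⊇ Bayesian, WPPCE ⊇
Bayesian and PCE), a generating model is counted as identified when it
lies within the 2-point margin of the best AIC; demanding a strict win
would score a correct tie between a model and itself-as-special-case as a
failure.  Defaults (10 datasets per generator, n_sim = 2·10³, coarse
grids) keep the study within minutes on one CPU; all knobs are exposed.

## Reproducibility

Every stochastic stage takes a seed; the pipeline derives per-stage seeds
from a master seed via a fixed counter scheme and serializes its full
configuration (with a content hash on every output).  The pipeline config
is a flat JSON object mirroring `PipelineConfig`: `seed`, the generating
`model` and its parameters (`sigma_p`, `sigma_l`, `w`, `alpha`, `sigma_n`,
`sigma_t`), `repetitions`, `use_asa` (staircase calibration versus exact
quantiles), `model_set`, `n_sim`, the recovery options
(`run_recovery`, `recovery_datasets`, `recovery_repetitions`,
`recovery_n_sim`) and `out_dir`.  Identity reductions
(DP(1) ≡ Bayesian, WPPCE(0) ≡ Bayesian, WPPCE(1) ≡ PCE) hold bitwise under
shared seeds because every observer consumes an identical per-trial block
of random draws regardless of model tag.

## Problem sizes

The acceptance checks run at: 100-point posterior sweep; 672-trial designs
for identity reductions; 20 replicate calibrated observers per model for
the confidence-bias directions; 20 replicate 672-trial datasets for w and
α recovery; 6 × 10 reduced datasets for model recovery; 30 replicate
calibrations for the staircase accuracy check.  These sizes give the
studies comfortable statistical resolution (recovery-bias tolerances of
10%, one-sided 95% sign tests) while remaining desk-scale.

## Known limitations

- The Bias-condition first-order fit inherits the single-Gaussian
  simplification; at extreme internal signals (|r| ≳ 40°) its choice
  probabilities deviate from the full mixture by up to ~3e−3.
- The EC observer's confidence is the posterior read-out only; no
  EC-specific confidence parameter exists, so EC differences show up
  through the encoding stage alone.
- The simulated likelihood is noisy at small n_sim; the common-random-
  numbers scheme removes jitter across parameter values but not the
  overall Monte-Carlo offset, which the ε floor bounds below.
- Human-data phenomena (metacognitive noise, interval bias, lapses) are
  deliberately outside the generator and the models.
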