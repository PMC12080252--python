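# Methods

This note documents the models, numerical choices and limitations behind
`daphtk`, in the spirit of a statistical-software methods appendix.

## Scope and data model

The package analyzes three tabular data streams from chronic
toxicity/bioaccumulation experiments with *Daphnia magna* under passive
dosing: exposure-water concentrations across media-change cycles,
cumulative offspring counts per mother per exposure level, and body-burden
time series with phase labels (uptake/depuration) and wet weights. All
concentrations are carried in mass units (µg/L, µg/kg wet weight) at the
I/O boundary and converted to molar units (nmol/L) internally only where
the chemistry demands it (activities, target lipid model, molar PNEC),
because those relations are molar.

## Exposure QC

Measured water concentrations are pooled per exposure level — initial and
final samples of every cycle together — and summarized as n, mean, SD and
CV (sample SD, ddof = 1). Pooling initial and final samples into one mean
is deliberate: under working passive dosing the two are exchangeable, and
the pooled mean is the exposure estimate used downstream. Stability is
tested per level with a one-sided Welch two-sample comparison (final <
initial, α = 0.05). Welch rather than pooled-variance Student: initial and
final samples have no reason to share a variance, and Welch costs nothing
when they do. Only the decline direction is tested because only losses
threaten the dosing system; an increase is biologically implausible and
would point to contamination, which the summary CV already exposes. Levels
with fewer than two measurements per stage return "inconclusive" rather
than a flag — absence of evidence is not stability. With several levels
screened at α = 0.05, occasional false declines are expected; flags are
advisories to inspect, not rejections.

## Dose–response

Validity first: parent mortality < 10 %, control mean offspring > 60, and
control offspring CV < 15 %, all strict inequalities as the OECD-211
criteria state them. Mortality is computed over all control mothers;
the mean and CV over surviving mothers only.

Per-replicate inhibition is 100·(1 − offspring/control mean), computed
against the control mean (not per-batch controls) and never clipped —
stimulation above the control mean is informative and harmless to the fit.

The concentration–response model is the variable-slope four-parameter
logistic on x = log₁₀(concentration):

    y = bottom + (top − bottom) / (1 + 10^((log10_ec50 − x)·hill))

fit by bounded trust-region least squares (`scipy.optimize.curve_fit`).
Default box constraints are bottom ∈ [−20, 20] %, top ∈ [80, 120] %: wide
enough that they never bind for well-behaved data, tight enough to prevent
the asymptotes wandering into biologically meaningless territory when the
tested range covers only part of the curve. Controls (conc = 0) cannot
enter a log₁₀ fit and contribute only through the control mean. ECx is
defined on the absolute inhibition scale — the concentration where the
fitted curve crosses y = x % — and inverted analytically:

    ECx = 10^(log10_ec50 − log10((top − bottom)/(x − bottom) − 1)/hill)

An ECx is therefore undefined when x lies outside (bottom, top), and any
ECx outside the tested concentration range is flagged "extrapolated"
rather than suppressed. At least five distinct non-zero concentrations are
required.

Confidence intervals are percentile case-resampling bootstrap (2.5/97.5):
replicates are resampled with replacement within each concentration —
including the controls, so the uncertainty of the control mean propagates
into every resampled inhibition value — the model refit (warm-started at
the original parameters; this changes nothing in the result, only the
time), and the ECx recomputed. Intervals are deterministic given a seed;
when more than 20 % of refits fail the interval is flagged unstable. See
"Known limitations" for the measured coverage of these intervals.

The critical target lipid body burden uses the chronic target lipid model

    log10 CTLBB [µmol/g octanol] = log10 EC10 [mmol/L] − m·log K_OW + Δc

with the universal chronic slope m = −0.94 and the polycyclic-aromatic
class correction Δc = 0.352 (both configurable). With study-scale inputs
(EC10 0.1–15 µg/L, MW ≈ 220–270 g/mol, log K_OW 5.2–6.9) this lands inside
the 0.36–137 µmol/g range characteristic of chronic baseline toxicity,
which is the model's consistency check.

Chemical activity is EA = ECx/S_L with S_L = S_W·exp(6.79·(T_M/T − 1)) for
chemicals solid at the test temperature (T default 293.15 K) and S_L = S_W
otherwise; 6.79 is the standard entropy-of-fusion constant (Walden's
rule). Baseline-activity bands are inclusive at both ends (chronic
0.001–0.01, acute 0.01–0.1); a value exactly on a bound reports the band
with a tie note, since the underlying ranges are stated without bound
semantics.

## Toxicokinetics

One-compartment, first-order throughout. k₂ is minus the OLS slope of
ln C_D against time over all retained depuration points, replicates pooled
(the experimental unit is a pooled sample of five animals; per-replicate
fits are possible but the pooled fit matches the design). Natural log for
kinetics, log₁₀ for BAF and cross-species regressions. k_g is the OLS
slope of ln(wet weight) vs time, fitted on the absolute clock (depuration
sampling times are phase-relative and are shifted by the uptake duration
before the growth fit). k₂g = k₂ − k_g; a negative k₂g is reported but
flagged invalid — growth outrunning elimination means the series cannot
support a corrected rate.

Times to steady state use t = −ln(1 − f)/k, so t₅₀ = ln 2/k and
t₉₅ = ln 20/k, with t₉₅/t₅₀ = ln 20/ln 2 ≈ 4.32 as an internal identity.
Which rate feeds them is configurable and recorded: default is k₂g when
available and valid, else k₂.

The uptake rate constant k₁ is not estimated. With simultaneous aqueous
and dietary exposure the uptake flux is not identifiable from body burdens
alone; k₁ exists only as a generation parameter in the synthetic module.
Consequently BAF\* = C_D(end of uptake)/C_W is a kinetic, not steady-state,
quantity; when steady state was not reached it is a lower-bound
approximation and is flagged as such. Lipid normalization is
BAF\*_L5% = BAF\*·0.05/f_lipid with f_lipid = 0.015 for *D. magna* by
default (0.05 is the reference). Averaging across exposure levels is
mean-of-logs, the convention that matches reporting BAF on the log scale.

Plateau detection is suggest-then-confirm: trailing depuration points are
flagged when their removal shifts k₂ by more than 20 % (relative) and the
local log-slope into the point is shallower than −0.005 h⁻¹ — i.e.
elimination has effectively stopped, suggesting elimination-resistant
residues. Flags never modify the fit; exclusions are an explicit input and
every excluded point is recorded on the fit object with its reason, so
fits remain auditable.

## Classification

Cross-species regressions (log BCF_L5% on log k₂, or on log K_OW) are
ordinary least squares; records excluded from a fit (e.g. chemicals whose
BCF is known to be underestimated because t₉₅ exceeded the uptake
duration) are excluded by explicit name, never inferred. The published
regression lines ship as named constants (`DAPHNIA_BCF_K2_LINE` etc.), so
threshold arithmetic is reproducible without the underlying literature
compilation, which this package does not redistribute.

Thresholds invert the line at the REACH criteria (B: 2000, vB: 5000 L/kg,
configurable): k₂ = 10^((log₁₀ BCFcrit − intercept)/slope), requiring a
negative slope. Classification is inclusive (vB if k₂ ≤ k₂_vB, else B if
k₂ ≤ k₂_B), matching the "≤" convention in which the thresholds are
stated; BCF high-accumulation cuts (log ≥ 3.3) are likewise inclusive on
both axes in the fish-vs-invertebrate concordance quadrants. For fish the
default thresholds are the UK Environment Agency literature values
(0.0059/0.0027 h⁻¹) rather than the fish-line inversion; the two nearly
coincide, and the literature values are the ones in regulatory use. Both
are exposed.

## Risk

PNEC = EC10/AF with AF = 100 by default (AF = 10 exposed for baseline
toxicants); RQ = MEC/PNEC with a strict > 1 exceedance flag; the REACH
"toxic to aquatic life" flag is strict EC10 < 10 µg/L. Molar PNECs
(pmol/L) are reported alongside mass units when a molar mass is available.

## Synthetic data

The generators emulate the experimental design, not just the model:

- **Body burdens**: uptake sampled at 24–120 h in 24 h steps, two
  replicates per time point; depuration at four points within 96 h of
  phase start. The uptake mean is (k₁/(k₂+k_g))·C_W·(1 − e^(−(k₂+k_g)t)),
  the depuration mean decays from the end-of-uptake value at k₂, and wet
  weights grow exponentially at k_g from 3 mg (a 10-day-old daphnid).
  Growth dilution enters uptake through the combined constant (k₂ + k_g)
  while the analysis corrects only the depuration fit — a deliberate
  asymmetry mirroring the experimental procedure. Noise is multiplicative
  lognormal with unit mean (default CV 15 %, the scale of body-burden
  measurement error).
- **Reproduction**: control counts are rounded lognormal draws at mean 75
  and CV 10 % (passing the OECD-211 criteria by construction — though at
  n = 10 controls the *sample* CV occasionally exceeds the 15 % cut, a
  realistic failure mode the tests acknowledge); treated replicates scale
  a control-like draw by the true logistic inhibition; counts are rounded
  and floored at zero; parent deaths are Bernoulli.
- **BCF–k₂ scatter**: x = log₁₀ k₂ uniform over a stated range (default
  −2.5 to 0.5), y on the target line plus Gaussian noise; a helper picks
  the residual SD that yields a target R².

All generators are pure functions of (parameters, seed); substream seeds
derive deterministically from one master seed. What the generators do
*not* emulate: the 24–72 h non-monotone body-burden dip seen in real
daphnids (offspring delivery/metabolism), biotransformation, polymer
dosing kinetics, and algal partitioning. Passing tests on synthetic data
therefore demonstrate estimator correctness under the stated model, not
robustness to those real-data features.

## Problem sizes in the test suite

Recovery checks use 200 seeded replications per scenario (k₂ at CV 15 % on
the study schedule; EC50 at CV 10 %, six levels × ten replicates) and the
bootstrap-coverage check uses 500 replications with a scaled-down 199
resamples per interval — sizes chosen to characterize median behavior and
coverage to a few percent.

## Known limitations

- Percentile bootstrap intervals for ECx are anti-conservative at this
  design. Measured over 500 replications (six levels × ten replicates,
  CV 10 %), EC50 coverage is ≈ 89 % at nominal 95 %: the estimator is
  unbiased and misses are symmetric, but case-resampling at n = 10 per
  group understates the sampling variance — the textbook small-sample
  narrowing of nonparametric bootstrap intervals. BCa and studentized
  (bootstrap-t) variants were evaluated and measured ≈ 91 % here, so the
  simpler percentile form is retained. Intervals should be read as
  approximate 90 % intervals at these sample sizes; designs with more
  replicates per concentration close the gap.
- The depuration fit assumes a single first-order compartment;
  elimination-resistant residues violate it, which is exactly what the
  plateau detector is for.
- BAF\* without steady state is a lower bound; comparisons against BCF
  criteria using it are conservative in the safe direction only if the
  true BAF is higher.
- k₂ thresholds for invertebrates rest on small literature regressions
  (n = 14 for *Daphnia*); they are first approximations, not regulatory
  constants, and the package keeps them configurable for that reason.
- The bundled chemical registry is a synthetic stand-in (correct molar
  masses, plausible solubilities and melting points); activity and molar
  PNEC outputs computed from it are demonstrative.
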