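# Methods

This note documents the models, numerical choices and limitations behind
the `multiorgan` package, in the order data flows through the pipeline.

## Pharmacokinetic forward models

**ICG (liver).** Blood concentration follows a one-compartment model with
zero-order infusion: zero before the injection start (default 180 s, i.e. a
3-minute pre-injection baseline), a rising phase during the 10 s bolus, and
monoexponential elimination afterwards at rate k = ln 2 / t½. The healthy
default half-life is 3 min; injury of severity s multiplies it by
(1 + 2s), so a severity-1 mouse clears ICG three times slower. The infusion
rate is normalised so the end-of-bolus peak equals the configured bolus
amplitude (arbitrary units — all downstream statistics are ratios or
within-mouse differences, so absolute concentration units never matter).
A one-compartment model is the simplest model producing the observed curve
shape (sharp bolus peak, clean exponential tail) and makes the post-peak
log-linear fit exact in the noiseless limit.

**IRDye (kidney).** A linear two-compartment chain: a square bolus input
delivers unit mass into the renal cortex over the injection window; the
cortex transfers to the pelvis at rate k_cp (default 1/60 s⁻¹, a ~1 min
cortical transit) and the pelvis washes out at k_pelvis (default
1/180 s⁻¹). Injury multiplies k_cp by exp(−1.8 s): slower cortex→pelvis
transit raises the cortex AUC and, over a finite recording window, lowers
the pelvis AUC, so the AUC C:P ratio increases monotonically with severity
(≈0.33 healthy to ≈2.1 at severity 1 over the default 20-minute
post-injection window). The system is solved in closed form piecewise (sums
of exponentials per constant-input phase), exact on any sampling grid; the
degenerate case k_cp = k_pelvis is handled by a 10⁻⁹ relative nudge of the
washout rate (error far below every tolerance used). Mass conservation —
pelvis content never exceeding the mass that has left the cortex — is a
structural property of the ODE and is asserted against the closed-form
cortex loss in the tests.

The fitted Tmax and decay-rate outputs of the monoexponential fit are
provided but are deliberately not part of the headline statistics: under
acute injury many curves lack a clean pelvic peak or cortical exponential
decay, which is precisely the regime the AUC C:P ratio is designed for.

## Imaging protocols and phantom rendering

The liver protocol records six wavelengths (700–900 nm) and the kidney
protocol two (775, 850 nm) at 10 frames/s with per-cycle frame averaging;
with identical per-wavelength settings the kidney cycle is exactly 3×
faster, a relationship the code derives from wavelength counts rather than
floating-point periods. Phantom stacks are forward-modelled as amplitude ×
reference spectrum summed over components plus i.i.d. Gaussian pixel noise,
on a 128×128 layout with non-overlapping ROIs (vessel disc; cortex annulus
around a pelvis core). The bundled reference spectra are literature-shaped
relative absorption curves normalised to unit peak (deoxyhaemoglobin
falling over 700–900 nm, oxyhaemoglobin rising, ICG peaking near 800 nm and
collapsing beyond 830 nm, IRDye peaking near 775 nm and nearly transparent
at 850 nm). Only spectral *shape* matters for unmixing correctness, and
amplitudes are reported in instrument-arbitrary units throughout.

Rendered cohorts sample stacks at a configurable render period (default
6 s) rather than the full cycle rate; table-mode ROI traces, by contrast,
use full cycle-rate sampling. This keeps a full rendered cohort in the
tens-of-megabytes range while the metric-level analyses operate at protocol
resolution.

## Unmixing

Per pixel and frame, ordinary (unconstrained) least squares of the observed
spectrum against the selected component spectra; negative amplitudes are
permitted by default, with an optional non-negative mode (NNLS). The design
matrix is checked for rank; collinear component pairs are named in the
error. No spatial regularisation or fluence correction is applied. The
two-wavelength difference protocol is implemented as direct band
subtraction and is, up to a factor of 2, the one-component least-squares
solution with spectrum (1, −1) — a relationship the tests assert.

## Clearance metrics

ROI traces are mean pixel amplitude over labelled mask pixels.
Baseline correction subtracts the mean of the pre-injection window
(default 180 s). AUC is the trapezoidal integral on the recorded grid — no
resampling or interpolation — over a window from injection start to the end
of the recording. This window/baseline convention makes the AUC exactly
zero under a no-dye null and is a configuration option, since reasonable
alternatives (uncorrected signal, fixed-length windows) exist. The AUC C:P
ratio is oriented cortex/pelvis so that it increases with injury; a
non-positive pelvis AUC yields an explicit "undefined" rather than an
infinity. Session deltas are day 4 − day 1 per mouse. The half-life fit is
least squares of log-values against time over the post-peak window, with
values clipped to a tiny positive floor (10⁻⁹ of the peak) so that
baseline-corrected traces with small negative excursions remain fittable;
a non-decaying window is flagged unreliable instead of returning a
negative half-life.

## Cardiac parameters

Volumes from M-mode diameters use the Teichholz cube-correction formula
V = 7D³/(2.4 + D) (D in mm, V in µl), the standard convention for this
instrument class; which volume model the acquisition software used is not
knowable from exports, so an area-length alternative V = 8A²/(3πL) is
provided for records carrying long-axis endocardial area and LV length.
Units: FS and EF in percent, SV in µl, CO in ml/min (µl·bpm/1000).

## Synthetic cohort: what it emulates and what it does not

Each mouse carries a dimensionless injury severity s ∈ [0, 1]; the default
arms are control (s ≈ 0–0.05, static), injured (s day 1 uniform on
0.25–0.45, worsening by +0.35 to day 4) and treated (same day-1 range,
worsening by only +0.08 for the kidney/liver axis but by the full +0.35 for
the heart — the therapy modelled helps filtration and clearance organs but
not the myocardium). Severity drives: ICG half-life and k_cp as above;
cardiac records via uniform chamber-scale shrinkage (0.30·s), heart-rate
depression (0.20·s) and a small systolic-diameter excess (0.012·s, the only
FS/EF effect); biomarkers as affine functions of day-4 severity with
lognormal noise (BUN 24.7 + 25·s mg/dl, SCr 0.25 + 0.05·s mg/dl, ALT
56.1 + 280·s U/l — intercepts placed at healthy control means); BLI flux
(day-1 lung-dominated pattern decaying everywhere by day 4 except
liver/kidney in injured arms, which gain by a factor 0.5 + 5·s; heart
pinned at background); and histology (kidney field scores ≈ 5·s with
integer jitter, liver % area ≈ 100·s binned to the 0–4 grade).

Noise terms: 1% multiplicative plus small additive trace noise (the
table-mode analogue of pixel noise averaged over an ROI), lognormal
day-to-day physiological jitter on bolus amplitude (4%), half-life (2.5%)
and k_cp (10%), 1.5%/4% cardiac dimension/heart-rate measurement noise, and
30% lognormal BLI flux noise. Effect sizes and noise levels were fixed once
so that, at the original study's group sizes (4/5/6), the generated cohorts
reproduce its qualitative fingerprint: significant ΔAUC C:P and ΔICG AUC
elevation in the injured arm only, significant ΔSV/ΔCO depression in both
injured arms, no significant ΔFS/ΔEF change, BUN/ALT but not SCr elevation,
and liver/kidney flux accumulation only with injury.

What passing tests on this cohort do **not** show: the generator has no
respiration or motion artefacts, no fluence or depth-dependent spectral
colouring, no arterial input function variability, no ROI mis-placement,
and severity is a modelling construct, not an estimate of any real dose–
response. Absolute metric values (e.g. printed ΔAUC magnitudes) are in
instrument-arbitrary units and are not comparable to any particular
scanner's output; only directions, orderings and significance structure
transfer.

## Statistics

One-way ANOVA for any number of groups (identical to the pooled-variance
t-test at two groups, F = t²), Tukey's HSD when more than two, significance
at P < 0.05, no correction across metrics. Zero-spread input (all
observations identical) is reported as F = 0 rather than NaN. The Tukey
step uses the scipy implementation; the statsmodels implementation serves
as an independent cross-check in the test suite. Correlations are Pearson's
r with R² = r² and two-sided P. Under the all-severity-0 null the pooled
false-flag rate across metrics is consistent with the nominal 5% (checked
over 500 seeded replicates). The liver histology scale bins % area affected
as 0 → 0, (0,25] → 1, (25,50] → 2, (50,75] → 3, (75,100] → 4; the upper
three grades follow the bin ordering, as the scale's grade labels are
conventionally consecutive.

## Problem sizes and determinism

Default analyses run on full-protocol-resolution traces (0.6 s liver cycle
over 18 min, 0.2 s kidney cycle over 23 min). The simulation studies in the
test suite use 100 seeded cohorts of 30 mice/group for the effect-pattern
check and 500 seeded cohorts at the study's own sizes for null calibration;
the half-life recovery study uses 200 replicates. All randomness flows
from a single `numpy` Generator seeded per run; a fixed configuration and
seed reproduce every table byte-for-byte, and each pipeline run writes a
manifest (seed, configuration hash, library versions) sufficient to
reproduce it.
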