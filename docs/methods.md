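# Methods

This note records the model assumptions, parameter defaults and numerical
choices behind `wristox`, and what the synthetic-data experiments do and
do not demonstrate.

## Signal model

Each optical channel is modelled as

    s(t) = DC · (1 + m(t) · w(φ(t))) + ε(t),

quantized to 18-bit integer counts at 50 Hz. `w` is a pulse waveform of
unit fundamental amplitude with one harmonic, w(φ) = sin φ + h·sin 2φ with
h = 0.25 by default; this is deliberately minimal — enough spectral
structure to exercise the band-pass and the spectral HR estimator without
pretending to be a hemodynamic model. φ(t) integrates the instantaneous
heart rate, so piecewise-constant and smoothly varying HR trajectories are
both supported. ε is white Gaussian noise (SD 3 counts by default, i.e.
well below the pulsatile amplitudes but above the quantization step).

The modulation depths encode saturation. Writing r = AC_RMS/DC for a
channel, the ratio of ratios is γ = ln r_IR / ln r_RED. The generator
fixes the IR operating point (r_IR = 0.02 by default, typical of a
well-perfused reflective site) and solves for the red channel,
r_RED = r_IR^(1/γ(SaO₂)), where γ(SaO₂) inverts the calibration quadratic
SpO₂ = aγ² + bγ + c on its monotone branch. Of the quadratic's two roots,
(−b − √(b² − 4a(c − s)))/(2a) is the one with SpO₂ strictly decreasing in
γ for either sign of a; saturations above the curve's maximum
(c − b²/4a ≈ 108.3 for the defaults) have no real root and raise.

Because the AC is measured as the RMS of the *filtered* epoch, the
waveform's RMS factor √((1+h²)/2) cancels between the two channels to
first order; the residual error from a harmonic falling outside the pass
band (HR > 90 bpm puts 2f above 3 Hz) perturbs γ by < 0.002, i.e. SpO₂ by
< 0.1 %, which the round-trip tolerance of ±1 % absorbs.

Accelerometer at rest is (0, 0, 64) arbitrary units plus Gaussian jitter
of SD 1 — more than an order of magnitude below the jolt threshold of 18,
so rest never trips the motion gate. Motion events add white bursts of
configurable amplitude on all three axes; events marked `corrupts_ppg`
add to both optical channels an excursion proportional to the
accelerometer-magnitude deviation (30 % of DC per unit of normalized
deviation), which reliably trips either the amplitude or the
accelerometer-correlation check.

### What the generator does not emulate

Real reflective PPG has baseline wander, respiratory modulation,
perfusion drifts, pulse-shape variability, ambient-light interference and
melanin-dependent attenuation; the generator has none of these, and the
skin-colour covariate does not alter the signal (the validation study
found no skin effect; an optional γ-offset knob exists to probe the
covariate regression). Passing round-trip tests therefore demonstrates
the *algorithmic* correctness of the chain — band selection, AC/DC
bookkeeping, γ algebra, calibration inversion, gating logic — not
robustness to physiological confounders.

## Pipeline choices

- **Jolt/stillness.** j[t] = |a[t]| − |a[t−1]|; a still window requires
  |j| < 18 strictly for every interior transition. Boundary values count
  as movement (conservative). Windows shorter than one epoch are useless
  and dropped.
- **Band-pass.** The pass band 0.5–3 Hz spans 30–180 bpm. A 51-tap FIR
  cannot realize the 0.1 → 0.7 Hz transition at 50 Hz (that would need
  roughly 130 taps), so the filter runs at a 10 Hz internal rate matched
  to the band: polyphase decimation, a 51-tap equiripple design
  (pass band weighted 8:1 for flatness), applied forward-backward for
  zero phase, then polyphase interpolation back to the input rate. The
  composite response, measured by tone probing, is flat within ±0.15 dB
  over 0.7–2.8 Hz with > 100 dB attenuation at 0.1 Hz and > 200 dB at
  6 Hz. Filtering is offline, so anti-causal (zero-phase) application is
  the natural reading and avoids phase distortion of the AC RMS.
- **Epochs.** 10 s epochs, 5 s step: at least five beats even at 40 bpm,
  and eight extraction points fit comfortably in a 2.5 min plateau at
  ≥ 20 s spacing. The first/last 25 samples (half the filter order) of
  each still window are trimmed to avoid edge transients. AC RMS is
  computed over the whole epoch, not beat-by-beat.
- **QC order.** DC range → AC peak-to-peak range → red/IR correlation,
  short-circuiting at the first failure; the reported reason is the first
  gate that failed. The "empirical" bounds are configuration with
  defaults (DC 5 000–250 000 counts, AC pp 20–50 000 counts, correlation
  > 0.8) chosen so the generator's clean output passes and its corrupted
  output fails; real deployments must re-derive them from hardware.
- **Motion check.** Band-passed amplitude above 50 000 counts, or
  |corr(|A|, PPG)| ≥ 0.5 on either channel, excludes the epoch.
  Zero-variance accelerometer magnitude makes the correlation undefined;
  it is defined as 0 (no evidence of coupling) so a perfectly still
  epoch passes.
- **HR.** Magnitude-spectrum peak of the Hann-windowed, zero-padded
  (×8) filtered IR epoch over 0.5–3 Hz, refined by parabolic
  interpolation on log power; IR is used for its larger modulation
  depth. A peak is accepted only if its power exceeds 10× the median
  in-band power — white noise fails this and raises instead of returning
  a number.
- **SpO₂ is never clamped.** Out-of-range compensated values are kept and
  flagged invalid by the 80–100 % acceptance rule, preserving diagnostic
  information.
- **Calibration.** Mean raw SpO₂ over valid epochs in the first 90 s of
  the finger and wrist baselines; offset = finger − wrist, added to every
  wrist reading. γ/SpO₂ and HR use the same epoch.

## Protocol and conditioning

The scheduler spreads each plateau's n extractions evenly over the hold
(spacing duration/(n−1)), which satisfies the ≥ 20 s constraint for the
default 150 s / 8-extraction plateaus (21.4 s) and errors out when
(n−1)·spacing exceeds the hold. Pairing takes the nearest *valid* device
measurement within ±5 s of each scheduled time; missing pairs are simply
absent, mirroring how motion gaps thin out a real session.

Outlier removal is a single pass: pairs whose SpO₂ error differs from the
mean error by more than 2 sample SDs are dropped, once — re-running the
rule on its own output could remove more, and deliberately is not done.
Range equalization rounds reference SpO₂ to the nearest integer percent
(oximeter display convention), bins into 80–86 / 87–93 / 94–100, and
cyclically visits subjects in ascending id order, removing each visited
subject's last-acquired pair in the oversized bin until it matches the
smallest bin. The smallest (non-empty) bin is never touched, retained
pairs keep their order, and ties in acquisition time are broken toward
later file order — all deterministic.

## Agreement statistics

A_RMS = √(Σ(dev−ref)²/n). The algebraic identity
A_RMS² = bias² + ((n−1)/n)·SD² links it to the Bland–Altman quantities;
at small bias the two are close, which is why accuracy is sometimes
loosely described as the SD of the differences. Both are reported.
Limits of agreement use the fixed multiplier 1.96. The paired t test
against zero reports p = 1 with an explicit degenerate flag when the
differences have zero variance (perfect synthetic agreement), instead of
raising. Lin's CCC uses population (1/n) moments with Lin's asymptotic
variance on the Fisher-z scale for the CI; the CI method is a package
choice. Classification at a cut-off c counts reference ≤ c as condition
positive and device ≤ c as test positive; ratios with empty denominators
are reported as missing, never as zero, and Cohen's κ comes from the 2×2
marginals. The covariate regression is OLS of (dev − ref) on the pair
average, age, sex (reference level: females), skin colour (reference
level: black) and BMI, optionally restricted to reference ≤ 94 or ≤ 90 %;
no multiple-testing correction is applied. Rounding in the human-readable
tables is 2 decimals for SpO₂ and 1 for bpm; JSON keeps full precision.

## Synthetic study conditions

The end-to-end CLI run simulates 12 subjects (10 male / 2 female, 8 white
/ 4 black skin, ages 20–51, BMI ≈ 26 ± 3), each with a 95 s finger
baseline and a wrist session of a 97 % lead-in plateau (which doubles as
the 90 s wrist baseline) followed by the four protocol plateaus with 30 s
ramps. The wrist signal encodes SaO₂ 1.5 points below the finger/true
value — the paper-level offset between sites is not published, and a
non-zero default keeps the offset-calibration path honestly exercised.
The reference device is modelled as truth plus independent Normal noise
(SD 1 % SpO₂, 1 bpm HR): small enough to treat as ground truth, non-zero
so pairs are non-degenerate. The acceptance computations use 500
replicates of 219 pairs — the conditioned sample size of the motivating
study design — with Gaussian error models at the whole-range bias/SD
(0.18 %, 2.7 % for SpO₂; 0.25 bpm, 3.7 bpm for HR); the analytic mean
A_RMS is √(bias² + SD²) up to O(1/n) concentration, ≈ 2.71 % and
≈ 3.71 bpm respectively.

## Known limitations

- QC bounds are tuned to the generator's operating point, not to any
  physical sensor.
- The HR estimator assumes a single dominant periodicity; arrhythmic or
  strongly multi-modal pulse trains are out of scope.
- The 423-vs-384 discrepancy between collected and scheduled pairs in
  the motivating study design is not modelled; the simulator follows the
  schedule (≤ 32 pairs per subject).
- Batch processing only; no streaming, no real-time constraints.
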