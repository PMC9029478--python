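# Methods

This note documents the forward model, the calibration of its committed
CONT/MCT parameter sets, the analysis conventions, and the choices made
where the design was genuinely open. It states no empirical number that the
test suite or `scripts/acceptance.py` does not itself compute.

## Forward model

**Ca transient.** Within a beat (2 Hz pacing, stimulus at t = 0) the
fura-2 ratio signal, in F/F₀ units, is

    Ca(t) = ca_dia·dia_mult + A·(exp(−t/τ_d) − exp(−t/τ_r)),

with A scaled so the peak above diastole equals `ca_amp·amp_mult`. The
two-exponential family was chosen because it has a closed-form peak time
t\* = τ_r τ_d/(τ_d−τ_r)·ln(τ_d/τ_r) and a monotone decay, matching the
atrial transients this pipeline targets (no ventricular secondary "bump").
Two consequences are worth knowing: the family enforces
T₅₀ ≥ 1.678·TTP (the limit as τ_r → τ_d), and the identity
τ_d ≈ T₅₀/ln 2 holds only asymptotically — within 5 % once
τ_d/τ_r ≳ 30, with ~31 % error at a ratio of 5.

**Force.** Activation follows a first-order ODE driven by a Hill function
of Ca above the beat's diastolic level,

    dA/dt = k_act·H·(1−A) − k_rel·A,
    H(c)  = (c/K)^n / (1 + (c/K)^n),   K = hill_k / sens_mult,
    F(t)  = passive(preload) + f_ref·fl_active(preload)·A(t),

integrated per beat by RK4 on the sampling grid (each beat starts from
A = 0; the residual activation at 2 Hz is ~10⁻³ of the peak, so carrying
state across beats would change forces by well under 0.1 %). The Hill
exponent is the effective cooperativity of the Ca→force coupling and is
calibrated **per group**: the published pairing of first-beat CaT gains and
force gains after a rest (≈1.19→≈3.0 in CONT, ≈1.10→≈2.7 in MCT) is not
consistent with a single exponent, and with no mechanistic model in scope a
per-group exponent is the minimal device. The default operating point
(`ca_amp` = 0.5 F/F₀ above diastole, `hill_k` = 1.0) keeps the coupling in
its power-law regime (H ≪ 1), so force gains compose multiplicatively —
which is also why inter-muscle variability in the slow-response gains is
amplified ~n-fold in force endpoints (see *Variability*).

**Frank–Starling maps.** `fl_active` maps preload (% of L_max) to an
active-tension scale on a fixed grid (0.25 at 75 % rising to 1.0 at
100 %), interpolated monotonically (PCHIP). Passive tension follows
`α·(exp(β·(L/L_max − ℓ₀)) − 1)` with (α, β, ℓ₀) = (0.1756 mN/mm², 10.42,
0.70), chosen so that passive tension exceeds peak active tension at 95 and
100 % L_max (the qualitative crossover reported for these preparations)
while staying small at 75 %. Peak active tension at 100 % L_max is anchored
at 2.0 mN/mm², typical for thin atrial strips at 30 °C and 2 Hz. Both
groups share the tension–length maps (the study found no group difference
there); they differ in kinetics and slow-response gains.

**Slow force response.** After the stretch, per-beat multipliers follow
mono-exponential envelopes 1 + g·(1 − e^(−t/τ_SFR)) with a shared
τ_SFR = 45 s for: CaT amplitude (`sfr_gain_ca`), myofilament sensitivity
(`sfr_gain_sens`, acting as 1/K), and the diastolic level
(`sfr_dia_gain` = 0.01, i.e. the ~1 % slow diastolic creep). The force rise
in CONT is carried mainly by sensitization: the calibrated CONT gains are a
*negative* CaT-amplitude gain (endpoint ≈ 90.6 %) and a positive
sensitivity gain, because a pure amplitude coupling cannot produce a force
endpoint above 100 % while CaT amplitude falls. In MCT the force rise is
nearly all Ca-driven and the calibrated sensitivity gain is ≈ 0. The
stretch itself is a 100-ms linear ramp placed late in one twitch's
relaxation under continuous pacing; that bisected twitch is tagged and
excluded from analysis, and the immediate Frank–Starling step acts at the
ramp (active force scales with the instantaneous preload).

**Post-rest potentiation.** A rest of length R multiplies the first
post-pause CaT amplitude by 1 + `prp_load_gain`·(1 − e^(−R/`prp_load_tau`))
(τ = 25 s), modeling SR loading during rest; subsequent beats return
geometrically to steady state with per-beat ratio `prp_recirc` = 0.7. The
diastolic level shows a small transient — a 2 % dip for three beats, then
an exponential approach to +1 % over ~5 beats — scaled by the same
rest-saturation factor so a zero-length rest produces exactly no effect.
The dip/overshoot magnitudes are not reported quantities; they are fixed
small constants reproducing the published qualitative shape.

**Noise and channels.** Measurement noise is additive white Gaussian per
channel (`noise_sd_force` = 3·10⁻⁴ mN ≈ 1 % of a CONT twitch;
`noise_sd_fluor` = 1.5 a.u. ≈ 0.3 % of the fluorescence intensities). The
two fluorescence channels are synthesized so that (F340/F380)/F₀ recovers
the model Ca exactly before noise, with F380 dimming by 10 % per unit
normalized Ca (the physical direction for fura-2).

**Variability.** Per-muscle parameters are the group defaults times
independent lognormal multipliers with unit mean: CV `cv_inter_muscle`
(0.05) on the slow-response gains and CV `cv_kinetics` (0.02) on time
constants and rates. Lognormal keeps signs and positivity. The CVs were set
from a variance budget: the group-mean standard error of every calibrated
endpoint must sit well inside the reproduction tolerance at the study's
n = 12/11 (the Hill exponent amplifies gain variability ~n-fold into force
endpoints, which the budget accounts for). The cost is realism of the
spread: the published cohort SDs of the percent endpoints (e.g. ≈13 pp for
the CONT SFR magnitude, ≈85 pp for the CONT PRP extent) are substantially
larger than the simulated ones, and `calibrate_defaults` reports these SD
targets as unmet. Passing tests therefore demonstrate that the *pipeline*
recovers the generator's endpoint means under modest, controlled
variability — not that real cohorts are this tight.

## Calibration

`calibrate_defaults` is deterministic and noise-free; it was run once and
its output committed as the package defaults
(`scripts/run_calibration.py` regenerates them).

Published endpoints pin only contrasts and slow-response ratios, so three
CONT anchors close the system: CaT TTP = 33.33 ms (forced exactly by the
pair of printed TTP contrasts, 42.6 % relative and 14.2 ms absolute), force
TTP = 60 ms, and CaT T₅₀ = 75 ms. The T₅₀ anchor deserves a note: the
reported ~20 % relative T₅₀ prolongation together with the 9.1 ms absolute
difference would imply a CONT T₅₀ near 45 ms, which lies below the
two-exponential family's floor of 1.678·TTP. The calibration keeps the
graded quantities exact — both TTPs and the 9.1 ms absolute T₅₀
difference — and accepts a smaller (~12 %) relative T₅₀ prolongation.

The sequence per group: (1) invert (TTP, T₅₀) to (τ_r, τ_d) by least
squares on the closed forms; (2) fixed-point loop of scalar root finds —
k_rel for the force TTP, k_act for the activation scale (A_peak = 0.02),
and hill_n for the post-rest force/Ca gain pairing; (3) f_ref from the
2.0 mN/mm² tension anchor; (4) SFR gains by Brent root finding with the
**full simulate→analyze pipeline** in the loop, so analysis-side
conventions (end-window averaging, baseline contamination, smoothing) are
absorbed exactly. A verification test re-runs the noise-free single-muscle
pipeline against every endpoint at 1 %.

## Analysis conventions

* Sampling: 1 kHz default (acquisition hardware of such setups runs at
  10 kHz; 1 kHz keeps timing errors ≤ 1 ms and all studies desk-scale; the
  simulator accepts any rate that resolves the pacing period).
* Beat windows run from 50 ms before each stimulus to the next stimulus,
  capped at the pacing period (hence no windows during rest). The baseline
  (passive tension / diastolic level) is the mean over the 50-ms
  pre-stimulus window; at 2 Hz it contains the tail of the preceding
  twitch, worth up to ~0.25 % of peak active tension — a real feature of
  baseline-referenced measurements, absorbed by the calibration.
* TTP is measured stimulus→argmax of the smoothed trace (5-ms centered
  moving average); T₅₀ by linear interpolation at the 50 %-of-active-
  amplitude crossing after the peak. Rates use a Savitzky–Golay derivative
  (5 ms window, order 2) on the raw trace: at 1 kHz a derivative of the
  moving-averaged trace biases the maximal normalized rise rate by ~6 %
  for τ = 50 ms, while the SG estimator stays under 4 % with comparable
  noise suppression. Whether the original rates were computed on filtered
  or raw signals is unknown; the smoothing width is configurable.
* Twitches with amplitude below 3× the baseline-noise SD are flagged
  degenerate and excluded (the study states no exclusion criterion).
* Force–length: per preload, beats tagged by events or failing a 2 %-per-
  10-beats amplitude-drift criterion are dropped, the last ≤30 stable beats
  are ensemble-averaged, then features are extracted once.
* SFR: the reference is the single first post-stretch twitch; "end of SFR"
  is the mean over the final 10 beats of the 3-min record (the endpoint
  window is not defined in the source; both are configurable).
* PRP: the reference is the single last complete pre-pause twitch
  (configurable); the potentiation extent is searched over the first 10
  post-pause beats rather than assumed at beat 1.
* Statistics: two-sided tests, uncorrected p-values by default (an
  optional Holm flag exists), exact MWU null for tie-free samples with
  both n ≤ 8, otherwise the tie- and continuity-corrected normal
  approximation.

## Problem sizes

The endpoint studies use the study's own design throughout: cohorts of
n = 12 (CONT) and n = 11 (MCT); SFR records of 30 pre-stretch beats plus
3 min post-stretch; PRP with 30 s of pre-pause pacing, a 60-s rest, and
30 s post-pause; force–length runs of 36 beats at each of six preloads.
At 1 kHz a full acceptance pass (three studies, 23 muscles each) takes a
few seconds per study on one CPU.

## Known limitations

* The simulated cohort SDs of percent endpoints understate the published
  ones (see *Variability*); between-muscle heterogeneity of kinetics is
  likewise mild (CV 0.02).
* CaT amplitude and kinetics are preload-independent in the generator;
  the real preload dependence of CaT characteristics is weak but not zero.
* The SFR decomposition into sensitization vs Ca-amplitude drift is a
  modeling device constrained only by endpoint pairs, not a mechanistic
  claim; likewise the per-group Hill exponent.
* No SR Ca-flux model, no troponin-binding kinetics, no action potential,
  no temperature dependence (30 °C is metadata only).
* Recordings are CSV + YAML sidecar only; no binary container and no
  readers for proprietary acquisition formats.
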