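# Methods

This note records the model, the study-condition presets and their
provenance, the numerical and design choices behind the detectors, and
what the synthetic data can and cannot establish about real recordings.

## Generative model

### Calcium and fluorescence

Acrosomal free Ca²⁺ follows a fusion-pore influx law with first-order
clearance:

    d[Ca]/dt = n_pores(t) · J · (Ca_ext − Ca)/Ca_ext − k_clear (Ca − Ca_rest)

with per-pore flux J (µM/s), clearance k_clear (default 0.02 s⁻¹), resting
Ca (default 100 µM) and external Ca (default 10 mM, the supplemented
medium; 0 for the chelated condition). The green channel is

    F_green = baseline + s(t) · ΔF_max · H(Ca),   H(Ca) = Caⁿ/(K_dⁿ + Caⁿ)

with K_d = 400 µM and n = 2, and s(t) the remaining sensor fraction. The
red channel sits at baseline until MF onset, then decays exponentially
with τ = duration/3 toward a floor of 5 % of baseline, so 95 % of the loss
is complete at the configured duration; s(t) is the normalized red
profile, which couples sensor loss back into the green channel and
produces the canonical ordering: green rise → red loss → green return.

Two generative modes share this law:

* **mechanistic** — pores are born in a Poisson process; the piecewise
  linear ODE is integrated exactly between births; MF fires at the
  critical pore count (default 5, a pore-coalescence threshold). This
  mode is the reference for closed-form/oracle tests.
* **calibrated** — cohort presets prescribe target event kinetics (onset,
  amplitude ΔF, slope, rise duration) and the pore schedule is constructed
  to realize them exactly on the noise-free trace. Any smooth Ca(t) is
  realizable by some non-negative pore schedule, so this is a
  reparameterization of the same model, not a departure from it.

### Rise-profile construction

A cell's green rise consists of a brief *ignition* segment (250 a.u./s, up
to min(120, 0.75·A, max(0.5·A, 90)) a.u.) followed by a saturating
exponential pinned to reach the target amplitude A exactly at the rise
duration D, after which pores close and clearance pulls Ca back. The
ignition segment encodes that the first pores open against the full
transmembrane gradient: signals leave the baseline abruptly, as the
recordings' switch-like onsets show, and it is what makes onset detection
accurate to ±2 frames at the default noise. The exponential rate λ is
calibrated per cell by bisection so that the least-squares slope measured
the way the analysis measures it — on the acquisition frame grid, from the
first frame above the onset threshold (3 noise SDs) to the frame reaching
80 % of amplitude — equals the drawn slope target. Targets outside the
family's achievable range (e.g. a drawn slope below the near-linear
minimum for the drawn A and D) realize the nearest achievable value;
ground truth always records realized values measured on the noise-free
frame-sampled trace, with the drawn targets kept alongside.

Prespike-foot (PSF) events are one transient early pore: a climb occupying
40 % of the foot duration to a shelf at `psf_amp_fraction` (default 1/5,
inside the published 4–7-fold amplitude ratio) of the rise amplitude,
holding until the main rise begins. Feet are generated on fast responders
only, and in footed fusing cells MF onset is floored past the
shelf-to-peak span so the foot's defining "small relative to the completed
rise" property holds.

### Noise

Additive Gaussian per frame, default SD = 2 % of ΔF_max (20 a.u.) in both
channels. Baselines are 100 a.u. (green; the resting Hill term adds
~59 a.u.) and 1000 a.u. (red), so the red floor and 95 %-completion
margins are large relative to noise.

## Study-condition presets

Each preset fixes: cohort size, ACR/MF fractions, fast/slow responder
split, kinetic means and SDs, PSF incidence and duration, external Ca²⁺,
and the ACR/MF initiation-site co-localization probability. Published
values used directly:

* fractions/transitions: A23187 75.3 %/30.1 % (40.0 %), GM1+CD
  31.9 %/26.5 % (83.1 %), CD 27.7 %/25.3 % (91.3 %), CD+EGTA 0 %/17.1 %;
  transition rates 42.7 % (low P4), 55.2 % (high P4), 58.1 % (high
  P4+bicarbonate); 40/60 fast/slow split under ionophore with per-class
  transition rates in the ratio 89.4:18;
* kinetics: onsets 231 ± 31 s (GM1) and 18.6 ± 3 s (HiP4+bicarb);
  amplitudes 576 ± 20, 454 ± 43, 304 ± 32, 352 ± 13, 297 ± 44, 577 ± 32
  ΔF; slopes 137 ± 25 and 124 ± 19 ΔF/s (lipid conditions); rise durations
  18.7 ± 5.4, 25.1 ± 12.4, 54.4 ± 8.6, 43.9 ± 5.1, 41.4 ± 6.3 s; MF onsets
  238 ± 38, 190 ± 29, 149 ± 16, 60 ± 11 s; MF durations 5 ± 0.6 (EGTA),
  29.41 ± 2.69 and 24.87 ± 3.60 s (P4), 11–15 s (others); CD ACR→MF delay
  6.1 ± 3 s; PSF incidence 15.1 % and 23.3 % of responding cells
  (ionophore, HiP4+bicarb); PSF durations 42.5 ± 4.6, 16.4 ± 1.6,
  13.1 ± 1 s; co-localization 14/47/43/36 %.

SDs are reconstructed as SEM × √n_event with n_event the event-positive
count implied by the cohort size and fractions. Values the source did not
print were fixed once, before any recovery run, to be consistent with the
printed transition rates and qualitative descriptions: ACR fractions for
the P4 conditions (0.43/0.60/0.82), onset means for
A23187/CD/LowP4/HiP4 (160/140/60/110 s), slope means for the non-lipid
conditions (~60–160 ΔF/s), PSF incidence ~6–8 % for the remaining
conditions, and several SDs. The A23187 amplitude SEM printed as "± 0.13"
is treated as a typo for ± 13 on the high-P4 value.

Distributional choices: event times (onsets, durations, delays) are
lognormal — strictly positive and right-skewed; onsets use a lognormal
*truncated to the recording window* with the truncated moments matched to
the printed mean/SD, because printed onset statistics are necessarily
computed from events observed within the 8-min recording (matching
untruncated moments and clipping would bias the realized mean far below
the printed value when the spread is large). Where the printed SD is not
achievable inside the window by any truncated lognormal, the mean is
matched exactly and the SD as closely as the family allows. Amplitudes and
slopes are mean-corrected truncated normals; the amplitude floor is
120 a.u. (≈6 noise SDs — dimmer rises would not have been scored as
responses).

MF is assigned within responders as an exact-count draw weighted by
slope², which structurally realizes the observed association between Ca²⁺
rise rate and fusion competence while hitting the configured fractions.
Fusions scheduled too late for their signal loss to complete inside the
recording are dropped and topped back up from remaining responders — the
published fractions are themselves counts of fusions observed within the
window. The ACR→MF delay is floored at 4 frame periods: the m-frame
sustained onset rule cannot order two events closer than a few frames, and
the recordings report the green-before-red ordering as universal outside
the chelated condition.

Slow responders (ionophore only; the other conditions are described and
printed as uniformly rapid) draw rise durations of 240 ± 60 s, usually
failing to peak within the recording; slow cells that do fuse do so
~150 s after onset, keeping their measured rise duration beyond the
120 s fast/slow boundary.

### Known internal tensions

The published numbers are not mutually consistent per cell: the CD rise
duration (25.1 s mean, heavy-tailed) exceeds the CD ACR→MF delay (6.1 s),
so the green rise often continues after red loss begins; the generator
permits this, scaling the green signal by the remaining sensor fraction,
and rise duration for MF-truncated cells ends at red-loss onset.
Consequently realized (and detected) CD amplitudes sit ~10 % below the
configured mean — within twice the published SEM, which is the tolerance
the recovery tests use throughout. Similarly, the printed GM1 onset/MF
onset pair implies a 7 s delay even though the CD delay is described as
shortest by a wide margin; presets keep both printed onset means. The
ionophore fast/slow subpopulation percentages (10.6 %/82 %) do not
reconcile with the 40/60 split; presets follow the 40/60 split with
per-class transition rates scaled to preserve the printed overall 40.0 %.

## Detection choices

* Onset rule: k_σ = 3, m = 3 sustained frames (no threshold is published;
  this is robust at the stated noise and 2–4 Hz frame rates). Baseline:
  full pre-stimulus window (60 frames at defaults) — short windows
  under-estimate σ and create false onsets.
* ACR peak and amplitude are measured on a 3-frame running mean (the raw
  argmax of a noisy plateau overstates amplitude and stretches the slope
  window); the 80 %-crossing for the slope window uses the raw trace
  (smoothing delays short rises by a frame). Ground truth uses the same
  conventions on the noise-free trace.
* The peak search stops at red-loss completion, so sensor loss does not
  masquerade as the falling flank of the rise.
* PSF: the window runs from the departure from baseline (walking back from
  the sustained crossing until three consecutive sub-σ frames) to the
  50 %-amplitude frame; a two-changepoint piecewise-linear fit restricted
  to admissible biphasic partitions (positive foot slope, middle-segment
  slope ≤ 0.25 of the hand-over slope) must beat the best single-changepoint
  fit by ≥ 1.5 in SSE; the shelf must have ≥ 1 s extent, amplitude
  ≤ 1/4 of the rise, and foot slope ≤ 0.5 of the main-rise slope. Feet
  shorter than ~8 frames at 2 Hz are at the resolution limit and drive the
  residual miss rate; truncated rises whose foot exceeds 1/4 of the
  *realized* amplitude are rejected by definition.
* MF: positive at ≥ 80 % loss of red F₀ ("complete loss" with a floor);
  the loss extent uses a robust floor (median of near-minimum frames of a
  5-frame smoothed trace) so the deepest noise dip does not inflate it;
  duration ends where the smoothed loss first reaches 95 % of its extent —
  the operational reading of "until minimum intensity" under noise.
* Fast/slow boundary: 120 s rise duration, or a peak never reached within
  the recording.
* Spatial: 10 axis bins; initiation regions by thirds; diffuse iff the
  bin-onset spread is ≤ 1.5 frame periods; per-bin thresholds use a pooled
  (median) bin SD since bins share pixel noise statistics; orientation is
  recovered from local arm thickness (distance transform) — the tapered
  perforatorium end maps to s = 1 — so labels are anatomical and
  mirror-invariant. Ties for earliest bin break toward the steepest
  initial slope. The ends-to-centre red pattern generates its two fronts
  staggered by half a second, making "bottom" its deterministic initiation
  region (the taxonomy has no centre-initiated red label).
* Statistics: Pearson χ² without continuity correction (df = 1) for count
  outcomes; Welch two-sided t for kinetics; no multiple-testing
  correction (pairwise p-values are reported directly). Percentages and
  times are rounded to one decimal in reports.

## What the synthetic data does and does not establish

The generator emulates: stimulus-locked onset distributions per condition,
fast/slow subpopulations, foot events, condition-dependent red-loss
kinetics, non-responders, Ca²⁺-independent fusion under chelation,
additive frame noise, and axis-parameterized wavefronts over a
crescent-shaped head. It does not emulate: cell motility or drift,
photobleaching, focus changes, autofluorescence structure, shot-noise
statistics (an optional Poisson mode is deliberately out of the default
conditions), multi-cell fields, or 3-D acrosome geometry. Passing
recovery tests therefore demonstrates that the detectors measure what they
claim on signals with the stated kinetics and noise — not that they are
robust to motion or bleaching artefacts, which real analyses must address
upstream.

Problem sizes in the test suite and acceptance script (cohorts of 200–400
cells, 10 seeds for recovery checks, 48–64 px movies) were chosen as the
smallest sizes at which the binomial and SEM tolerances are meaningful.

## Tolerances used by the recovery checks

Response fractions: 3 binomial SDs at the simulated sample size. Kinetic
means: twice the SEM of the corresponding published mean at its study
sample size (the natural uncertainty to attach to a printed mean ± SEM);
onset timing: ≤ 2 frames for ≥ 95 % of responders; noise-free fidelity:
one frame period for times, 1 % for amplitudes and slopes; closed-form vs
brute-force integration: 0.1 %.
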