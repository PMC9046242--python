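# acropore

Simulation and analysis of dual-reporter live-cell imaging of sperm
acrosome exocytosis (AE).

## The problem

Mammalian fertilization requires exocytosis of the acrosome, the single
secretory vesicle in the rostral sperm head. A dual-reporter sensor
targeted to the acrosomal matrix — a low-affinity, Ca²⁺-sensitive green
fluorophore fused to a Ca²⁺-insensitive red one — resolves two distinct
steps of this process in single live cells:

* **ACR** (acrosomal Ca²⁺ rise): small fusion pores between the plasma
  membrane and the outer acrosomal membrane admit extracellular Ca²⁺, and
  the green channel brightens;
* **MF** (membrane fusion): pores coalesce into full fusion, the ~75 kDa
  sensor protein escapes, and the red channel is lost — the readout of
  completed AE.

This package is for researchers analysing such two-channel recordings (or
prototyping analyses of them): it provides a generative model of the
traces and head movies with known ground truth, detectors for every event
class the recordings exhibit, spatial propagation-pattern classification,
and the population statistics used to compare stimulation conditions.

## The model

Acrosomal free Ca²⁺ obeys a fusion-pore influx law with first-order
clearance,

    d[Ca]/dt = n_pores(t) · J · (Ca_ext − Ca)/Ca_ext − k_clear (Ca − Ca_rest),

and the green channel reads the Hill saturation of the sensor
(K_d ≈ 400 µM, chosen for the acrosome's high luminal Ca²⁺),

    F_green(t) = F₀ + s(t) · ΔF_max · Ca^n / (K_d^n + Ca^n) + ε,

where s(t), the remaining sensor fraction, equals the normalized red
channel: after MF onset the red signal decays exponentially toward a
floor, dragging the green signal back down. Prespike-foot (PSF)–like
events — small, slow, biphasic green rises preceding the main ACR, the
signature of transient early pores — appear as a low shelf before the
rise.

Detection mirrors the measurements reported for such recordings: traces
are normalized to ΔF = F − F₀ over a pre-stimulus baseline; onsets are the
first sustained run of frames beyond k·σ of baseline noise; ACR slope is
the least-squares rise rate from onset to 80 % of amplitude; feet are
identified by a two-changepoint piecewise-linear (rise/shelf/rise) test
plus amplitude- and slope-dissimilarity criteria; MF is ≥80 % loss of red
F₀ with its onset, duration, fractional loss and decay slope; propagation
patterns (diffuse, top→bottom, centre-outward / ends-to-centre,
bottom→top) are classified from per-axis-bin onset profiles of head
movies. Cohort summaries produce response percentages, ACR→MF transition
rates, kinetic means ± SEM, and χ²/Welch-t condition comparisons.

## Worked example

Simulate 100 cells under ionophore stimulation, detect events, and
summarize:

```sh
acropore simulate --preset A23187 --n 100 --seed 7 --out-dir acrorun
acropore analyze-traces --in acrorun/traces_A23187.csv --out acrorun/events.csv
acropore summarize --events acrorun/events.csv --out acrorun/summary.json
acropore report --summary acrorun/summary.json
```

prints

```
== A23187 (n=100) ==
  ACR 75.0%  MF 32.0%  transition 42.7%
  PSF incidence 14.7% of responding cells
  acr_onset_s: 186.7 +/- 11.9 (n=75)
  acr_peak_s: 308.1 +/- 14.1 (n=75)
  rise_duration_s: 121.3 +/- 11.9 (n=75)
  amplitude_dF: 571.7 +/- 17.2 (n=75)
  slope_dF_per_s: 58.6 +/- 8.6 (n=75)
  psf_duration_s: 11.4 +/- 1.3 (n=11)
  psf_amplitude_dF: 115.6 +/- 11.1 (n=11)
  mf_onset_s: 240.1 +/- 20.5 (n=32)
  mf_duration_s: 13.1 +/- 1.0 (n=32)
  mf_dF_over_F0: 0.9 +/- 0.0 (n=32)
  acr_mf_delay_s: 47.0 +/- 8.8 (n=32)
```

75 of 100 cells show an acrosomal Ca²⁺ rise and 32 complete fusion — a
42.7 % transition rate, matching the ionophore preset in which most slow
responders never fuse. The long mean rise duration reflects the 40/60
fast/slow responder mixture; the mean ΔF amplitude (~572 a.u.) and the
per-event kinetics recover the generating study conditions. The same
commands accept any trace CSV with columns
`cell_id, condition, t_s, F_green_au, F_red_au`; `acropore analyze-movies`
classifies spatial patterns from two single-channel TIFF stacks with a
JSON frame-time sidecar.

The library surface mirrors the CLI: `simulate_cell` / `simulate_cohort` /
`simulate_movie`, `analyze_trace` (or `normalize`, `detect_acr`,
`detect_psf`, `detect_mf` individually), `analyze_movie`, and
`summarize_condition` / `compare_conditions`.

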