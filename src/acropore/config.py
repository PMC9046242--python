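"""Configuration types for the dual-reporter acrosome-exocytosis pipeline.

The package simulates and analyses two-channel fluorescence recordings of
single sperm heads: a green, low-affinity Ca2+-sensor channel that reports
the acrosomal Ca2+ rise (ACR) and a red, Ca2+-insensitive channel whose
loss reports membrane fusion (MF) and acrosome exocytosis (AE).

Everything tunable lives here: acquisition geometry, the Hill model of the
sensor, per-condition cohort presets, and the detection thresholds. All
times are seconds; event times are reported relative to stimulus onset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import yaml

__all__ = [
    "AcquisitionConfig",
    "CaSensorModel",
    "PSFParams",
    "MFParams",
    "SpatialParams",
    "SimCellParams",
    "ConditionPreset",
    "DetectionParams",
    "PipelineConfig",
    "PRESETS",
    "PRESET_NAMES",
    "load_config",
    "dump_presets_yaml",
    "config_hash",
]


# --------------------------------------------------------------------------
# Acquisition and sensor
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionConfig:
    """Recording geometry for a single-cell two-channel trace.

    Defaults follow the imaging protocol the presets were derived from:
    2 Hz two-channel confocal acquisition (hardware supported up to ~5 Hz),
    recordings up to 8 min, and a local stimulus puff applied after a
    pre-stimulus baseline window.
    """

    frame_rate_hz: float = 2.0
    duration_s: float = 480.0
    stim_time_s: float = 30.0
    noise_sd: float = 20.0          # a.u., additive Gaussian per frame
    baseline_green_au: float = 100.0
    baseline_red_au: float = 1000.0

    def __post_init__(self) -> None:
        if not (1.0 <= self.frame_rate_hz <= 5.0):
            raise ValueError(
                f"frame_rate_hz must be in [1, 5], got {self.frame_rate_hz}"
            )
        if not self.stim_time_s < self.duration_s:
            raise ValueError("stim_time_s must be < duration_s")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("frame_rate_hz", "duration_s", "stim_time_s",
                     "noise_sd", "baseline_green_au", "baseline_red_au"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass(frozen=True)
class CaSensorModel:
    """Hill model of the low-affinity green Ca2+ sensor.

    The sensor variant was chosen for the acrosome's high resting Ca2+
    (reported between ~256 uM and ~1 mM): Kd ~ 400 uM with good dynamic
    range over 1e-4 .. 1e-3 M. ``ca_rest_uM`` defaults to 100 uM, which
    yields the dim pre-stimulus baseline seen in recordings despite the
    high reported resting values; it is deliberately configurable because
    the two observations are hard to reconcile quantitatively.
    """

    kd_uM: float = 400.0
    hill_n: float = 2.0
    ca_rest_uM: float = 100.0
    ca_ext_uM: float = 10000.0      # medium supplemented with 10 mM CaCl2
    dFmax_green_au: float = 1000.0

    def __post_init__(self) -> None:
        if self.kd_uM <= 0:
            raise ValueError("kd_uM must be > 0")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be > 0")
        if self.ca_rest_uM < 0 or self.ca_ext_uM < 0:
            raise ValueError("calcium concentrations must be >= 0")

    def fraction_bound(self, ca_uM: np.ndarray | float) -> np.ndarray | float:
        """Fluorescent fraction ca^n / (kd^n + ca^n); monotone in ca."""
        ca = np.asarray(ca_uM, dtype=float)
        can = np.power(np.clip(ca, 0.0, None), self.hill_n)
        out = can / (self.kd_uM ** self.hill_n + can)
        return out if out.shape else float(out)

    def ca_for_fraction(self, frac: float) -> float:
        """Inverse Hill: Ca2+ level producing a given fluorescent fraction."""
        if not 0.0 <= frac < 1.0:
            raise ValueError(f"fraction must be in [0, 1), got {frac}")
        if frac == 0.0:
            return 0.0
        return self.kd_uM * (frac / (1.0 - frac)) ** (1.0 / self.hill_n)

    @property
    def rest_fraction(self) -> float:
        return float(self.fraction_bound(self.ca_rest_uM))


# --------------------------------------------------------------------------
# Per-cell simulation parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PSFParams:
    """A prespike-foot-like transient: one small, short-lived fusion pore
    producing a low shelf in the green signal before the main ACR rise."""

    psf_onset_s: float              # after stimulus; < acr_onset_s
    psf_duration_s: float           # foot start -> main rise start
    psf_amp_fraction: float = 0.2   # shelf amplitude / ACR amplitude

    def __post_init__(self) -> None:
        if not (0.0 < self.psf_amp_fraction <= 0.25):
            raise ValueError("psf_amp_fraction must be in (0, 1/4]")
        if self.psf_duration_s <= 0:
            raise ValueError("psf_duration_s must be > 0")


@dataclass(frozen=True)
class MFParams:
    """Membrane-fusion (red-channel loss) parameters for one cell."""

    mf_onset_s: float               # after stimulus
    mf_duration_s: float            # onset -> minimum intensity (95% of loss)
    n_crit_pores: int = 5           # pore-coalescence threshold (mechanistic mode)
    red_floor_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.red_floor_fraction <= 0.2):
            raise ValueError("red_floor_fraction must be in [0, 0.2]")
        if self.mf_duration_s <= 0:
            raise ValueError("mf_duration_s must be > 0")

    @property
    def decay_tau_s(self) -> float:
        # 95% of the loss is complete at mf_duration_s: tau = D / ln(20)
        return self.mf_duration_s / 3.0


# Legal propagation-pattern labels per channel.
ACR_PATTERNS = ("D", "T>B", "C>TB", "B>T")
MF_PATTERNS = ("D", "T>B", "TB>C", "B>T")


@dataclass(frozen=True)
class SpatialParams:
    """Wavefront parameters for a head movie (axis coordinate s in [0, 1],
    0 = subacrosomal ring / bottom, 1 = perforatorium tip / top)."""

    pattern_acr: str = "D"
    pattern_mf: str = "D"
    init_site_s01: float = 0.0      # used for directional ACR patterns
    wavefront_speed: float = 0.08   # axis units per second

    def __post_init__(self) -> None:
        if self.pattern_acr not in ACR_PATTERNS:
            raise ValueError(f"pattern_acr must be one of {ACR_PATTERNS}")
        if self.pattern_mf not in MF_PATTERNS:
            raise ValueError(f"pattern_mf must be one of {MF_PATTERNS}")
        if self.wavefront_speed <= 0:
            raise ValueError("wavefront_speed must be > 0")


@dataclass(frozen=True)
class SimCellParams:
    """Everything the generator needs for one cell.

    Two generative modes share the same calcium law
    d[Ca]/dt = n_pores(t) * pore_flux * (ca_ext - ca)/ca_ext
               - ca_clear_rate * (ca - ca_rest):

    * mechanistic: pores are born stochastically at ``pore_birth_rate`` and
      the ODE is integrated piecewise-exactly; MF fires when the pore count
      reaches ``n_crit_pores``.
    * calibrated: the target kinetics (``amp_dF``, ``slope_dF_per_s``,
      ``rise_duration_s``) prescribe a pore schedule realizing exactly those
      trace features; this is the mode cohort presets use.
    """

    responder_class: str = "none"   # none | fast | slow
    acr_onset_s: float = 0.0        # after stimulus
    pore_birth_rate: float = 0.2    # pores / second (mechanistic mode)
    pore_flux_uM_per_s: float = 400.0  # per pore
    ca_clear_rate: float = 0.02     # 1/s
    amp_dF: Optional[float] = None          # target ACR amplitude, a.u.
    slope_dF_per_s: Optional[float] = None  # target ACR slope, a.u./s
    rise_duration_s: Optional[float] = None # pore-open (rise) duration, s
    psf: Optional[PSFParams] = None
    mf: Optional[MFParams] = None
    spatial: Optional[SpatialParams] = None

    def __post_init__(self) -> None:
        if self.responder_class not in ("none", "fast", "slow"):
            raise ValueError("responder_class must be none|fast|slow")
        for name in ("acr_onset_s", "pore_birth_rate", "pore_flux_uM_per_s",
                     "ca_clear_rate"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.psf is not None:
            if self.responder_class == "none":
                raise ValueError("PSF requires a responding cell")
            if self.psf.psf_onset_s >= self.acr_onset_s:
                raise ValueError("psf_onset_s must be < acr_onset_s")


# --------------------------------------------------------------------------
# Condition presets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionPreset:
    """Population-level study conditions for one stimulation protocol.

    Fractions are over all imaged cells; kinetic means/SDs describe the
    event-positive subpopulation (SDs reconstructed from published SEMs as
    SEM * sqrt(n_event) where the mean was published, otherwise chosen to
    be consistent with the published transition rates and fold changes —
    see docs/methods.md for the full provenance table).
    """

    name: str
    n_study: int                    # imaged cohort size in the source study
    frac_acr: float
    frac_mf: float
    frac_fast_among_responders: float
    onset_mean_s: float
    onset_sd_s: float
    amp_mean_au: float
    amp_sd_au: float
    slope_mean_au_s: float
    slope_sd_au_s: float
    rise_dur_mean_s: float
    rise_dur_sd_s: float
    mf_onset_mean_s: float          # = onset_mean + delay_mean for ACR+ cells
    mf_duration_mean_s: float
    mf_duration_sd_s: float
    mf_delay_mean_s: float          # ACR onset -> MF onset
    mf_delay_sd_s: float
    psf_incidence: float            # fraction of responding cells
    psf_dur_mean_s: float
    psf_dur_sd_s: float
    psf_amp_fraction: float = 0.2
    ca_ext_uM: float = 10000.0
    coloc_p: Optional[float] = None  # P(ACR and MF initiate in same region)

    def __post_init__(self) -> None:
        for name in ("frac_acr", "frac_mf", "frac_fast_among_responders",
                     "psf_incidence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ca_ext_uM == 0.0 and self.frac_acr > 0.0:
            raise ValueError("zero extracellular Ca2+ forbids ACR")

    @property
    def transition_fraction(self) -> float:
        """P(MF | ACR); for the Ca2+-free preset MF occurs without ACR."""
        if self.frac_acr == 0.0:
            return 0.0
        return self.frac_mf / self.frac_acr


def _preset(**kw: Any) -> ConditionPreset:
    return ConditionPreset(**kw)


#: Study-condition presets. Published values: response fractions, transition
#: rates, onset/amplitude/slope/duration means and SEMs, MF kinetics, PSF
#: incidence and durations, co-localization percentages. Values the source
#: study did not print (marked in docs/methods.md) were fixed once from the
#: printed transition rates and qualitative descriptions.
PRESETS: dict[str, ConditionPreset] = {
    "A23187": _preset(
        name="A23187", n_study=93,
        frac_acr=0.753, frac_mf=0.301, frac_fast_among_responders=0.40,
        onset_mean_s=160.0, onset_sd_s=100.0,
        amp_mean_au=576.0, amp_sd_au=167.0,
        slope_mean_au_s=160.0, slope_sd_au_s=80.0,
        rise_dur_mean_s=70.0, rise_dur_sd_s=25.0,
        mf_onset_mean_s=190.0,
        mf_duration_mean_s=13.0, mf_duration_sd_s=5.0,
        mf_delay_mean_s=30.0, mf_delay_sd_s=15.0,
        psf_incidence=0.151, psf_dur_mean_s=15.0, psf_dur_sd_s=5.0,
        coloc_p=0.14,
    ),
    "GM1_CD": _preset(
        name="GM1_CD", n_study=113,
        frac_acr=0.319, frac_mf=0.265, frac_fast_among_responders=1.0,
        onset_mean_s=231.0, onset_sd_s=186.0,
        amp_mean_au=454.0, amp_sd_au=258.0,
        slope_mean_au_s=137.0, slope_sd_au_s=150.0,
        rise_dur_mean_s=18.7, rise_dur_sd_s=32.4,
        mf_onset_mean_s=238.0,
        mf_duration_mean_s=13.0, mf_duration_sd_s=5.0,
        mf_delay_mean_s=7.0, mf_delay_sd_s=5.0,
        psf_incidence=0.06, psf_dur_mean_s=15.0, psf_dur_sd_s=5.0,
        coloc_p=0.47,
    ),
    "CD": _preset(
        name="CD", n_study=166,
        frac_acr=0.277, frac_mf=0.253, frac_fast_among_responders=1.0,
        onset_mean_s=140.0, onset_sd_s=90.0,
        amp_mean_au=304.0, amp_sd_au=217.0,
        slope_mean_au_s=124.0, slope_sd_au_s=129.0,
        rise_dur_mean_s=25.1, rise_dur_sd_s=84.0,
        mf_onset_mean_s=146.1,
        mf_duration_mean_s=12.0, mf_duration_sd_s=4.0,
        mf_delay_mean_s=6.1, mf_delay_sd_s=19.4,
        psf_incidence=0.06, psf_dur_mean_s=15.0, psf_dur_sd_s=5.0,
        coloc_p=0.43,
    ),
    "CD_EGTA": _preset(
        name="CD_EGTA", n_study=164,
        frac_acr=0.0, frac_mf=0.171, frac_fast_among_responders=0.0,
        onset_mean_s=0.0, onset_sd_s=0.0,
        amp_mean_au=0.0, amp_sd_au=0.0,
        slope_mean_au_s=0.0, slope_sd_au_s=0.0,
        rise_dur_mean_s=0.0, rise_dur_sd_s=0.0,
        mf_onset_mean_s=120.0,
        mf_duration_mean_s=5.0, mf_duration_sd_s=3.2,
        mf_delay_mean_s=0.0, mf_delay_sd_s=0.0,
        psf_incidence=0.0, psf_dur_mean_s=0.0, psf_dur_sd_s=0.0,
        ca_ext_uM=0.0, coloc_p=None,
    ),
    "LowP4": _preset(
        name="LowP4", n_study=115,
        frac_acr=0.43, frac_mf=0.184, frac_fast_among_responders=1.0,
        onset_mean_s=60.0, onset_sd_s=40.0,
        amp_mean_au=297.0, amp_sd_au=308.0,
        slope_mean_au_s=60.0, slope_sd_au_s=35.0,
        rise_dur_mean_s=54.4, rise_dur_sd_s=60.0,
        mf_onset_mean_s=90.0,
        mf_duration_mean_s=25.0, mf_duration_sd_s=8.0,
        mf_delay_mean_s=30.0, mf_delay_sd_s=15.0,
        psf_incidence=0.06, psf_dur_mean_s=16.4, psf_dur_sd_s=5.0,
        coloc_p=0.30,
    ),
    "HiP4": _preset(
        name="HiP4", n_study=208,
        frac_acr=0.60, frac_mf=0.331, frac_fast_among_responders=1.0,
        onset_mean_s=110.0, onset_sd_s=70.0,
        amp_mean_au=352.0, amp_sd_au=108.0,
        slope_mean_au_s=65.0, slope_sd_au_s=35.0,
        rise_dur_mean_s=43.9, rise_dur_sd_s=42.0,
        mf_onset_mean_s=149.0,
        mf_duration_mean_s=24.87, mf_duration_sd_s=30.0,
        mf_delay_mean_s=39.0, mf_delay_sd_s=20.0,
        psf_incidence=0.08, psf_dur_mean_s=42.5, psf_dur_sd_s=14.0,
        coloc_p=0.36,
    ),
    "HiP4_bicarb": _preset(
        name="HiP4_bicarb", n_study=73,
        frac_acr=0.82, frac_mf=0.476, frac_fast_among_responders=1.0,
        onset_mean_s=18.6, onset_sd_s=22.9,
        amp_mean_au=577.0, amp_sd_au=244.0,
        slope_mean_au_s=70.0, slope_sd_au_s=35.0,
        rise_dur_mean_s=41.4, rise_dur_sd_s=48.0,
        mf_onset_mean_s=60.0,
        mf_duration_mean_s=29.41, mf_duration_sd_s=15.9,
        mf_delay_mean_s=41.4, mf_delay_sd_s=20.0,
        psf_incidence=0.233, psf_dur_mean_s=13.1, psf_dur_sd_s=4.0,
        coloc_p=0.33,
    ),
}

PRESET_NAMES = tuple(PRESETS)

# Slow-responder class (prominent only under ionophore stimulation): a
# gradual rise that usually does not peak, or peaks late, within the
# recording. Cells of this class that do fuse do so well past the fast/slow
# rise-duration boundary.
SLOW_RISE_MEAN_S = 240.0
SLOW_RISE_SD_S = 60.0
SLOW_MF_TIME_MEAN_S = 150.0   # ACR onset -> MF onset for slow fusing cells
SLOW_MF_TIME_SD_S = 40.0


# --------------------------------------------------------------------------
# Detection thresholds
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionParams:
    """Thresholds for event detection and classification.

    ``k_sigma``/``m_frames``: an onset is the first post-stimulus frame of a
    run of at least ``m_frames`` consecutive frames with |dF| beyond
    ``k_sigma`` baseline SDs (sign according to rise/loss).
    """

    k_sigma: float = 3.0
    m_frames: int = 3
    max_amp_ratio: float = 0.25     # PSF shelf amplitude / ACR amplitude
    max_slope_ratio: float = 0.5    # PSF foot slope / ACR slope
    biphasic_factor: float = 1.5    # residual-reduction for the biphasic test
    loss_fraction_min: float = 0.8  # fractional red loss defining MF-positive
    slow_min_rise_s: float = 120.0  # fast/slow rise-duration boundary
    spread_max_frames: float = 1.5  # diffuse-pattern onset spread, in frames
    slope_upper_frac: float = 0.8   # slope fitted onset -> this amplitude frac
    mf_complete_frac: float = 0.95  # red-loss completion fraction for duration
    n_axis_bins: int = 10
    baseline_window_s: Optional[float] = None  # default: full pre-stimulus

    def __post_init__(self) -> None:
        for name in ("k_sigma", "max_amp_ratio", "max_slope_ratio",
                     "biphasic_factor", "loss_fraction_min",
                     "slow_min_rise_s", "spread_max_frames",
                     "slope_upper_frac", "mf_complete_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.m_frames < 1:
            raise ValueError("m_frames must be >= 1")
        if self.n_axis_bins < 3:
            raise ValueError("n_axis_bins must be >= 3")


# --------------------------------------------------------------------------
# Pipeline configuration (strict parsing)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    sensor: CaSensorModel = field(default_factory=CaSensorModel)
    detection: DetectionParams = field(default_factory=DetectionParams)
    presets: Mapping[str, ConditionPreset] = field(
        default_factory=lambda: dict(PRESETS))
    seed: int = 0
    output_dir: str = "acropore_out"


def _build_dataclass(cls: type, data: Mapping[str, Any], where: str) -> Any:
    """Construct ``cls`` from a mapping, rejecting unknown keys."""
    if not isinstance(data, Mapping):
        raise ValueError(f"{where}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(
            f"{where}: unknown key(s) {sorted(unknown)}; valid keys: {sorted(names)}"
        )
    return cls(**data)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a strict YAML pipeline configuration; misspelled keys fail fast."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, Mapping):
        raise ValueError("config root must be a mapping")
    top = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - top
    if unknown:
        raise ValueError(f"config: unknown top-level key(s) {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    if "acquisition" in raw:
        kwargs["acquisition"] = _build_dataclass(
            AcquisitionConfig, raw["acquisition"], "acquisition")
    if "sensor" in raw:
        kwargs["sensor"] = _build_dataclass(CaSensorModel, raw["sensor"], "sensor")
    if "detection" in raw:
        kwargs["detection"] = _build_dataclass(
            DetectionParams, raw["detection"], "detection")
    if "presets" in raw:
        presets = {}
        for name, block in raw["presets"].items():
            block = dict(block)
            block.setdefault("name", name)
            presets[name] = _build_dataclass(
                ConditionPreset, block, f"presets.{name}")
        kwargs["presets"] = presets
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    return PipelineConfig(**kwargs)


def dump_presets_yaml(path: str | Path,
                      presets: Mapping[str, ConditionPreset] = PRESETS) -> None:
    """Write presets as YAML, one block per condition."""
    out = {name: dataclasses.asdict(p) for name, p in presets.items()}
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of a full pipeline configuration (for run manifests)."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
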