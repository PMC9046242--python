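"""File I/O: trace CSV, ground-truth JSON, events tables, TIFF movies,
summaries and run manifests.

Formats (UTF-8, comma-separated, '.' decimal, mandatory header):

* traces: long CSV with columns cell_id, condition, t_s, F_green_au,
  F_red_au; acquisition metadata travels in the pipeline config.
* ground truth: JSON sidecar, one record per cell.
* events: one row per cell (wide CSV + JSON) plus a long-format PSF CSV.
* movies: one multi-page uint16 TIFF per channel plus a JSON sidecar with
  frame times and stimulus time.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .events import ACREvent, CellOutcome, EventSet, MFEvent, PSFEvent
from .simulate import CellTrace, GroundTruth, HeadMovie
from .spatial import PatternCall

__all__ = [
    "write_traces", "read_traces", "write_truth", "read_truth",
    "write_events", "read_events", "write_movie", "read_movie",
    "write_patterns", "read_patterns", "write_summary",
]

TRACE_COLUMNS = ["cell_id", "condition", "t_s", "F_green_au", "F_red_au"]
FLOAT_FMT = "%.6g"


class SchemaError(ValueError):
    """A file does not match the expected column schema."""


def _require_columns(df: pd.DataFrame, required: Sequence[str],
                     what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{what}: missing required column(s) {missing}; "
            f"found {list(df.columns)}")


# --------------------------------------------------------------------------
# Traces
# --------------------------------------------------------------------------

def write_traces(path: str | Path, traces: Sequence[CellTrace]) -> None:
    frames = [pd.DataFrame({
        "cell_id": tr.cell_id, "condition": tr.condition, "t_s": tr.t_s,
        "F_green_au": tr.f_green_au, "F_red_au": tr.f_red_au,
    }) for tr in traces]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT)


def read_traces(path: str | Path,
                stim_time_s: float = 30.0) -> list[CellTrace]:
    """Read a long-format trace CSV (any CSV with the same columns works).

    The CSV does not carry the stimulus time; supply the one used during
    acquisition (defaults to the package's acquisition default).
    """
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, f"trace file {path}")
    out = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        t = g["t_s"].to_numpy(float)
        if len(t) < 2:
            raise SchemaError(f"cell {cell_id}: fewer than 2 frames")
        rate = 1.0 / float(np.median(np.diff(t)))
        out.append(CellTrace(
            cell_id=str(cell_id), condition=str(g["condition"].iloc[0]),
            t_s=t, f_green_au=g["F_green_au"].to_numpy(float),
            f_red_au=g["F_red_au"].to_numpy(float),
            frame_rate_hz=rate, stim_time_s=stim_time_s))
    return out


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

def write_truth(path: str | Path, truths: Sequence[GroundTruth]) -> None:
    records = [dataclasses.asdict(t) for t in truths]
    Path(path).write_text(json.dumps(records, indent=1, default=float))


def read_truth(path: str | Path) -> list[GroundTruth]:
    return [GroundTruth(**rec) for rec in json.loads(Path(path).read_text())]


# --------------------------------------------------------------------------
# Events
# --------------------------------------------------------------------------

_EVENT_COLS = {
    "acr": ("onset_s", "peak_s", "rise_duration_s", "amplitude_dF",
            "slope_dF_per_s", "speed_class", "peak_truncated"),
    "mf": ("mf_onset_s", "duration_s", "dF_over_F0",
           "decay_slope_dF_per_s", "acr_mf_delay_s"),
}


def events_frame(outcomes: Sequence[CellOutcome]) -> pd.DataFrame:
    """One row per cell with every detected kinetic parameter."""
    rows = []
    for o in outcomes:
        row: dict[str, object] = {
            "cell_id": o.cell_id, "condition": o.condition,
            "acr_positive": o.acr_positive, "mf_positive": o.mf_positive,
            "psf_count": o.psf_count,
            "ca_independent_mf": o.ca_independent_mf,
        }
        acr = o.events.acr
        for c in _EVENT_COLS["acr"]:
            row[f"acr_{c}"] = getattr(acr, c) if acr is not None else None
        mf = o.events.mf
        for c in _EVENT_COLS["mf"]:
            row[f"mf_{c}"] = getattr(mf, c) if mf is not None else None
        if o.events.psf:
            p = o.events.psf[0]
            row.update(psf_onset_s=p.psf_onset_s,
                       psf_duration_s=p.duration_s,
                       psf_amplitude_dF=p.amplitude_dF,
                       psf_slope_dF_per_s=p.slope_dF_per_s)
        rows.append(row)
    return pd.DataFrame(rows)


def psf_long_frame(outcomes: Sequence[CellOutcome]) -> pd.DataFrame:
    rows = [{"cell_id": o.cell_id, "condition": o.condition,
             "psf_onset_s": p.psf_onset_s, "duration_s": p.duration_s,
             "amplitude_dF": p.amplitude_dF,
             "slope_dF_per_s": p.slope_dF_per_s}
            for o in outcomes for p in o.events.psf]
    return pd.DataFrame(rows, columns=["cell_id", "condition", "psf_onset_s",
                                       "duration_s", "amplitude_dF",
                                       "slope_dF_per_s"])


def write_events(path: str | Path, outcomes: Sequence[CellOutcome]) -> None:
    """Events as wide CSV plus JSON and a long-format PSF CSV alongside."""
    path = Path(path)
    df = events_frame(outcomes)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    path.with_suffix(".json").write_text(
        df.to_json(orient="records", indent=1))
    psf_long_frame(outcomes).to_csv(
        path.with_name(path.stem + "_psf.csv"), index=False,
        float_format=FLOAT_FMT)


def read_events(path: str | Path) -> list[CellOutcome]:
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "condition", "acr_positive",
                          "mf_positive", "psf_count"], f"events file {path}")
    out = []
    for _, row in df.iterrows():
        acr = None
        if bool(row["acr_positive"]):
            acr = ACREvent(
                onset_s=row["acr_onset_s"], peak_s=row["acr_peak_s"],
                rise_duration_s=row["acr_rise_duration_s"],
                amplitude_dF=row["acr_amplitude_dF"],
                slope_dF_per_s=row["acr_slope_dF_per_s"],
                speed_class=row.get("acr_speed_class"),
                peak_truncated=bool(row.get("acr_peak_truncated", False)))
        mf = None
        if bool(row["mf_positive"]):
            delay = row.get("mf_acr_mf_delay_s")
            mf = MFEvent(
                mf_onset_s=row["mf_mf_onset_s"],
                duration_s=row["mf_duration_s"],
                dF_over_F0=row["mf_dF_over_F0"],
                decay_slope_dF_per_s=row["mf_decay_slope_dF_per_s"],
                acr_mf_delay_s=None if pd.isna(delay) else float(delay))
        psf = []
        if int(row["psf_count"]) > 0 and not pd.isna(row.get("psf_onset_s")):
            psf = [PSFEvent(psf_onset_s=row["psf_onset_s"],
                            duration_s=row["psf_duration_s"],
                            amplitude_dF=row["psf_amplitude_dF"],
                            slope_dF_per_s=row["psf_slope_dF_per_s"])]
        out.append(CellOutcome(
            cell_id=str(row["cell_id"]), condition=str(row["condition"]),
            acr_positive=bool(row["acr_positive"]),
            mf_positive=bool(row["mf_positive"]),
            psf_count=int(row["psf_count"]),
            ca_independent_mf=bool(row.get("ca_independent_mf", False)),
            events=EventSet(acr=acr, psf=psf, mf=mf)))
    return out


# --------------------------------------------------------------------------
# Movies
# --------------------------------------------------------------------------

def write_movie(green_path: str | Path, red_path: str | Path,
                sidecar_path: str | Path, movie: HeadMovie) -> None:
    tifffile.imwrite(green_path, movie.green_stack.astype(np.uint16))
    tifffile.imwrite(red_path, movie.red_stack.astype(np.uint16))
    Path(sidecar_path).write_text(json.dumps({
        "frame_times_s": [float(t) for t in movie.frame_times_s],
        "stim_time_s": float(movie.stim_time_s),
        "pixel_size_um": float(movie.pixel_size_um),
    }, indent=1))


def read_movie(green_path: str | Path, red_path: str | Path,
               sidecar_path: str | Path) -> HeadMovie:
    try:
        green = tifffile.imread(green_path)
        red = tifffile.imread(red_path)
    except Exception as exc:       # corrupt / truncated stacks
        raise ValueError(f"cannot read TIFF stack: {exc}") from exc
    meta = json.loads(Path(sidecar_path).read_text())
    for key in ("frame_times_s", "stim_time_s"):
        if key not in meta:
            raise SchemaError(f"movie sidecar missing key {key!r}")
    green = np.atleast_3d(np.asarray(green, dtype=np.uint16))
    red = np.atleast_3d(np.asarray(red, dtype=np.uint16))
    if green.size == 0 or red.size == 0:
        raise ValueError("cannot read TIFF stack: file empty or truncated")
    if green.shape != red.shape:
        raise SchemaError("green and red stacks have different shapes")
    times = np.asarray(meta["frame_times_s"], dtype=float)
    if len(times) != green.shape[0]:
        raise SchemaError("frame_times_s length does not match stack length")
    return HeadMovie(green_stack=green, red_stack=red, frame_times_s=times,
                     stim_time_s=float(meta["stim_time_s"]),
                     pixel_size_um=float(meta.get("pixel_size_um", 0.1)))


# --------------------------------------------------------------------------
# Pattern calls and summaries
# --------------------------------------------------------------------------

def write_patterns(path: str | Path,
                   calls: Sequence[tuple[str, PatternCall, PatternCall]],
                   ) -> None:
    """Per-cell pattern CSV: (cell_id, ACR call, MF call) triples."""
    rows = []
    for cell_id, acr, mf in calls:
        for call in (acr, mf):
            rows.append({"cell_id": cell_id, "channel": call.channel,
                         "label": call.label,
                         "init_site_s01": call.init_site_s01,
                         "init_region": call.init_region})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_patterns(path: str | Path) -> dict[str, dict[str, PatternCall]]:
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "channel", "label", "init_region"],
                     f"pattern file {path}")
    out: dict[str, dict[str, PatternCall]] = {}
    for _, row in df.iterrows():
        label = None if pd.isna(row["label"]) else str(row["label"])
        region = None if pd.isna(row["init_region"]) else str(row["init_region"])
        call = PatternCall(channel=str(row["channel"]), label=label,
                           init_site_s01=float(row.get("init_site_s01",
                                                       float("nan"))),
                           init_region=region)
        out.setdefault(str(row["cell_id"]), {})[call.channel] = call
    return out


def write_summary(path: str | Path, summaries) -> None:
    """Summaries as JSON keyed by condition, plus a CSV table alongside."""
    from .summary import summary_frame
    path = Path(path)
    payload = {s.condition: dataclasses.asdict(s) for s in summaries}
    path.write_text(json.dumps(payload, indent=1, default=float))
    summary_frame(summaries).to_csv(path.with_suffix(".csv"), index=False,
                                    float_format=FLOAT_FMT)
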