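"""Cohort-level population metrics and condition comparisons.

Aggregates per-cell outcomes into the population statistics reported for
each stimulation condition: response fractions (% of cells with ACR, % with
MF), the ACR-to-MF transition rate, PSF incidence, kinetic means +/- SEM,
propagation-pattern fractions and initiation-site co-localization, plus the
pairwise tests used to compare conditions (Pearson chi-square on outcome
counts, Welch two-sample t on kinetic samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import CellOutcome
from .spatial import PatternCall, same_initiation

__all__ = [
    "CohortSummary",
    "ComparisonResult",
    "transition_rate",
    "combined_lipid_response",
    "fold_ratio",
    "summarize_condition",
    "compare_conditions",
    "compare_kinetics",
    "summary_frame",
]

#: Kinetic parameters summarized per condition (event-positive cells only).
KINETIC_FIELDS = (
    "acr_onset_s", "acr_peak_s", "rise_duration_s", "amplitude_dF",
    "slope_dF_per_s", "psf_duration_s", "psf_amplitude_dF",
    "mf_onset_s", "mf_duration_s", "mf_dF_over_F0", "acr_mf_delay_s",
)


@dataclass
class CohortSummary:
    condition: str
    n_cells: int
    pct_acr: float
    pct_mf: float
    transition_pct: Optional[float]     # None when no cell shows ACR
    psf_incidence_pct_responding: float
    psf_incidence_pct_total: float
    kinetic_means: dict[str, tuple[float, float, int]] = field(
        default_factory=dict)           # name -> (mean, sem, n)
    pattern_fractions: dict[str, dict[str, float]] = field(
        default_factory=dict)           # channel -> label -> %
    colocalization_pct: Optional[float] = None


@dataclass
class ComparisonResult:
    metric: str
    conditions: tuple[str, str]
    statistic: float
    p_value: float
    test: str                           # chi_square | t_test


# --------------------------------------------------------------------------
# Worked-example arithmetic
# --------------------------------------------------------------------------

def transition_rate(pct_acr: float, pct_mf: float) -> float:
    """Percentage of ACR-positive cells that proceed to MF/AE,
    100 * pct_mf / pct_acr, to one decimal."""
    if pct_acr <= 0:
        raise ValueError("transition rate undefined when pct_acr is 0")
    return round(100.0 * pct_mf / pct_acr, 1)


def combined_lipid_response(pct_first: float, pct_second_of_remaining: float,
                            remaining_pct: float) -> float:
    """Combined response to two sequential membrane-lipid stimuli: cells
    responding to the first plus the stated fraction of the remaining
    pool responding to the second."""
    for v in (pct_first, pct_second_of_remaining, remaining_pct):
        if not 0.0 <= v <= 100.0:
            raise ValueError("percentages must be in [0, 100]")
    return pct_first + pct_second_of_remaining * remaining_pct / 100.0


def fold_ratio(a: float, b: float) -> float:
    """Fold change a/b (e.g. onset-time ratio between conditions)."""
    if b == 0:
        raise ValueError("fold ratio undefined for zero denominator")
    return a / b


# --------------------------------------------------------------------------
# Cohort summaries
# --------------------------------------------------------------------------

def _mean_sem(values: Sequence[float]) -> tuple[float, float, int]:
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)])
    n = len(arr)
    if n == 0:
        return math.nan, math.nan, 0
    sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(arr.mean()), sem, n


def _collect_kinetics(outcomes: Sequence[CellOutcome]) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {k: [] for k in KINETIC_FIELDS}
    for o in outcomes:
        acr, mf = o.events.acr, o.events.mf
        if acr is not None:
            out["acr_onset_s"].append(acr.onset_s)
            out["acr_peak_s"].append(acr.peak_s)
            out["rise_duration_s"].append(acr.rise_duration_s)
            out["amplitude_dF"].append(acr.amplitude_dF)
            out["slope_dF_per_s"].append(acr.slope_dF_per_s)
        for p in o.events.psf:
            out["psf_duration_s"].append(p.duration_s)
            out["psf_amplitude_dF"].append(p.amplitude_dF)
        if mf is not None:
            out["mf_onset_s"].append(mf.mf_onset_s)
            out["mf_duration_s"].append(mf.duration_s)
            out["mf_dF_over_F0"].append(mf.dF_over_F0)
            if mf.acr_mf_delay_s is not None:
                out["acr_mf_delay_s"].append(mf.acr_mf_delay_s)
    return out


def summarize_condition(outcomes: Sequence[CellOutcome],
                        patterns: Sequence[tuple[PatternCall, PatternCall]]
                        | None = None) -> CohortSummary:
    """Population summary for one condition.

    Fractions are over all cells; kinetic means +/- SEM over cells with the
    event; PSF incidence is reported against both denominators (responding
    cells, the primary figure, and all cells). Order-independent.
    """
    if len(outcomes) == 0:
        raise ValueError("cannot summarize an empty cohort")
    condition = outcomes[0].condition
    n = len(outcomes)
    n_acr = sum(o.acr_positive for o in outcomes)
    n_mf = sum(o.mf_positive for o in outcomes)
    n_psf_cells = sum(o.psf_count > 0 for o in outcomes)
    pct_acr = round(100.0 * n_acr / n, 1)
    pct_mf = round(100.0 * n_mf / n, 1)
    summary = CohortSummary(
        condition=condition, n_cells=n, pct_acr=pct_acr, pct_mf=pct_mf,
        transition_pct=(transition_rate(pct_acr, pct_mf)
                        if n_acr > 0 else None),
        psf_incidence_pct_responding=round(
            100.0 * n_psf_cells / n_acr, 1) if n_acr else 0.0,
        psf_incidence_pct_total=round(100.0 * n_psf_cells / n, 1),
        kinetic_means={k: _mean_sem(v)
                       for k, v in _collect_kinetics(outcomes).items()})
    if patterns:
        for channel, i in (("ACR", 0), ("MF", 1)):
            calls = [p[i] for p in patterns if not p[i].unclassifiable]
            frac: dict[str, float] = {}
            for c in calls:
                frac[c.label] = frac.get(c.label, 0.0) + 1
            summary.pattern_fractions[channel] = {
                k: round(100.0 * v / len(calls), 1)
                for k, v in sorted(frac.items())} if calls else {}
        flags = [same_initiation(a, m) for a, m in patterns]
        flags = [f for f in flags if f is not None]
        if flags:
            summary.colocalization_pct = round(
                100.0 * sum(flags) / len(flags), 1)
    return summary


# --------------------------------------------------------------------------
# Condition comparisons
# --------------------------------------------------------------------------

def compare_conditions(metric: str, cond_a: str, cond_b: str,
                       pos_a: int, n_a: int, pos_b: int,
                       n_b: int) -> ComparisonResult:
    """Pearson chi-square (df = 1, no continuity correction) on a 2x2
    outcome table for a count metric such as pct_acr or pct_mf."""
    table = np.array([[pos_a, n_a - pos_a], [pos_b, n_b - pos_b]])
    if (table < 0).any():
        raise ValueError("negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a zero margin makes the "
                         "expected count 0; test not run")
    if (table == table[0]).all():
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ComparisonResult(metric=metric, conditions=(cond_a, cond_b),
                            statistic=float(chi2), p_value=float(p),
                            test="chi_square")


def compare_kinetics(metric: str, cond_a: str, cond_b: str,
                     sample_a: Sequence[float],
                     sample_b: Sequence[float]) -> ComparisonResult:
    """Welch two-sided t test on a continuous kinetic parameter."""
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if np.array_equal(np.sort(a), np.sort(b)):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(metric=metric, conditions=(cond_a, cond_b),
                            statistic=float(t), p_value=float(p),
                            test="t_test")


def summary_frame(summaries: Sequence[CohortSummary]) -> pd.DataFrame:
    """Flat one-row-per-condition table of a set of cohort summaries."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "condition": s.condition, "n_cells": s.n_cells,
            "pct_acr": s.pct_acr, "pct_mf": s.pct_mf,
            "transition_pct": s.transition_pct,
            "psf_pct_responding": s.psf_incidence_pct_responding,
            "psf_pct_total": s.psf_incidence_pct_total,
            "colocalization_pct": s.colocalization_pct,
        }
        for name, (mean, sem, n_e) in s.kinetic_means.items():
            row[f"{name}_mean"] = round(mean, 1) if np.isfinite(mean) else None
            row[f"{name}_sem"] = round(sem, 1) if np.isfinite(sem) else None
            row[f"{name}_n"] = n_e
        rows.append(row)
    return pd.DataFrame(rows)
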