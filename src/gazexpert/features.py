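"""Trial-level 46-feature aggregation of cleaned event streams.

Each trial is summarised by two event frequencies (fixations and saccades per
second of trial duration) plus average / standard deviation / minimum /
maximum of eleven event measures: fixation duration and dispersion, saccade
duration, amplitude, mean and peak acceleration, peak deceleration, mean and
peak velocity, and smooth-pursuit duration and dispersion — 2 + 11 x 4 = 46
named features.  The standard deviation uses the n-1 denominator (a sample
statistic over a trial's events) and is 0 for a single event.

Trials missing an event type yield missing values for that type's features;
the default policy drops such trials from the matrix (logged in the result).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import EventStream

#: Measures aggregated per trial, in canonical order, with their extractors.
_MEASURES = (
    ("fixation_duration_ms", "fixations", "duration_ms"),
    ("fixation_dispersion_px", "fixations", "dispersion_px"),
    ("saccade_duration_ms", "saccades", "duration_ms"),
    ("saccade_amplitude_deg", "saccades", "amplitude_deg"),
    ("saccade_mean_acceleration", "saccades", "mean_acceleration"),
    ("saccade_peak_acceleration", "saccades", "peak_acceleration"),
    ("saccade_peak_deceleration", "saccades", "peak_deceleration"),
    ("saccade_mean_velocity", "saccades", "mean_velocity"),
    ("saccade_peak_velocity", "saccades", "peak_velocity"),
    ("pursuit_duration_ms", "pursuits", "duration_ms"),
    ("pursuit_dispersion_px", "pursuits", "dispersion_px"),
)

_DERIVATIONS = ("avg", "std", "min", "max")

FEATURE_NAMES = ["fixation_frequency_hz", "saccade_frequency_hz"] + [
    f"{measure}_{d}" for measure, _, _ in _MEASURES for d in _DERIVATIONS
]

ID_COLUMNS = ["participant_id", "class_label", "trial_id"]


def _aggregate(values: np.ndarray) -> tuple:
    if values.size == 0:
        return (np.nan,) * 4
    avg = float(values.mean())
    std = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return avg, std, float(values.min()), float(values.max())


def trial_features(stream: EventStream) -> dict:
    """The 46 named aggregates for one cleaned trial."""
    trial = stream.trial
    duration_s = trial.duration_ms / 1000.0
    out = {
        "participant_id": trial.participant_id,
        "class_label": trial.class_label,
        "trial_id": trial.trial_id,
        "fixation_frequency_hz": len(stream.fixations) / duration_s,
        "saccade_frequency_hz": len(stream.saccades) / duration_s,
    }
    for measure, group, attr in _MEASURES:
        events = getattr(stream, group)
        values = np.array([getattr(e, attr) for e in events], dtype=float)
        values = values[np.isfinite(values)]
        for d, v in zip(_DERIVATIONS, _aggregate(values)):
            out[f"{measure}_{d}"] = v
    return out


def feature_matrix(streams, policy: str = "drop"):
    """Feature table over trials: one row per trial, deterministic order.

    ``policy`` governs trials lacking an event type: ``"drop"`` removes them
    (count reported), ``"keep"`` leaves NaNs in place.  Returns
    ``(matrix, n_dropped)``.
    """
    if not streams:
        raise ValueError("empty dataset")
    if policy not in ("drop", "keep"):
        raise ValueError(f"unknown missing-feature policy {policy!r}")
    rows = [trial_features(s) for s in streams]
    matrix = pd.DataFrame(rows, columns=ID_COLUMNS + FEATURE_NAMES)
    matrix = matrix.sort_values(["participant_id", "trial_id"], kind="mergesort")
    matrix = matrix.reset_index(drop=True)
    n_dropped = 0
    if policy == "drop":
        complete = matrix[FEATURE_NAMES].notna().all(axis=1)
        n_dropped = int((~complete).sum())
        matrix = matrix[complete].reset_index(drop=True)
    return matrix, n_dropped


def class_summary(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-class mean and SD of every feature (population-table style report)."""
    agg = matrix.groupby("class_label")[FEATURE_NAMES].agg(["mean", "std"])
    agg.columns = [f"{feat}_{stat}" for feat, stat in agg.columns]
    return agg
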