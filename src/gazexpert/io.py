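"""CSV dialects for samples, events, features and run results.

The sample dialect is a minimal documented stand-in for proprietary
eye-tracker exports: one row per sample with columns ``trial_id,
participant_id, class_label, block, t_ms, x_px, y_px, valid``, grouped by
trial and time-sorted within each trial.  ``(x, y) = (0, 0)`` with
``valid = 0`` encodes a device error.  A column-mapping hook lets custom
vendor exports be adapted without touching the reader.

Every file written by the pipeline starts with a comment line recording the
config hash and seed that produced it; readers skip ``#`` comments.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .events import GazeTrial

SAMPLE_COLUMNS = [
    "trial_id", "participant_id", "class_label", "block",
    "t_ms", "x_px", "y_px", "valid",
]

EVENT_COLUMNS = [
    "trial_id", "participant_id", "class_label", "event_type",
    "start_ms", "end_ms", "duration_ms", "centroid_x_px", "centroid_y_px",
    "dispersion_px", "amplitude_deg", "mean_velocity", "peak_velocity",
    "mean_acceleration", "peak_acceleration", "peak_deceleration",
    "n_samples", "n_invalid", "start_invalid", "reasons",
    "trial_duration_ms", "tracking_ratio",
]


class DataFormatError(ValueError):
    """Malformed input data; message carries the first offending line."""


def _stamp(path, config_hash: str = "", seed=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# gazexpert config_hash={config_hash or 'n/a'} seed={seed}\n")


def write_trials(trials, path, config_hash: str = "", seed=None) -> None:
    """Serialize trials to the sample CSV dialect."""
    frames = []
    for tr in trials:
        frames.append(pd.DataFrame({
            "trial_id": tr.trial_id,
            "participant_id": tr.participant_id,
            "class_label": tr.class_label,
            "block": tr.block,
            "t_ms": tr.t_ms,
            "x_px": tr.x,
            "y_px": tr.y,
            "valid": tr.valid.astype(int),
        }))
    _stamp(path, config_hash, seed)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, mode="a")


def read_trials(path, rate_hz: float = 250.0, frame=(3840, 1920),
                column_map: dict | None = None) -> list:
    """Parse the sample dialect back into trials.

    ``column_map`` renames vendor columns onto the dialect's schema before
    validation.  Unsorted timestamps or duplicate (trial, t) pairs raise
    :class:`DataFormatError` naming the first offending CSV line (1-based,
    header and stamp included).
    """
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"missing columns: {missing}")
    # line numbers: +2 for header row and 1-based counting, +1 for the stamp
    offset = 3
    trials = []
    for trial_id, g in df.groupby("trial_id", sort=True):
        t = g["t_ms"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            line = int(g.index[bad[0] + 1]) + offset
            kind = "duplicate timestamp" if t[bad[0] + 1] == t[bad[0]] else "unsorted time"
            raise DataFormatError(f"{kind} in trial {trial_id!r} at line {line}")
        trials.append(GazeTrial(
            participant_id=str(g["participant_id"].iloc[0]),
            class_label=str(g["class_label"].iloc[0]),
            trial_id=str(trial_id),
            block=int(g["block"].iloc[0]),
            t_ms=t,
            x=g["x_px"].to_numpy(dtype=float),
            y=g["y_px"].to_numpy(dtype=float),
            valid=g["valid"].to_numpy().astype(bool),
            rate_hz=rate_hz,
            frame=tuple(frame),
        ))
    return trials


def events_frame(streams, ledger=None) -> pd.DataFrame:
    """One row per event (plus gaps), typed columns, across trials."""
    from .cleaning import tracking_ratio

    rows = []
    for stream in streams:
        tr = stream.trial
        base = dict(trial_id=tr.trial_id, participant_id=tr.participant_id,
                    class_label=tr.class_label, trial_duration_ms=tr.duration_ms,
                    tracking_ratio=tracking_ratio(tr))
        for ev in stream.fixations + stream.pursuits:
            rows.append(dict(base, event_type=ev.kind, start_ms=ev.start_ms,
                             end_ms=ev.end_ms, duration_ms=ev.duration_ms,
                             centroid_x_px=ev.centroid[0], centroid_y_px=ev.centroid[1],
                             dispersion_px=ev.dispersion_px, amplitude_deg=np.nan,
                             mean_velocity=np.nan, peak_velocity=np.nan,
                             mean_acceleration=np.nan, peak_acceleration=np.nan,
                             peak_deceleration=np.nan, n_samples=ev.i1 - ev.i0 + 1,
                             n_invalid=ev.n_invalid, start_invalid=False, reasons=""))
        for ev in stream.saccades:
            rows.append(dict(base, event_type="saccade", start_ms=ev.start_ms,
                             end_ms=ev.end_ms, duration_ms=ev.duration_ms,
                             centroid_x_px=np.nan, centroid_y_px=np.nan,
                             dispersion_px=np.nan,
                             amplitude_deg=np.nan if ev.amplitude_deg is None else ev.amplitude_deg,
                             mean_velocity=ev.mean_velocity, peak_velocity=ev.peak_velocity,
                             mean_acceleration=ev.mean_acceleration,
                             peak_acceleration=ev.peak_acceleration,
                             peak_deceleration=ev.peak_deceleration,
                             n_samples=ev.i1 - ev.i0 + 1, n_invalid=ev.n_invalid,
                             start_invalid=bool(ev.start_invalid),
                             reasons=";".join(ev.reasons)))
        for gap in stream.gaps:
            rows.append(dict(base, event_type=gap.kind, start_ms=gap.start_ms,
                             end_ms=gap.end_ms, duration_ms=gap.duration_ms,
                             centroid_x_px=np.nan, centroid_y_px=np.nan,
                             dispersion_px=np.nan, amplitude_deg=np.nan,
                             mean_velocity=np.nan, peak_velocity=np.nan,
                             mean_acceleration=np.nan, peak_acceleration=np.nan,
                             peak_deceleration=np.nan, n_samples=0, n_invalid=0,
                             start_invalid=False, reasons=""))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_frame(df: pd.DataFrame, path, config_hash: str = "", seed=None) -> None:
    _stamp(path, config_hash, seed)
    df.to_csv(path, index=False, mode="a")


def read_frame(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def features_from_events_frame(df: pd.DataFrame, policy: str = "drop"):
    """Feature matrix computed from a serialized events table.

    Mirrors :func:`gazexpert.features.feature_matrix` for the CSV pipeline
    path (event streams round-trip through the events table losslessly at
    the aggregate level).
    """
    from .features import FEATURE_NAMES, ID_COLUMNS, _DERIVATIONS, _MEASURES, _aggregate

    kinds = {"fixations": "fixation", "pursuits": "pursuit", "saccades": "saccade"}
    attr_col = {
        "duration_ms": "duration_ms", "dispersion_px": "dispersion_px",
        "amplitude_deg": "amplitude_deg", "mean_velocity": "mean_velocity",
        "peak_velocity": "peak_velocity", "mean_acceleration": "mean_acceleration",
        "peak_acceleration": "peak_acceleration", "peak_deceleration": "peak_deceleration",
    }
    rows = []
    for trial_id, g in df.groupby("trial_id", sort=True):
        duration_s = float(g["trial_duration_ms"].iloc[0]) / 1000.0
        row = {
            "participant_id": str(g["participant_id"].iloc[0]),
            "class_label": str(g["class_label"].iloc[0]),
            "trial_id": str(trial_id),
            "fixation_frequency_hz": int((g["event_type"] == "fixation").sum()) / duration_s,
            "saccade_frequency_hz": int((g["event_type"] == "saccade").sum()) / duration_s,
        }
        for measure, group, attr in _MEASURES:
            sel = g[g["event_type"] == kinds[group]][attr_col[attr]]
            values = sel.to_numpy(dtype=float)
            values = values[np.isfinite(values)]
            for d, v in zip(_DERIVATIONS, _aggregate(values)):
                row[f"{measure}_{d}"] = v
        rows.append(row)
    matrix = pd.DataFrame(rows, columns=ID_COLUMNS + FEATURE_NAMES)
    matrix = matrix.sort_values(["participant_id", "trial_id"], kind="mergesort")
    matrix = matrix.reset_index(drop=True)
    n_dropped = 0
    if policy == "drop":
        complete = matrix[FEATURE_NAMES].notna().all(axis=1)
        n_dropped = int((~complete).sum())
        matrix = matrix[complete].reset_index(drop=True)
    return matrix, n_dropped


def runs_frame(results) -> pd.DataFrame:
    """Serializable table of run results (one row per run)."""
    rows = []
    for r in results:
        rows.append({
            "run_index": r.run_index,
            "regime": r.regime,
            "seed": r.seed,
            "n_eval": r.n_eval,
            "accuracy": r.accuracy,
            **{f"miss_rate_{lab}": r.miss_rates[lab] for lab in r.labels},
            **{f"recall_{lab}": r.recalls[lab] for lab in r.labels},
            "confusion": json.dumps(r.confusion.tolist()),
            "top_features": ";".join(r.importance[:10]),
        })
    return pd.DataFrame(rows)
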