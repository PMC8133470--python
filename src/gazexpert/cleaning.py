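"""Trial-level and saccade-level quality control, plus saccade amplitude.

Two filters mirror the recording pipeline's quality rules:

* trials with a tracking ratio (valid samples / total samples) below 75% are
  discarded outright — gaze below that threshold is not reliable;
* individual saccades are removed when (1) their starting sample is invalid,
  (2) any intra-saccade sample is invalid, or (3) their kinematics exceed
  physiological bounds (peak velocity > 1000 deg/s, |peak acceleration| or
  |peak deceleration| > 100,000 deg/s^2).

A sample counts as invalid here if the device flagged it *or* if it sits at
the (0;0) error encoding; reasons may co-occur, and a saccade violating
several rules is removed (and counted) once.  Saccade amplitude follows the
path-length definition: mean sample-to-sample angular velocity times event
duration, i.e. the total distance travelled along the possibly curved
trajectory, not the start-to-end chord.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .events import EventStream, SaccadeRecord

TRACKING_RATIO_THRESHOLD = 0.75
MAX_PEAK_VELOCITY = 1000.0      # deg/s
MAX_ABS_ACCELERATION = 100_000.0  # deg/s^2

#: Reason codes, part of the public events-table schema.
REASONS = ("invalid_start", "invalid_intra", "velocity_bound", "accel_bound")


def tracking_ratio(trial) -> float:
    """Fraction of a trial's samples the device flagged as validly tracked."""
    if trial.n_samples == 0:
        raise ValueError("empty trial")
    return float(trial.valid.mean())


@dataclass
class TrialFilterLedger:
    threshold: float
    n_total: int
    n_kept: int
    removed_per_participant: dict

    @property
    def n_removed(self) -> int:
        return self.n_total - self.n_kept

    @property
    def fraction_lost(self) -> float:
        return self.n_removed / self.n_total if self.n_total else 0.0


def filter_trials(trials, threshold: float = TRACKING_RATIO_THRESHOLD):
    """Discard trials below the tracking-ratio threshold; account per participant."""
    kept, removed = [], {}
    for tr in trials:
        if tracking_ratio(tr) < threshold:
            removed[tr.participant_id] = removed.get(tr.participant_id, 0) + 1
        else:
            kept.append(tr)
    ledger = TrialFilterLedger(threshold, len(trials), len(kept), removed)
    return kept, ledger


def saccade_amplitude(record: SaccadeRecord) -> float:
    """Amplitude in degrees: mean sample-to-sample speed x event duration.

    Equals the angular path length along the trajectory (for a straight
    saccade traversed in equal steps this reduces to the chord length).
    Invalid pairs are excluded from the mean, never interpolated.
    """
    if record.speeds is None or record.speeds.size < 1 or record.i1 - record.i0 < 1:
        raise ValueError("amplitude needs a record with at least two samples")
    return float(record.mean_velocity * record.duration_ms / 1000.0)


def validate_saccade(
    record: SaccadeRecord,
    max_velocity: float = MAX_PEAK_VELOCITY,
    max_acceleration: float = MAX_ABS_ACCELERATION,
) -> frozenset:
    """Quality reasons for one saccade; an empty set means keep."""
    reasons = set()
    if record.start_invalid:
        reasons.add("invalid_start")
    if record.n_invalid > (1 if record.start_invalid else 0):
        reasons.add("invalid_intra")
    if record.peak_velocity > max_velocity:
        reasons.add("velocity_bound")
    if abs(record.peak_acceleration) > max_acceleration or (
        abs(record.peak_deceleration) > max_acceleration
    ):
        reasons.add("accel_bound")
    return frozenset(reasons)


@dataclass
class CleaningReport:
    n_saccades: int = 0
    n_removed: int = 0
    removed_by_reason: dict = field(default_factory=lambda: {r: 0 for r in REASONS})
    n_samples: int = 0
    n_samples_removed: int = 0

    @property
    def fraction_saccades_removed(self) -> float:
        return self.n_removed / self.n_saccades if self.n_saccades else 0.0

    @property
    def fraction_samples_removed(self) -> float:
        return self.n_samples_removed / self.n_samples if self.n_samples else 0.0


def clean_stream(stream: EventStream, max_velocity=MAX_PEAK_VELOCITY,
                 max_acceleration=MAX_ABS_ACCELERATION):
    """Annotate amplitudes and reasons; drop flagged saccades from the stream."""
    kept = []
    removed = []
    for rec in stream.saccades:
        rec.amplitude_deg = saccade_amplitude(rec)
        rec.reasons = tuple(sorted(validate_saccade(rec, max_velocity, max_acceleration)))
        (removed if rec.reasons else kept).append(rec)
    cleaned = EventStream(
        trial=stream.trial,
        fixations=stream.fixations,
        pursuits=stream.pursuits,
        saccades=kept,
        gaps=stream.gaps,
    )
    return cleaned, removed


def clean_dataset(streams, max_velocity=MAX_PEAK_VELOCITY,
                  max_acceleration=MAX_ABS_ACCELERATION):
    """Apply saccade quality rules across segmented trials.

    Fixations and smooth pursuits are left untouched.  The report counts each
    removed saccade once in the total even when reasons co-occur.
    """
    report = CleaningReport()
    cleaned_streams = []
    for stream in streams:
        cleaned, removed = clean_stream(stream, max_velocity, max_acceleration)
        cleaned_streams.append(cleaned)
        report.n_saccades += len(stream.saccades)
        report.n_removed += len(removed)
        report.n_samples += stream.trial.n_samples
        for rec in removed:
            report.n_samples_removed += rec.i1 - rec.i0 + 1
            for r in rec.reasons:
                report.removed_by_reason[r] += 1
    return cleaned_streams, report
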