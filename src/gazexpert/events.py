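"""Segmentation of raw 250 Hz gaze traces into saccades, fixations and smooth pursuits.

The detector is a velocity-threshold (I-VT style) segmentation: per-sample
angular speeds are computed on the equirectangular frame, maximal runs of
supra-threshold speed become saccade candidates, and the complement intervals
between saccades and tracking-loss gaps become fixations.  Fixation-like
intervals whose spatial dispersion (I-DT bounding-box sum) exceeds a pixel
threshold are relabelled smooth pursuits, since slow tracking of a moving
target looks like a long, wide fixation to a velocity detector.

Angular geometry follows the equirectangular convention of the recording
set-up: a full frame width corresponds to a 360° horizontal turn and a full
frame height to a 360° vertical turn, so on a 3840x1920 frame one pixel is
0.09375° horizontally and 0.1875° vertically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default equirectangular frame size in pixels (width, height).
DEFAULT_FRAME = (3840, 1920)
#: Peak-velocity threshold for saccade detection, deg/s.
SACCADE_PEAK_THRESHOLD = 40.0
#: Minimum fixation duration, ms; shorter inter-saccade intervals are rejected.
MIN_FIXATION_MS = 50.0
#: Dispersion split between fixations and smooth pursuits, px.
PURSUIT_DISPERSION_PX = 100.0
#: Minimum saccade length in inter-sample (pair) steps.
MIN_SACCADE_SAMPLES = 3
#: Invalid runs at least this many samples long become tracking-loss gaps.
GAP_MIN_SAMPLES = 25


def px_to_deg(dx, dy, frame=DEFAULT_FRAME, wrap_x: bool = False):
    """Convert a pixel displacement to degrees of visual angle.

    ``wrap_x`` optionally folds horizontal displacements across the
    equirectangular seam (360° footage is continuous there); it is off by
    default, matching the arithmetic convention in which 2400 px on a
    3840 px frame is a 225° sweep.
    """
    w, h = frame
    if w <= 0 or h <= 0:
        raise ValueError(f"frame dimensions must be positive, got {frame}")
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if wrap_x:
        dx = (dx + w / 2.0) % w - w / 2.0
    return dx * 360.0 / w, dy * 360.0 / h


def deg_to_px(ax, ay, frame=DEFAULT_FRAME):
    """Inverse of :func:`px_to_deg` (no seam wrap); round-trips exactly."""
    w, h = frame
    if w <= 0 or h <= 0:
        raise ValueError(f"frame dimensions must be positive, got {frame}")
    return np.asarray(ax, dtype=float) * w / 360.0, np.asarray(ay, dtype=float) * h / 360.0


@dataclass
class GazeTrial:
    """One participant x stimulus trace: time-ordered samples with validity flags.

    ``valid`` carries the device's own confidence signal; a sample at (0;0)
    is the device's error encoding and may additionally appear *unflagged* in
    raw exports — cleaning treats such samples as invalid regardless of flag.
    """

    participant_id: str
    class_label: str
    trial_id: str
    block: int
    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    rate_hz: float = 250.0
    frame: tuple = DEFAULT_FRAME
    truth: list | None = None  # generator ground truth, when simulated

    def __post_init__(self):
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.t_ms.size == 0:
            raise ValueError("trial must contain at least one sample")
        if not (self.t_ms.size == self.x.size == self.y.size == self.valid.size):
            raise ValueError("t_ms, x, y and valid must have equal length")
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return int(self.t_ms.size)

    @property
    def duration_ms(self) -> float:
        return float(self.t_ms[-1] - self.t_ms[0])

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate_hz

    def effective_invalid(self) -> np.ndarray:
        """Invalid by device flag *or* by the (0;0) error encoding."""
        return (~self.valid) | ((self.x == 0) & (self.y == 0))


@dataclass
class Fixation:
    start_ms: float
    end_ms: float
    duration_ms: float
    centroid: tuple
    dispersion_px: float
    i0: int  # first sample index
    i1: int  # last sample index
    n_invalid: int = 0

    @property
    def kind(self) -> str:
        return "fixation"


@dataclass
class SmoothPursuit(Fixation):
    @property
    def kind(self) -> str:
        return "pursuit"


@dataclass
class SaccadeRecord:
    start_ms: float
    end_ms: float
    duration_ms: float
    i0: int
    i1: int
    speeds: np.ndarray = field(repr=False, default=None)
    mean_velocity: float = np.nan
    peak_velocity: float = np.nan
    mean_acceleration: float = np.nan
    peak_acceleration: float = np.nan
    peak_deceleration: float = np.nan
    amplitude_deg: float | None = None  # filled by the cleaning stage (Eq 1-2)
    n_invalid: int = 0
    start_invalid: bool = False
    reasons: tuple = ()

    @property
    def kind(self) -> str:
        return "saccade"


@dataclass
class GapInterval:
    start_ms: float
    end_ms: float
    kind: str  # "tracking_loss" (blink/device loss) or "discarded" (<50 ms interval)

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class EventStream:
    """Ordered, non-overlapping events plus gaps tiling one trial's timeline."""

    trial: GazeTrial
    fixations: list
    pursuits: list
    saccades: list
    gaps: list

    def all_events(self):
        ev = self.fixations + self.pursuits + self.saccades
        return sorted(ev, key=lambda e: e.start_ms)

    def span_accounting(self) -> float:
        """Summed duration of all events and gaps (equals trial duration)."""
        total = sum(e.duration_ms for e in self.all_events())
        total += sum(g.duration_ms for g in self.gaps)
        return total


def sample_velocity(trial: GazeTrial, wrap_x: bool = False) -> np.ndarray:
    """Per-pair angular speed in deg/s; pairs touching a flagged-invalid sample are NaN.

    Speed i covers the interval between samples i and i+1.  Note that masking
    follows the device *flag* only: unflagged (0;0) error samples produce the
    same physically impossible speeds the device itself would report, which is
    exactly what the cleaning bounds are there to catch.
    """
    if trial.n_samples < 2:
        raise ValueError("velocity needs at least two samples")
    ax, ay = px_to_deg(np.diff(trial.x), np.diff(trial.y), trial.frame, wrap_x=wrap_x)
    dt_s = np.diff(trial.t_ms) / 1000.0
    speeds = np.hypot(ax, ay) / dt_s
    bad = ~(trial.valid[:-1] & trial.valid[1:])
    speeds[bad] = np.nan
    return speeds


def _bool_runs(mask: np.ndarray):
    """Maximal runs of True as (start, end) inclusive index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def detect_saccades(
    speeds: np.ndarray,
    threshold: float = SACCADE_PEAK_THRESHOLD,
    min_samples: int = MIN_SACCADE_SAMPLES,
    merge_gap: int = 1,
    max_bridge: int = GAP_MIN_SAMPLES - 1,
):
    """Candidate saccades as maximal supra-threshold speed runs (pair indices).

    Runs separated by at most ``merge_gap`` finite sub-threshold samples are
    merged (robustness to single-sample flicker), and runs separated by short
    all-or-mostly-NaN stretches — tracking dropouts shorter than a blink gap —
    are bridged so that a saccade interrupted by a device error stays one
    saccade.  Runs spanning fewer than ``min_samples`` pairs are discarded.
    """
    speeds = np.asarray(speeds, dtype=float)
    finite = np.isfinite(speeds)
    supra = np.zeros(speeds.shape, dtype=bool)
    supra[finite] = speeds[finite] > threshold
    runs = _bool_runs(supra)
    merged: list[list[int]] = []
    for i, j in runs:
        if merged:
            lo, hi = merged[-1][1] + 1, i - 1
            sep = speeds[lo : hi + 1]
            n_sep = hi - lo + 1
            n_finite = int(np.isfinite(sep).sum())
            if n_sep <= max_bridge and n_finite <= merge_gap:
                merged[-1][1] = j
                continue
        merged.append([i, j])
    return [(i, j) for i, j in merged if j - i + 1 >= min_samples]


def detect_gaps(trial: GazeTrial, min_samples: int = GAP_MIN_SAMPLES):
    """Blink / tracking-loss intervals: runs of >= min_samples flagged-invalid samples."""
    return [(s, e) for s, e in _bool_runs(~trial.valid) if e - s + 1 >= min_samples]


def dispersion(x, y, valid=None) -> float:
    """I-DT bounding-box dispersion: (max x - min x) + (max y - min y), px.

    Computed over valid samples only; raises on an all-invalid event.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        x, y = x[valid], y[valid]
    if x.size == 0:
        raise ValueError("dispersion needs at least one valid sample")
    return float((x.max() - x.min()) + (y.max() - y.min()))


def assemble_fixations(n_pairs, saccade_runs, gap_runs, dt_ms, min_fixation_ms=MIN_FIXATION_MS):
    """Complement pair-intervals between saccades and gaps.

    Returns (kept, discarded) lists of inclusive pair runs; intervals shorter
    than the minimum fixation duration are rejected, not emitted as fixations.
    """
    occupied = np.zeros(n_pairs, dtype=bool)
    for i, j in list(saccade_runs) + list(gap_runs):
        occupied[i : j + 1] = True
    kept, discarded = [], []
    for i, j in _bool_runs(~occupied):
        if (j - i + 1) * dt_ms >= min_fixation_ms:
            kept.append((i, j))
        else:
            discarded.append((i, j))
    return kept, discarded


def split_smooth_pursuits(fixations, threshold: float = PURSUIT_DISPERSION_PX):
    """Partition fixation-like events by dispersion; > threshold => smooth pursuit."""
    fix, pursuits = [], []
    for f in fixations:
        if f.dispersion_px > threshold:
            pursuits.append(
                SmoothPursuit(
                    f.start_ms, f.end_ms, f.duration_ms, f.centroid,
                    f.dispersion_px, f.i0, f.i1, f.n_invalid,
                )
            )
        else:
            fix.append(f)
    return fix, pursuits


def _saccade_record(trial, speeds, i, j, invalid_eff, dt_s):
    t = trial.t_ms
    s_run = speeds[i : j + 1]
    finite = s_run[np.isfinite(s_run)]
    mean_v = float(finite.mean()) if finite.size else np.nan
    peak_v = float(finite.max()) if finite.size else np.nan
    acc = np.diff(s_run) / dt_s
    acc_f = acc[np.isfinite(acc)]
    pos = acc_f[acc_f > 0]
    mean_a = float(pos.mean()) if pos.size else 0.0
    peak_a = float(acc_f.max()) if acc_f.size else np.nan
    peak_d = float(acc_f.min()) if acc_f.size else np.nan
    inv = invalid_eff[i : j + 2]
    return SaccadeRecord(
        start_ms=float(t[i]),
        end_ms=float(t[j + 1]),
        duration_ms=float(t[j + 1] - t[i]),
        i0=i,
        i1=j + 1,
        speeds=s_run.copy(),
        mean_velocity=mean_v,
        peak_velocity=peak_v,
        mean_acceleration=mean_a,
        peak_acceleration=peak_a,
        peak_deceleration=peak_d,
        n_invalid=int(inv.sum()),
        start_invalid=bool(inv[0]),
    )


def segment_trial(
    trial: GazeTrial,
    threshold: float = SACCADE_PEAK_THRESHOLD,
    min_fixation_ms: float = MIN_FIXATION_MS,
    pursuit_dispersion_px: float = PURSUIT_DISPERSION_PX,
    min_saccade_samples: int = MIN_SACCADE_SAMPLES,
    merge_gap: int = 1,
    gap_min_samples: int = GAP_MIN_SAMPLES,
    wrap_x: bool = False,
) -> EventStream:
    """Segment one trial into an ordered, non-overlapping event stream.

    Events are defined on inter-sample (pair) intervals so that fixations,
    pursuits, saccades, tracking-loss gaps and rejected (<50 ms) intervals tile
    the trial timeline exactly.  Short invalid runs immediately adjacent to a
    detected saccade are attached to it — during a dropout abutting a saccade
    the true onset/offset is unknowable, and the paper's quality rules exist
    precisely to remove such saccades downstream.
    """
    if trial.n_samples < 2:
        raise ValueError("cannot segment a single-sample trial")
    n_pairs = trial.n_samples - 1
    dt_ms = trial.dt_ms
    dt_s = dt_ms / 1000.0
    speeds = sample_velocity(trial, wrap_x=wrap_x)
    invalid_eff = trial.effective_invalid()

    gap_sample_runs = detect_gaps(trial, gap_min_samples) or []
    gap_pair_runs = [(max(s - 1, 0), min(e, n_pairs - 1)) for s, e in gap_sample_runs]
    in_gap = np.zeros(n_pairs, dtype=bool)
    for i, j in gap_pair_runs:
        in_gap[i : j + 1] = True

    sac_runs = detect_saccades(
        speeds, threshold, min_saccade_samples, merge_gap, max_bridge=gap_min_samples - 1
    )
    # attach short invalid sample runs that directly flank a saccade
    valid = trial.valid
    attached = []
    prev_end = -1
    for i, j in sac_runs:
        while i - 1 > prev_end and not valid[i - 1] and not in_gap[i - 1]:
            i -= 1
        while j + 1 < n_pairs and not valid[j + 2] and not in_gap[j + 1]:
            j += 1
        attached.append((i, j))
        prev_end = j
    # clip saccades out of gap regions (bridging never spans a full gap, but
    # attachment must not eat into one)
    sac_runs = []
    for i, j in attached:
        while i <= j and in_gap[i]:
            i += 1
        while j >= i and in_gap[j]:
            j -= 1
        if j - i + 1 >= min_saccade_samples:
            sac_runs.append((i, j))

    fix_runs, short_runs = assemble_fixations(
        n_pairs, sac_runs, gap_pair_runs, dt_ms, min_fixation_ms
    )

    t = trial.t_ms
    fixations = []
    discarded_extra = []
    for i, j in fix_runs:
        s0, s1 = i, j + 1
        ok = ~invalid_eff[s0 : s1 + 1]
        if not ok.any():
            discarded_extra.append((i, j))
            continue
        xs = trial.x[s0 : s1 + 1][ok]
        ys = trial.y[s0 : s1 + 1][ok]
        fixations.append(
            Fixation(
                start_ms=float(t[s0]),
                end_ms=float(t[s1]),
                duration_ms=float(t[s1] - t[s0]),
                centroid=(float(xs.mean()), float(ys.mean())),
                dispersion_px=float((xs.max() - xs.min()) + (ys.max() - ys.min())),
                i0=s0,
                i1=s1,
                n_invalid=int(invalid_eff[s0 : s1 + 1].sum()),
            )
        )
    fixations, pursuits = split_smooth_pursuits(fixations, pursuit_dispersion_px)

    saccades = [_saccade_record(trial, speeds, i, j, invalid_eff, dt_s) for i, j in sac_runs]

    gaps = [
        GapInterval(float(t[i]), float(t[j + 1]), "tracking_loss") for i, j in gap_pair_runs
    ]
    gaps += [
        GapInterval(float(t[i]), float(t[j + 1]), "discarded")
        for i, j in short_runs + discarded_extra
    ]
    gaps.sort(key=lambda g: g.start_ms)
    return EventStream(trial=trial, fixations=fixations, pursuits=pursuits,
                       saccades=saccades, gaps=gaps)
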