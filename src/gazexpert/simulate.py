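"""Synthetic 250 Hz gaze-trace generator with class-conditioned event statistics.

The generator emulates what the analysis pipeline assumes about real
recordings: trials are alternating sequences of hold events (fixations and
smooth pursuits) separated by ballistic saccades, rendered as (x, y) pixel
positions on a 3840x1920 equirectangular frame, with participant-level
idiosyncratic offsets and device-error injection ((0;0) dropout bursts,
position-spike artefacts, low-tracking-ratio trials).

Event statistics are sampled from truncated log-normal distributions
moment-matched to per-class population targets (fixation duration and
dispersion, saccade duration, amplitude and peak velocity, pursuit
dispersion).  Saccades follow a Beta(a, a)-family speed profile whose
peakedness is fitted per event to the sampled peak velocity, so amplitude,
duration and peak velocity all calibrate against their targets while mean
velocity and the acceleration summaries emerge from the kinematics.  Holds
are slow drifts (plus smoothed micro-jitter) rescaled to an exact target
dispersion; drift speed is kept safely below the saccade detector's velocity
threshold, which forces two departures from the population tables, both
documented in the methods note: a fixation whose sampled dispersion would
require supra-threshold drift has its duration lengthened, and smooth-pursuit
duration is emergent (dispersion / drift speed) rather than sampled, because
the tabled pursuit duration/dispersion pairs are mutually inconsistent under
a 40 deg/s velocity-threshold segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.special import beta as _beta_fn
from scipy.special import betainc
from scipy.stats import norm

from .events import DEFAULT_FRAME, GazeTrial, deg_to_px

CLASS_LABELS = ("novice", "intermediate", "expert")

#: Measure names shared by every ClassProfile (schema-identical across classes).
MEASURES = (
    "fixation_duration_ms",
    "fixation_dispersion_px",
    "saccade_duration_ms",
    "saccade_amplitude_deg",
    "saccade_mean_acceleration",
    "saccade_peak_acceleration",
    "saccade_peak_deceleration",
    "saccade_mean_velocity",
    "saccade_peak_velocity",
    "pursuit_duration_ms",
    "pursuit_dispersion_px",
)

#: Closed-loop calibration offsets compensating systematic detector effects
#: (saccade tails accrue to neighbouring holds; supra-threshold runs are
#: slightly shorter than the nominal kinematic duration).  Estimated once by
#: regressing detected against nominal event statistics on large simulated
#: samples; see docs/methods.md.
CALIBRATION = {
    "saccade_pad_ms": 2.0,        # added to the detected-duration target
    "threshold_margin": 1.10,     # tail solve uses margin*threshold (discrete
                                  # crossing bins average below the threshold)
    "fixation_pad_ms": 16.0,      # subtracted from nominal fixation duration
    "hold_disp_pad_px": 0.0,      # subtracted from nominal hold dispersion
    "render_cut": 0.55,           # saccade tails rendered down to cut*threshold
}


@dataclass(frozen=True)
class MeasureSpec:
    """Population target for one event measure: mean/SD plus truncation range."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("scale parameter must be >= 0")
        if not (self.lo <= self.mean <= self.hi):
            raise ValueError(f"mean {self.mean} outside [{self.lo}, {self.hi}]")

    def scaled(self, factor: float) -> "MeasureSpec":
        return MeasureSpec(self.mean * factor, self.sd * factor,
                           self.lo * factor, self.hi * factor)


@dataclass
class ClassProfile:
    """Per-class generator targets plus event-rate and pursuit parameters.

    ``fixations_per_s`` / ``saccades_per_s`` are nominal event rates: event
    pacing is duration-driven (holds and saccades alternate), so the realised
    rates emerge from the duration targets; setting either rate to zero
    degenerates the trial to a single fixation.
    """

    class_label: str
    measures: dict
    fixations_per_s: float = 2.0
    saccades_per_s: float = 2.5
    pursuit_fraction: float = 0.25
    pursuit_drift_speed: float = 26.0  # deg/s, kept well below the 40 deg/s threshold

    def __post_init__(self):
        missing = set(MEASURES) - set(self.measures)
        if missing:
            raise ValueError(f"profile lacks measures: {sorted(missing)}")
        for name in ("fixation_duration_ms", "saccade_duration_ms", "pursuit_duration_ms"):
            if self.measures[name].mean <= 0:
                raise ValueError(f"{name} location must be positive")
        if not 0 <= self.pursuit_fraction <= 1:
            raise ValueError("pursuit_fraction must lie in [0, 1]")


@dataclass
class ParticipantProfile:
    """A ClassProfile displaced by zero-mean relative idiosyncratic offsets."""

    participant_id: str
    class_label: str
    offsets: dict
    base: ClassProfile

    def effective(self) -> ClassProfile:
        measures = {
            name: spec.scaled(1.0 + self.offsets.get(name, 0.0))
            for name, spec in self.base.measures.items()
        }
        return replace(self.base, measures=measures)


@dataclass
class SimConfig:
    """Study conditions for dataset generation."""

    participants_per_class: dict = field(
        default_factory=lambda: {"expert": 12, "intermediate": 10, "novice": 13}
    )
    trials_per_participant: int = 52
    trial_duration_s: float = 20.0
    rate_hz: float = 250.0
    frame: tuple = DEFAULT_FRAME
    dropout_rate: float = 0.006          # target invalid-sample fraction
    dropout_burst_mean: float = 3.0      # geometric mean burst length, samples
    spike_rate: float = 0.00025          # position-artefact bursts per sample
    low_track_fraction: float = 0.034    # trials degraded below 75% tracking
    idiosyncrasy_spread: float = 0.05    # SD of relative participant offsets
    jitter_px: float = 0.2               # micro-jitter amplitude within holds
    saccade_threshold: float = 40.0      # deg/s, mirrored from the detector
    pursuit_split_px: float = 100.0      # dispersion split, mirrored from the detector
    seed: int = 0

    def __post_init__(self):
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.frame[0] <= 0 or self.frame[1] <= 0:
            raise ValueError("frame dimensions must be positive")
        for name in ("dropout_rate", "spike_rate", "low_track_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.idiosyncrasy_spread < 0:
            raise ValueError("idiosyncrasy spread must be >= 0")


def _spec(mean, sd, lo, hi):
    return MeasureSpec(mean, sd, lo, hi)


def default_class_profiles() -> dict:
    """The three expertise-class profiles carrying the population targets.

    The kinematic measures (mean velocity, accelerations, pursuit duration)
    are stored as reference values; they emerge from the saccade speed profile
    and the pursuit drift model rather than being sampled directly.
    """
    novice = ClassProfile(
        class_label="novice",
        measures={
            "fixation_duration_ms": _spec(214.017, 31.926, 190.49, 239.30),
            "fixation_dispersion_px": _spec(72.092, 25.68, 24.67, 110.523),
            "saccade_duration_ms": _spec(71.688, 38.869, 26.514, 175.460),
            "saccade_amplitude_deg": _spec(9.294, 9.417, 0.574, 51.402),
            "saccade_mean_acceleration": _spec(4263.381, 2482.019, 366.666, 13984.563),
            "saccade_peak_acceleration": _spec(9322.483168, 5777.273817, 231.836, 28355.224),
            "saccade_peak_deceleration": _spec(-6848.104, 4166.262, -35563.646, -411.760),
            "saccade_mean_velocity": _spec(105.463, 65.023, 20.288, 298.134),
            "saccade_peak_velocity": _spec(215.245, 129.294, 40.310, 766.157),
            "pursuit_duration_ms": _spec(302.637, 278.112, 75.629, 1026.329),
            "pursuit_dispersion_px": _spec(622.805, 201.268, 185.437, 1085.903),
        },
    )
    intermediate = ClassProfile(
        class_label="intermediate",
        measures={
            "fixation_duration_ms": _spec(255.225, 53.379, 215.835, 299.623),
            "fixation_dispersion_px": _spec(73.173, 26.548, 23.070, 114.762),
            "saccade_duration_ms": _spec(84.349, 59.726, 26.127, 246.121),
            "saccade_amplitude_deg": _spec(9.883, 10.674, 0.572, 54.835),
            "saccade_mean_acceleration": _spec(4123.970, 2685.991, 315.346, 15472.889),
            "saccade_peak_acceleration": _spec(8920.177, 5989.251, 216.722, 28266.000),
            "saccade_peak_deceleration": _spec(-6948.491, 4770.063, -36334.137, -231.355),
            "saccade_mean_velocity": _spec(104.199, 66.682, 21.520, 331.111),
            "saccade_peak_velocity": _spec(213.835, 136.529, 40.109, 764.027),
            "pursuit_duration_ms": _spec(291.092, 278.718, 73.835, 977.120),
            "pursuit_dispersion_px": _spec(425.089, 124.853, 168.320, 694.370),
        },
    )
    expert = ClassProfile(
        class_label="expert",
        measures={
            "fixation_duration_ms": _spec(241.509, 58.629, 198.132, 291.721),
            "fixation_dispersion_px": _spec(72.837, 25.989, 21.736, 114.549),
            "saccade_duration_ms": _spec(65.472, 35.548, 25.019, 163.415),
            "saccade_amplitude_deg": _spec(8.938, 9.430, 0.567, 52.029),
            "saccade_mean_acceleration": _spec(4769.655, 3064.343, 390.094, 18965.944),
            "saccade_peak_acceleration": _spec(10026.456, 7094.930, 175.242, 39445.125),
            "saccade_peak_deceleration": _spec(-7912.190, 5492.287, -43479.916, -362.396),
            "saccade_mean_velocity": _spec(110.675, 72.737, 21.182, 375.363),
            "saccade_peak_velocity": _spec(238.371, 157.740, 40.262, 935.514),
            "pursuit_duration_ms": _spec(276.785, 265.679, 74.404, 953.660),
            "pursuit_dispersion_px": _spec(399.939, 112.414, 336.016, 505.031),
        },
    )
    return {"novice": novice, "intermediate": intermediate, "expert": expert}


def sample_participant(
    profile: ClassProfile,
    spread: float,
    rng: np.random.Generator,
    participant_id: str = "P00",
) -> ParticipantProfile:
    """Draw a participant with i.i.d. zero-mean relative offsets on each measure.

    Offsets are relative (dimensionless) so a single spread parameter applies
    across measures with very different units; zero spread reproduces the
    class profile exactly and the expectation of every measure equals the
    class value.
    """
    if spread < 0:
        raise ValueError("idiosyncrasy spread must be >= 0")
    if spread == 0:
        offsets = {name: 0.0 for name in MEASURES}
    else:
        draws = np.clip(rng.normal(0.0, spread, len(MEASURES)), -0.6, 0.6)
        offsets = dict(zip(MEASURES, draws))
    return ParticipantProfile(participant_id, profile.class_label, offsets, profile)


def _trunc_lognormal(rng, spec: MeasureSpec, size=None):
    """Log-normal moment-matched to (mean, sd), rejection-truncated to [lo, hi]."""
    if spec.mean <= 0:
        raise ValueError("truncated log-normal requires a positive location")
    if spec.sd == 0:
        return np.full(size, spec.mean) if size else spec.mean
    sigma2 = math.log(1.0 + (spec.sd / spec.mean) ** 2)
    mu = math.log(spec.mean) - sigma2 / 2.0
    n = 1 if size is None else int(size)
    out = np.empty(n)
    filled = 0
    for _ in range(20):
        draw = rng.lognormal(mu, math.sqrt(sigma2), max(2 * (n - filled), 8))
        ok = draw[(draw >= spec.lo) & (draw <= spec.hi)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
        if filled == n:
            break
    if filled < n:  # pathological truncation window; clip the remainder
        out[filled:] = np.clip(rng.lognormal(mu, math.sqrt(sigma2), n - filled),
                               spec.lo, spec.hi)
    return float(out[0]) if size is None else out


@lru_cache(maxsize=512)
def _matched_lognormal_params(mean, sd, lo, hi):
    """Log-normal (mu, sigma) whose [lo, hi]-truncated mean equals ``mean``.

    Truncation of a moment-matched log-normal shifts its mean; this solves
    (by bisection on the analytic truncated-lognormal mean) for the location
    shift restoring the target, so detection-level truncation caps do not
    bias the calibrated measures.
    """
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    s = math.sqrt(sigma2)
    llo, lhi = math.log(max(lo, 1e-9)), math.log(hi)

    def trunc_mean(mu):
        a, b = (llo - mu) / s, (lhi - mu) / s
        den = norm.cdf(b) - norm.cdf(a)
        if den < 1e-12:
            return math.exp(mu + sigma2 / 2.0)
        num = math.exp(mu + sigma2 / 2.0) * (norm.cdf(b - s) - norm.cdf(a - s))
        return num / den

    mu0 = math.log(mean) - sigma2 / 2.0
    lo_mu, hi_mu = mu0 - 2.0, mu0 + 2.0
    for _ in range(60):
        mid = 0.5 * (lo_mu + hi_mu)
        if trunc_mean(mid) < mean:
            lo_mu = mid
        else:
            hi_mu = mid
    return 0.5 * (lo_mu + hi_mu), s


def _trunc_lognormal_matched(rng, spec: MeasureSpec, hi_cap: float | None = None,
                             lo_cap: float | None = None):
    """Truncated log-normal draw with the truncated mean pinned to spec.mean."""
    hi = min(spec.hi, hi_cap) if hi_cap is not None else spec.hi
    if spec.sd == 0 or spec.mean <= 0:
        return min(spec.mean, hi)
    lo = max(spec.lo, lo_cap) if lo_cap is not None else spec.lo
    lo = min(lo, hi * 0.99)
    mu, s = _matched_lognormal_params(spec.mean, spec.sd, lo, hi)
    for _ in range(64):
        draw = rng.lognormal(mu, s)
        if lo <= draw <= hi:
            return float(draw)
    return float(np.clip(rng.lognormal(mu, s), lo, hi))


# peak/mean velocity ratio of the Beta(a, a) speed profile, on a monotone grid
_SHAPE_A = np.linspace(1.1, 9.0, 240)
_SHAPE_RHO = 1.0 / (_beta_fn(_SHAPE_A, _SHAPE_A) * 4.0 ** (_SHAPE_A - 1.0))


def _shape_for_ratio(rho: float) -> float:
    return float(np.interp(rho, _SHAPE_RHO, _SHAPE_A))


def _deg_factor(ux, uy, frame):
    """Angular degrees swept per pixel step along px-space unit vector (ux, uy)."""
    return math.hypot(ux * 360.0 / frame[0], uy * 360.0 / frame[1])


def _steered_direction(rng, pos, frame, min_angle_deg=2.0, max_angle_deg=24.0):
    """Mostly horizontal px-space unit direction, biased toward frame centre."""
    theta = math.radians(rng.uniform(min_angle_deg, max_angle_deg))
    sy = 1.0 if rng.random() < 0.5 else -1.0
    to_centre = 1.0 if pos[0] < frame[0] / 2.0 else -1.0
    pull = 0.5 + 0.5 * min(1.0, (abs(pos[0] - frame[0] / 2.0) / (0.4 * frame[0])) ** 2)
    sx = to_centre if rng.random() < pull else -to_centre
    return math.cos(theta) * sx, math.sin(theta) * sy


def _flip_into_frame(pos, dx, dy, frame, margin=60.0):
    if not (margin <= pos[0] + dx <= frame[0] - margin):
        dx = -dx
    if not (margin <= pos[1] + dy <= frame[1] - margin):
        dy = -dy
    return dx, dy


def _smooth_jitter(rng, n, amplitude):
    """Temporally smoothed micro-jitter so jitter speed stays far sub-threshold.

    The vertical component is halved so the jitter is roughly isotropic in
    degree space (one pixel sweeps twice the angle vertically on a 2:1
    equirectangular frame).
    """
    if amplitude <= 0 or n < 3:
        return np.zeros((n, 2))
    raw = rng.normal(0.0, 1.0, (n + 8, 2))
    kern = np.ones(9) / 9.0
    sm = np.column_stack([np.convolve(raw[:, k], kern, mode="valid") for k in (0, 1)])
    sm = sm[:n]
    scale = amplitude / max(sm.std(), 1e-9)
    sm = sm * scale
    sm[:, 1] *= 0.5
    return sm


def _build_hold(pos, kind, eff: ClassProfile, config: SimConfig, rng):
    """Positions (steps 1..m) of a drifting hold rescaled to an exact dispersion."""
    m_specs = eff.measures
    dt = 1.0 / config.rate_hz
    thr = config.saccade_threshold
    split = config.pursuit_split_px
    if kind == "fixation":
        # dispersion capped below the pursuit split so the operational
        # fixation/pursuit partition matches the generated event kinds
        disp = _trunc_lognormal_matched(
            rng, m_specs["fixation_dispersion_px"], hi_cap=0.95 * split
        )
        dur_s = _trunc_lognormal(rng, m_specs["fixation_duration_ms"]) / 1000.0
        dur_s = max(dur_s - CALIBRATION["fixation_pad_ms"] / 1000.0, 0.08)
    else:
        disp = _trunc_lognormal_matched(
            rng, m_specs["pursuit_dispersion_px"], lo_cap=1.1 * split
        )
    disp = max(disp - CALIBRATION["hold_disp_pad_px"], 3.0)

    ux, uy = _steered_direction(rng, pos, config.frame, 8.0, 20.0)
    span = abs(ux) + abs(uy)
    f = _deg_factor(ux, uy, config.frame)
    path_px = disp / span
    if kind == "fixation":
        # lengthen the hold if the sampled dispersion would force the drift
        # speed into the saccade detector's band
        dur_s = max(dur_s, path_px * f / (0.82 * thr))
    else:
        v = eff.pursuit_drift_speed * rng.uniform(0.88, 1.0)
        dur_s = path_px * f / v
    m = max(int(round(dur_s / dt)), 2)
    dx, dy = _flip_into_frame(pos, ux * path_px, uy * path_px, config.frame)

    ks = np.arange(m + 1) / m
    base = np.column_stack((dx * ks, dy * ks))
    jit = _smooth_jitter(rng, m + 1, config.jitter_px)
    off = base + (jit - jit[0])
    bbox = np.ptp(off[:, 0]) + np.ptp(off[:, 1])
    if bbox > 0:
        off *= disp / bbox
    xs = pos[0] + off[1:, 0]
    ys = pos[1] + off[1:, 1]
    return xs, ys, {"kind": kind, "dispersion_px": disp, "duration_ms": m * dt * 1000.0}


#: Fixed saccade speed-profile shape; Beta(3.5, 3.5) has a peak/mean velocity
#: ratio of ~2.03, matching the population tables' peak-to-mean proportions.
_SACCADE_SHAPE_A = 3.5
_SACCADE_RHO = float(1.0 / (_beta_fn(_SACCADE_SHAPE_A, _SACCADE_SHAPE_A)
                            * 4.0 ** (_SACCADE_SHAPE_A - 1.0)))


def _solve_saccade_profile(A_det, D_det, thr):
    """Total duration/amplitude whose supra-threshold portion hits the targets.

    The sampled targets describe what the velocity-threshold detector sees
    (the supra-threshold run); the Beta-profile's sub-threshold tails mean the
    full kinematic event must be stretched.  A short fixed-point iteration
    solves the stretch; a detectability floor keeps the effective peak
    velocity comfortably above the threshold, shortening slow small saccades
    the way the saccadic main sequence would.
    """
    a = _SACCADE_SHAPE_A
    rho = _SACCADE_RHO
    thr_m = thr * CALIBRATION["threshold_margin"]
    A_tot, D_tot = A_det, D_det
    for _ in range(4):
        vp_eff = rho * A_tot / D_tot
        if vp_eff < 1.35 * thr_m:  # undetectable: shorten rather than stretch
            D_tot = rho * A_tot / (1.35 * thr_m)
            vp_eff = 1.35 * thr_m
        q = (thr_m / vp_eff) ** (1.0 / (a - 1.0))
        tau0 = min((1.0 - math.sqrt(max(1.0 - q, 0.0))) / 2.0, 0.24)
        s_dur = 1.0 - 2.0 * tau0
        s_path = float(betainc(a, a, 1.0 - tau0) - betainc(a, a, tau0))
        D_tot = min(D_det / s_dur, rho * A_tot / (1.35 * thr_m))
        A_tot = A_det / max(s_path, 0.8)
    return a, A_tot, D_tot


def _build_saccade(pos, eff: ClassProfile, config: SimConfig, rng):
    """Positions (steps 1..ns) of a ballistic jump with a Beta-family speed profile."""
    m_specs = eff.measures
    dt = 1.0 / config.rate_hz
    thr = config.saccade_threshold
    # amplitude and duration sampled with main-sequence-style rank
    # correlation (Gaussian copula): long saccades are also large ones, so
    # their peak velocity stays comfortably detectable
    spec_a = m_specs["saccade_amplitude_deg"]
    spec_d = m_specs["saccade_duration_ms"]
    mu_a, s_a = _matched_lognormal_params(spec_a.mean, spec_a.sd, spec_a.lo, spec_a.hi)
    mu_d, s_d = _matched_lognormal_params(spec_d.mean, spec_d.sd, spec_d.lo, spec_d.hi)
    corr = 0.85
    A = D = None
    for _ in range(40):
        z_a = rng.normal()
        z_d = corr * z_a + math.sqrt(1.0 - corr**2) * rng.normal()
        A_try = math.exp(mu_a + s_a * z_a)
        D_try = math.exp(mu_d + s_d * z_d)
        if spec_a.lo <= A_try <= spec_a.hi and spec_d.lo <= D_try <= spec_d.hi:
            A, D = A_try, D_try
            break
    if A is None:
        A = float(np.clip(math.exp(mu_a + s_a * rng.normal()), spec_a.lo, spec_a.hi))
        D = float(np.clip(math.exp(mu_d + s_d * rng.normal()), spec_d.lo, spec_d.hi))
    D = D / 1000.0 + CALIBRATION["saccade_pad_ms"] / 1000.0
    # physiological-consistency caps: duration long enough to keep the peak
    # velocity below the 1000 deg/s cleaning bound and accelerations below
    # the 1e5 deg/s^2 bound
    D = max(D, _SACCADE_RHO * A / 850.0, math.sqrt(8.0 * A / 85000.0))
    a, A_tot, D_tot = _solve_saccade_profile(A, D, thr)
    Vp = _SACCADE_RHO * A_tot / D_tot

    # render the profile only down to a sub-threshold cut speed: the deep
    # slow tails carry negligible path and would otherwise be attached to
    # the neighbouring holds by the detector
    cut = CALIBRATION["render_cut"] * thr
    q_r = (cut / Vp) ** (1.0 / (a - 1.0)) if Vp > cut else 1.0
    tau_r = min((1.0 - math.sqrt(max(1.0 - q_r, 0.0))) / 2.0, 0.3)
    lo_i = float(betainc(a, a, tau_r))
    hi_i = float(betainc(a, a, 1.0 - tau_r))
    ns = max(int(round(D_tot * (1.0 - 2.0 * tau_r) / dt)), 4)

    phi = math.radians(rng.uniform(-30.0, 30.0))
    ax_deg = A_tot * math.cos(phi)
    ay_deg = A_tot * math.sin(phi) * (1.0 if rng.random() < 0.5 else -1.0)
    sx = 1.0 if pos[0] < config.frame[0] / 2.0 else -1.0
    dx_px, dy_px = deg_to_px(ax_deg * sx, ay_deg, config.frame)
    dx_px, dy_px = _flip_into_frame(pos, float(dx_px), float(dy_px), config.frame)

    taus = tau_r + (1.0 - 2.0 * tau_r) * np.arange(1, ns + 1) / ns
    frac = (betainc(a, a, taus) - lo_i) / max(hi_i - lo_i, 1e-12)
    xs = pos[0] + dx_px * (hi_i - lo_i) * frac
    ys = pos[1] + dy_px * (hi_i - lo_i) * frac
    return xs, ys, {
        "kind": "saccade",
        "amplitude_deg": A,          # detected-amplitude target
        "duration_ms": D * 1000.0,   # detected-duration target
        "peak_velocity": Vp,
        "n_pairs_total": ns,
    }


def generate_trial(
    participant,
    config: SimConfig,
    rng: np.random.Generator,
    participant_id: str | None = None,
    trial_id: str = "T00",
    block: int = 0,
) -> GazeTrial:
    """One alternating hold/saccade trace with exact 1/rate sample spacing.

    ``participant`` may be a :class:`ParticipantProfile` or a bare
    :class:`ClassProfile`.  Ground-truth event parameters are attached as
    ``trial.truth`` (last entry flagged ``truncated`` when the trial boundary
    cuts it short).
    """
    if isinstance(participant, ParticipantProfile):
        eff = participant.effective()
        pid = participant_id or participant.participant_id
    else:
        eff = participant
        pid = participant_id or "P00"
    n_pairs = int(round(config.trial_duration_s * config.rate_hz))
    if n_pairs * (1000.0 / config.rate_hz) < 100.0:
        raise ValueError("trial too short to hold a single event")
    dt_ms = 1000.0 / config.rate_hz
    centre = (config.frame[0] / 2.0, config.frame[1] / 2.0)
    pos = (centre[0] + rng.uniform(-250, 250), centre[1] + rng.uniform(-150, 150))

    xs_all = [np.array([pos[0]])]
    ys_all = [np.array([pos[1]])]
    truth: list[dict] = []
    cursor = 0
    degenerate = eff.saccades_per_s <= 0 or eff.fixations_per_s <= 0
    next_is_hold = True
    while cursor < n_pairs:
        if degenerate:
            # single fixation spanning the trial: a barely-drifting hold
            disp = min(_trunc_lognormal(rng, eff.measures["fixation_dispersion_px"]),
                       0.5 * config.saccade_threshold * (n_pairs * dt_ms / 1000.0)
                       / _deg_factor(1.0, 0.0, config.frame))
            ux, uy = _steered_direction(rng, pos, config.frame)
            dxy = _flip_into_frame(pos, ux * disp, uy * disp, config.frame)
            ks = np.arange(1, n_pairs + 1) / n_pairs
            xs, ys = pos[0] + dxy[0] * ks, pos[1] + dxy[1] * ks
            entry = {"kind": "fixation", "dispersion_px": disp,
                     "duration_ms": n_pairs * dt_ms}
        elif next_is_hold:
            kind = "pursuit" if rng.random() < eff.pursuit_fraction else "fixation"
            xs, ys, entry = _build_hold(pos, kind, eff, config, rng)
            if kind == "pursuit" and xs.size > (n_pairs - cursor):
                # a pursuit cut by the trial boundary would dilute the
                # dispersion statistics; fill the remainder with a fixation
                xs, ys, entry = _build_hold(pos, "fixation", eff, config, rng)
        else:
            xs, ys, entry = _build_saccade(pos, eff, config, rng)
            if xs.size > n_pairs - cursor - 25:
                # a saccade cut by the trial boundary would still be detected
                # as a (spurious-looking) saccade; hold the gaze instead
                r = n_pairs - cursor
                jit = _smooth_jitter(rng, r + 1, config.jitter_px)
                jit -= jit[0]
                xs = pos[0] + jit[1:, 0]
                ys = pos[1] + jit[1:, 1]
                if truth and truth[-1]["kind"] in ("fixation", "pursuit"):
                    truth[-1]["n_pairs"] += r
                    truth[-1]["duration_ms"] += r * dt_ms
                    xs_all.append(xs)
                    ys_all.append(ys)
                    cursor += r
                    break
                entry = {"kind": "fixation", "dispersion_px": float(np.ptp(jit[:, 0]) + np.ptp(jit[:, 1])),
                         "duration_ms": r * dt_ms}
        remaining = n_pairs - cursor
        if xs.size > remaining:
            xs, ys = xs[:remaining], ys[:remaining]
            entry = dict(entry, truncated=True, duration_ms=remaining * dt_ms)
            if entry["kind"] != "saccade" and xs.size:
                seg_x = np.concatenate(([pos[0]], xs))
                seg_y = np.concatenate(([pos[1]], ys))
                entry["dispersion_px"] = float(np.ptp(seg_x) + np.ptp(seg_y))
        entry["start_pair"] = cursor
        entry["n_pairs"] = int(xs.size)
        truth.append(entry)
        xs_all.append(xs)
        ys_all.append(ys)
        cursor += xs.size
        pos = (float(xs[-1]), float(ys[-1])) if xs.size else pos
        next_is_hold = not next_is_hold

    x = np.concatenate(xs_all)
    y = np.concatenate(ys_all)
    t = np.arange(n_pairs + 1) * dt_ms
    return GazeTrial(
        participant_id=pid,
        class_label=eff.class_label,
        trial_id=trial_id,
        block=block,
        t_ms=t,
        x=x,
        y=y,
        valid=np.ones(n_pairs + 1, dtype=bool),
        rate_hz=config.rate_hz,
        frame=config.frame,
        truth=truth,
    )


def inject_errors(
    trial: GazeTrial,
    config: SimConfig,
    rng: np.random.Generator,
    force_low_tracking: bool = False,
) -> GazeTrial:
    """Overlay device errors: (0;0) dropout bursts and valid-flagged position spikes.

    ``force_low_tracking`` degrades the whole trial below the 75% tracking
    ratio (the trial-filter stage is expected to discard it).
    """
    x, y = trial.x.copy(), trial.y.copy()
    valid = trial.valid.copy()
    n = trial.n_samples
    rate = rng.uniform(0.27, 0.45) if force_low_tracking else config.dropout_rate
    if rate > 0:
        q = min(rate / config.dropout_burst_mean, 1.0)
        for s in np.flatnonzero(rng.random(n) < q):
            length = int(rng.geometric(1.0 / config.dropout_burst_mean))
            x[s : s + length] = 0.0
            y[s : s + length] = 0.0
            valid[s : s + length] = False
    if config.spike_rate > 0:
        w, h = trial.frame
        for s in np.flatnonzero(rng.random(n) < config.spike_rate):
            length = int(rng.integers(2, 5))
            e = min(s + length, n)
            steps = rng.normal(0.0, 350.0, (e - s, 2)).cumsum(axis=0)
            x[s:e] = np.clip(x[s] + steps[:, 0], 0.0, w - 1.0)
            y[s:e] = np.clip(y[s] + steps[:, 1], 0.0, h - 1.0)
    return GazeTrial(
        participant_id=trial.participant_id,
        class_label=trial.class_label,
        trial_id=trial.trial_id,
        block=trial.block,
        t_ms=trial.t_ms.copy(),
        x=x,
        y=y,
        valid=valid,
        rate_hz=trial.rate_hz,
        frame=trial.frame,
        truth=trial.truth,
    )


def generate_dataset(config: SimConfig, profiles: dict | None = None,
                     inject: bool = True) -> list:
    """Full dataset: participants x trials, reproducible from the master seed."""
    profiles = profiles or default_class_profiles()
    root = np.random.SeedSequence(config.seed)
    trials: list[GazeTrial] = []
    pidx = 0
    for label in ("expert", "intermediate", "novice"):
        count = config.participants_per_class.get(label, 0)
        for _ in range(count):
            pidx += 1
            pid = f"P{pidx:02d}"
            children = root.spawn(1)[0].spawn(config.trials_per_participant + 1)
            prng = np.random.default_rng(children[0])
            participant = sample_participant(
                profiles[label], config.idiosyncrasy_spread, prng, pid
            )
            for k in range(config.trials_per_participant):
                trng = np.random.default_rng(children[k + 1])
                trial = generate_trial(
                    participant, config, trng,
                    trial_id=f"{pid}_T{k:02d}",
                    block=0 if k < config.trials_per_participant / 2 else 1,
                )
                if inject:
                    force = trng.random() < config.low_track_fraction
                    trial = inject_errors(trial, config, trng, force_low_tracking=force)
                trials.append(trial)
    return trials


def dataset_manifest(trials):
    """Per-participant trial ledger (participant, class, number of trials)."""
    import pandas as pd

    rows = {}
    for tr in trials:
        key = (tr.participant_id, tr.class_label)
        rows[key] = rows.get(key, 0) + 1
    return pd.DataFrame(
        [(p, c, n) for (p, c), n in sorted(rows.items())],
        columns=["participant_id", "class_label", "n_trials"],
    )
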