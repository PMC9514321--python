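"""Synthetic sessions with known ground truth.

The study's raw recordings are not deposited, so everything downstream is
exercised on simulated observers. The generator emulates, at 500 Hz:

* fixational drift as a mean-reverting 2-D random walk shared by the two
  eyes, plus independent per-eye tracker noise;
* ballistic microsaccades with a minimum-jerk position profile whose peak
  velocity follows the main sequence (peak velocity proportional to
  amplitude, with multiplicative noise);
* slow pupil dynamics (AR(1) baseline) with a trial-locked dilation bump
  during the target window;
* full blinks (both pupils and gaze missing for ~150 ms) and partial
  blinks (fast pupil transients exceeding 20 a.u. per sample);
* a configurable per-participant coupling between the latent visibility
  of the target and the per-period microsaccade rate / pupil offsets —
  the planted signal that the decoder is later asked to recover.

Latent visibility is Bernoulli per non-catch trial (catch trials are
never visible); the reported decision is the latent state flipped with a
small decision-noise probability, so labels carry the planted coupling
only through the latent state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
import json
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    ALL_POSITIONS,
    CATCH,
    OTHER_POSITIONS,
    POSITIONS_OF_INTEREST,
    ConfigurationError,
    DEFAULT_CONFIG,
    EyeRecording,
    SessionConfig,
    Trial,
    TrialSchedule,
)

__all__ = [
    "ObserverParams",
    "PlantedSaccade",
    "PlantedBlink",
    "GroundTruth",
    "SimulatedSession",
    "make_schedule",
    "simulate_session",
    "sample_feature_table",
    "run_staircase",
    "StaircaseResult",
    "LogisticObserver",
    "grating_drift_speed",
]

#: order of the six features everywhere: saccade rate then pupil,
#: each over (adaptation, ISI, target).
FEATURE_ORDER = (
    "sacrate_adapt",
    "sacrate_isi",
    "sacrate_target",
    "pupil_adapt",
    "pupil_isi",
    "pupil_target",
)


def grating_drift_speed(temporal_hz: float = 0.83, spatial_cpd: float = 1.6) -> float:
    """Drift speed (deg/s) of a grating whose phase follows a triangular wave.

    A phase modulation with fundamental temporal frequency ``temporal_hz``
    over a carrier of spatial frequency ``spatial_cpd`` displaces the
    pattern at ``temporal_hz / spatial_cpd`` degrees per second — the
    adaptor gratings drift at 0.83 / 1.6 = 0.52 deg/s.
    """
    return temporal_hz / spatial_cpd


# ---------------------------------------------------------------------------
# Trial schedule


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def make_schedule(
    n_blocks: int = 4,
    trials_per_block: int = 43,
    proportions: dict[str, float] | None = None,
    seed: int = 0,
    cfg: SessionConfig = DEFAULT_CONFIG,
) -> TrialSchedule:
    """Build a session schedule (default: 4 blocks x 43 trials).

    Per block, each category count is the nearest integer of
    proportion x trials_per_block (defaults 0.65 interest / 0.15 other /
    0.20 catch give 28 + 6 + 9 = 43); interest trials split equally
    between top-left and bottom-right, the six other positions balanced
    as evenly as the remainder allows (extras rotate across blocks).
    Only the trial order depends on the seed. The first trial of each
    block carries the 60 s adaptation.
    """
    if trials_per_block < 1:
        raise ConfigurationError("trials_per_block must be >= 1")
    props = proportions or {"interest": cfg.p_interest, "other": cfg.p_other, "catch": cfg.p_catch}
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ConfigurationError("proportions must sum to 1")
    n_int = _round_half_up(props["interest"] * trials_per_block)
    n_other = _round_half_up(props["other"] * trials_per_block)
    n_catch = _round_half_up(props["catch"] * trials_per_block)
    if n_int + n_other + n_catch != trials_per_block:
        raise ConfigurationError(
            f"nearest-integer rounding gives {n_int}+{n_other}+{n_catch} "
            f"!= {trials_per_block} trials per block"
        )
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    t = 0.0
    for b in range(n_blocks):
        conds: list[str] = []
        n_tl = (n_int + 1) // 2
        conds += ["topleft"] * n_tl + ["bottomright"] * (n_int - n_tl)
        base, extra = divmod(n_other, len(OTHER_POSITIONS))
        for j, pos in enumerate(OTHER_POSITIONS):
            k = base + (1 if (j - b) % len(OTHER_POSITIONS) < extra else 0)
            conds += [pos] * k
        conds += [CATCH] * n_catch
        order = rng.permutation(len(conds))
        conds = [conds[i] for i in order]
        for i, cond in enumerate(conds):
            adapt = cfg.first_adapt_ms if i == 0 else cfg.adapt_ms
            trial = Trial(
                block_index=b,
                trial_index=i,
                condition=cond,
                adapt_start_ms=t,
                adapt_end_ms=t + adapt,
                isi_end_ms=t + adapt + cfg.isi_ms,
                target_end_ms=t + adapt + cfg.isi_ms + cfg.target_ms,
            )
            trials.append(trial)
            t = trial.target_end_ms + cfg.response_ms
    sched = TrialSchedule(trials=trials, n_blocks=n_blocks, trials_per_block=trials_per_block)
    sched.validate()
    return sched


# ---------------------------------------------------------------------------
# Observer and ground truth


@dataclass
class ObserverParams:
    """Parameters of one simulated observer.

    ``coupling`` links latent visibility to the six per-period features in
    the order of :data:`FEATURE_ORDER`: the first three entries are
    additive microsaccade-rate offsets (events/s) and the last three are
    additive pupil offsets (a.u.). ``conf_coupling`` does the same for the
    latent confidence state.
    """

    coupling: np.ndarray = field(default_factory=lambda: np.zeros(6))
    conf_coupling: np.ndarray = field(default_factory=lambda: np.zeros(6))
    base_saccade_rate: float = 1.2  # events/s, typical fixational rate
    main_sequence_slope: float = 60.0  # (deg/s) per deg of amplitude
    main_sequence_noise: float = 0.12  # lognormal sigma on peak velocity (within-observer scatter)
    amplitude_range_arcmin: tuple[float, float] = (18.0, 42.0)
    pupil_base: float = 1000.0  # a.u.
    pupil_dilation: float = 30.0  # a.u., target-locked bump
    pupil_ar_coef: float = 0.998
    pupil_noise_sd: float = 8.0  # stationary sd of the AR(1) baseline, a.u.
    eye_pupil_noise_sd: float = 1.0  # independent per-eye pupil noise, a.u.
    blink_rate_per_min: float = 4.0  # full blinks
    partial_blink_rate_per_min: float = 1.5
    blink_duration_ms: float = 150.0
    drift_diffusion: float = 0.001  # deg^2/s per axis
    drift_relaxation: float = 1.0  # 1/s, mean reversion toward fixation
    tracker_noise_deg: float = 0.005  # per-eye white gaze noise sd
    p_visible: float = 0.5
    decision_noise: float = 0.1  # probability the report flips the latent state
    p_sure: float = 0.5
    confidence_noise: float = 0.1

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.conf_coupling = np.asarray(self.conf_coupling, dtype=float)
        if self.coupling.shape != (6,) or self.conf_coupling.shape != (6,):
            raise ConfigurationError("coupling vectors must have 6 entries")
        if not (np.all(np.isfinite(self.coupling)) and np.all(np.isfinite(self.conf_coupling))):
            raise ConfigurationError("coupling must be finite")
        if self.base_saccade_rate < 0 or self.blink_rate_per_min < 0:
            raise ConfigurationError("rates must be nonnegative")


@dataclass
class PlantedSaccade:
    onset_ms: float
    offset_ms: float
    amplitude_arcmin: float
    peak_velocity: float  # deg/s
    direction_rad: float
    trial_index: int | None = None
    period: str | None = None


@dataclass
class PlantedBlink:
    onset_ms: float
    offset_ms: float
    kind: str  # "full" | "partial"


@dataclass
class GroundTruth:
    """Everything the simulator planted, for oracle checks downstream."""

    saccades: list[PlantedSaccade]
    blinks: list[PlantedBlink]
    visibility: np.ndarray  # 0/1 per trial
    confidence_state: np.ndarray  # 0/1 per trial
    coupling: np.ndarray
    conf_coupling: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "saccades": [asdict(s) for s in self.saccades],
            "blinks": [asdict(b) for b in self.blinks],
            "visibility": self.visibility.astype(int).tolist(),
            "confidence_state": self.confidence_state.astype(int).tolist(),
            "coupling": self.coupling.tolist(),
            "conf_coupling": self.conf_coupling.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            saccades=[PlantedSaccade(**d) for d in payload["saccades"]],
            blinks=[PlantedBlink(**d) for d in payload["blinks"]],
            visibility=np.array(payload["visibility"]),
            confidence_state=np.array(payload["confidence_state"]),
            coupling=np.array(payload["coupling"]),
            conf_coupling=np.array(payload["conf_coupling"]),
        )


@dataclass
class SimulatedSession:
    recording: EyeRecording
    schedule: TrialSchedule  # responses filled in
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# Session simulation


def _min_jerk_profile(n: int) -> np.ndarray:
    """Normalized minimum-jerk displacement profile s(tau), s(0)=0, s(1)=1."""
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _draw_event_times(
    rng: np.random.Generator,
    start_ms: float,
    end_ms: float,
    rate_hz: float,
    min_gap_ms: float = 120.0,
    margin_ms: float = 60.0,
) -> list[float]:
    """Homogeneous event times in [start+margin, end-margin) with a refractory gap."""
    lo, hi = start_ms + margin_ms, end_ms - margin_ms
    if hi <= lo or rate_hz <= 0:
        return []
    n = rng.poisson(rate_hz * (end_ms - start_ms) / 1000.0)
    times: list[float] = []
    for _ in range(n):
        for _attempt in range(20):
            t = rng.uniform(lo, hi)
            if all(abs(t - u) >= min_gap_ms for u in times):
                times.append(t)
                break
    return sorted(times)


def simulate_session(
    schedule: TrialSchedule,
    observer: ObserverParams | None = None,
    seed: int = 0,
    cfg: SessionConfig = DEFAULT_CONFIG,
) -> SimulatedSession:
    """Render one full session: 500 Hz binocular traces + responses + truth.

    Microsaccade event times form an inhomogeneous point process whose
    per-period rate is ``base + coupling . latent state``; each event is a
    ~20-40 ms minimum-jerk displacement with main-sequence peak velocity.
    Pupil = AR(1) baseline + per-period coupling offsets + target-locked
    dilation; full blinks blank both eyes, partial blinks inject fast
    transients. The response is the latent visibility flipped with
    probability ``decision_noise``.
    """
    obs = observer or ObserverParams()
    rng = np.random.default_rng(seed)
    dt_ms = 2.0
    n = int(round(schedule.end_ms / dt_ms))
    time = np.arange(n) * dt_ms

    trials = list(schedule.trials)
    n_trials = len(trials)
    visibility = np.zeros(n_trials, dtype=int)
    conf_state = rng.random(n_trials) < obs.p_sure
    for i, tr in enumerate(trials):
        if not tr.is_catch:
            visibility[i] = int(rng.random() < obs.p_visible)

    # ---- blinks first (saccades avoid them) -------------------------------
    blinks: list[PlantedBlink] = []
    total_min = schedule.end_ms / 60_000.0
    for kind, rate in (("full", obs.blink_rate_per_min), ("partial", obs.partial_blink_rate_per_min)):
        k = rng.poisson(rate * total_min)
        for _ in range(k):
            onset = rng.uniform(500.0, schedule.end_ms - 1000.0)
            dur = max(60.0, rng.normal(obs.blink_duration_ms, 30.0))
            blinks.append(PlantedBlink(onset_ms=onset, offset_ms=onset + dur, kind=kind))
    blinks.sort(key=lambda b: b.onset_ms)

    def in_blink(t_ms: float, pad: float = 320.0) -> bool:
        return any(b.onset_ms - pad <= t_ms <= b.offset_ms + pad for b in blinks)

    # ---- saccade event times ---------------------------------------------
    planted: list[PlantedSaccade] = []
    spans: list[tuple[float, float, float, int | None, str | None]] = []
    for i, tr in enumerate(trials):
        for p_idx, (name, (s, e)) in enumerate(tr.periods().items()):
            rate = obs.base_saccade_rate + obs.coupling[p_idx] * visibility[i]
            rate += obs.conf_coupling[p_idx] * conf_state[i]
            spans.append((s, e, max(rate, 0.0), i, name))
        # response screen at base rate, keeps fixation behaviour continuous
        spans.append((tr.target_end_ms, tr.target_end_ms + cfg.response_ms, obs.base_saccade_rate, None, None))

    sacc_offset = np.zeros(2)  # running saccadic displacement, kept bounded
    lx = np.zeros(n)
    ly = np.zeros(n)
    sac_dx = np.zeros(n)
    sac_dy = np.zeros(n)
    for s, e, rate, tr_idx, period in spans:
        for t0 in _draw_event_times(rng, s, e, rate):
            if in_blink(t0):
                continue
            amp_arcmin = math.exp(rng.uniform(math.log(obs.amplitude_range_arcmin[0]),
                                              math.log(obs.amplitude_range_arcmin[1])))
            amp_deg = amp_arcmin / 60.0
            vpeak = obs.main_sequence_slope * amp_deg * math.exp(rng.normal(0.0, obs.main_sequence_noise))
            vpeak = min(vpeak, 110.0)
            dur_s = 1.875 * amp_deg / vpeak
            m = max(6, int(round(dur_s / 0.002)))
            i0 = int(round(t0 / dt_ms))
            if i0 + m >= n:
                continue
            if np.hypot(*sacc_offset) < 0.15:
                theta = rng.uniform(0, 2 * math.pi)
            else:  # steer back toward fixation (square-wave-like pattern)
                theta = math.atan2(-sacc_offset[1], -sacc_offset[0]) + rng.normal(0.0, 0.3)
            prof = _min_jerk_profile(m + 1)
            dx, dy = amp_deg * math.cos(theta), amp_deg * math.sin(theta)
            sac_dx[i0 : i0 + m + 1] += prof * dx
            sac_dx[i0 + m + 1 :] += dx
            sac_dy[i0 : i0 + m + 1] += prof * dy
            sac_dy[i0 + m + 1 :] += dy
            sacc_offset += (dx, dy)
            planted.append(
                PlantedSaccade(
                    onset_ms=time[i0],
                    offset_ms=time[i0 + m],
                    amplitude_arcmin=amp_arcmin,
                    peak_velocity=vpeak,
                    direction_rad=theta,
                    trial_index=tr_idx,
                    period=period,
                )
            )
    planted.sort(key=lambda s: s.onset_ms)

    # ---- fixational drift: mean-reverting random walk, shared binocularly --
    step_sd = math.sqrt(obs.drift_diffusion * 0.002)
    lam = obs.drift_relaxation * 0.002
    drift = np.zeros((n, 2))
    steps = rng.normal(0.0, step_sd, size=(n, 2))
    for k in range(1, n):
        drift[k] = drift[k - 1] * (1.0 - lam) + steps[k]
    gx = drift[:, 0] + sac_dx
    gy = drift[:, 1] + sac_dy
    lx = gx + rng.normal(0.0, obs.tracker_noise_deg, n)
    ly = gy + rng.normal(0.0, obs.tracker_noise_deg, n)
    rx = gx + rng.normal(0.0, obs.tracker_noise_deg, n)
    ry = gy + rng.normal(0.0, obs.tracker_noise_deg, n)

    # ---- pupil -------------------------------------------------------------
    rho = obs.pupil_ar_coef
    innov_sd = obs.pupil_noise_sd * math.sqrt(1.0 - rho * rho)
    ar = np.empty(n)
    ar[0] = rng.normal(0.0, obs.pupil_noise_sd)
    innov = rng.normal(0.0, innov_sd, n)
    for k in range(1, n):
        ar[k] = rho * ar[k - 1] + innov[k]
    pupil = obs.pupil_base + ar

    # per-period coupling offsets, applied with 100 ms cosine ramps so the
    # partial-blink derivative rule is never tripped by design
    ramp_n = 50
    ramp = 0.5 * (1 - np.cos(np.linspace(0, math.pi, ramp_n)))
    def add_offset(s_ms: float, e_ms: float, amount: float) -> None:
        if amount == 0.0:
            return
        i0, i1 = int(s_ms / dt_ms), min(int(e_ms / dt_ms), n)
        if i1 <= i0:
            return
        box = np.full(i1 - i0, amount)
        k = min(ramp_n, len(box))
        box[:k] *= ramp[:k]
        box[-k:] *= ramp[:k][::-1]
        pupil[i0:i1] += box

    for i, tr in enumerate(trials):
        for p_idx, (name, (s, e)) in enumerate(tr.periods().items()):
            amount = obs.coupling[3 + p_idx] * visibility[i] + obs.conf_coupling[3 + p_idx] * conf_state[i]
            add_offset(s, e, amount)
        # target-locked dilation bump in every trial
        c = tr.target_start_ms + 500.0
        i0, i1 = int(tr.target_start_ms / dt_ms), min(int((tr.target_end_ms + 500.0) / dt_ms), n)
        tt = time[i0:i1]
        pupil[i0:i1] += obs.pupil_dilation * np.exp(-0.5 * ((tt - c) / 200.0) ** 2)

    lp = pupil + rng.normal(0.0, obs.eye_pupil_noise_sd, n)
    rp = pupil + rng.normal(0.0, obs.eye_pupil_noise_sd, n)

    # ---- blinks applied last ----------------------------------------------
    l_valid = np.ones(n, dtype=bool)
    r_valid = np.ones(n, dtype=bool)
    for b in blinks:
        i0, i1 = int(b.onset_ms / dt_ms), min(int(b.offset_ms / dt_ms), n)
        if b.kind == "full":
            l_valid[i0:i1] = False
            r_valid[i0:i1] = False
            for arr in (lx, ly, rx, ry, lp, rp):
                arr[i0:i1] = np.nan
        else:  # partial: sharp dip exceeding 20 a.u. per sample at the edges
            depth = 35.0
            lp[i0:i1] -= depth
            rp[i0:i1] -= depth

    rec = EyeRecording(time=time, lx=lx, ly=ly, rx=rx, ry=ry, lp=lp, rp=rp,
                       l_valid=l_valid, r_valid=r_valid)

    # ---- responses ----------------------------------------------------------
    responses = []
    for i, tr in enumerate(trials):
        seen = bool(visibility[i]) ^ (rng.random() < obs.decision_noise)
        sure = bool(conf_state[i]) ^ (rng.random() < obs.confidence_noise)
        tr.decision = "yes" if seen else "no"
        tr.confidence = "sure" if sure else "maybe"
        responses.append({"trial": i, "decision": tr.decision, "confidence": tr.confidence})

    truth = GroundTruth(
        saccades=planted,
        blinks=blinks,
        visibility=visibility,
        confidence_state=conf_state.astype(int),
        coupling=obs.coupling.copy(),
        conf_coupling=obs.conf_coupling.copy(),
    )
    return SimulatedSession(recording=rec, schedule=schedule, ground_truth=truth)


# ---------------------------------------------------------------------------
# Feature-level sampling (fast path for decoder calibration experiments)


def sample_feature_table(
    n_trials: int = 112,
    coupling: Sequence[float] | None = None,
    seed: int = 0,
    base_saccade_rate: float = 1.2,
    durations_s: tuple[float, float, float] = (6.0, 0.5, 1.0),
    pupil_noise_sd: float = 1.0,
    p_visible: float = 0.5,
    decision_noise: float = 0.1,
    conf_coupling: Sequence[float] | None = None,
    p_sure: float = 0.5,
    confidence_noise: float = 0.1,
) -> pd.DataFrame:
    """Draw a per-trial feature table directly from the generative model.

    This is the simulator's feature-level shortcut: per trial, the saccade
    rate in period *p* is a Poisson count at rate ``base + c_p * state``
    divided by the period duration, and the pupil feature is Gaussian with
    mean ``c_{3+p} * state`` (z-units). It skips trace rendering and
    detection, and is the right tool for decoder calibration studies where
    hundreds of synthetic participants are needed.
    """
    c = np.zeros(6) if coupling is None else np.asarray(coupling, dtype=float)
    cc = np.zeros(6) if conf_coupling is None else np.asarray(conf_coupling, dtype=float)
    rng = np.random.default_rng(seed)
    vis = (rng.random(n_trials) < p_visible).astype(int)
    conf = (rng.random(n_trials) < p_sure).astype(int)
    rows = []
    for i in range(n_trials):
        feats = {}
        for p, (name, dur) in enumerate(zip(("adapt", "isi", "target"), durations_s)):
            rate = max(base_saccade_rate + c[p] * vis[i] + cc[p] * conf[i], 0.0)
            feats[f"sacrate_{name}"] = rng.poisson(rate * dur) / dur
            feats[f"pupil_{name}"] = rng.normal(c[3 + p] * vis[i] + cc[3 + p] * conf[i], pupil_noise_sd)
        seen = bool(vis[i]) ^ (rng.random() < decision_noise)
        sure = bool(conf[i]) ^ (rng.random() < confidence_noise)
        rows.append(
            {
                "block": i // max(n_trials // 4, 1),
                "trial": i,
                "condition": POSITIONS_OF_INTEREST[i % 2],
                "decision": "yes" if seen else "no",
                "confidence": "sure" if sure else "maybe",
                **feats,
                "gaze_deviation": False,
                "blink_total_s": float(rng.exponential(0.2)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Adaptive staircase


@dataclass
class LogisticObserver:
    """Psychometric observer: P(seen) is logistic in log10 contrast."""

    threshold: float  # 50% point, log10 contrast
    slope: float = 0.1  # logistic scale, log10 units

    def prob_seen(self, level: float) -> float:
        return 1.0 / (1.0 + math.exp(-(level - self.threshold) / self.slope))


@dataclass
class StaircaseResult:
    threshold: float
    n_trials: int
    n_reversals: int
    levels: list[float]
    reversal_levels: list[float]
    warning: bool


def run_staircase(
    observer,
    start_level: float = 0.0,
    step: float = 0.05,
    max_reversals: int = 15,
    max_trials: int = 65,
    seed: int = 0,
) -> StaircaseResult:
    """1-up-1-down fixed-step staircase (0.05 log-unit steps).

    Seen responses step the contrast down, unseen responses step it up;
    the run stops after ``max_reversals`` direction reversals or
    ``max_trials`` trials, whichever comes first. The threshold estimate
    is the mean of the reversal levels excluding the first two (which can
    bias the estimate); with fewer than three reversals the mean of all
    visited levels is returned with a warning flag. The 1-up-1-down rule
    converges on the 50% point of the psychometric function.
    """
    p_seen: Callable[[float], float]
    p_seen = observer.prob_seen if hasattr(observer, "prob_seen") else observer
    probe = [p_seen(start_level + d) for d in np.linspace(-2.0, 2.0, 41)]
    if any(b < a - 1e-9 for a, b in zip(probe, probe[1:])):
        raise ConfigurationError("psychometric function must be monotone increasing in contrast")

    rng = np.random.default_rng(seed)
    level = start_level
    levels: list[float] = []
    reversal_levels: list[float] = []
    last_move: int | None = None
    for _ in range(max_trials):
        levels.append(level)
        seen = rng.random() < p_seen(level)
        move = -1 if seen else +1
        if last_move is not None and move != last_move:
            reversal_levels.append(level)
            if len(reversal_levels) >= max_reversals:
                last_move = move
                break
        last_move = move
        level += move * step

    if len(reversal_levels) >= 3:
        thr = float(np.mean(reversal_levels[2:]))
        warning = False
    else:
        thr = float(np.mean(levels))
        warning = True
    return StaircaseResult(
        threshold=thr,
        n_trials=len(levels),
        n_reversals=len(reversal_levels),
        levels=levels,
        reversal_levels=reversal_levels,
        warning=warning,
    )
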