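"""Unsupervised microsaccade detection by velocity-peak clustering.

The detector takes the binocular speed trace, keeps the six highest
velocity peaks per second as candidates, z-transforms three features per
candidate (peak velocity, initial acceleration, final acceleration),
reduces them by PCA (components with eigenvalues above 5% of the
maximum), separates noise from microsaccades with 2-means clustering
(the cluster with the larger mean peak velocity is the saccade cluster),
delimits each saccade around its peak, and finally enforces the
physiological filters: duration >= 8 ms, amplitude 10-120 arcmin, mean
velocity 3-120 deg/s. A session passes main-sequence QC when the
Pearson correlation between amplitude and peak velocity exceeds 0.6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.cluster import KMeans

from .io_core import (
    DEFAULT_CONFIG,
    DegenerateSignalError,
    EyeRecording,
    SessionConfig,
)
from .preprocess import BlinkEvent

__all__ = [
    "Candidate",
    "Microsaccade",
    "MainSequenceQC",
    "DetectionResult",
    "DegenerateCandidatesError",
    "binocular_speed",
    "select_candidates",
    "cluster_candidates",
    "delimit_and_filter",
    "main_sequence_qc",
    "saccade_rate",
    "detect_microsaccades",
]


class DegenerateCandidatesError(DegenerateSignalError):
    """Fewer than two candidates, or all candidates identical."""


@dataclass
class Candidate:
    index: int  # sample index of the velocity peak
    peak_time_ms: float
    peak_velocity: float  # deg/s, raw
    initial_accel: float  # deg/s^2, signed extremum before the peak
    final_accel: float  # deg/s^2, signed extremum after the peak


@dataclass
class Microsaccade:
    onset_ms: float
    offset_ms: float  # half-open
    peak_time_ms: float
    amplitude_arcmin: float
    peak_velocity: float  # deg/s
    mean_velocity: float  # deg/s

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class MainSequenceQC:
    r: float | None
    passed: bool | None  # None = indeterminate (< 3 events)
    n_events: int


@dataclass
class DetectionResult:
    saccades: list[Microsaccade]
    qc: MainSequenceQC
    n_candidates: int
    degenerate: bool = False


def _five_point_derivative(x: np.ndarray, dt_s: float) -> np.ndarray:
    """Smoothed central difference over +/-2 samples; NaN at the edges."""
    v = np.full_like(x, np.nan)
    v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt_s)
    return v


def binocular_speed(rec: EyeRecording) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample speed (deg/s) and its derivative (deg/s^2).

    Horizontal and vertical velocities are estimated per eye by a
    5-point smoothed central difference, combined as sqrt(vx^2 + vy^2)
    and averaged across the two eyes. Invalid spans propagate as NaN.
    With one eye entirely missing the other eye is used alone (with a
    warning).
    """
    dt_s = rec.dt_ms / 1000.0
    speeds = []
    for gx, gy, valid, name in (
        (rec.lx, rec.ly, rec.l_valid, "left"),
        (rec.rx, rec.ry, rec.r_valid, "right"),
    ):
        if not valid.any():
            warnings.warn(f"{name} eye has no valid samples; computing speed monocularly")
            continue
        vx = _five_point_derivative(gx, dt_s)
        vy = _five_point_derivative(gy, dt_s)
        speeds.append(np.hypot(vx, vy))
    if not speeds:
        raise DegenerateSignalError("no valid gaze on either eye")
    speed = speeds[0] if len(speeds) == 1 else 0.5 * (speeds[0] + speeds[1])
    accel = _five_point_derivative(speed, dt_s)
    return speed, accel


def _signed_extremum(window: np.ndarray) -> float:
    finite = window[np.isfinite(window)]
    if finite.size == 0:
        return 0.0
    return float(finite[np.argmax(np.abs(finite))])


def select_candidates(
    speed: np.ndarray,
    accel: np.ndarray,
    time: np.ndarray,
    exclude_mask: np.ndarray | None = None,
    cfg: SessionConfig = DEFAULT_CONFIG,
) -> list[Candidate]:
    """Keep the six highest velocity peaks per second as candidates.

    The recording is tiled into consecutive non-overlapping 1 s windows
    from t=0; within each window the local maxima of the speed trace
    (plateaus count once, at their first sample) are ranked and the top
    six retained. Peaks inside ``exclude_mask`` (invalid/blink spans) or
    with non-finite speed are never candidates.
    """
    n = len(speed)
    usable = np.isfinite(speed)
    if exclude_mask is not None:
        usable &= ~exclude_mask
    with np.errstate(invalid="ignore"):
        is_peak = np.zeros(n, dtype=bool)
        is_peak[1:-1] = (speed[1:-1] > speed[:-2]) & (speed[1:-1] >= speed[2:])
    is_peak &= usable
    peak_idx = np.flatnonzero(is_peak)
    if peak_idx.size == 0:
        return []
    win_ms = 1000.0
    window_of = (time[peak_idx] // win_ms).astype(int)
    acc_win = max(int(round(cfg.accel_window_ms / (time[1] - time[0]))), 1) if n > 1 else 1
    cands: list[Candidate] = []
    for w in np.unique(window_of):
        in_w = peak_idx[window_of == w]
        top = in_w[np.argsort(speed[in_w])[::-1][: cfg.peaks_per_second]]
        for i in sorted(top):
            cands.append(
                Candidate(
                    index=int(i),
                    peak_time_ms=float(time[i]),
                    peak_velocity=float(speed[i]),
                    initial_accel=_signed_extremum(accel[max(i - acc_win, 0) : i]),
                    final_accel=_signed_extremum(accel[i + 1 : i + 1 + acc_win]),
                )
            )
    cands.sort(key=lambda c: c.index)
    return cands


def _zscore_features(cands: list[Candidate]) -> np.ndarray:
    """(n, 3) z-transformed feature matrix across the candidate set."""
    X = np.array([[c.peak_velocity, c.initial_accel, c.final_accel] for c in cands])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0.0] = 1.0  # constant feature carries no information
    return (X - mu) / sd


def cluster_candidates(
    cands: list[Candidate],
    seed: int = 0,
    cfg: SessionConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Label candidates saccade (True) / noise (False) by PCA + 2-means.

    PCA runs on the three z-transformed features; components with
    eigenvalues larger than 5% of the maximum are retained, and K-means
    (K=2, seeded, multiple restarts) clusters the retained scores. The
    cluster with the larger mean raw peak velocity is the saccade
    cluster; exact ties break toward the smaller cluster (saccades are
    rarer than noise peaks).
    """
    if len(cands) < 2:
        raise DegenerateCandidatesError("need at least 2 candidates to cluster")
    Z = _zscore_features(cands)
    if np.allclose(Z, Z[0]):
        raise DegenerateCandidatesError("all candidates have identical features")
    cov = np.cov(Z.T)
    evals, evecs = np.linalg.eigh(cov)
    keep = evals > cfg.pca_eigen_frac * evals.max()
    scores = Z @ evecs[:, keep]
    km = KMeans(n_clusters=2, n_init=cfg.kmeans_restarts, random_state=seed)
    labels = km.fit_predict(scores)
    pv = np.array([c.peak_velocity for c in cands])
    mean_pv = [pv[labels == k].mean() for k in (0, 1)]
    sizes = [int((labels == k).sum()) for k in (0, 1)]
    if mean_pv[0] == mean_pv[1]:
        sacc_cluster = int(np.argmin(sizes))
    else:
        sacc_cluster = int(np.argmax(mean_pv))
    return labels == sacc_cluster


def delimit_and_filter(
    rec: EyeRecording,
    speed: np.ndarray,
    cands: list[Candidate],
    labels: np.ndarray,
    cfg: SessionConfig = DEFAULT_CONFIG,
) -> list[Microsaccade]:
    """Delimit saccade-labelled candidates and apply the physiological filters.

    Each event extends from its peak sample in both directions while the
    speed stays above max(3 deg/s, 20% of the peak) and finite. The
    amplitude is the Euclidean displacement of the binocular-mean gaze
    between onset and offset (arcmin); mean velocity = amplitude /
    duration. Events failing duration >= 8 ms, amplitude in
    [10, 120] arcmin or mean velocity in [3, 120] deg/s are discarded;
    overlapping survivors are merged keeping the higher peak.
    """
    n = rec.n_samples
    dt = rec.dt_ms
    gx = np.where(rec.l_valid & rec.r_valid, 0.5 * (rec.lx + rec.rx),
                  np.where(rec.l_valid, rec.lx, rec.rx))
    gy = np.where(rec.l_valid & rec.r_valid, 0.5 * (rec.ly + rec.ry),
                  np.where(rec.l_valid, rec.ly, rec.ry))
    lo, hi = cfg.amplitude_bounds_arcmin
    mv_lo, mv_hi = cfg.mean_velocity_bounds
    out: list[Microsaccade] = []
    for c, is_sacc in zip(cands, labels):
        if not is_sacc:
            continue
        thr = max(cfg.onset_speed_floor, cfg.onset_peak_frac * c.peak_velocity)
        i0 = c.index
        while i0 - 1 >= 0 and np.isfinite(speed[i0 - 1]) and speed[i0 - 1] >= thr:
            i0 -= 1
        i1 = c.index
        while i1 + 1 < n and np.isfinite(speed[i1 + 1]) and speed[i1 + 1] >= thr:
            i1 += 1
        duration = (i1 - i0 + 1) * dt
        if not (np.isfinite(gx[i0]) and np.isfinite(gx[i1])):
            continue
        amp_deg = float(np.hypot(gx[i1] - gx[i0], gy[i1] - gy[i0]))
        amp_arcmin = amp_deg * 60.0
        mean_v = amp_deg / (duration / 1000.0)
        if duration < cfg.min_duration_ms:
            continue
        if not (lo <= amp_arcmin <= hi):
            continue
        if not (mv_lo <= mean_v <= mv_hi):
            continue
        out.append(
            Microsaccade(
                onset_ms=float(rec.time[i0]),
                offset_ms=float(rec.time[i1] + dt),
                peak_time_ms=c.peak_time_ms,
                amplitude_arcmin=amp_arcmin,
                peak_velocity=c.peak_velocity,
                mean_velocity=mean_v,
            )
        )
    out.sort(key=lambda s: s.onset_ms)
    merged: list[Microsaccade] = []
    for ev in out:
        if merged and ev.onset_ms < merged[-1].offset_ms:
            if ev.peak_velocity > merged[-1].peak_velocity:
                merged[-1] = ev
        else:
            merged.append(ev)
    return merged


def main_sequence_qc(
    saccades: list[Microsaccade],
    threshold: float = 0.6,
) -> MainSequenceQC:
    """Pearson r between peak velocity and amplitude; pass iff r > 0.6."""
    if len(saccades) < 3:
        return MainSequenceQC(r=None, passed=None, n_events=len(saccades))
    amp = np.array([s.amplitude_arcmin for s in saccades])
    pv = np.array([s.peak_velocity for s in saccades])
    if np.ptp(amp) == 0 or np.ptp(pv) == 0:
        return MainSequenceQC(r=None, passed=None, n_events=len(saccades))
    r = float(sps.pearsonr(amp, pv).statistic)
    return MainSequenceQC(r=r, passed=r > threshold, n_events=len(saccades))


def saccade_rate(saccades: list[Microsaccade], start_ms: float, end_ms: float) -> float:
    """Events per second: count of peaks in [start, end) over the duration."""
    if end_ms <= start_ms:
        raise ValueError("period must have positive duration")
    count = sum(1 for s in saccades if start_ms <= s.peak_time_ms < end_ms)
    return count / ((end_ms - start_ms) / 1000.0)


def detect_microsaccades(
    rec: EyeRecording,
    blinks: list[BlinkEvent] | None = None,
    seed: int = 0,
    cfg: SessionConfig = DEFAULT_CONFIG,
) -> DetectionResult:
    """Full pipeline: speed -> candidates -> clustering -> delimit/filter -> QC.

    Candidates inside blink events (already padded +/-200 ms) are
    excluded from the search. A degenerate candidate set (all identical
    or fewer than two) yields no events and a QC-failure flag instead of
    an error.
    """
    speed, accel = binocular_speed(rec)
    exclude = np.zeros(rec.n_samples, dtype=bool)
    for ev in blinks or ():
        i0 = max(rec.sample_index(ev.onset_ms), 0)
        i1 = min(rec.sample_index(ev.offset_ms), rec.n_samples)
        exclude[i0:i1] = True
    cands = select_candidates(speed, accel, rec.time, exclude_mask=exclude, cfg=cfg)
    try:
        labels = cluster_candidates(cands, seed=seed, cfg=cfg)
    except DegenerateCandidatesError:
        return DetectionResult(
            saccades=[],
            qc=MainSequenceQC(r=None, passed=None, n_events=0),
            n_candidates=len(cands),
            degenerate=True,
        )
    saccades = delimit_and_filter(rec, speed, cands, labels, cfg)
    return DetectionResult(
        saccades=saccades,
        qc=main_sequence_qc(saccades, cfg.main_sequence_r),
        n_candidates=len(cands),
    )
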