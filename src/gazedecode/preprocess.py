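"""Pupil preprocessing: blinks, binocular combination, filtering, z-scoring.

Full blink events are maximal runs where both eyes' pupil is missing,
padded by 200 ms on each side; partial blinks (pupil not fully occluded)
are runs where the combined pupil changes by more than 20 a.u. per
sample, padded the same way. The combined pupil averages the two eyes
when both are available, uses the single available eye otherwise, and
linearly interpolates across gaps and blink spans. Sessions where more
than 45% of the samples were interpolated are flagged as excluded. The
clean trace is low-pass filtered (zero-phase 4th-order Butterworth,
10 Hz) and z-transformed over the union of the adaptation, ISI and
target periods.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .io_core import (
    DEFAULT_CONFIG,
    DegenerateSignalError,
    EyeRecording,
    SessionConfig,
    TrialSchedule,
    UnrecoverableSignalError,
)

__all__ = [
    "BlinkEvent",
    "CleanPupil",
    "detect_blinks",
    "combine_pupil",
    "lowpass",
    "zscore_pupil",
    "preprocess_pupil",
    "blink_overlap_s",
]


@dataclass(frozen=True)
class BlinkEvent:
    onset_ms: float
    offset_ms: float
    kind: str  # "full" | "partial"

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class CleanPupil:
    """Combined, gap-free pupil trace with interpolation accounting."""

    trace: np.ndarray
    interpolated_mask: np.ndarray
    interpolated_fraction: float
    excluded: bool
    zscored: bool = False
    norm_mean: float | None = None
    norm_sd: float | None = None

    @property
    def n_samples(self) -> int:
        return len(self.trace)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as half-open (start, end) pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _combined_raw(rec: EyeRecording) -> np.ndarray:
    """Binocular pupil before interpolation: mean / single eye / NaN."""
    both = rec.l_valid & rec.r_valid
    out = np.full(rec.n_samples, np.nan)
    out[both] = 0.5 * (rec.lp[both] + rec.rp[both])
    only_l = rec.l_valid & ~rec.r_valid
    only_r = rec.r_valid & ~rec.l_valid
    out[only_l] = rec.lp[only_l]
    out[only_r] = rec.rp[only_r]
    return out


def detect_blinks(rec: EyeRecording, cfg: SessionConfig = DEFAULT_CONFIG) -> list[BlinkEvent]:
    """Find full and partial blink events, padded +/-200 ms and merged.

    Overlapping events are merged; a merged event is "full" if any
    constituent was full. Detection is deterministic, so it is idempotent
    on a given recording.
    """
    pad = cfg.blink_pad_ms
    dt = rec.dt_ms
    events: list[BlinkEvent] = []

    both_missing = ~rec.l_valid & ~rec.r_valid
    for i0, i1 in _runs(both_missing):
        events.append(BlinkEvent(rec.time[i0] - pad, rec.time[i1 - 1] + dt + pad, "full"))

    combined = _combined_raw(rec)
    delta = np.abs(np.diff(combined))
    jump = np.zeros(rec.n_samples, dtype=bool)
    with np.errstate(invalid="ignore"):
        idx = np.flatnonzero(delta > cfg.partial_blink_delta_au)
    jump[idx] = True
    jump[np.minimum(idx + 1, rec.n_samples - 1)] = True
    for i0, i1 in _runs(jump):
        events.append(BlinkEvent(rec.time[i0] - pad, rec.time[i1 - 1] + dt + pad, "partial"))

    if not events:
        return []
    events.sort(key=lambda e: (e.onset_ms, e.offset_ms))
    merged: list[BlinkEvent] = [events[0]]
    for ev in events[1:]:
        last = merged[-1]
        if ev.onset_ms <= last.offset_ms:
            kind = "full" if "full" in (ev.kind, last.kind) else "partial"
            merged[-1] = BlinkEvent(last.onset_ms, max(last.offset_ms, ev.offset_ms), kind)
        else:
            merged.append(ev)
    # clip to the recording
    end = rec.time[-1] + dt
    return [
        BlinkEvent(max(e.onset_ms, 0.0), min(e.offset_ms, end), e.kind)
        for e in merged
    ]


def combine_pupil(
    rec: EyeRecording,
    blinks: list[BlinkEvent] | None = None,
    cfg: SessionConfig = DEFAULT_CONFIG,
) -> CleanPupil:
    """Combine the two eyes and interpolate gaps and blink spans.

    Per sample: mean of the two eyes when both are valid, the single
    valid eye when one is, and linear interpolation (nearest valid
    flanking samples) across runs with none and across all blink spans.
    Leading/trailing invalid runs are filled with the nearest valid
    value. ``excluded`` is set when more than 45% of the samples were
    interpolated.
    """
    if blinks is None:
        blinks = detect_blinks(rec, cfg)
    x = _combined_raw(rec)
    mask = ~np.isfinite(x)
    for ev in blinks:
        i0 = max(rec.sample_index(ev.onset_ms), 0)
        i1 = min(rec.sample_index(ev.offset_ms), rec.n_samples)
        mask[i0:i1] = True
    good = np.flatnonzero(~mask)
    if good.size == 0:
        raise UnrecoverableSignalError("recording has no valid pupil samples")
    idx = np.arange(rec.n_samples)
    filled = x.copy()
    filled[mask] = np.interp(idx[mask], good, x[good])
    frac = float(mask.mean())
    return CleanPupil(
        trace=filled,
        interpolated_mask=mask,
        interpolated_fraction=frac,
        excluded=frac > cfg.interpolation_exclusion_frac,
    )


def lowpass(
    trace: np.ndarray,
    cutoff_hz: float = 10.0,
    fs: float = 500.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass; length-preserving."""
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise DegenerateSignalError("lowpass requires a finite trace")
    b, a = butter(order, cutoff_hz, fs=fs)
    padlen = 3 * max(len(a), len(b))
    if len(trace) <= padlen:
        raise DegenerateSignalError(
            f"trace of {len(trace)} samples is shorter than the filter warm-up ({padlen + 1})"
        )
    return filtfilt(b, a, trace)


def zscore_pupil(
    clean: CleanPupil,
    schedule: TrialSchedule,
    dt_ms: float = 2.0,
) -> CleanPupil:
    """Z-transform the trace using stats over the adaptation/ISI/target union.

    The mean and SD are computed over the union of all trial periods of
    the session (inter-trial response screens excluded); the whole trace
    is transformed with those statistics, so only the period-union
    samples are guaranteed mean 0 / SD 1.
    """
    sel = np.zeros(clean.n_samples, dtype=bool)
    for tr in schedule:
        i0 = int(round(tr.adapt_start_ms / dt_ms))
        i1 = min(int(round(tr.target_end_ms / dt_ms)), clean.n_samples)
        sel[i0:i1] = True
    vals = clean.trace[sel]
    mu = float(vals.mean())
    sd = float(vals.std())
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSignalError("pupil trace has zero variance over the trial periods")
    return replace(
        clean,
        trace=(clean.trace - mu) / sd,
        zscored=True,
        norm_mean=mu,
        norm_sd=sd,
    )


def preprocess_pupil(
    rec: EyeRecording,
    schedule: TrialSchedule,
    cfg: SessionConfig = DEFAULT_CONFIG,
) -> tuple[CleanPupil, list[BlinkEvent]]:
    """Blink detection -> combination/interpolation -> low-pass -> z-score."""
    blinks = detect_blinks(rec, cfg)
    clean = combine_pupil(rec, blinks, cfg)
    clean = replace(clean, trace=lowpass(clean.trace, cfg.lowpass_hz, rec.sample_rate, cfg.lowpass_order))
    clean = zscore_pupil(clean, schedule, rec.dt_ms)
    return clean, blinks


def blink_overlap_s(blinks: list[BlinkEvent], start_ms: float, end_ms: float) -> float:
    """Total blink-event overlap with [start_ms, end_ms), in seconds."""
    total = 0.0
    for ev in blinks:
        total += max(0.0, min(ev.offset_ms, end_ms) - max(ev.onset_ms, start_ms))
    return total / 1000.0
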