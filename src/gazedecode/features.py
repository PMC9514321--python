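"""Per-trial feature extraction and quality-control flags.

Each trial yields six features: the microsaccade rate (events/s) and the
mean z-scored pupil size over the adaptation, ISI and target periods.
Two QC quantities travel with them: the total blink duration overlapping
the trial (seconds) and a flag marking trials where the binocular-mean
gaze strayed more than 0.8 deg from fixation at any point during the
three periods (gaps linearly interpolated first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import DEFAULT_CONFIG, EyeRecording, SessionConfig, Trial, TrialSchedule
from .microsaccades import Microsaccade, saccade_rate
from .preprocess import BlinkEvent, CleanPupil, blink_overlap_s

__all__ = [
    "FEATURE_COLUMNS",
    "TrialFeatures",
    "extract_features",
    "flag_gaze_deviation",
    "build_feature_table",
    "event_locked_averages",
]

FEATURE_COLUMNS = [
    "sacrate_adapt",
    "sacrate_isi",
    "sacrate_target",
    "pupil_adapt",
    "pupil_isi",
    "pupil_target",
]


@dataclass
class TrialFeatures:
    block: int
    trial: int
    condition: str
    decision: str | None
    confidence: str | None
    sacrate_adapt: float
    sacrate_isi: float
    sacrate_target: float
    pupil_adapt: float
    pupil_isi: float
    pupil_target: float
    gaze_deviation: bool
    blink_total_s: float


def _interp_nan(x: np.ndarray) -> np.ndarray:
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    good = np.flatnonzero(~bad)
    if good.size == 0:
        return x
    out = x.copy()
    idx = np.arange(len(x))
    out[bad] = np.interp(idx[bad], good, x[good])
    return out


def flag_gaze_deviation(
    rec: EyeRecording,
    trial: Trial,
    threshold_deg: float = 0.8,
) -> bool:
    """True iff binocular-mean gaze leaves a 0.8 deg radius around fixation.

    Checked over the adaptation, ISI and target periods only (excursions
    during the response screen do not count); gaze gaps are linearly
    interpolated before the check. Fixation is the screen centre (0, 0).
    """
    gx = _interp_nan(0.5 * (np.where(rec.l_valid, rec.lx, rec.rx) + np.where(rec.r_valid, rec.rx, rec.lx)))
    gy = _interp_nan(0.5 * (np.where(rec.l_valid, rec.ly, rec.ry) + np.where(rec.r_valid, rec.ry, rec.ly)))
    sl = rec.sample_slice(trial.adapt_start_ms, trial.target_end_ms)
    d = np.hypot(gx[sl], gy[sl])
    return bool(np.any(d > threshold_deg))


def extract_features(
    trial: Trial,
    saccades: list[Microsaccade],
    zpupil: CleanPupil,
    blinks: list[BlinkEvent],
    rec: EyeRecording | None = None,
    cfg: SessionConfig = DEFAULT_CONFIG,
    dt_ms: float = 2.0,
) -> TrialFeatures:
    """The 6-vector for one trial plus labels and QC fields."""
    rates = {}
    pupils = {}
    for name, (s, e) in trial.periods().items():
        rates[name] = saccade_rate(saccades, s, e)
        i0, i1 = int(round(s / dt_ms)), min(int(round(e / dt_ms)), zpupil.n_samples)
        pupils[name] = float(zpupil.trace[i0:i1].mean())
    deviation = flag_gaze_deviation(rec, trial, cfg.gaze_deviation_deg) if rec is not None else False
    return TrialFeatures(
        block=trial.block_index,
        trial=trial.trial_index,
        condition=trial.condition,
        decision=trial.decision,
        confidence=trial.confidence,
        sacrate_adapt=rates["adapt"],
        sacrate_isi=rates["isi"],
        sacrate_target=rates["target"],
        pupil_adapt=pupils["adapt"],
        pupil_isi=pupils["isi"],
        pupil_target=pupils["target"],
        gaze_deviation=deviation,
        blink_total_s=blink_overlap_s(blinks, trial.adapt_start_ms, trial.target_end_ms),
    )


def build_feature_table(
    rec: EyeRecording,
    zpupil: CleanPupil,
    blinks: list[BlinkEvent],
    saccades: list[Microsaccade],
    schedule: TrialSchedule,
    cfg: SessionConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """One row per scheduled trial (catch trials included)."""
    rows = [
        extract_features(tr, saccades, zpupil, blinks, rec=rec, cfg=cfg, dt_ms=rec.dt_ms).__dict__
        for tr in schedule
    ]
    return pd.DataFrame(rows)


def event_locked_averages(
    zpupil: CleanPupil,
    saccades: list[Microsaccade],
    schedule: TrialSchedule,
    group_by: str = "condition",
    bin_ms: float = 100.0,
    dt_ms: float = 2.0,
) -> pd.DataFrame:
    """Event-locked averages of pupil size and microsaccade counts.

    Reporting utility: trials are aligned at adaptation offset (only the
    final 6 s of adaptation enter, so 60 s first-of-block trials align
    with the rest), covering -6 s .. +1.5 s around that point, and
    averaged within groups ("condition" or "decision"). Returns a tidy
    frame with columns (group, time_ms, pupil, saccade_count).
    """
    lo, hi = -6000.0, 1500.0
    edges = np.arange(lo, hi + bin_ms, bin_ms)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks = np.array([s.peak_time_ms for s in saccades])
    rows = []
    groups: dict[str, list[int]] = {}
    for i, tr in enumerate(schedule):
        key = tr.condition if group_by == "condition" else (tr.decision or "none")
        groups.setdefault(key, []).append(i)
    trials = list(schedule)
    for key, idxs in groups.items():
        pupil_sum = np.zeros(len(centers))
        sacc_sum = np.zeros(len(centers))
        n_ok = 0
        for i in idxs:
            tr = trials[i]
            t0 = tr.adapt_end_ms
            n_ok += 1
            for j, c in enumerate(centers):
                a = int(round((t0 + edges[j]) / dt_ms))
                b = int(round((t0 + edges[j + 1]) / dt_ms))
                pupil_sum[j] += float(zpupil.trace[a:b].mean())
                sacc_sum[j] += int(np.sum((peaks >= t0 + edges[j]) & (peaks < t0 + edges[j + 1])))
        for j, c in enumerate(centers):
            rows.append(
                {
                    "group": key,
                    "time_ms": float(c),
                    "pupil": pupil_sum[j] / n_ok,
                    "saccade_count": sacc_sum[j] / n_ok,
                }
            )
    return pd.DataFrame(rows)
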