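"""Shared conventions, domain types, file formats and configuration.

Conventions inherited by every other module:

* time is in milliseconds, sampled uniformly at 500 Hz (2 ms per sample);
* gaze is in degrees of visual angle relative to the screen centre
  (the fixation bullseye), x rightward, y upward;
* pupil size is in arbitrary tracker units (a.u.);
* all sample indexing is 0-based and every period is the half-open
  interval ``[start, end)`` in ms;
* a missing pupil or gaze sample is carried by an explicit per-eye
  validity flag, never by a sentinel number.

The on-disk formats are deliberately plain: recordings are a documented
CSV dialect (one row per sample), trial schedules and decoding results
are JSON, and the session configuration is a flat key/value JSON file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SAMPLE_RATE_HZ",
    "DT_MS",
    "CATCH",
    "ALL_POSITIONS",
    "POSITIONS_OF_INTEREST",
    "OTHER_POSITIONS",
    "FormatError",
    "ConfigurationError",
    "DegenerateSignalError",
    "UnrecoverableSignalError",
    "EyeRecording",
    "Trial",
    "TrialSchedule",
    "SessionConfig",
    "read_recording",
    "write_recording",
    "save_config",
    "load_config",
]

SAMPLE_RATE_HZ = 500.0
DT_MS = 2.0

CATCH = "catch"
#: the eight possible target locations, evenly spaced on a circle on the
#: cardinal and diagonal axes.
ALL_POSITIONS = (
    "top",
    "topright",
    "right",
    "bottomright",
    "bottom",
    "bottomleft",
    "left",
    "topleft",
)
#: the two locations carrying 65% of target presentations.
POSITIONS_OF_INTEREST = ("topleft", "bottomright")
OTHER_POSITIONS = tuple(p for p in ALL_POSITIONS if p not in POSITIONS_OF_INTEREST)

RECORDING_COLUMNS = ("time_ms", "lx", "ly", "rx", "ry", "lp", "rp", "lvalid", "rvalid")


class FormatError(ValueError):
    """A file violates the documented CSV/JSON dialect."""


class ConfigurationError(ValueError):
    """Inconsistent configuration (e.g. proportions that cannot be rounded)."""


class DegenerateSignalError(ValueError):
    """A signal has no usable variance or is too short for an operation."""


class UnrecoverableSignalError(ValueError):
    """A recording carries no valid samples at all for a required channel."""


# ---------------------------------------------------------------------------
# EyeRecording


@dataclass(eq=False)
class EyeRecording:
    """Uniformly sampled binocular gaze + pupil traces with validity flags.

    Gaze/pupil arrays hold NaN at invalid samples; the ``l_valid`` /
    ``r_valid`` boolean arrays are authoritative.
    """

    time: np.ndarray  # ms
    lx: np.ndarray
    ly: np.ndarray
    rx: np.ndarray
    ry: np.ndarray
    lp: np.ndarray
    rp: np.ndarray
    l_valid: np.ndarray
    r_valid: np.ndarray
    sample_rate: float = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        arrays = [self.time, self.lx, self.ly, self.rx, self.ry, self.lp, self.rp]
        for name in ("time", "lx", "ly", "rx", "ry", "lp", "rp"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("l_valid", "r_valid"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    def validate(self) -> None:
        n = len(self.time)
        for name in ("lx", "ly", "rx", "ry", "lp", "rp", "l_valid", "r_valid"):
            if len(getattr(self, name)) != n:
                raise FormatError(f"channel {name!r} has length {len(getattr(self, name))}, expected {n}")
        if n > 1:
            dts = np.diff(self.time)
            bad = np.flatnonzero(np.abs(dts - self.dt_ms) > 1e-6)
            if bad.size:
                raise FormatError(
                    f"nonuniform sampling: interval of {dts[bad[0]]:g} ms "
                    f"at t={self.time[bad[0] + 1]:g} ms (expected {self.dt_ms:g} ms)"
                )
        for vname, channels in (("l_valid", (self.lx, self.ly)), ("r_valid", (self.rx, self.ry))):
            v = getattr(self, vname)
            for ch in channels:
                if not np.all(np.isfinite(ch[v])):
                    raise FormatError(f"non-finite gaze on samples flagged valid ({vname})")

    def sample_index(self, t_ms: float) -> int:
        """Index of the sample at time ``t_ms`` (0-based)."""
        return int(round(t_ms / self.dt_ms))

    def sample_slice(self, start_ms: float, end_ms: float) -> slice:
        """Half-open sample slice covering ``[start_ms, end_ms)``."""
        return slice(self.sample_index(start_ms), self.sample_index(end_ms))

    def equals(self, other: "EyeRecording") -> bool:
        if self.n_samples != other.n_samples:
            return False
        for name in ("time", "lx", "ly", "rx", "ry", "lp", "rp"):
            a, b = getattr(self, name), getattr(other, name)
            if not np.array_equal(a, b, equal_nan=True):
                return False
        return bool(
            np.array_equal(self.l_valid, other.l_valid)
            and np.array_equal(self.r_valid, other.r_valid)
        )


def read_recording(path) -> EyeRecording:
    """Read a sample-CSV eye-tracking recording.

    The header must declare exactly the columns
    ``time_ms, lx, ly, rx, ry, lp, rp, lvalid, rvalid``; empty gaze/pupil
    cells become missing-flags. Nonuniform sampling is a format error
    naming the first offending timestamp.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if tuple(df.columns) != RECORDING_COLUMNS:
        unknown = [c for c in df.columns if c not in RECORDING_COLUMNS]
        missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
        raise FormatError(f"bad recording header: unknown columns {unknown}, missing {missing}")
    col = {name: df[name].to_numpy(dtype=float) for name in RECORDING_COLUMNS}
    lvalid = col["lvalid"] > 0.5
    rvalid = col["rvalid"] > 0.5
    # an empty pupil/gaze cell is a missing sample whatever the flag column says
    lvalid &= np.isfinite(col["lp"]) & np.isfinite(col["lx"]) & np.isfinite(col["ly"])
    rvalid &= np.isfinite(col["rp"]) & np.isfinite(col["rx"]) & np.isfinite(col["ry"])
    return EyeRecording(
        time=col["time_ms"],
        lx=col["lx"],
        ly=col["ly"],
        rx=col["rx"],
        ry=col["ry"],
        lp=col["lp"],
        rp=col["rp"],
        l_valid=lvalid,
        r_valid=rvalid,
    )


def write_recording(rec: EyeRecording, path) -> None:
    """Write a recording as sample-CSV; NaN cells are written empty.

    ``read_recording(write_recording(rec))`` reproduces ``rec`` exactly
    (floats are serialized with shortest-roundtrip repr).
    """
    df = pd.DataFrame(
        {
            "time_ms": rec.time,
            "lx": rec.lx,
            "ly": rec.ly,
            "rx": rec.rx,
            "ry": rec.ry,
            "lp": rec.lp,
            "rp": rec.rp,
            "lvalid": rec.l_valid.astype(int),
            "rvalid": rec.r_valid.astype(int),
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Trials and schedules


@dataclass
class Trial:
    """One trial: condition, period boundaries (ms, half-open) and response.

    The adaptation period lasts 60 s on the first trial of a block and
    6 s on every other trial; the ISI is 0.5 s and the target window 1 s.
    """

    block_index: int
    trial_index: int
    condition: str
    adapt_start_ms: float
    adapt_end_ms: float
    isi_end_ms: float
    target_end_ms: float
    decision: str | None = None  # "yes" | "no"
    confidence: str | None = None  # "sure" | "maybe"

    @property
    def isi_start_ms(self) -> float:
        return self.adapt_end_ms

    @property
    def target_start_ms(self) -> float:
        return self.isi_end_ms

    @property
    def is_catch(self) -> bool:
        return self.condition == CATCH

    @property
    def is_interest(self) -> bool:
        return self.condition in POSITIONS_OF_INTEREST

    @property
    def first_of_block(self) -> bool:
        return self.trial_index == 0

    def periods(self) -> dict[str, tuple[float, float]]:
        return {
            "adapt": (self.adapt_start_ms, self.adapt_end_ms),
            "isi": (self.adapt_end_ms, self.isi_end_ms),
            "target": (self.isi_end_ms, self.target_end_ms),
        }

    def validate(self) -> None:
        adapt = self.adapt_end_ms - self.adapt_start_ms
        expected = 60_000.0 if self.first_of_block else 6_000.0
        if adapt != expected:
            raise FormatError(
                f"block {self.block_index} trial {self.trial_index}: adaptation "
                f"duration {adapt:g} ms, expected {expected:g}"
            )
        if self.isi_end_ms - self.adapt_end_ms != 500.0:
            raise FormatError("ISI duration must be 500 ms")
        if self.target_end_ms - self.isi_end_ms != 1000.0:
            raise FormatError("target duration must be 1000 ms")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrialSchedule:
    """Block/trial structure of one session plus the response log."""

    trials: list[Trial]
    n_blocks: int
    trials_per_block: int

    def __iter__(self):
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def end_ms(self) -> float:
        return max(t.target_end_ms for t in self.trials) + 1500.0

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.trials:
            out[t.condition] = out.get(t.condition, 0) + 1
        return out

    def validate(self) -> None:
        for t in self.trials:
            t.validate()
        prev_end = 0.0
        for t in self.trials:
            if t.adapt_start_ms < prev_end:
                raise FormatError("overlapping trials in schedule")
            prev_end = t.target_end_ms

    def to_json(self, path) -> None:
        payload = {
            "n_blocks": self.n_blocks,
            "trials_per_block": self.trials_per_block,
            "trials": [t.to_dict() for t in self.trials],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TrialSchedule":
        with open(path) as fh:
            payload = json.load(fh)
        trials = [Trial(**d) for d in payload["trials"]]
        return cls(trials=trials, n_blocks=payload["n_blocks"], trials_per_block=payload["trials_per_block"])


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SessionConfig:
    """Every tunable constant of the pipeline, with its default value.

    Defaults reproduce the published analysis settings; the synthetic
    observer's own parameters live in :class:`gazedecode.synth.ObserverParams`.
    """

    # seeds
    seed_schedule: int = 0
    seed_simulation: int = 1
    seed_cv: int = 2
    seed_permutation: int = 3
    seed_resampling: int = 4

    # schedule
    n_blocks: int = 4
    trials_per_block: int = 43
    p_interest: float = 0.65
    p_other: float = 0.15
    p_catch: float = 0.20
    first_adapt_ms: float = 60_000.0
    adapt_ms: float = 6_000.0
    isi_ms: float = 500.0
    target_ms: float = 1_000.0
    response_ms: float = 1_500.0

    # pupil preprocessing
    blink_pad_ms: float = 200.0
    partial_blink_delta_au: float = 20.0
    interpolation_exclusion_frac: float = 0.45
    lowpass_hz: float = 10.0
    lowpass_order: int = 4

    # microsaccade detection
    peaks_per_second: int = 6
    accel_window_ms: float = 12.0
    pca_eigen_frac: float = 0.05
    kmeans_restarts: int = 10
    onset_speed_floor: float = 3.0  # deg/s
    onset_peak_frac: float = 0.20
    min_duration_ms: float = 8.0
    amplitude_bounds_arcmin: tuple[float, float] = (10.0, 120.0)
    mean_velocity_bounds: tuple[float, float] = (3.0, 120.0)
    main_sequence_r: float = 0.6

    # features / QC
    gaze_deviation_deg: float = 0.8

    # decoding
    cv_repeats: int = 10
    cv_folds: int = 10
    c_grid_lo: float = 1.0
    c_grid_hi: float = 1000.0
    c_grid_size: int = 31
    balanced_repeats: int = 20

    # statistics
    n_permutations: int = 1000
    bf_prior_scale: float = 0.707

    # staircase
    staircase_step: float = 0.05  # log10 contrast units
    staircase_max_reversals: int = 15
    staircase_max_trials: int = 65
    staircase_drop_reversals: int = 2

    def replace(self, **kw) -> "SessionConfig":
        return replace(self, **kw)


DEFAULT_CONFIG = SessionConfig()


def save_config(cfg: SessionConfig, path) -> None:
    """Serialize a configuration as a flat key/value JSON file."""
    d = asdict(cfg)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1, sort_keys=True)


def load_config(path) -> SessionConfig:
    with open(path) as fh:
        d = json.load(fh)
    for k in ("amplitude_bounds_arcmin", "mean_velocity_bounds"):
        if k in d:
            d[k] = tuple(d[k])
    return SessionConfig(**d)
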