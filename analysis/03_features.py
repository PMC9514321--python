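#!/usr/bin/env python
"""Build the per-trial 6-feature tables (saccade rate + pupil per period).

For every participant: one row per scheduled trial carrying the three
per-period microsaccade rates (events/s), the three per-period mean
z-scored pupil sizes, the behavioral labels, the 0.8-deg gaze-deviation
flag and the total blink time overlapping the trial.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

import json

from gazedecode.features import build_feature_table
from gazedecode.io_core import TrialSchedule, read_recording
from gazedecode.microsaccades import detect_microsaccades
from gazedecode.preprocess import preprocess_pupil

RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> int:
    sched = TrialSchedule.from_json(RESULTS / "schedule.json")
    for rec_path in sorted(SCRATCH.glob("p*_recording.csv")):
        name = rec_path.stem.split("_")[0]
        rec = read_recording(rec_path)
        with open(SCRATCH / f"{name}_responses.json") as fh:
            responses = json.load(fh)
        for tr, resp in zip(sched, responses):
            tr.decision = resp["decision"]
            tr.confidence = resp["confidence"]
        clean, blinks = preprocess_pupil(rec, sched)
        det = detect_microsaccades(rec, blinks, seed=0)
        tab = build_feature_table(rec, clean, blinks, det.saccades, sched)
        tab.to_csv(RESULTS / f"features_{name}.csv", index=False)
        flagged = int(tab.gaze_deviation.sum())
        print(
            f"{name}: {len(tab)} trials, {flagged} gaze-deviation flags "
            f"({flagged / len(tab):.0%}), mean blink time "
            f"{tab.blink_total_s.mean():.2f} s/trial"
        )
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
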