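#!/usr/bin/env python
"""Simulate the study: staircase calibration, then full synthetic sessions.

Builds the default 4 x 43-trial schedule, calibrates each simulated
observer's target contrast with the 1-up-1-down staircase, and renders
full 500 Hz binocular sessions for a small cohort of observers with
idiosyncratic feature couplings (each observer links target visibility
to a different mix of per-period microsaccade-rate and pupil offsets).

Raw recordings (tens of MB) go to scratch/; the schedule, ground truth
and the calibration table go to results/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from gazedecode.io_core import write_recording
from gazedecode.synth import (
    LogisticObserver,
    ObserverParams,
    make_schedule,
    run_staircase,
    simulate_session,
)

RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
N_PARTICIPANTS = 3
SEED = 1

# per-observer couplings: different balances of saccade-rate (events/s) and
# pupil (a.u.) offsets, mirroring idiosyncratic observers; confidence has its
# own (weaker, ISI-pupil-heavy) coupling
COUPLINGS = {
    "p01": [0.8, 0.2, 0.4, 10.0, 4.0, 18.0],
    "p02": [-0.5, 0.6, 0.0, -8.0, 14.0, 6.0],
    "p03": [0.2, -0.4, 0.9, 5.0, -12.0, 10.0],
}
CONF_COUPLINGS = {
    "p01": [0.0, 0.3, 0.0, 0.0, 10.0, 3.0],
    "p02": [0.2, 0.0, 0.0, 0.0, 8.0, 0.0],
    "p03": [0.0, 0.0, 0.3, 4.0, 9.0, 0.0],
}


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)

    # --- staircase calibration -------------------------------------------
    rows = []
    for name in COUPLINGS:
        true_thr = rng.normal(-0.5, 0.1)
        obs = LogisticObserver(threshold=true_thr, slope=0.08)
        res = run_staircase(obs, start_level=0.0, seed=int(rng.integers(2**31)))
        rows.append(
            {
                "participant": name,
                "true_threshold_log10": round(true_thr, 4),
                "estimated_threshold_log10": round(res.threshold, 4),
                "n_trials": res.n_trials,
                "n_reversals": res.n_reversals,
                "warning": res.warning,
            }
        )
    stair = pd.DataFrame(rows)
    stair.to_csv(RESULTS / "staircase.csv", index=False)
    err = (stair.estimated_threshold_log10 - stair.true_threshold_log10).abs().mean()
    print(f"staircase calibration: mean |error| = {err:.3f} log10 units over {len(stair)} observers")

    # --- full sessions ----------------------------------------------------
    sched = make_schedule(seed=SEED)
    sched.to_json(RESULTS / "schedule.json")
    print(f"schedule: {len(sched)} trials, counts {sched.counts()}")

    for name, coupling in COUPLINGS.items():
        obs = ObserverParams(
            coupling=np.array(coupling),
            conf_coupling=np.array(CONF_COUPLINGS[name]),
        )
        sim = simulate_session(sched, obs, seed=int(rng.integers(2**31)))
        write_recording(sim.recording, SCRATCH / f"{name}_recording.csv")
        sim.ground_truth.to_json(SCRATCH / f"{name}_truth.json")
        responses = [
            {"block": t.block_index, "trial": t.trial_index, "condition": t.condition,
             "decision": t.decision, "confidence": t.confidence}
            for t in sim.schedule
        ]
        with open(SCRATCH / f"{name}_responses.json", "w") as fh:
            json.dump(responses, fh)
        n_yes = sum(r["decision"] == "yes" for r in responses)
        print(
            f"{name}: {sim.recording.n_samples} samples, "
            f"{len(sim.ground_truth.saccades)} planted saccades, "
            f"{len(sim.ground_truth.blinks)} blinks, {n_yes}/{len(responses)} yes"
        )
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
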