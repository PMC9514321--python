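#!/usr/bin/env python
"""Statistics over the cohort: permutation test, weights, blink control.

Assesses the participant-averaged decision-decoding AUC against a
label-permutation null (reduced permutation count at desk scale),
summarizes decoder weights across participants (per-feature mean with
JZS Bayes factors, saccade-rate vs pupil weight correlations per
period, decision-vs-confidence weight overlap), and runs the blink-
duration yes/no control comparison.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

import json

import numpy as np

from gazedecode.decode import DecodingResult, default_c_grid
from gazedecode.stats import blink_comparison, permutation_test, weight_summary

RESULTS = ROOT / "results"
SEED = 3
N_PERM = 200  # desk-scale; the full analysis default is 1,000


def main() -> int:
    tables = {
        p.stem.replace("features_", ""): pd.read_csv(p)
        for p in sorted(RESULTS.glob("features_p*.csv"))
    }
    with open(RESULTS / "decoding.json") as fh:
        decoding = json.load(fh)

    perm = permutation_test(
        tables, metric="auc", n_perm=N_PERM, seed=SEED,
        grid=default_c_grid()[::3], reuse_c=True,
    )
    print(
        f"permutation test: observed mean AUC {perm.observed:.3f}, "
        f"null mean {perm.null.mean():.3f}, p = {perm.p:.4f} ({N_PERM} permutations)"
    )

    dec = {p: DecodingResult.from_dict(decoding[p]["both"]) for p in tables}
    conf = {p: DecodingResult.from_dict(decoding[p]["confidence_all"]) for p in tables}
    weights = weight_summary(dec, conf)
    for feat, entry in weights["features"].items():
        bf = entry.get("bf10")
        print(f"  weight {feat}: mean {entry['mean']:+.3f}"
              + (f", BF10 {bf:.2f} ({entry['category']})" if bf is not None else ""))

    blink = blink_comparison(tables)
    print(
        f"blink control: yes {blink.mean_yes_s:.3f} s vs no {blink.mean_no_s:.3f} s, "
        f"t({blink.n - 1}) = {blink.t:.2f}, p = {blink.p:.3f}, BF10 = {blink.bf10:.2f}"
    )

    out = {
        "permutation": {
            "observed": perm.observed,
            "null_mean": float(perm.null.mean()),
            "p": perm.p,
            "n_perm": N_PERM,
        },
        "weights": weights,
        "blink_comparison": blink.__dict__,
    }
    with open(RESULTS / "stats.json", "w") as fh:
        json.dump(out, fh, indent=1, default=float)
    print(f"wrote {RESULTS / 'stats.json'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
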