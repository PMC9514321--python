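#!/usr/bin/env python
"""Decode perceptual decisions and confidence per participant.

Runs the sparse logistic decoder with 10 x 10-fold stratified CV and the
31-point C grid on each participant's positions-of-interest trials, in
four variants (both positions, per-position averaged, best position,
balanced resampling), the confidence decoder (all / yes-only / no-only
trials), and the leave-one-participant-out group decoder.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

import json

from gazedecode.decode import decode_confidence, decode_decision, group_decoder

RESULTS = ROOT / "results"
SEED = 2


def main() -> int:
    tables = {
        p.stem.replace("features_", ""): pd.read_csv(p)
        for p in sorted(RESULTS.glob("features_p*.csv"))
    }
    if not tables:
        raise SystemExit("no feature tables found; run 03_features.py first")

    out: dict = {}
    for name, tab in tables.items():
        out[name] = {}
        for variant in ("both", "per", "best", "balanced"):
            res = decode_decision(tab, variant, seed=SEED, balanced_repeats=5)
            out[name][variant] = res.to_dict()
        for subset in ("all", "yes", "no"):
            res = decode_confidence(tab, subset, seed=SEED)
            out[name][f"confidence_{subset}"] = res.to_dict()
        both, best = out[name]["both"], out[name]["best"]
        conf = out[name]["confidence_all"]
        conf_str = ("excluded" if conf["excluded"]
                    else f"AUC {conf['mean_auc']:.3f} acc {conf['mean_accuracy']:.3f}")
        print(
            f"{name}: decision AUC {both['mean_auc']:.3f} "
            f"(acc {both['mean_accuracy']:.3f}, C {both['c']:.3g}), "
            f"best-position AUC {best['mean_auc']:.3f}; confidence {conf_str}"
        )

    grp = group_decoder(tables, seed=SEED)
    out["group"] = grp.to_dict()
    print(f"group (leave-one-participant-out) AUC {grp.mean_auc:.3f}")

    with open(RESULTS / "decoding.json", "w") as fh:
        json.dump(out, fh, indent=1)
    print(f"wrote {RESULTS / 'decoding.json'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
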