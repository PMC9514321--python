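"""Permutation significance, JZS Bayes factors, weight summaries, controls.

Significance of the decoding metrics against chance is assessed with a
label-permutation test: each permutation reassigns the "yes" labels
uniformly at random per participant (class counts preserved), the
decoding is rerun, and the metric is averaged across participants; the
p-value uses the add-one estimator (1 + #{null >= observed}) /
(1 + n_perm), which can never return 0.

The Bayesian paired t-test follows the JZS formulation: a Cauchy prior
(scale 0.707) on the standardized effect size, integrated numerically.
BF10 > 1 favors the alternative (1-3 anecdotal, 3-10 moderate, > 10
strong evidence).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps

from .decode import DecodingResult, cross_validate, decode_decision, _xy
from .features import FEATURE_COLUMNS
from .io_core import POSITIONS_OF_INTEREST, DegenerateSignalError

__all__ = [
    "PermutationResult",
    "BayesFactorResult",
    "permutation_test",
    "paired_bf10",
    "bf_category",
    "weight_summary",
    "blink_comparison",
]


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p: float
    metric: str

    @property
    def n_perm(self) -> int:
        return len(self.null)


@dataclass
class BayesFactorResult:
    t: float
    n: int
    bf10: float
    category: str


def _permute_labels(rng: np.random.Generator, labels: np.ndarray) -> np.ndarray:
    out = labels[rng.permutation(len(labels))]
    assert (out == "yes").sum() == (labels == "yes").sum(), "class counts must be preserved"
    return out


def permutation_test(
    tables: Mapping[str, pd.DataFrame],
    metric: str = "auc",
    n_perm: int = 1000,
    seed: int = 0,
    variant: str = "both",
    repeats: int = 10,
    folds: int = 10,
    grid: Sequence[float] | None = None,
    reuse_c: bool = False,
) -> PermutationResult:
    """Label-permutation test of the participant-averaged decoding metric.

    Each permutation reassigns the "yes" labels at random within each
    participant (exactly preserving that participant's class counts),
    reruns the decoding, and averages accuracy or AUC across
    participants. By default the C grid search is rerun per permutation
    (conservative); ``reuse_c=True`` re-uses each participant's observed
    best C, which leaves the null mean unchanged and is much cheaper.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if metric not in ("accuracy", "auc"):
        raise ValueError("metric must be 'accuracy' or 'auc'")
    rng = np.random.default_rng(seed)

    observed_res = {
        p: decode_decision(t, variant=variant, seed=seed, repeats=repeats, folds=folds, grid=grid)
        for p, t in tables.items()
    }
    pick = (lambda r: r.mean_accuracy) if metric == "accuracy" else (lambda r: r.mean_auc)
    observed = float(np.mean([pick(r) for r in observed_res.values()]))

    null = np.empty(n_perm)
    for k in range(n_perm):
        vals = []
        for p, t in tables.items():
            poi = t[t["condition"].isin(POSITIONS_OF_INTEREST)].copy()
            poi["decision"] = _permute_labels(rng, poi["decision"].to_numpy())
            if reuse_c:
                X, y = _xy(poi)
                acc, auc = cross_validate(X, y, observed_res[p].c, repeats=repeats,
                                          folds=folds, seed=seed)
                vals.append(float(np.mean(acc if metric == "accuracy" else auc)))
            else:
                res = decode_decision(poi, variant="both", seed=seed, repeats=repeats,
                                      folds=folds, grid=grid)
                vals.append(pick(res))
        null[k] = np.mean(vals)
    p_val = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_perm)
    return PermutationResult(observed=observed, null=null, p=p_val, metric=metric)


# ---------------------------------------------------------------------------
# JZS Bayes factor


def bf_category(bf10: float) -> str:
    """Evidence bands for the alternative: boundaries exactly at 1, 3, 10."""
    if bf10 > 10:
        return "strong"
    if bf10 > 3:
        return "moderate"
    if bf10 > 1:
        return "anecdotal"
    return "favors-null"


def _jzs_bf10(t: float, n: int, r: float) -> float:
    """JZS BF10 by one-dimensional quadrature over the variance scale g.

    Marginal likelihood under the alternative integrates the noncentral
    likelihood over g ~ InverseGamma(1/2, r^2/2), the scale-mixture
    representation of the Cauchy(0, r) prior on the effect size.
    """
    nu = n - 1

    def integrand(g: float) -> float:
        like = (1.0 + n * g) ** -0.5 * (1.0 + t * t / ((1.0 + n * g) * nu)) ** (-(nu + 1) / 2.0)
        prior = r / math.sqrt(2.0 * math.pi) * g ** -1.5 * math.exp(-r * r / (2.0 * g))
        return like * prior

    num, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    den = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    return num / den


def paired_bf10(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    prior_scale: float = 0.707,
) -> BayesFactorResult:
    """Bayesian paired-samples t-test (JZS, Cauchy prior scale 0.707).

    Pass either paired samples ``(x, y)`` (differences are formed) or a
    single sample of differences tested against zero.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if len(d) < 2:
        raise ValueError("need at least 2 pairs")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateSignalError("zero-variance differences")
    n = len(d)
    t = float(d.mean() / (sd / math.sqrt(n)))
    bf = _jzs_bf10(t, n, prior_scale)
    return BayesFactorResult(t=t, n=n, bf10=bf, category=bf_category(bf))


# ---------------------------------------------------------------------------
# Weight summaries and control comparisons


def weight_summary(
    decision_results: Mapping[str, DecodingResult],
    confidence_results: Mapping[str, DecodingResult] | None = None,
) -> dict:
    """Cross-participant summary of decoder weights.

    Per feature: mean weight and BF10 of a one-sample test against 0
    (a zero-variance feature column is flagged instead). Per period:
    the Pearson correlation across participants between the SacRate and
    Pupil weights. If confidence decoders are supplied, the per-
    participant correlation between decision and confidence weight
    vectors is reported and averaged.
    """
    names = list(decision_results)
    if len(names) < 3:
        raise ValueError("weight summary needs at least 3 participants")
    W = np.vstack([decision_results[p].weights for p in names])  # (P, 6)
    report: dict = {"participants": names, "features": {}}
    for j, feat in enumerate(FEATURE_COLUMNS):
        col = W[:, j]
        entry: dict = {"mean": float(col.mean())}
        if col.std(ddof=1) == 0.0:
            entry["qc_flag"] = "zero-variance weights; BF undefined"
        else:
            bf = paired_bf10(col)
            entry.update({"bf10": bf.bf10, "t": bf.t, "category": bf.category})
        report["features"][feat] = entry
    report["sacrate_pupil_correlation"] = {}
    for p_idx, period in enumerate(("adapt", "isi", "target")):
        a, b = W[:, p_idx], W[:, 3 + p_idx]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            report["sacrate_pupil_correlation"][period] = {
                "qc_flag": "zero variance; correlation undefined"
            }
        else:
            rr = sps.pearsonr(a, b)
            report["sacrate_pupil_correlation"][period] = {
                "r": float(rr.statistic),
                "p": float(rr.pvalue),
            }
    if confidence_results is not None:
        rs = []
        for p in names:
            if p not in confidence_results or confidence_results[p].excluded:
                continue
            wd = decision_results[p].weights
            wc = confidence_results[p].weights
            if np.ptp(wd) == 0 or np.ptp(wc) == 0:
                continue
            rs.append(float(sps.pearsonr(wd, wc).statistic))
        report["decision_confidence_weight_correlation"] = {
            "per_participant": rs,
            "mean": float(np.mean(rs)) if rs else None,
        }
    return report


@dataclass
class BlinkComparison:
    mean_yes_s: float
    mean_no_s: float
    t: float
    p: float
    bf10: float
    n: int


def blink_comparison(tables: Mapping[str, pd.DataFrame]) -> BlinkComparison:
    """Does total per-trial blink duration differ between yes and no trials?

    Per participant, the mean of ``blink_total_s`` is formed for each
    label; the participant means are compared with a paired t-test and
    the JZS paired Bayes factor. Participants missing one label are
    skipped with a warning.
    """
    ys, ns = [], []
    for p, t in tables.items():
        yes = t.loc[t["decision"] == "yes", "blink_total_s"]
        no = t.loc[t["decision"] == "no", "blink_total_s"]
        if len(yes) == 0 or len(no) == 0:
            warnings.warn(f"participant {p} lacks one response label; skipped")
            continue
        ys.append(float(yes.mean()))
        ns.append(float(no.mean()))
    if len(ys) < 2:
        raise ValueError("paired comparison needs at least 2 participants with both labels")
    tt = sps.ttest_rel(ys, ns)
    bf = paired_bf10(ys, ns)
    return BlinkComparison(
        mean_yes_s=float(np.mean(ys)),
        mean_no_s=float(np.mean(ns)),
        t=float(tt.statistic),
        p=float(tt.pvalue),
        bf10=bf.bf10,
        n=len(ys),
    )
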