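"""L1-regularized logistic decoding with repeated stratified CV.

The decision decoder classifies yes/no reports from the six per-trial
features using sparse (L1) logistic regression. Performance is measured
with 10x10-fold stratified cross-validation (accuracy at the 0.5
probability threshold and AUC per test fold, 100 folds in total);
standardization is fit on the training folds only. The inverse penalty
C is grid-searched over 31 log-spaced values between 1 and 10^3 to
maximize mean AUC (smaller C wins ties, i.e. the sparser model); the C
search shares the report folds by default, mirroring the original
analysis, with a ``nested=True`` option for a properly nested search.

Variants: both positions of interest pooled; per-position decoders
(metrics averaged); the best position per participant; balanced
resampling of the majority class; a leave-one-participant-out group
decoder; and the confidence (sure/maybe) decoder on all / yes-only /
no-only trials.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

from .io_core import DEFAULT_CONFIG, POSITIONS_OF_INTEREST, SessionConfig
from .features import FEATURE_COLUMNS

__all__ = [
    "DecodingResult",
    "default_c_grid",
    "cross_validate",
    "grid_search_c",
    "decode_decision",
    "decode_confidence",
    "group_decoder",
    "save_results_json",
]


@dataclass
class DecodingResult:
    variant: str
    weights: np.ndarray  # 6-vector on standardized features
    intercept: float
    c: float
    fold_accuracy: np.ndarray
    fold_auc: np.ndarray
    n_trials: int
    excluded: bool = False
    note: str = ""

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy)) if len(self.fold_accuracy) else float("nan")

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc)) if len(self.fold_auc) else float("nan")

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "weights": np.asarray(self.weights).tolist(),
            "intercept": self.intercept,
            "c": self.c,
            "fold_accuracy": np.asarray(self.fold_accuracy).tolist(),
            "fold_auc": np.asarray(self.fold_auc).tolist(),
            "mean_accuracy": self.mean_accuracy,
            "mean_auc": self.mean_auc,
            "n_trials": self.n_trials,
            "excluded": self.excluded,
            "note": self.note,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecodingResult":
        return cls(
            variant=d["variant"],
            weights=np.array(d["weights"]),
            intercept=d["intercept"],
            c=d["c"],
            fold_accuracy=np.array(d["fold_accuracy"]),
            fold_auc=np.array(d["fold_auc"]),
            n_trials=d["n_trials"],
            excluded=d.get("excluded", False),
            note=d.get("note", ""),
        )


def _l1_logistic(C: float) -> LogisticRegression:
    """Lasso-penalized logistic regression (liblinear handles pure L1)."""
    return LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", random_state=0)


def default_c_grid(cfg: SessionConfig = DEFAULT_CONFIG) -> np.ndarray:
    """31 values between 1 and 10^3, evenly spaced on a log scale."""
    return np.logspace(np.log10(cfg.c_grid_lo), np.log10(cfg.c_grid_hi), cfg.c_grid_size)


def _check_class_sizes(y: np.ndarray, folds: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    for cls_, cnt in zip(classes, counts):
        if cnt < folds:
            raise ValueError(
                f"class {cls_!r} has {cnt} trials, fewer than the {folds} CV folds"
            )


def _fit_fold(Xtr, ytr, Xte, C: float, standardize: str):
    if standardize == "fold":
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
    else:  # "global" is handled by the caller; "none" leaves data untouched
        mu, sd = np.zeros(Xtr.shape[1]), np.ones(Xtr.shape[1])
    sd = np.where(sd == 0.0, 1.0, sd)
    clf = _l1_logistic(C)
    clf.fit((Xtr - mu) / sd, ytr)
    prob = clf.predict_proba((Xte - mu) / sd)[:, 1]
    return clf, prob


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
    standardize: str = "fold",
    return_models: bool = False,
):
    """Repeated stratified CV at a fixed C; returns per-fold (accuracy, AUC).

    Folds preserve class proportions; each repeat reshuffles with a seed
    derived from ``seed``. Standardization is fit on the training folds
    only (``standardize="fold"``, the default) or skipped entirely
    (``"none"``, for data standardized globally beforehand).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if np.any(X.std(axis=0) == 0.0) and standardize == "fold":
        # constant features carry no information but are harmless after scaling
        pass
    _check_class_sizes(y, folds)
    rskf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    accs, aucs, models = [], [], []
    for tr_idx, te_idx in rskf.split(X, y):
        clf, prob = _fit_fold(X[tr_idx], y[tr_idx], X[te_idx], C, standardize)
        yte = y[te_idx]
        accs.append(float(np.mean((prob >= 0.5).astype(int) == yte)))
        aucs.append(float(roc_auc_score(yte, prob)))
        if return_models:
            models.append(clf)
    out = np.array(accs), np.array(aucs)
    return (*out, models) if return_models else out


def _fit_full(X: np.ndarray, y: np.ndarray, C: float) -> tuple[np.ndarray, float]:
    """Final weights: fit on all data, standardized globally."""
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    clf = _l1_logistic(C)
    clf.fit((X - mu) / sd, y)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def grid_search_c(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[float] | None = None,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
    variant: str = "both-positions",
    nested: bool = False,
) -> tuple[float, DecodingResult]:
    """Grid-search C to maximize mean AUC; ties go to the smaller C.

    Every C is evaluated on the same folds (same seed). With
    ``nested=True`` the reported metrics come from an outer CV whose C is
    chosen by an inner 5-fold search per outer fold (no selection
    optimism); the default shares folds between selection and report.
    The returned weights always come from a fit on all standardized data
    at the chosen C.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if np.all(X.std(axis=0) == 0.0):
        raise ValueError("degenerate features: zero variance everywhere")
    grid = np.asarray(default_c_grid() if grid is None else grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty C grid")

    if nested:
        _check_class_sizes(y, folds)
        rskf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
        accs, aucs, picked = [], [], []
        for tr_idx, te_idx in rskf.split(X, y):
            inner_best, inner_auc = None, -np.inf
            inner_folds = min(5, int(np.bincount(y[tr_idx]).min()))
            for C in grid:
                _, a = cross_validate(X[tr_idx], y[tr_idx], C, repeats=1,
                                      folds=inner_folds, seed=seed)
                if a.mean() > inner_auc:
                    inner_auc, inner_best = a.mean(), C
            _, prob = _fit_fold(X[tr_idx], y[tr_idx], X[te_idx], inner_best, "fold")
            accs.append(float(np.mean((prob >= 0.5).astype(int) == y[te_idx])))
            aucs.append(float(roc_auc_score(y[te_idx], prob)))
            picked.append(inner_best)
        best_c = float(np.median(picked))
        w, b = _fit_full(X, y, best_c)
        return best_c, DecodingResult(variant, w, b, best_c, np.array(accs), np.array(aucs), len(y))

    best_c, best_auc, best_metrics = None, -np.inf, None
    for C in grid:  # ascending grid: strict improvement keeps the smaller C on ties
        acc, auc = cross_validate(X, y, C, repeats=repeats, folds=folds, seed=seed)
        if auc.mean() > best_auc:
            best_c, best_auc, best_metrics = float(C), auc.mean(), (acc, auc)
    w, b = _fit_full(X, y, best_c)
    acc, auc = best_metrics
    return best_c, DecodingResult(variant, w, b, best_c, acc, auc, len(y))


def _xy(table: pd.DataFrame, label_column: str = "decision", positive: str = "yes"):
    X = table[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = (table[label_column] == positive).to_numpy().astype(int)
    return X, y


def decode_decision(
    table: pd.DataFrame,
    variant: str = "both",
    seed: int = 0,
    repeats: int = 10,
    folds: int = 10,
    grid: Sequence[float] | None = None,
    balanced_repeats: int = 20,
    nested: bool = False,
) -> DecodingResult:
    """Decode yes/no reports on positions-of-interest trials.

    ``variant``: "both" pools the two positions; "per" fits one decoder
    per position and averages the metrics; "best" keeps the position
    with the higher AUC; "balanced" undersamples the majority class to
    the minority size (20 seeded repeats, averaged).
    """
    poi = table[table["condition"].isin(POSITIONS_OF_INTEREST)]
    if variant == "both":
        X, y = _xy(poi)
        _, res = grid_search_c(X, y, grid, repeats, folds, seed, "both-positions", nested)
        return res

    if variant in ("per", "best"):
        results = []
        for pos in POSITIONS_OF_INTEREST:
            sub = poi[poi["condition"] == pos]
            X, y = _xy(sub)
            counts = np.bincount(y, minlength=2)
            if counts.min() < folds:
                warnings.warn(f"position {pos}: a class has fewer than {folds} trials; skipped")
                continue
            _, res = grid_search_c(X, y, grid, repeats, folds, seed, f"pos-{pos}", nested)
            results.append(res)
        if not results:
            raise ValueError("no position had enough trials per class")
        if variant == "best":
            return max(results, key=lambda r: r.mean_auc)
        return DecodingResult(
            variant="per-position",
            weights=np.mean([r.weights for r in results], axis=0),
            intercept=float(np.mean([r.intercept for r in results])),
            c=float(np.median([r.c for r in results])),
            fold_accuracy=np.concatenate([r.fold_accuracy for r in results]),
            fold_auc=np.concatenate([r.fold_auc for r in results]),
            n_trials=sum(r.n_trials for r in results),
        )

    if variant == "balanced":
        X, y = _xy(poi)
        rng = np.random.default_rng(seed)
        counts = np.bincount(y, minlength=2)
        minority = int(np.argmin(counts))
        n_min = counts[minority]
        accs, aucs, ws, cs = [], [], [], []
        for _ in range(balanced_repeats):
            keep_maj = rng.choice(np.flatnonzero(y != minority), size=n_min, replace=False)
            idx = np.sort(np.concatenate([np.flatnonzero(y == minority), keep_maj]))
            _, res = grid_search_c(X[idx], y[idx], grid, repeats, folds, seed, "balanced", nested)
            accs.append(res.fold_accuracy)
            aucs.append(res.fold_auc)
            ws.append(res.weights)
            cs.append(res.c)
        return DecodingResult(
            variant="balanced",
            weights=np.mean(ws, axis=0),
            intercept=0.0,
            c=float(np.median(cs)),
            fold_accuracy=np.mean(accs, axis=0),
            fold_auc=np.mean(aucs, axis=0),
            n_trials=2 * int(n_min),
        )

    raise ValueError(f"unknown variant {variant!r}")


def decode_confidence(
    table: pd.DataFrame,
    subset: str = "all",
    seed: int = 0,
    repeats: int = 10,
    folds: int = 10,
    grid: Sequence[float] | None = None,
) -> DecodingResult:
    """Decode sure/maybe confidence on all / yes-only / no-only trials.

    A participant whose minority confidence class has fewer than 2
    trials is excluded (flagged, no metrics). The fold count is capped
    at the minority class size.
    """
    if subset == "yes":
        sub = table[table["decision"] == "yes"]
    elif subset == "no":
        sub = table[table["decision"] == "no"]
    elif subset == "all":
        sub = table
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if len(sub) == 0:
        raise ValueError(f"subset {subset!r} selects no trials")
    X, y = _xy(sub, label_column="confidence", positive="sure")
    counts = np.bincount(y, minlength=2)
    variant = f"confidence-{subset}"
    if counts.min() < 2:
        return DecodingResult(
            variant=variant,
            weights=np.full(len(FEATURE_COLUMNS), np.nan),
            intercept=float("nan"),
            c=float("nan"),
            fold_accuracy=np.array([]),
            fold_auc=np.array([]),
            n_trials=len(sub),
            excluded=True,
            note="minority confidence class has fewer than 2 trials",
        )
    folds_eff = min(folds, int(counts.min()))
    _, res = grid_search_c(X, y, grid, repeats, folds_eff, seed, variant)
    return res


def group_decoder(
    tables: Mapping[str, pd.DataFrame],
    seed: int = 0,
    repeats: int = 10,
    folds: int = 10,
    grid: Sequence[float] | None = None,
) -> DecodingResult:
    """Leave-one-participant-out decision decoder.

    The remaining participants' positions-of-interest trials form the
    training set (C chosen by CV on that pool, standardization fit on
    it); metrics are one accuracy/AUC pair per held-out participant.
    """
    names = list(tables)
    if len(names) < 2:
        raise ValueError("group decoding needs at least 2 participants")
    accs, aucs, ws = [], [], []
    for held in names:
        train = pd.concat([tables[p] for p in names if p != held], ignore_index=True)
        test = tables[held]
        Xtr, ytr = _xy(train[train["condition"].isin(POSITIONS_OF_INTEREST)])
        Xte, yte = _xy(test[test["condition"].isin(POSITIONS_OF_INTEREST)])
        best_c, _ = grid_search_c(Xtr, ytr, grid, repeats=min(repeats, 3), folds=folds,
                                  seed=seed, variant="group-inner")
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd = np.where(sd == 0.0, 1.0, sd)
        clf = _l1_logistic(best_c)
        clf.fit((Xtr - mu) / sd, ytr)
        prob = clf.predict_proba((Xte - mu) / sd)[:, 1]
        accs.append(float(np.mean((prob >= 0.5).astype(int) == yte)))
        aucs.append(float(roc_auc_score(yte, prob)))
        ws.append(clf.coef_[0].copy())
    return DecodingResult(
        variant="group",
        weights=np.mean(ws, axis=0),
        intercept=0.0,
        c=float("nan"),
        fold_accuracy=np.array(accs),
        fold_auc=np.array(aucs),
        n_trials=sum(len(t) for t in tables.values()),
    )


def save_results_json(results: Mapping[str, DecodingResult], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: v.to_dict() for k, v in results.items()}, fh, indent=1)
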