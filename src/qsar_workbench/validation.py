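"""Model validation statistics, triage views, external validation and
Y-scrambling.

Categorical models are summarised by confusion counts, sensitivity,
specificity and a ROC curve (descending-score threshold sweep, tied scores
grouped into one step, trapezoidal area).  Continuous models are summarised
by the coefficient of determination R², RMSE and a regression error
characteristic (REC) curve — the fraction of predictions within an absolute
error tolerance ε, swept over ε.

Undefined rates (a class absent from the truth, zero response variance) are
reported as NaN, never silently as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class ValidationStats:
    """Train- or test-side statistics for one model."""

    # categorical
    tp: int | None = None
    fp: int | None = None
    tn: int | None = None
    fn: int | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    roc_auc: float | None = None
    roc_points: list[tuple[float, float]] | None = None
    # continuous
    r_squared: float | None = None
    rmse: float | None = None
    rec_points: list[tuple[float, float]] | None = None
    rec_area: float | None = None

    def to_dict(self, include_curves: bool = False) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if v is not None and (include_curves or k not in ("roc_points", "rec_points"))
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ValidationStats":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


# ---------------------------------------------------------------------------
# Categorical statistics
# ---------------------------------------------------------------------------

def confusion_and_rates(
    labels_true: Sequence, labels_pred: Sequence, positive_class
) -> dict:
    """Binary confusion counts plus sensitivity and specificity.

    Sensitivity = TP/(TP+FN); specificity = TN/(TN+FP).  A rate whose
    denominator class is absent from the truth is NaN (undefined), not 0.
    """
    yt = [str(v) for v in labels_true]
    yp = [str(v) for v in labels_pred]
    if len(yt) != len(yp):
        raise ValueError("label vectors differ in length")
    pos = str(positive_class)
    tp = sum(1 for t, p in zip(yt, yp) if t == pos and p == pos)
    fn = sum(1 for t, p in zip(yt, yp) if t == pos and p != pos)
    tn = sum(1 for t, p in zip(yt, yp) if t != pos and p != pos)
    fp = sum(1 for t, p in zip(yt, yp) if t != pos and p == pos)
    sens = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    spec = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    acc = (tp + tn) / len(yt) if yt else math.nan
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": sens, "specificity": spec, "accuracy": acc,
    }


def roc_auc(
    scores: Sequence[float], labels: Sequence, positive_class
) -> tuple[list[tuple[float, float]], float]:
    """ROC curve and area by descending-score threshold sweep.

    Tied scores are grouped into a single step (so all-equal scores give the
    chance diagonal and AUC 0.5); the area is the trapezoidal integral, which
    equals the positive–negative pairwise concordance with ties counted ½.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([str(v) == str(positive_class) for v in labels])
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present in the truth")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        tp += int(y[i:j].sum())
        fp += int((j - i) - y[i:j].sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    area = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return points, float(area)


# ---------------------------------------------------------------------------
# Continuous statistics
# ---------------------------------------------------------------------------

def regression_stats(y_true: Sequence[float], y_pred: Sequence[float]) -> dict:
    """R² (coefficient of determination, 1 − SSres/SStot) and RMSE.

    R² is NaN when the truth has zero variance; RMSE is always returned.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.size < 2:
        raise ValueError("regression statistics need at least 2 records")
    ss_res = float(((yt - yp) ** 2).sum())
    ss_tot = float(((yt - yt.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    rmse = math.sqrt(ss_res / yt.size)
    return {"r_squared": r2, "rmse": rmse}


def rec_curve(
    y_true: Sequence[float],
    y_pred: Sequence[float],
    epsilon_grid: Sequence[float] | None = None,
    n_grid: int = 100,
) -> tuple[list[tuple[float, float]], float]:
    """REC curve: fraction of records with |error| ≤ ε over an ε grid.

    The default grid is ``n_grid`` evenly spaced tolerances from 0 to the
    maximum absolute error.  The area is the curve's mean height over the
    grid span (normalised to [0, 1] so models on different response scales
    are comparable).
    """
    err = np.abs(np.asarray(y_true, float) - np.asarray(y_pred, float))
    if epsilon_grid is None:
        top = float(err.max())
        epsilon_grid = np.linspace(0.0, top if top > 0 else 1.0, n_grid)
    eps = np.asarray(list(epsilon_grid), dtype=float)
    if eps.size == 0:
        raise ValueError("epsilon grid must be non-empty")
    frac = [(float(e), float((err <= e).mean())) for e in eps]
    span = eps[-1] - eps[0]
    if span > 0:
        area = float(np.trapezoid([f for _, f in frac], eps) / span)
    else:
        area = frac[0][1]
    return frac, area


# ---------------------------------------------------------------------------
# Stats for a fitted model on one side of a split
# ---------------------------------------------------------------------------

def stats_for_predictions(
    endpoint_type: str,
    y_true: Sequence,
    y_pred: Sequence,
    scores: Sequence[float] | None = None,
    positive_class=None,
) -> ValidationStats:
    """Bundle the appropriate statistics for one prediction set."""
    st = ValidationStats()
    if endpoint_type == "categorical":
        rates = confusion_and_rates(y_true, y_pred, positive_class)
        for k, v in rates.items():
            setattr(st, k, v)
        if scores is not None:
            try:
                points, area = roc_auc(scores, y_true, positive_class)
                st.roc_points, st.roc_auc = points, area
            except ValueError:
                st.roc_auc = math.nan
    else:
        for k, v in regression_stats(y_true, y_pred).items():
            setattr(st, k, v)
        points, area = rec_curve(y_true, y_pred)
        st.rec_points, st.rec_area = points, area
    return st


# ---------------------------------------------------------------------------
# Triage
# ---------------------------------------------------------------------------

@dataclass
class TriageTable:
    """Sortable, filterable spreadsheet view over a model matrix.

    ``table`` has one row per model with the provenance triple
    (split/subset/learner) and all scalar train/test statistics; filtering
    and sorting never mutate the underlying results.
    """

    table: pd.DataFrame
    summary_series: pd.DataFrame
    breakdown: dict[str, dict]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


_FILTER_OPS: dict[str, Callable] = {
    ">=": lambda a, b: a >= b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    "<": lambda a, b: a < b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
}


def triage(
    results: Sequence,
    sort_keys: Sequence[str] | None = None,
    ascending: bool | Sequence[bool] = True,
    filters: Sequence[tuple[str, str, object]] = (),
) -> TriageTable:
    """Build the triage table from a collection of ModelResult objects.

    ``filters`` are (column, op, value) predicates, e.g.
    ``("test_roc_auc", ">=", 0.9)`` or ``("learner_name", "==", "svm")``.
    Sorting is stable (mergesort), so equal keys keep their prior order.
    The summary series pairs each model's train statistic with its test
    statistic (the train-vs-test scatter of the model-triage view), and the
    breakdown counts the filtered selection by learner, split and subset.
    """
    if not results:
        raise ValueError("no model results to triage")
    rows = []
    for r in results:
        row = {
            "model_id": r.model_id,
            "split_label": r.split_label,
            "subset_label": r.subset_label,
            "learner_name": r.learner_name,
            "status": r.status,
        }
        if r.train_stats is not None:
            row.update({f"train_{k}": v for k, v in r.train_stats.to_dict().items()})
        if r.test_stats is not None:
            row.update({f"test_{k}": v for k, v in r.test_stats.to_dict().items()})
        rows.append(row)
    df = pd.DataFrame(rows)
    for col, op, value in filters:
        if col not in df.columns:
            raise KeyError(f"unknown filter column {col!r}")
        if op not in _FILTER_OPS:
            raise ValueError(f"unknown filter op {op!r}")
        mask = _FILTER_OPS[op](df[col], value)
        df = df[mask.fillna(False)] if hasattr(mask, "fillna") else df[mask]
    if sort_keys:
        for k in sort_keys:
            if k not in df.columns:
                raise KeyError(f"unknown sort key {k!r}")
        df = df.sort_values(list(sort_keys), ascending=ascending, kind="mergesort")
    df = df.reset_index(drop=True)

    stat = "roc_auc" if "test_roc_auc" in df.columns else "r_squared"
    cols = [c for c in (f"train_{stat}", f"test_{stat}") if c in df.columns]
    summary = df[["model_id", "split_label", "subset_label", "learner_name", *cols]].copy()
    breakdown = {
        dim: df[dim].value_counts().to_dict()
        for dim in ("learner_name", "split_label", "subset_label")
    }
    return TriageTable(df, summary, breakdown)


# ---------------------------------------------------------------------------
# External validation and Y-scrambling
# ---------------------------------------------------------------------------

def external_validate(model_result, X_external: pd.DataFrame, y_external: Sequence,
                      endpoint_type: str, positive_class=None) -> ValidationStats:
    """Statistics for a fitted model on an external set (never refits)."""
    if len(X_external) == 0:
        raise ValueError("external set is empty")
    from .model_matrix import predict_with_scores  # local import to avoid cycle

    if hasattr(X_external, "to_numpy"):
        X_external = X_external.to_numpy()

    y_pred, scores = predict_with_scores(model_result.fitted_model, X_external,
                                         positive_class)
    return stats_for_predictions(endpoint_type, list(y_external), list(y_pred),
                                 scores, positive_class)


def y_scramble(
    fit_fn: Callable[[pd.DataFrame, Sequence], object],
    score_fn: Callable[[object], float],
    X_train: pd.DataFrame,
    y_train: Sequence,
    n_permutations: int,
    seed: int,
    observed: float | None = None,
) -> dict:
    """Chance-correlation baseline by response scrambling.

    Permutes the training responses, refits with ``fit_fn`` and records the
    test statistic computed by ``score_fn`` for each permutation.  Returns the
    observed statistic, the scrambled mean/sd, all scrambled values, and the
    fraction of permutations whose statistic reaches the observed one.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(list(y_train))
    scrambled = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(y))
        model = fit_fn(X_train, y[perm])
        scrambled.append(float(score_fn(model)))
    arr = np.asarray(scrambled)
    out = {
        "scrambled": scrambled,
        "scrambled_mean": float(arr.mean()),
        "scrambled_sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        "scrambled_max": float(arr.max()),
    }
    if observed is not None:
        out["observed"] = float(observed)
        out["exceedance_fraction"] = float((arr >= observed).mean())
    return out
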