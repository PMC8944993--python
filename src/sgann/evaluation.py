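"""Model evaluation: agreement regression, classification metrics, k-fold CV.

Regression agreement between codified targets (actual) and network outputs
(predicted) is summarised by the Pearson correlation R, the determination
coefficient R^2, and the fitted line predicted = slope * actual + intercept,
together with a two-sided Student t-test of H0: slope = 1 and
H0: intercept = 0 at a configurable confidence level (99.8% by default).

Classification takes SGA as the positive class.  Network outputs are mapped
to classes through the output intervals (SGA band below the AGA band); for
confusion counting an output below the SGA band still counts as an SGA call,
since it is more SGA-leaning than the band itself.  AUROC is the rank-based
(Mann-Whitney) probability that a random SGA case gets a more SGA-leaning
score than a random AGA case, with ties counted one half; because *lower*
network outputs indicate SGA, outputs are negated before ranking.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats

from . import network as nn
from .panel import AGA, SGA
from .simulator import ClassificationIntervals


@dataclass
class SlopeInterceptTest:
    """Two-sided t-tests of slope = 1 and intercept = 0 for the agreement
    regression; ``passed`` means neither null is rejected at the stated
    confidence level."""

    t_slope: float
    t_intercept: float
    df: int
    confidence: float
    p_slope: float
    p_intercept: float
    passed: bool


@dataclass
class PerformanceReport:
    """Agreement and classification metrics of one evaluation.

    Classification fields are fractions in [0, 1]; ratios with a zero
    denominator (e.g. PPV with no positive call) are NaN ("undefined"),
    never silently 0.
    """

    n: int = 0
    rmse: float = math.nan
    r: float = math.nan
    r2: float = math.nan
    slope: float = math.nan
    intercept: float = math.nan
    slope_intercept: SlopeInterceptTest | None = None
    accuracy: float = math.nan
    f1: float = math.nan
    ppv: float = math.nan
    npv: float = math.nan
    recall: float = math.nan
    auroc: float = math.nan
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, allow_nan=True)


def regression_performance(actual, predicted) -> tuple[float, float, float, float]:
    """(r, r2, slope, intercept) of the OLS line predicted = a * actual + b.

    Requires n >= 3 and non-constant ``actual``.
    """
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if actual.size != predicted.size:
        raise ValueError("actual and predicted must have equal length")
    if actual.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(actual) == 0:
        raise ValueError("actual values are constant; regression is degenerate")
    res = scipy.stats.linregress(actual, predicted)
    r = float(res.rvalue)
    return r, r * r, float(res.slope), float(res.intercept)


def slope_intercept_test(actual, predicted,
                         confidence: float = 0.998) -> SlopeInterceptTest:
    """Student t-tests of H0: slope = 1 and H0: intercept = 0 with n-2 df.

    ``passed`` is True iff neither hypothesis is rejected at
    alpha = 1 - confidence, i.e. the fitted line is statistically
    indistinguishable from the identity at that confidence.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if actual.size < 3:
        raise ValueError("slope/intercept test needs at least 3 points")
    res = scipy.stats.linregress(actual, predicted)
    df = actual.size - 2
    se_slope = res.stderr
    se_int = res.intercept_stderr
    t_slope = (res.slope - 1.0) / se_slope if se_slope > 0 else math.inf
    t_int = res.intercept / se_int if se_int > 0 else math.inf
    p_slope = 2.0 * scipy.stats.t.sf(abs(t_slope), df)
    p_int = 2.0 * scipy.stats.t.sf(abs(t_int), df)
    alpha = 1.0 - confidence
    return SlopeInterceptTest(
        t_slope=float(t_slope), t_intercept=float(t_int), df=df,
        confidence=confidence, p_slope=float(p_slope), p_intercept=float(p_int),
        passed=bool(p_slope > alpha and p_int > alpha))


def binarize_outputs(outputs, intervals: ClassificationIntervals | None = None
                     ) -> np.ndarray:
    """Predicted labels from network outputs: SGA below the AGA band, AGA
    inside it (the two-decimal rounding rule resolves the band gap)."""
    intervals = intervals or ClassificationIntervals()
    outputs = np.asarray(outputs, dtype=float).ravel()
    rounded = np.round(outputs, 2)
    return np.where(rounded < intervals.aga_low, SGA, AGA)


def confusion_metrics(labels, outputs,
                      intervals: ClassificationIntervals | None = None
                      ) -> PerformanceReport:
    """Confusion counts and derived metrics with SGA as the positive class.

    accuracy = (TP+TN)/n, PPV = TP/(TP+FP), NPV = TN/(TN+FN),
    recall = TP/(TP+FN), F1 = 2*PPV*recall/(PPV+recall); ratios with a zero
    denominator are NaN (undefined).
    """
    labels = np.asarray(labels, dtype=object).ravel()
    outputs = np.asarray(outputs, dtype=float).ravel()
    if labels.size == 0:
        raise ValueError("confusion metrics of an empty set are undefined")
    if labels.size != outputs.size:
        raise ValueError("labels and outputs must have equal length")
    bad = set(labels) - {SGA, AGA}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    pred = binarize_outputs(outputs, intervals)
    tp = int(np.sum((labels == SGA) & (pred == SGA)))
    fn = int(np.sum((labels == SGA) & (pred == AGA)))
    tn = int(np.sum((labels == AGA) & (pred == AGA)))
    fp = int(np.sum((labels == AGA) & (pred == SGA)))
    n = labels.size

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    recall = ratio(tp, tp + fn)
    if math.isnan(ppv) or math.isnan(recall) or (ppv + recall) == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * ppv * recall / (ppv + recall)
    return PerformanceReport(
        n=n, accuracy=(tp + tn) / n, f1=f1, ppv=ppv, npv=npv, recall=recall,
        tp=tp, fp=fp, tn=tn, fn=fn)


def auroc(labels, scores, positive: str = SGA) -> float:
    """Rank-based AUROC: probability that a random positive case scores
    higher than a random negative case, ties counted one half (midranks,
    Mann-Whitney formulation).  Higher score must favor the positive class.
    """
    labels = np.asarray(labels, dtype=object).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    pos = labels == positive
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = scipy.stats.rankdata(scores)        # midranks
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auroc_from_outputs(labels, outputs, positive: str = SGA) -> float:
    """AUROC with the network-output orientation: lower outputs indicate
    SGA, so outputs are negated before ranking."""
    return auroc(labels, -np.asarray(outputs, dtype=float), positive=positive)


def evaluate(actual_targets, outputs, labels=None,
             intervals: ClassificationIntervals | None = None,
             confidence: float = 0.998) -> PerformanceReport:
    """Full performance report: RMSE + agreement regression (+ the
    slope/intercept test), and classification metrics when labels are given."""
    actual_targets = np.asarray(actual_targets, dtype=float).ravel()
    outputs = np.asarray(outputs, dtype=float).ravel()
    report = PerformanceReport(n=actual_targets.size)
    report.rmse = nn.rmse(outputs, actual_targets)
    if actual_targets.size >= 3 and np.ptp(actual_targets) > 0:
        report.r, report.r2, report.slope, report.intercept = \
            regression_performance(actual_targets, outputs)
        report.slope_intercept = slope_intercept_test(
            actual_targets, outputs, confidence)
    if labels is not None:
        cls = confusion_metrics(labels, outputs, intervals)
        for f in ("accuracy", "f1", "ppv", "npv", "recall",
                  "tp", "fp", "tn", "fn"):
            setattr(report, f, getattr(cls, f))
        labels_arr = np.asarray(labels, dtype=object)
        if 0 < np.sum(labels_arr == SGA) < labels_arr.size:
            report.auroc = auroc_from_outputs(labels, outputs)
    return report


@dataclass
class CVResult:
    """k-fold cross-validation outcome: per-fold reports, fold assignment,
    and mean +/- SD aggregates of each numeric metric."""

    fold_reports: list
    fold_assignment: np.ndarray
    k: int
    seed: int

    def aggregate(self) -> pd.DataFrame:
        metrics = ("rmse", "r", "r2", "accuracy", "f1", "ppv", "npv", "auroc")
        rows = []
        for m in metrics:
            vals = np.array([getattr(rep, m) for rep in self.fold_reports],
                            dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            rows.append({"metric": m, "mean": float(vals.mean()),
                         "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                         "n_folds": int(vals.size)})
        return pd.DataFrame(rows).set_index("metric")

    def to_csv(self, path) -> None:
        rows = []
        for i, rep in enumerate(self.fold_reports):
            d = {"fold": i}
            for m in ("n", "rmse", "r", "r2", "accuracy", "f1", "ppv",
                      "npv", "auroc"):
                d[m] = getattr(rep, m)
            rows.append(d)
        pd.DataFrame(rows).to_csv(path, index=False)


def kfold_indices(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Seeded fold assignment: each row gets a fold id in [0, k); fold sizes
    differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows n={n}")
    rng = np.random.default_rng(seed)
    folds = np.tile(np.arange(k), int(np.ceil(n / k)))[:n]
    rng.shuffle(folds)
    return folds


def kfold_cv(X, t, k: int, h: int, config=None, seed: int = 0,
             labels=None, intervals=None,
             train_fn=None) -> CVResult:
    """k-fold cross-validation of the trainer.

    Each fold is held out exactly once; the network is trained on the other
    k-1 folds and evaluated on the held-out fold.  ``train_fn`` may override
    the default single-run Levenberg-Marquardt training (it receives
    X_train, t_train, h, config and must return NetworkParams).
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    folds = kfold_indices(len(t), k, seed)
    reports = []
    for fold in range(k):
        hold = folds == fold
        if train_fn is not None:
            params = train_fn(X[~hold], t[~hold], h, config)
        else:
            params, _ = nn.train_lm(X[~hold], t[~hold], h, config)
        out = nn.forward(X[hold], params)
        fold_labels = (np.asarray(labels, dtype=object)[hold]
                       if labels is not None else None)
        reports.append(evaluate(t[hold], out, fold_labels, intervals))
    return CVResult(fold_reports=reports, fold_assignment=folds, k=k, seed=seed)


def scatter_plot(actual, predicted, path, title="Actual vs predicted"):
    """Optional artifact: scatter of actual vs predicted with the fitted
    regression line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    r, r2, slope, intercept = regression_performance(actual, predicted)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(actual, predicted, s=18, alpha=0.7)
    xs = np.linspace(actual.min(), actual.max(), 50)
    ax.plot(xs, slope * xs + intercept, "r-",
            label=f"fit: y={slope:.3f}x+{intercept:.3f} (R²={r2:.3f})")
    ax.plot(xs, xs, "k--", lw=0.8, label="identity")
    ax.set_xlabel("actual (codified target)")
    ax.set_ylabel("predicted (network output)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
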