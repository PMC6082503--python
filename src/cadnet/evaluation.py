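"""Threshold selection, blinded-verification statistics and cohort comparisons.

The trained predictor emits a continuous score (a predicted modified Gensini
value); a fixed decision threshold, chosen on the validation split alone and
frozen before verification, converts it to a binary CAD call.  Performance on
the naive verification cohort is summarized by the confusion matrix,
sensitivity / specificity / NPV / PPV / AUC, and 95% bias-corrected and
accelerated (BCa) bootstrap confidence intervals from subject-level
resampling.

Table-1-style demographic comparisons use a pooled-variance two-sample
t-test (computable from printed mean / sd / n summaries) for continuous
variables and a Pearson chi-square test on the 2x2 counts for categorical
ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .elastic_net import ModelWeights
from .feature_reduction import ReductionResult
from .ga import Genome, rank_auc

__all__ = [
    "ConfusionMatrix",
    "TrainedModel",
    "PerformanceReport",
    "classify",
    "confusion_and_metrics",
    "select_threshold",
    "bootstrap_ci",
    "sensitivity_metric",
    "specificity_metric",
    "npv_metric",
    "ppv_metric",
    "auc_metric",
    "ttest_from_summary",
    "chi2_from_counts",
    "compare_demographics",
    "ContinuousSummary",
    "CategoricalCounts",
]


# --------------------------------------------------------------------------
# classification and confusion metrics

def classify(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Binary call: below the threshold is CAD negative; otherwise positive
    (a score exactly at the threshold is positive)."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return scores >= threshold


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, predictions: np.ndarray, labels: np.ndarray) -> "ConfusionMatrix":
        predictions = np.asarray(predictions, dtype=bool)
        labels = np.asarray(labels, dtype=bool)
        if predictions.shape != labels.shape:
            raise ValueError("predictions and labels lengths differ")
        return cls(
            tp=int(np.sum(predictions & labels)),
            fp=int(np.sum(predictions & ~labels)),
            tn=int(np.sum(~predictions & ~labels)),
            fn=int(np.sum(~predictions & labels)),
        )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_and_metrics(
    predictions: np.ndarray, labels: np.ndarray
) -> tuple[ConfusionMatrix, dict[str, float | None]]:
    """Standard diagnostic metrics; undefined ratios (zero denominator)
    are reported as ``None``, never coerced to 0."""
    cm = ConfusionMatrix.from_predictions(predictions, labels)
    metrics = {
        "sensitivity": _ratio(cm.tp, cm.tp + cm.fn),
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
        "npv": _ratio(cm.tn, cm.tn + cm.fn),
        "ppv": _ratio(cm.tp, cm.tp + cm.fp),
    }
    return cm, metrics


# --------------------------------------------------------------------------
# threshold selection on the validation split

def select_threshold(
    val_scores: np.ndarray,
    val_labels: np.ndarray,
    sens_floor: float = 0.90,
) -> tuple[float, dict]:
    """Choose the decision threshold from validation ROC operating points.

    Among operating points with sensitivity >= ``sens_floor`` (the safety
    constraint: a missed CAD-positive is the costly error), return the
    threshold maximizing specificity; ties break toward higher sensitivity,
    then the lower threshold.  If no point reaches the floor, the maximal-
    sensitivity point is returned with ``warning`` set.
    """
    scores = np.asarray(val_scores, dtype=float)
    labels = np.asarray(val_labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present in validation data")

    # candidate thresholds: each observed score (score >= t -> positive)
    # plus one above the maximum (the all-negative classifier)
    candidates = np.unique(scores)
    candidates = np.append(candidates, candidates[-1] + 1.0)

    best = None  # (spec, sens, -threshold)
    best_t = None
    best_stats = None
    for t in candidates:
        pred = scores >= t
        _, m = confusion_and_metrics(pred, labels)
        sens, spec = m["sensitivity"], m["specificity"]
        if sens is None or spec is None:  # cannot happen with both classes
            continue
        key = (spec, sens, -t)
        if sens >= sens_floor and (best is None or key > best):
            best, best_t = key, float(t)
            best_stats = {"sensitivity": sens, "specificity": spec}

    if best_t is not None:
        return best_t, {**best_stats, "warning": False}

    # floor unreachable: fall back to the maximal-sensitivity point
    best = None
    for t in candidates:
        pred = scores >= t
        _, m = confusion_and_metrics(pred, labels)
        key = (m["sensitivity"], m["specificity"], -t)
        if best is None or key > best:
            best, best_t = key, float(t)
            best_stats = {"sensitivity": m["sensitivity"], "specificity": m["specificity"]}
    return best_t, {**best_stats, "warning": True}


# --------------------------------------------------------------------------
# metric functions for bootstrapping (NaN signals an undefined resample)

def sensitivity_metric(predictions, labels):
    n_pos = np.sum(labels)
    return np.sum(predictions & labels) / n_pos if n_pos else np.nan


def specificity_metric(predictions, labels):
    n_neg = np.sum(~labels)
    return np.sum(~predictions & ~labels) / n_neg if n_neg else np.nan


def npv_metric(predictions, labels):
    n_predneg = np.sum(~predictions)
    return np.sum(~predictions & ~labels) / n_predneg if n_predneg else np.nan


def ppv_metric(predictions, labels):
    n_predpos = np.sum(predictions)
    return np.sum(predictions & labels) / n_predpos if n_predpos else np.nan


def auc_metric(scores, labels):
    try:
        return rank_auc(scores, labels)
    except ValueError:
        return np.nan


class DegenerateBootstrapError(RuntimeError):
    pass


def bootstrap_ci(
    metric,
    predictions: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """95% BCa bootstrap interval for ``metric(predictions, labels)``.

    Subjects are resampled with replacement; resamples where the metric is
    undefined (NaN, e.g. a resample with no positives) are skipped and
    counted, and more than 50% degenerate resamples is an error.  The bias
    correction uses the fraction of bootstrap replicates below the point
    estimate (ties counted half) and the acceleration comes from a
    jackknife.  Deterministic for a given seed.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    n = labels.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    theta_hat = metric(predictions, labels)
    if np.isnan(theta_hat):
        raise ValueError("metric undefined on the full sample")

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot[b] = metric(predictions[idx], labels[idx])
    valid = boot[~np.isnan(boot)]
    n_degenerate = n_boot - valid.size
    if n_degenerate > 0.5 * n_boot:
        raise DegenerateBootstrapError(
            f"{n_degenerate}/{n_boot} bootstrap resamples had an undefined "
            "metric; the cohort is too small for this interval"
        )
    if np.all(valid == valid[0]):
        return float(valid[0]), float(valid[0])

    # bias correction
    prop = (np.sum(valid < theta_hat) + 0.5 * np.sum(valid == theta_hat)) / valid.size
    prop = min(max(prop, 1e-12), 1 - 1e-12)
    z0 = stats.norm.ppf(prop)

    # acceleration from the jackknife
    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        jack[i] = metric(predictions[mask], labels[mask])
        mask[i] = True
    jack = jack[~np.isnan(jack)]
    jmean = jack.mean()
    num = np.sum((jmean - jack) ** 3)
    den = 6.0 * np.sum((jmean - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0

    alpha = (1.0 - level) / 2.0
    lo_hi = []
    for q in (alpha, 1.0 - alpha):
        z = z0 + stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + z / (1.0 - a * z))
        lo_hi.append(float(np.quantile(valid, adj)))
    return lo_hi[0], lo_hi[1]


# --------------------------------------------------------------------------
# the frozen predictor and its verification report

@dataclass
class TrainedModel:
    """The frozen development-phase output: retained columns, linear weights,
    the winning hyperparameter genome and the fixed decision threshold."""

    reduction: ReductionResult
    weights: ModelWeights
    genome: Genome
    threshold: float
    standardize: bool = True
    feature_hash: str | None = None
    metadata: dict = field(default_factory=dict)

    def scores(self, X: np.ndarray) -> np.ndarray:
        from .elastic_net import predict

        return predict(self.weights, np.asarray(X, dtype=float)[:, self.weights.feature_index])

    def classify(self, X: np.ndarray) -> np.ndarray:
        return classify(self.scores(X), self.threshold)

    def to_dict(self) -> dict:
        return {
            "reduction": self.reduction.to_dict(),
            "weights": self.weights.to_dict(),
            "genome": self.genome.to_dict(),
            "threshold": float(self.threshold),
            "standardize": self.standardize,
            "feature_hash": self.feature_hash,
            "metadata": self.metadata,
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        return cls(
            reduction=ReductionResult.from_dict(d["reduction"]),
            weights=ModelWeights.from_dict(d["weights"]),
            genome=Genome(**d["genome"]),
            threshold=float(d["threshold"]),
            standardize=bool(d.get("standardize", True)),
            feature_hash=d.get("feature_hash"),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


_METRICS = {
    "sensitivity": sensitivity_metric,
    "specificity": specificity_metric,
    "npv": npv_metric,
    "ppv": ppv_metric,
}


@dataclass
class PerformanceReport:
    confusion: ConfusionMatrix
    metrics: dict
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "confusion": {
                "tp": self.confusion.tp, "fp": self.confusion.fp,
                "tn": self.confusion.tn, "fn": self.confusion.fn,
            },
            "metrics": self.metrics,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }

    def to_text(self) -> str:
        lines = [
            f"n = {self.confusion.total}   "
            f"TP={self.confusion.tp} FP={self.confusion.fp} "
            f"TN={self.confusion.tn} FN={self.confusion.fn}"
        ]
        for name, m in self.metrics.items():
            if m["value"] is None:
                lines.append(f"{name:>12s}: undefined")
            elif name == "auc":
                lines.append(
                    f"{name:>12s}: {m['value']:.2f} "
                    f"(95% CI: {m['ci_low']:.2f}-{m['ci_high']:.2f})"
                )
            else:
                lines.append(
                    f"{name:>12s}: {100 * m['value']:.0f}% "
                    f"(95% CI: {100 * m['ci_low']:.0f}%-{100 * m['ci_high']:.0f}%)"
                )
        return "\n".join(lines)


def performance_report(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    n_boot: int = 2000,
    seed: int = 0,
) -> PerformanceReport:
    """Single-pass blinded evaluation: classify at the frozen threshold,
    tabulate the confusion matrix, and attach BCa intervals to every metric."""
    labels = np.asarray(labels, dtype=bool)
    predictions = classify(scores, threshold)
    cm, points = confusion_and_metrics(predictions, labels)
    report_metrics = {}
    for i, (name, fn) in enumerate(_METRICS.items()):
        value = points[name]
        if value is None:
            report_metrics[name] = {"value": None, "ci_low": None, "ci_high": None}
            continue
        lo, hi = bootstrap_ci(fn, predictions, labels, n_boot=n_boot, seed=seed + i)
        report_metrics[name] = {"value": value, "ci_low": lo, "ci_high": hi}
    auc = rank_auc(scores, labels)
    lo, hi = bootstrap_ci(
        auc_metric, np.asarray(scores, float), labels, n_boot=n_boot, seed=seed + 10
    )
    report_metrics["auc"] = {"value": auc, "ci_low": lo, "ci_high": hi}
    return PerformanceReport(confusion=cm, metrics=report_metrics, n_boot=n_boot, seed=seed)


# --------------------------------------------------------------------------
# Table-1-style demographics comparison

@dataclass(frozen=True)
class ContinuousSummary:
    mean: float
    sd: float
    n: int

    @classmethod
    def from_raw(cls, x: np.ndarray) -> "ContinuousSummary":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


@dataclass(frozen=True)
class CategoricalCounts:
    count: int
    n: int

    @classmethod
    def from_raw(cls, x: np.ndarray) -> "CategoricalCounts":
        x = np.asarray(x, dtype=bool)
        return cls(count=int(x.sum()), n=int(x.size))


def ttest_from_summary(
    a: ContinuousSummary, b: ContinuousSummary
) -> tuple[float, int, float]:
    """Two-sided pooled-variance (Student) two-sample t-test from summaries."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    t = 0.0 if se == 0 else (a.mean - b.mean) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(min(p, 1.0))


def chi2_from_counts(a: CategoricalCounts, b: CategoricalCounts) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on the 2x2 table."""
    table = np.array([[a.count, a.n - a.count], [b.count, b.n - b.count]])
    if np.any(table.sum(axis=0) == 0):
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def compare_demographics(group_a: dict, group_b: dict) -> pd.DataFrame:
    """Per-variable p-values between two cohorts.

    Each group maps a variable name to a :class:`ContinuousSummary`, a
    :class:`CategoricalCounts`, or a raw array (1-D float -> continuous,
    bool -> categorical).  Returns a table with the test used, the summary
    of each group, p at full precision and p rounded to 2 decimals.
    """

    def coerce(v):
        if isinstance(v, (ContinuousSummary, CategoricalCounts)):
            return v
        arr = np.asarray(v)
        if arr.dtype == bool:
            return CategoricalCounts.from_raw(arr)
        return ContinuousSummary.from_raw(arr)

    rows = []
    for name in group_a:
        if name not in group_b:
            raise KeyError(f"variable {name!r} missing from second group")
        a, b = coerce(group_a[name]), coerce(group_b[name])
        if type(a) is not type(b):
            raise TypeError(f"variable {name!r} has mixed types across groups")
        if isinstance(a, ContinuousSummary):
            _, _, p = ttest_from_summary(a, b)
            summ_a = f"{a.mean:.1f} ± {a.sd:.1f}"
            summ_b = f"{b.mean:.1f} ± {b.sd:.1f}"
            test = "pooled t"
        else:
            _, p = chi2_from_counts(a, b)
            summ_a = f"{100 * a.count / a.n:.1f}%"
            summ_b = f"{100 * b.count / b.n:.1f}%"
            test = "chi-square"
        rows.append(
            {
                "variable": name,
                "group_a": summ_a,
                "group_b": summ_b,
                "test": test,
                "p_value": p,
                "p_display": round(p, 2),
            }
        )
    return pd.DataFrame(rows)
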