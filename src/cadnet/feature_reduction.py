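"""Correlation-based feature filtering.

Before model fitting, features that are nearly collinear with an
already-retained feature are dropped: a greedy scan in ascending column
order keeps a feature only if its absolute Pearson correlation with every
previously kept feature is at or below the threshold.  The scan is
deterministic, and of any correlated pair the smaller original index
survives.  Correlations are measured on training rows only so the
verification split never influences column selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReductionResult", "reduce_by_correlation", "abs_correlation_matrix"]


@dataclass
class ReductionResult:
    kept_indices: np.ndarray
    dropped_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    zero_variance: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def to_dict(self) -> dict:
        return {
            "kept_indices": [int(i) for i in self.kept_indices],
            "dropped_pairs": [
                [int(d), int(k), float(r)] for d, k, r in self.dropped_pairs
            ],
            "zero_variance": [int(i) for i in self.zero_variance],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReductionResult":
        return cls(
            kept_indices=np.asarray(d["kept_indices"], dtype=int),
            dropped_pairs=[(int(a), int(b), float(r)) for a, b, r in d["dropped_pairs"]],
            zero_variance=np.asarray(d.get("zero_variance", []), dtype=int),
        )


def abs_correlation_matrix(X: np.ndarray) -> np.ndarray:
    """|Pearson r| between all column pairs; NaN where a column has zero variance."""
    X = np.asarray(X, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    return np.abs(corr)


def reduce_by_correlation(
    X: np.ndarray,
    threshold: float,
    *,
    corr: np.ndarray | None = None,
) -> ReductionResult:
    """Greedy correlation filter.

    Parameters
    ----------
    X : array of shape (n_subjects, n_features)
        Training-rows feature matrix (>= 2 rows).
    threshold : float in (0, 1]
        A feature is dropped when its |r| with a kept feature *exceeds*
        this value.
    corr : array, optional
        Precomputed ``abs_correlation_matrix(X)``; passing it lets a
        hyperparameter search re-filter at many thresholds cheaply.

    Zero-variance columns have undefined correlation; they are never
    dropped for correlation but are flagged in ``zero_variance``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 subjects")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if corr is None:
        corr = abs_correlation_matrix(X)
    p = X.shape[1]
    if corr.shape != (p, p):
        raise ValueError("corr shape does not match X")

    zero_var = np.where(np.isnan(np.diag(corr)) | (X.std(axis=0) == 0.0))[0]
    kept: list[int] = []
    dropped: list[tuple[int, int, float]] = []
    for j in range(p):
        if kept:
            rs = corr[j, kept]
            hits = np.where(~np.isnan(rs) & (rs > threshold))[0]
        else:
            hits = np.array([], dtype=int)
        if hits.size:
            k = kept[int(hits[0])]
            dropped.append((j, k, float(corr[j, k])))
        else:
            kept.append(j)
    return ReductionResult(
        kept_indices=np.asarray(kept, dtype=int),
        dropped_pairs=dropped,
        zero_variance=zero_var,
    )
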