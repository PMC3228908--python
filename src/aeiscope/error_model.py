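"""Measurement-error models for log2 AEI ratios.

Genomic DNA from a marker-heterozygous individual carries the two mSNP
alleles exactly 1:1, so after per-gene bias correction any deviation of a
gDNA log2AEI ratio from 0 is experimental error.  Two estimators are
provided:

1. distribution statistics of the normalized gDNA ratios (mean, SD, SEM and
   the central 95% interval, read as empirical percentiles), and
2. the "rectangle" method: the confidence-level quantile of |log2 ratio|
   among measurements backed by more than X sequencing reads, swept over a
   grid of X to give an error bound E(X) that shrinks with read depth.

The theoretical floor is the binomial sampling envelope: exact quantiles of
Binomial(N, 1/2) mapped to the log2-ratio scale.  Real data sit above this
floor because PCR amplification noise is extra-binomial.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "GdnaErrorStats",
    "ErrorCurve",
    "EmpiricalErrorCurve",
    "DEFAULT_READ_GRID",
    "gdna_distribution_stats",
    "binomial_envelope",
    "binomial_halfwidth_asymptotic",
    "rectangle_error_estimate",
    "build_error_curve",
]

#: read-count thresholds swept by default (includes the quoted anchor depths)
DEFAULT_READ_GRID = (500, 1_000, 2_000, 5_000, 10_000, 13_500, 24_300, 50_000)


@dataclass(frozen=True)
class GdnaErrorStats:
    """Distribution statistics of normalized gDNA AEI ratios."""

    n: int
    mean: float
    sd: float
    sem: float
    confidence: float
    interval_linear: tuple[float, float]
    interval_log2: tuple[float, float]


def gdna_distribution_stats(ratios, confidence: float = 0.95) -> GdnaErrorStats:
    """Mean/SD/SEM and central percentile interval of gDNA linear ratios.

    The interval is the empirical (1-confidence)/2 .. (1+confidence)/2
    percentile range, reported on both the linear and log2 scales.  Fewer
    than 20 ratios triggers a warning (the interval is then poorly resolved).
    """
    r = np.asarray(ratios, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 ratios")
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    if r.size < 20:
        warnings.warn(f"only {r.size} gDNA ratios; interval estimate is unstable")
    lo, hi = np.percentile(r, [(1 - confidence) / 2 * 100, (1 + confidence) / 2 * 100])
    return GdnaErrorStats(
        n=int(r.size),
        mean=float(r.mean()),
        sd=float(r.std(ddof=1)),
        sem=float(r.std(ddof=1) / math.sqrt(r.size)),
        confidence=confidence,
        interval_linear=(float(lo), float(hi)),
        interval_log2=(float(np.log2(lo)), float(np.log2(hi))),
    )


def binomial_envelope(
    n_reads: int, p: float = 0.5, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact binomial sampling envelope for the log2 allele ratio.

    For X ~ Binomial(N, p) the bounds are log2(q/(N-q)) at the lower and upper
    (1±confidence)/2 quantiles; quantiles of 0 or N are truncated to the
    nearest interior count so the ratio is defined.
    """
    if n_reads < 10:
        raise ValueError("n_reads must be >= 10")
    alpha = 1.0 - confidence
    q_lo = stats.binom.ppf(alpha / 2, n_reads, p)
    q_hi = stats.binom.ppf(1 - alpha / 2, n_reads, p)
    q_lo = float(np.clip(q_lo, 1, n_reads - 1))
    q_hi = float(np.clip(q_hi, 1, n_reads - 1))
    return (
        math.log2(q_lo / (n_reads - q_lo)),
        math.log2(q_hi / (n_reads - q_hi)),
    )


def binomial_halfwidth_asymptotic(n_reads: int, confidence: float = 0.95) -> float:
    """Delta-method large-N limit of the envelope half-width.

    log2(p_hat/(1-p_hat)) at p=1/2 has derivative 4/ln2 and sd(p_hat) =
    1/(2*sqrt(N)), giving half-width z * 2 / (ln2 * sqrt(N)).
    """
    z = stats.norm.ppf((1 + confidence) / 2)
    return float(2.0 * z / (math.log(2.0) * math.sqrt(n_reads)))


def rectangle_error_estimate(
    log2_ratios,
    reads,
    threshold: float,
    confidence: float = 0.95,
    min_points: int = 20,
) -> float:
    """Error bound E at a read-count threshold X by the rectangle method.

    E is the smallest half-height such that the rectangle [X, inf) x [-E, E]
    contains at least the confidence-level fraction of the (reads, log2 ratio)
    points with reads > X — i.e. the ceil(confidence * n)-th order statistic
    of |log2 ratio| among those points.
    """
    l2 = np.asarray(log2_ratios, dtype=float)
    rd = np.asarray(reads, dtype=float)
    if l2.shape != rd.shape:
        raise ValueError("log2_ratios and reads must have equal length")
    mask = rd > threshold
    n = int(mask.sum())
    if n < min_points:
        raise ValueError(
            f"only {n} points with reads > {threshold}; need >= {min_points}"
        )
    a = np.abs(l2[mask])
    k = math.ceil(confidence * n)
    return float(np.partition(a, k - 1)[k - 1])


@dataclass(frozen=True)
class ErrorCurve:
    """Non-increasing error bound E as a step function of read number.

    ``points`` is an ascending-X tuple of (read_threshold, E).  Lookup uses
    the bound for the largest threshold the read count exceeds; read counts
    at or below the smallest threshold fall back to the largest bound with a
    warning.
    """

    confidence: float
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        xs = [p[0] for p in self.points]
        es = [p[1] for p in self.points]
        if not self.points:
            raise ValueError("error curve needs at least one point")
        if sorted(xs) != xs:
            raise ValueError("points must be sorted by read threshold")
        if any(e <= 0 for e in es):
            raise ValueError("error bounds must be positive")
        if any(e1 < e2 for e1, e2 in zip(es, es[1:])):
            raise ValueError("error bounds must be non-increasing in reads")

    def lookup(self, reads):
        xs = np.array([p[0] for p in self.points])
        es = np.array([p[1] for p in self.points])
        r = np.atleast_1d(np.asarray(reads, dtype=float))
        idx = np.searchsorted(xs, r, side="left") - 1
        if np.any(idx < 0):
            warnings.warn(
                "read count(s) at or below the smallest curve threshold; "
                "using the largest error bound"
            )
        out = es[np.clip(idx, 0, len(es) - 1)]
        return out if out.size > 1 else float(out[0])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"confidence": self.confidence, "points": [list(p) for p in self.points]},
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "ErrorCurve":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            confidence=float(d["confidence"]),
            points=tuple((float(x), float(e)) for x, e in d["points"]),
        )


def build_error_curve(
    log2_ratios,
    reads,
    x_grid=DEFAULT_READ_GRID,
    confidence: float = 0.95,
    min_points: int = 20,
) -> ErrorCurve:
    """Sweep the rectangle estimator over a threshold grid.

    Grid points with fewer than ``min_points`` supporting measurements are
    omitted.  Sampling noise can invert adjacent estimates, so the curve is
    flattened to be non-increasing by raising each bound to the maximum of
    all bounds at higher thresholds (conservative isotonic flattening).
    """
    xs, es = [], []
    for x in sorted(x_grid):
        try:
            es.append(rectangle_error_estimate(log2_ratios, reads, x, confidence, min_points))
            xs.append(float(x))
        except ValueError:
            continue
    if not xs:
        raise ValueError("no grid point has enough supporting measurements")
    es = np.maximum.accumulate(np.asarray(es)[::-1])[::-1]
    return ErrorCurve(confidence=confidence, points=tuple(zip(xs, es.tolist())))


class EmpiricalErrorCurve(BaseEstimator):
    """Scikit-learn style wrapper around :func:`build_error_curve`.

    ``fit(X)`` takes a 2-column array (log2 ratio, reads); ``predict(reads)``
    returns the depth-specific error bound.  Fitted attribute: ``curve_``.
    """

    def __init__(self, x_grid=DEFAULT_READ_GRID, confidence: float = 0.95, min_points: int = 20):
        self.x_grid = x_grid
        self.confidence = confidence
        self.min_points = min_points

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be a 2-column array: (log2_ratio, reads)")
        self.curve_ = build_error_curve(
            X[:, 0], X[:, 1], self.x_grid, self.confidence, self.min_points
        )
        return self

    def predict(self, reads):
        if not hasattr(self, "curve_"):
            raise AttributeError("fit must be called first")
        return self.curve_.lookup(reads)
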