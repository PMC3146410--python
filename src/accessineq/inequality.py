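"""Weighted inequality measures for access-time samples.

The central statistic is the relative mean difference

    D = ( sum_i sum_j w_i w_j |x_i - x_j| / W^2 ) / xbar,   W = sum_i w_i,

the mean absolute pairwise difference divided by the weighted mean.  With
the W^2 denominator D equals exactly twice the Gini coefficient, which is
the normative reading adopted here.  D is dimensionless, scale invariant
and lies in [0, 2); it is computed by an O(n log n) sorted formula that is
algebraically identical to the O(n^2) double sum.

Weights are population counts: a block with weight w behaves exactly like
w children sharing the block's access time, so block-level input
reproduces the per-child computation.

Robin Hood, Theil and Atkinson indices are provided as alternative
dispersion measures; any of them can stand in for D in the
standardization, though in practice they rank regions almost identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError, ZeroMeanError


@dataclass
class WeightedSample:
    """Nonnegative values with nonnegative weights (population counts)."""

    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.values.shape != self.weights.shape:
            raise InputError("values and weights must have the same length")
        if self.values.size == 0:
            raise InputError("sample is empty")
        if not np.all(np.isfinite(self.values)) or not np.all(
            np.isfinite(self.weights)
        ):
            raise InputError("sample contains non-finite values or weights")
        if np.any(self.values < 0):
            raise InputError("access values must be nonnegative")
        if np.any(self.weights < 0):
            raise InputError("weights must be nonnegative")
        if not self.total_weight > 0:
            raise InputError("total weight must be positive")

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    @property
    def n_effective(self) -> float:
        """Effective sample size: the total population behind the sample."""
        return self.total_weight

    @property
    def mean(self) -> float:
        return float(np.average(self.values, weights=self.weights))

    def sorted(self) -> tuple[np.ndarray, np.ndarray]:
        order = np.argsort(self.values, kind="stable")
        return self.values[order], self.weights[order]


def _require_positive_mean(sample: WeightedSample) -> float:
    xbar = sample.mean
    if not xbar > 0:
        raise ZeroMeanError(
            "weighted mean access value is zero; the relative mean "
            "difference is undefined"
        )
    return xbar


def relative_mean_difference(sample: WeightedSample) -> float:
    """Relative mean difference D of a weighted sample.

    Sorted O(n log n) evaluation of the pairwise double sum: every pair
    straddling the gap between sorted positions k and k+1 contributes
    that gap once, so with x ascending and C_k the cumulative weight,

        sum_{i,j} w_i w_j |x_i - x_j|
          = 2 * sum_k (x_{k+1} - x_k) * C_k * (W - C_k).

    Formulating the sum over adjacent gaps (rather than products of
    values with cumulative weights) makes D exactly zero for tied
    values, so perfectly equitable samples report D = 0.0, not rounding
    noise.
    """
    xbar = _require_positive_mean(sample)
    x, w = sample.sorted()
    total = sample.total_weight
    cw = np.cumsum(w)[:-1]
    gaps = np.diff(x)
    pair_sum = 2.0 * float(np.sum(gaps * cw * (total - cw)))
    return pair_sum / (total * total) / xbar


def gini(sample: WeightedSample) -> float:
    """Gini coefficient via the weighted Lorenz-curve trapezoid rule.

    Independent of :func:`relative_mean_difference`; for discrete weighted
    data the two satisfy D = 2 G exactly.
    """
    _require_positive_mean(sample)
    x, w = sample.sorted()
    p = np.concatenate(([0.0], np.cumsum(w))) / sample.total_weight
    wx = w * x
    L = np.concatenate(([0.0], np.cumsum(wx))) / float(wx.sum())
    # area under the Lorenz polyline by trapezoids
    auc = float(np.sum(np.diff(p) * (L[1:] + L[:-1])) / 2.0)
    return 1.0 - 2.0 * auc


@dataclass(frozen=True)
class InequalityResult:
    """D, Gini, mean and effective n of one weighted access sample."""

    D: float
    gini: float
    mean: float
    n_effective: float


def inequality_summary(sample: WeightedSample) -> InequalityResult:
    return InequalityResult(
        D=relative_mean_difference(sample),
        gini=gini(sample),
        mean=sample.mean,
        n_effective=sample.n_effective,
    )


def robin_hood(sample: WeightedSample) -> float:
    """Robin Hood (Pietra) index: maximum vertical Lorenz-curve gap.

    The share of the total that would have to be transferred from
    above-mean to below-mean units to equalize the distribution.
    """
    _require_positive_mean(sample)
    x, w = sample.sorted()
    p = np.cumsum(w) / sample.total_weight
    wx = w * x
    L = np.cumsum(wx) / float(wx.sum())
    return float(np.max(p - L))


def theil(sample: WeightedSample) -> float:
    """Theil's T entropy measure, with the 0*log(0) = 0 convention."""
    xbar = _require_positive_mean(sample)
    r = sample.values / xbar
    fw = sample.weights / sample.total_weight
    terms = np.where(r > 0, r * np.log(np.where(r > 0, r, 1.0)), 0.0)
    return float(np.sum(fw * terms))


def atkinson(sample: WeightedSample, epsilon: float = 0.5) -> float:
    """Atkinson index with inequality-aversion parameter epsilon > 0."""
    if not (epsilon > 0) or not math.isfinite(epsilon):
        raise InputError(f"Atkinson epsilon must be positive, got {epsilon!r}")
    xbar = _require_positive_mean(sample)
    fw = sample.weights / sample.total_weight
    x = sample.values
    if epsilon == 1.0:
        if np.any((x == 0) & (fw > 0)):
            return 1.0
        ede = math.exp(float(np.sum(fw * np.log(np.where(x > 0, x, 1.0)))))
    else:
        ede = float(np.sum(fw * np.power(x, 1.0 - epsilon))) ** (1.0 / (1.0 - epsilon))
    return 1.0 - ede / xbar


def alt_measures(
    sample: WeightedSample,
    which: tuple[str, ...] = ("robin_hood", "theil", "atkinson"),
    epsilon: float = 0.5,
) -> dict[str, float]:
    """Alternative dispersion measures keyed by name.

    Any of these can replace D inside the CSR standardization; they are
    reported alongside D, which remains the default for the ratio.
    """
    funcs = {
        "robin_hood": robin_hood,
        "theil": theil,
        "atkinson": lambda s: atkinson(s, epsilon),
    }
    out = {}
    for name in which:
        if name not in funcs:
            raise InputError(f"unknown inequality measure {name!r}")
        out[name] = funcs[name](sample)
    return out
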