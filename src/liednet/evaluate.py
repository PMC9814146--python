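"""Model-quality metrics and error propagation.

Covers the evaluation toolkit of the retrieval pipeline: mean absolute error
between predicted and true label vectors, the Pearson correlation between a
measured map and the map recomputed from the retrieved structure (the
self-consistency check), a bootstrap confidence interval for that
correlation, propagation of Poisson counting error through the network into
the structure labels, and the brute-force cost-scaling estimate that
motivates learning-based retrieval in the first place.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .prep import CountsMap, DiffMap, counts_to_map, difference_map, normalize_map, poisson_extrema

__all__ = [
    "CorrelationReport", "mae", "pearson", "bootstrap_ci",
    "self_consistency", "error_budget", "scaling_estimate",
]


def mae(predicted, true) -> float:
    """Mean absolute error over all samples and label components."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    return float(np.mean(np.abs(p - t)))


def pearson(x, y) -> float:
    """Product-moment correlation of two flattened arrays."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("inputs must have non-zero variance")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class CorrelationReport:
    """Pearson correlation with an OLS fit and a bootstrap percentile CI."""

    pearson_r: float
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    level: float
    n_resamples: int
    n_degenerate: int
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def bootstrap_ci(x, y, level: float = 0.90, n_resamples: int = 1000,
                 seed: int = 0) -> CorrelationReport:
    """Percentile bootstrap confidence interval for the Pearson correlation.

    Pairs are resampled with replacement ``n_resamples`` times (seeded);
    degenerate resamples with zero variance are skipped and counted.  Also
    reports the ordinary least-squares line through the scatter.
    """
    if n_resamples < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    r = pearson(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    rng = np.random.default_rng(seed)
    rs, skipped = [], 0
    n = x.size
    for _ in range(n_resamples):
        idx = rng.integers(0, n, n)
        xs, ys = x[idx], y[idx]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            skipped += 1
            continue
        rs.append(pearson(xs, ys))
    lo, hi = np.percentile(rs, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return CorrelationReport(r, float(slope), float(intercept),
                             float(lo), float(hi), level, n_resamples,
                             skipped, seed)


def self_consistency(measured_values: np.ndarray, predicted_values: np.ndarray) -> float:
    """Pearson r between two normalized full maps, flattened to 1D.

    The standard check that a retrieved structure actually explains the
    measurement: correlate the normalized measured map against the normalized
    map recomputed from the predicted structure.
    """
    return pearson(normalize_map(measured_values).ravel(),
                   normalize_map(predicted_values).ravel())


def error_budget(results, nominal: DiffMap, counts: CountsMap,
                 reference_map) -> np.ndarray:
    """Per-dimension experimental error from Poisson counting statistics.

    The +-sqrt(n) extremal maps of ``counts`` are pushed through the same
    differencing (against ``reference_map``) and prediction as the nominal
    input; the experimental error of each label dimension is the largest
    absolute deviation of an extremal prediction from the nominal one.
    ``results`` is anything with a ``predict`` method (a fitted results
    object); for an ensemble, pass the ensemble-mean predictor.
    """
    if counts.grid != nominal.grid:
        raise ValueError("counts map and nominal input are on different grids")
    lower, upper = poisson_extrema(counts)
    p_nom = np.asarray(results.predict(nominal), dtype=float)
    deviations = []
    for extremum in (lower, upper):
        dm = difference_map(extremum, reference_map)
        deviations.append(np.abs(np.asarray(results.predict(dm), dtype=float) - p_nom))
    return np.maximum(*deviations)


def scaling_estimate(n_steps: int, n_atoms: int, minutes_per_map: float
                     ) -> tuple[int, float]:
    """Brute-force database cost: ``n * 3**N`` configurations and total hours.

    Exhaustive retrieval must precompute every configuration on an n-step
    grid over all 3N coordinates, so the map count scales as n x 3^N; at
    ``minutes_per_map`` per map this is the total compute in hours — the
    scaling that makes exhaustive retrieval of large molecules intractable.
    """
    if n_steps < 1 or n_atoms < 1:
        raise ValueError("n_steps and n_atoms must be >= 1")
    if minutes_per_map <= 0:
        raise ValueError("minutes_per_map must be positive")
    count = n_steps * 3 ** n_atoms
    return count, count * minutes_per_map / 60.0
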