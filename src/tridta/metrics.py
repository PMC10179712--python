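"""Regression metrics for binding-affinity prediction.

Four metrics are reported throughout: mean squared error, concordance
index (the fraction of strictly ordered true pairs whose predictions
preserve the order, ties scoring one half), the Pearson correlation
coefficient, and rm^2 = r^2 (1 - sqrt(r^2 - r0^2)), where r^2 is the
squared correlation with intercept and r0^2 the coefficient of
determination of the least-squares fit of y on p through the origin.
Pairs tied in the true affinity contribute neither to the concordance
numerator nor to its normalizer.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["mse", "concordance_index", "pearson", "rm2", "evaluate_all"]


class MetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


def _check(y, p, min_n: int = 1):
    y = np.asarray(y, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if y.shape != p.shape:
        raise MetricError(f"length mismatch: {y.shape} vs {p.shape}")
    if y.size < min_n:
        raise MetricError(f"need at least {min_n} observations")
    if not (np.isfinite(y).all() and np.isfinite(p).all()):
        raise MetricError("inputs must be finite")
    return y, p


def mse(y, p) -> float:
    """Mean squared error (1/n) sum (y_i - p_i)^2."""
    y, p = _check(y, p)
    return float(np.mean((y - p) ** 2))


def concordance_index(y, p) -> float:
    """Concordance index over strictly ordered true pairs.

    For every pair with y_i > y_j the prediction difference scores 1 if
    positive, 0.5 if zero, 0 if negative; the total is divided by the
    number of such pairs.
    """
    y, p = _check(y, p, min_n=2)
    comparable = (y[:, None] - y[None, :]) > 0        # y_i > y_j
    if not comparable.any():
        raise MetricError("concordance index undefined: no pair with "
                          "strictly ordered true affinities")
    d = p[:, None] - p[None, :]
    h = (d > 0) + 0.5 * (d == 0)
    return float(h[comparable].sum() / comparable.sum())


def pearson(y, p) -> float:
    """Pearson correlation cov(p, y) / (sigma(p) sigma(y))."""
    y, p = _check(y, p, min_n=2)
    sy, sp = y.std(), p.std()
    if sy == 0.0 or sp == 0.0:
        raise MetricError("Pearson undefined for a constant vector")
    return float(((y - y.mean()) * (p - p.mean())).mean() / (sy * sp))


def rm2(y, p) -> float:
    """External-validity metric r^2 (1 - sqrt(r^2 - r0^2)).

    r0^2 is computed from the through-origin least-squares slope
    k = sum(y p) / sum(p^2) as 1 - sum((y - k p)^2) / sum((y - mean y)^2).
    A slightly negative radicand (numerical noise) is clamped to zero
    with a warning.
    """
    y, p = _check(y, p, min_n=2)
    r = pearson(y, p)
    r2 = r * r
    denom_p = float((p ** 2).sum())
    if denom_p == 0.0:
        raise MetricError("rm2 undefined for all-zero predictions")
    k = float((y * p).sum()) / denom_p
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise MetricError("rm2 undefined for constant true values")
    r02 = 1.0 - float(((y - k * p) ** 2).sum()) / ss_tot
    radicand = r2 - r02
    if radicand < 0.0:
        if radicand < -1e-9:
            warnings.warn(
                f"rm2 radicand r^2 - r0^2 = {radicand:.3g} < 0; clamping "
                "to 0", RuntimeWarning, stacklevel=2)
        radicand = 0.0
    return float(r2 * (1.0 - np.sqrt(radicand)))


def evaluate_all(y, p) -> dict:
    """All four metrics as a JSON-ready dict."""
    return {
        "mse": mse(y, p),
        "ci": concordance_index(y, p),
        "pearson": pearson(y, p),
        "rm2": rm2(y, p),
    }
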