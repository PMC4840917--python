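"""Storey q-values for per-protein p-value families.

The q-value of a test is the smallest false-discovery rate at which it would
be called significant:

    q_(i) = min_{t >= p_(i)}  pi0 * m * t / #{p <= t},

computed as a cumulative minimum over the sorted p-values. pi0, the
proportion of true nulls, is estimated from the flat right tail of the
p-value histogram: pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) over a
grid of lambda values, smoothed with a natural cubic smoothing spline at
3 effective degrees of freedom and read off at the largest lambda (the
"smoother" convention). With pi0 fixed at 1 the procedure is exactly
Benjamini–Hochberg.

Each analysis family (PIVKA-II association; deficiency-group difference) is
corrected separately, never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QValueResult", "storey_qvalues", "estimate_pi0",
           "threshold_report"]

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


def _smoothing_spline(x: np.ndarray, y: np.ndarray,
                      df_target: float = 3.0) -> np.ndarray:
    """Natural cubic smoothing spline fit with a target effective df.

    Standard Reinsch/Green–Silverman construction: fitted values are
    (I + a*K)^-1 y with K = Q R^-1 Q' from the second-difference basis; the
    penalty a is solved by bisection so that trace((I + a*K)^-1), the
    effective degrees of freedom, equals ``df_target``. Equivalent to R's
    smooth.spline(x, y, df = df_target) at the design points.
    """
    n = len(x)
    if n < 4:
        return y.copy()
    h = np.diff(x)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        Q[j - 1, j - 1] = 1.0 / h[j - 1]
        Q[j, j - 1] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, j - 1] = 1.0 / h[j]
        R[j - 1, j - 1] = (h[j - 1] + h[j]) / 3.0
        if j < n - 2:
            R[j - 1, j] = R[j, j - 1] = h[j] / 6.0
    K = Q @ np.linalg.solve(R, Q.T)
    eye = np.eye(n)

    def smoother(log10_a: float) -> np.ndarray:
        return np.linalg.inv(eye + (10.0 ** log10_a) * K)

    lo, hi = -14.0, 14.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if np.trace(smoother(mid)) > df_target:
            lo = mid
        else:
            hi = mid
    return smoother(0.5 * (lo + hi)) @ y


@dataclass
class QValueResult:
    pi0_hat: float
    q_values: np.ndarray
    lambda_grid: np.ndarray
    pi0_method: str

    def __post_init__(self) -> None:
        if not (0.0 < self.pi0_hat <= 1.0):
            raise ValueError("pi0 must lie in (0, 1]")


def estimate_pi0(p_values: np.ndarray, lambda_grid=DEFAULT_LAMBDA_GRID,
                 method: str = "smoother") -> float:
    """Estimate the null proportion pi0.

    method "smoother": natural cubic smoothing spline (3 effective df) of
    pi0(lambda) over the grid, evaluated at the largest lambda — the
    conventional default. method "fixed": pi0(lambda) at the single supplied
    grid value (median of grid if several). method "one": pi0 = 1
    (Benjamini–Hochberg behaviour).
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if method == "one":
        return 1.0
    lam = np.atleast_1d(np.asarray(lambda_grid, dtype=float))
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if method == "fixed":
        pi0 = pi0_lam[len(lam) // 2]
    elif method == "smoother":
        pi0 = float(_smoothing_spline(lam, pi0_lam)[-1])
    else:
        raise ValueError(f"unknown pi0 method {method!r}")
    # guard against degenerate estimates on small or signal-rich families
    return float(min(max(pi0, 1.0 / m if m else 1.0), 1.0))


def storey_qvalues(p_values, lambda_grid=DEFAULT_LAMBDA_GRID,
                   pi0_method: str = "smoother",
                   pi0: float | None = None) -> QValueResult:
    """Compute q-values for a family of p-values.

    ``pi0`` overrides estimation when given (``pi0 = 1`` reproduces BH
    adjusted p-values exactly).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if pi0 is None:
        pi0 = estimate_pi0(p, lambda_grid, method=pi0_method)
        method = pi0_method
    else:
        if not (0.0 < pi0 <= 1.0):
            raise ValueError("pi0 must lie in (0, 1]")
        method = "supplied"
    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate((pi0 * m * p_sorted / ranks)[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(pi0_hat=float(pi0), q_values=q,
                        lambda_grid=np.atleast_1d(np.asarray(lambda_grid,
                                                             dtype=float)),
                        pi0_method=method)


def threshold_report(q_values, thresholds=(0.10, 0.20), ids=None) -> dict:
    """Count discoveries strictly below each q threshold.

    Returns ``{threshold: {"count": int, "ids": list}}``; ``ids`` (optional)
    aligns identifiers with the q-values.
    """
    q = np.asarray(q_values, dtype=float)
    report = {}
    for t in thresholds:
        mask = q < t
        entry = {"count": int(mask.sum())}
        if ids is not None:
            entry["ids"] = [i for i, keep in zip(ids, mask) if keep]
        else:
            entry["ids"] = list(np.flatnonzero(mask))
        report[t] = entry
    return report
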