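"""Random-intercept linear mixed model estimated by REML.

The model combines measurements from E multiplexed experiments:

    y_i = beta0 + beta1 * x_i + u_{j(i)} + e_i,
    u_j ~ N(0, sigma_u^2),   e_i ~ N(0, sigma_e^2),

with one random intercept per experiment j. Estimation profiles the
restricted likelihood over the variance ratio lambda = sigma_u^2 / sigma_e^2:
for fixed lambda the GLS fixed effects and the residual variance have closed
forms, so the REML criterion is a one-dimensional function of lambda,
maximized by a coarse grid followed by bounded scalar refinement. sigma_u^2
is constrained non-negative; a boundary estimate of 0 reduces the fit to
ordinary least squares exactly (ties in the criterion are broken toward
lambda = 0).

Inference on the slope is a Wald test. The reference distribution is
selectable: standard normal, or Student t with n_groups - 1 degrees of
freedom (n - p for a single group, the OLS limit). The plug-in GLS standard
error ignores the uncertainty in the estimated variance components, whose
effective sample size is the number of experiments, so with ~72 experiments
the normal reference is slightly anticonservative in the far tail whenever
the outcome carries real between-experiment variance; the grouped-df t
reference restores tail calibration and is what the proteome-wide scans use.

Fitted values include the BLUP random intercepts by default (that is what
"variance explained by the fitted values" refers to); a fixed-effects-only
mode is available.

`grid_reml_oracle` is a brute-force reference implementation of the same
criterion via dense-matrix linear algebra on a fixed lambda grid, kept
deliberately independent of the profiled fast path so the two can be checked
against each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ModelSpec", "LmeFit", "RandomInterceptLM", "RandomInterceptLMResults",
    "DegenerateDesignError", "fit_random_intercept", "wald_test", "fitted_r2",
    "grid_reml_oracle",
]

_Z975 = stats.norm.ppf(0.975)


class DegenerateDesignError(ValueError):
    """The design admits no slope (constant predictor or too few rows)."""


@dataclass
class ModelSpec:
    """One model instance: equal-length outcome, predictor, group vectors.

    ``direction`` documents which analysis the spec belongs to:
    ``"nutrient_on_protein"`` (outcome = log2 PIVKA-II, predictor = protein)
    or ``"protein_on_group"`` (outcome = protein, predictor = deficiency
    indicator). It is a tag only; the algebra is identical.
    """

    outcome: np.ndarray
    predictor: np.ndarray | None
    group: np.ndarray
    direction: str = "nutrient_on_protein"

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.group = np.asarray(self.group)
        if self.predictor is not None:
            self.predictor = np.asarray(self.predictor, dtype=float)
            if len(self.predictor) != len(self.outcome):
                raise ValueError("outcome and predictor lengths differ")
        if len(self.group) != len(self.outcome):
            raise ValueError("outcome and group lengths differ")
        if np.isnan(self.outcome).any() or (
                self.predictor is not None and np.isnan(self.predictor).any()):
            raise ValueError("missing values must be removed by the caller")


@dataclass
class LmeFit:
    """REML estimates for one random-intercept fit."""

    beta0: float
    beta1: float | None
    sigma2_u: float
    sigma2_e: float
    se_beta1: float | None
    fitted_values: np.ndarray
    n_obs: int
    n_groups: int
    converged: bool
    loglik_reml: float
    lam: float = 0.0
    random_intercepts: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# profiled REML criterion
# ---------------------------------------------------------------------------

def _group_sums(X: np.ndarray, y: np.ndarray, codes: np.ndarray,
                n_groups: int):
    n_j = np.bincount(codes, minlength=n_groups).astype(float)
    s = np.column_stack([np.bincount(codes, weights=X[:, k],
                                     minlength=n_groups)
                         for k in range(X.shape[1])])
    t = np.bincount(codes, weights=y, minlength=n_groups)
    return n_j, s, t


def _criterion_terms(lam: float, XtX, Xty, yty, n_j, s, t, n, p):
    """GLS pieces and -2 * restricted log-likelihood at variance ratio lam."""
    c = lam / (1.0 + lam * n_j)
    A = XtX - (s * c[:, None]).T @ s
    b = Xty - s.T @ (c * t)
    yVy = yty - float(c @ (t * t))
    beta = np.linalg.solve(A, b)
    rss = yVy - float(beta @ b)
    rss = max(rss, 0.0)
    sigma2 = rss / (n - p)
    sign, logdet_A = np.linalg.slogdet(A)
    logdet_V = float(np.sum(np.log1p(lam * n_j)))
    with np.errstate(divide="ignore"):
        m2ll = ((n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0)
                + logdet_V + logdet_A)
    return m2ll, beta, sigma2, A, c


class RandomInterceptLM:
    """Random-intercept linear model, statsmodels-style.

    Parameters
    ----------
    endog : outcome vector.
    exog : single predictor vector, or None for an intercept-only
        (variance-components) model.
    groups : experiment labels, one per observation.
    """

    def __init__(self, endog, exog, groups):
        self.spec = ModelSpec(np.asarray(endog, dtype=float),
                              None if exog is None else np.asarray(exog,
                                                                   dtype=float),
                              np.asarray(groups))
        y = self.spec.outcome
        n = len(y)
        if n < 3:
            raise DegenerateDesignError("need at least 3 observations")
        if self.spec.predictor is None:
            X = np.ones((n, 1))
        else:
            x = self.spec.predictor
            if np.ptp(x) == 0.0:
                raise DegenerateDesignError("predictor is constant")
            X = np.column_stack([np.ones(n), x])
        self.endog = y
        self.exog = X
        labels, codes = np.unique(self.spec.group, return_inverse=True)
        self.group_labels = labels
        self.group_codes = codes
        self.n_groups = len(labels)

    @classmethod
    def from_spec(cls, spec: ModelSpec) -> "RandomInterceptLM":
        model = cls(spec.outcome, spec.predictor, spec.group)
        model.spec.direction = spec.direction
        return model

    # -- fitting ------------------------------------------------------------

    def _neg2_reml(self, lam: float):
        return _criterion_terms(lam, self._XtX, self._Xty, self._yty,
                                self._n_j, self._s, self._t,
                                len(self.endog), self.exog.shape[1])

    def fit(self, lam_max: float = 1e7, tol: float = 1e-8
            ) -> "RandomInterceptLMResults":
        X, y, codes = self.exog, self.endog, self.group_codes
        n, p = X.shape
        self._XtX = X.T @ X
        self._Xty = X.T @ y
        self._yty = float(y @ y)
        self._n_j, self._s, self._t = _group_sums(X, y, codes, self.n_groups)

        converged = True
        if self.n_groups == 1 or self.n_groups == n:
            # the REML criterion is exactly flat in the variance ratio
            # (random intercept confounded with the fixed intercept / the
            # residual): take the OLS limit
            lam_best = 0.0
        else:
            grid = np.concatenate([[0.0],
                                   np.logspace(-6, np.log10(lam_max), 53)])
            crits = np.array([self._neg2_reml(l)[0] for l in grid])
            i = int(np.nanargmin(crits))
            lam_best, crit_best = grid[i], crits[i]
            lo = grid[i - 1] if i > 0 else 0.0
            hi = grid[i + 1] if i + 1 < len(grid) else grid[-1] * 10.0
            if hi > lo and np.isfinite(crit_best):
                res = optimize.minimize_scalar(
                    lambda l: self._neg2_reml(l)[0], bounds=(lo, hi),
                    method="bounded", options={"xatol": tol})
                if np.isfinite(res.fun) and res.fun < crit_best:
                    lam_best, crit_best = float(res.x), float(res.fun)
                converged = bool(res.success) or np.isfinite(crit_best)
            # boundary tie-break: prefer the OLS limit when it is as good
            crit0 = crits[0]
            if crit0 <= crit_best + 1e-10 or not np.isfinite(crit_best):
                lam_best = 0.0

        m2ll, beta, sigma2, A, c = self._neg2_reml(lam_best)
        cov_beta = sigma2 * np.linalg.inv(A)
        resid = y - X @ beta
        t_resid = np.bincount(codes, weights=resid, minlength=self.n_groups)
        u_hat = c * t_resid
        fitted = X @ beta + u_hat[codes]
        fit = LmeFit(
            beta0=float(beta[0]),
            beta1=float(beta[1]) if p == 2 else None,
            sigma2_u=float(lam_best * sigma2),
            sigma2_e=float(sigma2),
            se_beta1=float(np.sqrt(max(cov_beta[1, 1], 0.0))) if p == 2 else None,
            fitted_values=fitted,
            n_obs=n,
            n_groups=self.n_groups,
            converged=converged,
            loglik_reml=float(-0.5 * m2ll),
            lam=float(lam_best),
            random_intercepts=u_hat,
        )
        return RandomInterceptLMResults(self, fit, cov_beta)


class RandomInterceptLMResults:
    """Estimates, uncertainties and diagnostics for one fit."""

    def __init__(self, model: RandomInterceptLM, fit: LmeFit,
                 cov_beta: np.ndarray):
        self.model = model
        self.fit = fit
        self.cov_beta = cov_beta

    # convenient aliases -----------------------------------------------------
    @property
    def beta0(self) -> float:
        return self.fit.beta0

    @property
    def beta1(self) -> float | None:
        return self.fit.beta1

    @property
    def se_beta1(self) -> float | None:
        return self.fit.se_beta1

    @property
    def sigma2_u(self) -> float:
        return self.fit.sigma2_u

    @property
    def sigma2_e(self) -> float:
        return self.fit.sigma2_e

    @property
    def loglik_reml(self) -> float:
        return self.fit.loglik_reml

    @property
    def converged(self) -> bool:
        return self.fit.converged

    def fitted(self, include_random: bool = True) -> np.ndarray:
        if include_random:
            return self.fit.fitted_values
        return self.model.exog @ np.array(
            [self.fit.beta0] + ([self.fit.beta1] if self.fit.beta1 is not None
                                else []))

    def wald_pvalue(self, reference: str = "normal") -> float:
        return wald_test(self.fit, reference=reference)

    def conf_int_beta1(self, level: float = 0.95) -> tuple[float, float]:
        if self.fit.beta1 is None or self.fit.se_beta1 is None:
            raise ValueError("model has no slope")
        z = stats.norm.ppf(0.5 + level / 2.0)
        return (self.fit.beta1 - z * self.fit.se_beta1,
                self.fit.beta1 + z * self.fit.se_beta1)

    def r2(self, include_random: bool = True) -> float:
        return fitted_r2(self.fit, self.model.endog,
                         include_random=include_random,
                         exog=self.model.exog)

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Random-intercept linear mixed model (REML)",
            f"  observations: {f.n_obs}   groups: {f.n_groups}",
            f"  sigma2_u (between-experiment): {f.sigma2_u:.6g}",
            f"  sigma2_e (residual):           {f.sigma2_e:.6g}",
            f"  REML log-likelihood: {f.loglik_reml:.6g}",
            f"  intercept: {f.beta0:.6g}",
        ]
        if f.beta1 is not None:
            p = self.wald_pvalue() if (f.se_beta1 or 0) > 0 else float("nan")
            lo, hi = (self.conf_int_beta1() if (f.se_beta1 or 0) > 0
                      else (float("nan"), float("nan")))
            lines.append(
                f"  slope: {f.beta1:.6g}  SE {f.se_beta1:.4g}  "
                f"95% CI ({lo:.6g}, {hi:.6g})  p {p:.4g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# spec-level operations
# ---------------------------------------------------------------------------

def fit_random_intercept(spec: ModelSpec, **options) -> LmeFit:
    """Fit the random-intercept model for a :class:`ModelSpec`."""
    return RandomInterceptLM.from_spec(spec).fit(**options).fit


def wald_test(fit: LmeFit, reference: str = "normal") -> float:
    """Two-sided p-value for slope = 0 from z = beta1 / SE.

    ``reference="normal"``: standard normal. ``reference="t_groups"``:
    Student t with n_groups - 1 df (n_obs - 2 when there is a single group),
    which keeps the far tail calibrated when between-experiment variance is
    real and must be estimated from few experiments.
    """
    if fit.beta1 is None or fit.se_beta1 is None:
        raise ValueError("fit has no slope")
    if fit.se_beta1 == 0.0:
        raise ValueError("standard error is zero; Wald test undefined")
    z = fit.beta1 / fit.se_beta1
    if reference == "normal":
        return float(2.0 * stats.norm.sf(abs(z)))
    if reference == "t_groups":
        df = fit.n_groups - 1 if fit.n_groups > 1 else fit.n_obs - 2
        return float(2.0 * stats.t.sf(abs(z), df=max(df, 1)))
    raise ValueError(f"unknown reference {reference!r}")


def fitted_r2(fit: LmeFit, outcome, include_random: bool = True,
              exog: np.ndarray | None = None) -> float:
    """Proportion of outcome variance explained by the fitted values.

    r2 = Var(fitted) / Var(outcome), clipped to [0, 1]. By default the
    fitted values include the BLUP random intercepts.
    """
    y = np.asarray(outcome, dtype=float)
    var_y = float(np.var(y))
    if var_y == 0.0:
        raise ValueError("outcome is constant; r2 undefined")
    if include_random:
        fitted = fit.fitted_values
    else:
        if exog is None:
            raise ValueError("exog required for fixed-effects-only r2")
        beta = np.array([fit.beta0] + ([fit.beta1]
                                       if fit.beta1 is not None else []))
        fitted = exog @ beta
    return float(np.clip(np.var(fitted) / var_y, 0.0, 1.0))


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def grid_reml_oracle(endog, exog, groups, lam_grid=None):
    """Brute-force REML criterion maximization on a lambda grid.

    Builds the dense covariance V = I + lam * Z Z' per grid point and
    evaluates the restricted log-likelihood with generic dense linear
    algebra (slogdet / solve) — no profiling, no grouped shortcuts. Returns
    ``(best_loglik, best_lam, logliks)``.

    Intended as an independent reference for small instances; cost grows as
    O(len(grid) * n^3).
    """
    y = np.asarray(endog, dtype=float)
    n = len(y)
    if exog is None:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), np.asarray(exog, dtype=float)])
    p = X.shape[1]
    _, codes = np.unique(np.asarray(groups), return_inverse=True)
    Z = np.zeros((n, codes.max() + 1))
    Z[np.arange(n), codes] = 1.0
    if lam_grid is None:
        lam_grid = np.concatenate([[0.0], np.logspace(-6, 6, 400)])
    logliks = np.empty(len(lam_grid))
    for k, lam in enumerate(lam_grid):
        V = np.eye(n) + lam * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        A = X.T @ Vi @ X
        beta = np.linalg.solve(A, X.T @ Vi @ y)
        r = y - X @ beta
        rss = float(r @ Vi @ r)
        sigma2 = rss / (n - p)
        _, logdet_V = np.linalg.slogdet(V)
        _, logdet_A = np.linalg.slogdet(A)
        with np.errstate(divide="ignore"):
            m2ll = ((n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0)
                    + logdet_V + logdet_A)
        logliks[k] = -0.5 * m2ll
    k = int(np.nanargmax(logliks))
    return float(logliks[k]), float(lam_grid[k]), logliks
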