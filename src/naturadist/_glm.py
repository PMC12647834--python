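"""Binomial GLM with complementary log-log link, fitted by IRLS.

The cloglog link log(-log(1-p)) is asymmetric and suited to rare-event binary
data. Fitting is iteratively reweighted least squares on the working response;
convergence is declared when the maximum absolute score drops below
``tol_score`` or the relative log-likelihood change below ``tol_loglik``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GlmFit", "ConvergenceError", "RankDeficiencyError", "fit_cloglog_glm", "cloglog_inverse"]

_ETA_LO, _ETA_HI = -30.0, 3.5  # exp(3.5) ~ 33 -> p ~ 1; avoids overflow
_MU_EPS = 1e-10


class ConvergenceError(RuntimeError):
    """IRLS failed to converge (e.g. complete separation)."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


def cloglog_inverse(eta: np.ndarray) -> np.ndarray:
    """p = 1 - exp(-exp(eta)), computed stably."""
    return -np.expm1(-np.exp(np.clip(eta, _ETA_LO, _ETA_HI)))


def _link_parts(eta: np.ndarray):
    eta = np.clip(eta, _ETA_LO, _ETA_HI)
    ee = np.exp(eta)
    mu = np.clip(-np.expm1(-ee), _MU_EPS, 1.0 - _MU_EPS)
    dmu = np.exp(eta - ee)  # d mu / d eta
    dmu = np.maximum(dmu, 1e-300)
    return mu, dmu


@dataclass
class GlmFit:
    params: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    deviance: float
    n_iter: int
    converged: bool
    columns: list

    @property
    def sigma2_species(self) -> float:  # fixed-effects model: no random variance
        return 0.0

    @property
    def sigma2_region(self) -> float:
        return 0.0


def _check_rank(X: np.ndarray, columns) -> None:
    # pivoted QR flags which columns are (numerically) linear combinations
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        q, rr = np.linalg.qr(X)
        diag = np.abs(np.diag(rr))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [columns[j] for j in range(X.shape[1]) if diag[j] <= tol]
        raise RankDeficiencyError(f"design matrix is rank deficient; collinear columns: {bad or columns}")


def fit_cloglog_glm(
    X: np.ndarray,
    y: np.ndarray,
    columns=None,
    max_iter: int = 100,
    tol_score: float = 1e-8,
    tol_loglik: float = 1e-10,
) -> GlmFit:
    """Maximum-likelihood fit of a binomial cloglog GLM via IRLS.

    Raises :class:`RankDeficiencyError` for singular designs and
    :class:`ConvergenceError` when coefficients diverge (separation) or the
    iteration limit is reached without meeting the tolerances.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-d with one row per outcome")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both outcome classes must be present")
    n, p = X.shape
    columns = list(columns) if columns is not None else [f"x{j}" for j in range(p)]
    _check_rank(X, columns)

    beta = np.zeros(p)
    # start from the intercept-only closed form when an intercept-like column exists
    const = np.where(np.ptp(X, axis=0) == 0)[0]
    q = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    if const.size:
        j = const[0]
        beta[j] = np.log(-np.log1p(-q)) / X[0, j]

    ll_old = -np.inf
    converged = False
    it = 0
    polish = 0  # extra steps after the log-likelihood plateaus
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu, dmu = _link_parts(eta)
        var = mu * (1.0 - mu)
        w = dmu**2 / var
        z = eta + (y - mu) / dmu
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"weighted least squares became singular: {err}") from err
        if np.max(np.abs(beta_new)) > 1e3:
            raise ConvergenceError(
                "coefficients diverged (possible complete separation); "
                f"max |beta| = {np.max(np.abs(beta_new)):.3g}"
            )
        # step-halve if the likelihood drops
        step = beta_new - beta
        ll = _loglik(X, y, beta_new)
        halves = 0
        while ll < ll_old - 1e-12 and halves < 10:
            step *= 0.5
            beta_new = beta + step
            ll = _loglik(X, y, beta_new)
            halves += 1
        beta = beta_new
        score = X.T @ ((y - _link_parts(X @ beta)[0]) * _score_weight(X @ beta))
        if np.max(np.abs(score)) < tol_score:
            converged = True
            ll_old = ll
            break
        if np.isfinite(ll_old) and abs(ll - ll_old) < tol_loglik * (abs(ll_old) + 1.0):
            # plateau reached: IRLS contracts quadratically near the optimum,
            # so two polishing steps pin the estimate down before stopping
            polish += 1
            if polish > 2:
                converged = True
                ll_old = ll
                break
        ll_old = ll
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")

    dev = -2.0 * ll_old  # saturated binary model has zero log-likelihood
    if dev < 1e-3 and np.max(np.abs(beta)) > 50.0:
        raise ConvergenceError(
            "complete separation: the deviance vanished with diverging coefficients "
            f"(max |beta| = {np.max(np.abs(beta)):.3g})"
        )
    eta = X @ beta
    mu, dmu = _link_parts(eta)
    w = dmu**2 / (mu * (1.0 - mu))
    cov = np.linalg.inv((X.T * w) @ X)
    return GlmFit(
        params=beta,
        se=np.sqrt(np.diag(cov)),
        cov=cov,
        loglik=float(ll_old),
        deviance=float(dev),
        n_iter=it,
        converged=True,
        columns=columns,
    )


def _score_weight(eta: np.ndarray) -> np.ndarray:
    mu, dmu = _link_parts(eta)
    return dmu / (mu * (1.0 - mu))


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    mu, _ = _link_parts(X @ beta)
    return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log1p(-mu)))
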