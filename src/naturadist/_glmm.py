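"""Binomial cloglog GLMM with crossed random intercepts (species x region).

Fitting is penalized quasi-likelihood: each outer step solves the working
linear mixed model implied by the current linearization through Henderson's
mixed-model equations and updates the two variance components with an
effective-degrees-of-freedom REML step (Aitken-accelerated, since that fixed
point converges geometrically). An optional refinement then re-estimates the
variance components by maximizing the Laplace approximation to the marginal
likelihood, profiling the fixed effects and random-effect modes at each
candidate. Fixed-effect standard errors come from the fixed-effect block of
the inverse mixed-model-equation matrix, as usual for PQL.

Because every observation belongs to exactly one level of each grouping
factor, the equations have arrow structure: the block for the largest factor
is diagonal and is eliminated by a Schur complement, so one solve costs
O((p + q_small)^2 * q_big) instead of a dense factorization of the full
system.

With both variance components constrained to zero the estimates coincide with
the plain GLM fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import optimize, sparse

from ._glm import ConvergenceError, _link_parts, fit_cloglog_glm

__all__ = ["GlmmFit", "fit_cloglog_glmm"]

_SIGMA_FLOOR = 1e-8


@dataclass
class GlmmFit:
    params: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    sigma2: dict  # group name -> variance component
    u: dict  # group name -> BLUP vector
    loglik_laplace: float
    n_iter: int
    converged: bool
    columns: list
    boundary: dict = field(default_factory=dict)  # group -> pinned-at-zero flag

    @property
    def sigma2_species(self) -> float:
        return self.sigma2.get("species", 0.0)

    @property
    def sigma2_region(self) -> float:
        return self.sigma2.get("region", 0.0)


def _encode(values):
    levels, idx = np.unique(np.asarray(values), return_inverse=True)
    return idx.astype(np.int64), levels


class _MME:
    """Henderson's equations for <=2 crossed intercept factors, solved by
    eliminating the largest factor's (diagonal) block."""

    def __init__(self, X: np.ndarray, group_codes: dict) -> None:
        self.X = X
        self.n, self.p = X.shape
        self.names = list(group_codes)  # estimation order of sigma2
        if not 1 <= len(self.names) <= 2:
            raise ValueError("one or two grouping factors are supported")
        codes = {g: np.asarray(c, dtype=np.int64) for g, c in group_codes.items()}
        sizes = {g: int(c.max()) + 1 for g, c in codes.items()}
        # eliminate the biggest factor
        self.big = max(self.names, key=lambda g: sizes[g])
        self.small = next((g for g in self.names if g != self.big), None)
        self.cb = codes[self.big]
        self.qb = sizes[self.big]
        self.cs = codes[self.small] if self.small else None
        self.qs = sizes[self.small] if self.small else 0
        self.d = self.p + self.qs  # retained (non-eliminated) dimension

    def solve(self, w, z, sigma2: dict, want_traces: bool = False):
        """Solve the working mixed-model equations.

        Returns a dict with beta, per-group u, the retained-block inverse
        S_inv (covariance of [beta, u_small]), optional per-group traces of
        the A-inverse diagonal blocks, and the log-determinant of the u-block
        Hessian (for the Laplace criterion).
        """
        X, p = self.X, self.p
        Xw = X * w[:, None]
        F = Xw.T @ X
        rhs_x = Xw.T @ z
        g_big = np.bincount(self.cb, weights=w, minlength=self.qb) + 1.0 / max(
            sigma2[self.big], _SIGMA_FLOOR
        )
        rhs_big = np.bincount(self.cb, weights=w * z, minlength=self.qb)
        B_big = np.vstack(
            [np.bincount(self.cb, weights=w * X[:, j], minlength=self.qb) for j in range(p)]
        )  # p x qb

        if self.small is not None:
            g_small_diag = np.bincount(self.cs, weights=w, minlength=self.qs) + 1.0 / max(
                sigma2[self.small], _SIGMA_FLOOR
            )
            rhs_small = np.bincount(self.cs, weights=w * z, minlength=self.qs)
            B_small = np.vstack(
                [np.bincount(self.cs, weights=w * X[:, j], minlength=self.qs) for j in range(p)]
            )  # p x qs
            cross = sparse.coo_matrix(
                (w, (self.cs, self.cb)), shape=(self.qs, self.qb)
            ).toarray()  # qs x qb
            M_cross = np.vstack([B_big, cross])  # d x qb
            M_top = np.empty((self.d, self.d))
            M_top[:p, :p] = F
            M_top[:p, p:] = B_small
            M_top[p:, :p] = B_small.T
            M_top[p:, p:] = np.diag(g_small_diag)
            rhs_top = np.concatenate([rhs_x, rhs_small])
        else:
            M_cross = B_big
            M_top = F
            rhs_top = rhs_x

        V = M_cross / g_big  # d x qb
        S = M_top - V @ M_cross.T
        rhs_s = rhs_top - V @ rhs_big
        c, low = sla.cho_factor(S, lower=True, check_finite=False)
        t = sla.cho_solve((c, low), rhs_s, check_finite=False)
        S_inv = sla.cho_solve((c, low), np.eye(self.d), check_finite=False)
        u_big = (rhs_big - M_cross.T @ t) / g_big
        beta = t[:p]
        u = {self.big: u_big}
        if self.small is not None:
            u[self.small] = t[p:]

        out = {"beta": beta, "u": u, "S_inv": S_inv}
        if want_traces:
            # A^-1 big-block diagonal: 1/g + (c_i' S^-1 c_i)/g^2
            sv = S_inv @ V  # d x qb
            quad = np.einsum("ij,ij->j", V, sv)
            out["traces"] = {self.big: float(np.sum(1.0 / g_big) + np.sum(quad / g_big))}
            if self.small is not None:
                out["traces"][self.small] = float(np.trace(S_inv[p:, p:]))
        # log-determinant of the u-block Hessian Z'WZ + D^-1
        logdet = float(np.sum(np.log(g_big)))
        if self.small is not None:
            h_small = np.diag(g_small_diag) - (cross / g_big) @ cross.T
            sign, ld = np.linalg.slogdet(h_small)
            logdet += float(ld)
        out["logdet_h"] = logdet
        return out

    def eta_random(self, u: dict) -> np.ndarray:
        eta = u[self.big][self.cb]
        if self.small is not None:
            eta = eta + u[self.small][self.cs]
        return eta


def _working(y, eta):
    mu, dmu = _link_parts(eta)
    w = dmu**2 / (mu * (1.0 - mu))
    z = eta + (y - mu) / dmu
    return mu, w, z


def _pirls(mme: _MME, y, sigma2: dict, beta, u, max_iter=40, tol=1e-9, want_traces=False):
    """Inner penalized IRLS at fixed variance components."""
    sol = None
    for _ in range(max_iter):
        eta = mme.X @ beta + mme.eta_random(u)
        _, w, z = _working(y, eta)
        sol = mme.solve(w, z, sigma2, want_traces=want_traces)
        delta = np.max(np.abs(sol["beta"] - beta))
        for g in u:
            delta = max(delta, np.max(np.abs(sol["u"][g] - u[g]), initial=0.0))
        beta, u = sol["beta"], sol["u"]
        if delta < tol:
            break
    return beta, u, sol


def _laplace_loglik(mme: _MME, y, beta, u, sigma2: dict, logdet_h: float) -> float:
    eta = mme.X @ beta + mme.eta_random(u)
    mu, _ = _link_parts(eta)
    ll = float(np.sum(y * np.log(mu) + (1.0 - y) * np.log1p(-mu)))
    q_total = 0
    for g, ug in u.items():
        s2 = max(sigma2[g], _SIGMA_FLOOR)
        ll += -0.5 * float(ug @ ug) / s2 - 0.5 * len(ug) * np.log(2.0 * np.pi * s2)
        q_total += len(ug)
    ll -= 0.5 * (logdet_h - q_total * np.log(2.0 * np.pi))
    return ll


def fit_cloglog_glmm(
    X: np.ndarray,
    y: np.ndarray,
    species=None,
    region=None,
    columns=None,
    max_iter: int = 200,
    tol: float = 1e-5,
    laplace_refine: bool = True,
    fix_sigma2: dict | None = None,
) -> GlmmFit:
    """Fit the cloglog GLMM with species and region random intercepts.

    Parameters
    ----------
    X, y:
        Fixed-effect design (including the intercept column) and 0/1 outcomes.
    species, region:
        Grouping labels (one per row). Either may be omitted to drop that
        random effect; with both omitted the call degenerates to the GLM.
    laplace_refine:
        After PQL converges, re-optimize the variance components against the
        Laplace-approximate marginal likelihood. Disable inside large
        simulation loops where the PQL solution is sufficient.
    fix_sigma2:
        Map of group name to a fixed variance value (e.g. ``{"species": 0.0}``)
        excluded from estimation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = {}
    if species is not None:
        groups["species"], _ = _encode(species)
    if region is not None:
        groups["region"], _ = _encode(region)
    p = X.shape[1]
    columns = list(columns) if columns is not None else [f"x{j}" for j in range(p)]
    fix_sigma2 = dict(fix_sigma2 or {})

    glm = fit_cloglog_glm(X, y, columns=columns)
    if not groups:
        return GlmmFit(
            params=glm.params, se=glm.se, cov=glm.cov, sigma2={}, u={},
            loglik_laplace=glm.loglik, n_iter=glm.n_iter, converged=True, columns=columns,
        )

    mme = _MME(X, groups)
    names = mme.names
    sigma2 = {g: fix_sigma2.get(g, 0.1) for g in names}
    free = [g for g in names if g not in fix_sigma2]
    beta = glm.params.copy()
    u = {g: np.zeros(mme.qb if g == mme.big else mme.qs) for g in names}

    converged = False
    it = 0
    history: list = []
    low_count: dict = {}
    for it in range(1, max_iter + 1):
        eta = mme.X @ beta + mme.eta_random(u)
        _, w, z = _working(y, eta)
        sol = mme.solve(w, z, sigma2, want_traces=bool(free))
        sigma2_new = dict(sigma2)
        for g in free:
            ug = sol["u"][g]
            tr = sol["traces"][g]
            # effective-dof REML step; EM fallback near the zero boundary
            edf = len(ug) - tr / max(sigma2[g], _SIGMA_FLOOR)
            if edf > 1e-8:
                sigma2_new[g] = float(ug @ ug) / edf
            else:
                sigma2_new[g] = (float(ug @ ug) + tr) / len(ug)
        # Aitken extrapolation: the variance fixed point converges
        # geometrically, so periodically jump toward its limit
        history.append(dict(sigma2_new))
        if len(history) >= 3 and it >= 8 and it % 4 == 0:
            s0, s1, s2 = history[-3], history[-2], history[-1]
            for g in free:
                d0, d1 = s1[g] - s0[g], s2[g] - s1[g]
                if d0 != 0.0 and abs(d1) < abs(d0):  # only for contracting sequences
                    r = min(d1 / d0, 0.9)  # cap the multiplier at 9x
                    if r > 0.0:
                        jump = s2[g] + d1 * r / (1.0 - r)
                        # clamp: the limit may be near but not at the boundary,
                        # and a noisy ratio must not explode the step
                        sigma2_new[g] = float(
                            np.clip(jump, max(0.2 * s2[g], _SIGMA_FLOOR), 5.0 * s2[g])
                        )
        # a component collapsing to the boundary is pinned and frozen,
        # otherwise its geometric crawl toward 0 never meets the tolerance
        for g in list(free):
            if sigma2_new[g] < 1e-6:
                low_count[g] = 3
            elif sigma2_new[g] < 1e-4 and sigma2_new[g] < sigma2[g]:
                low_count[g] = low_count.get(g, 0) + 1
            else:
                low_count[g] = 0
            if low_count[g] >= 3:  # SD below 0.01 and still shrinking: negligible
                sigma2_new[g] = _SIGMA_FLOOR
                free.remove(g)
        # convergence is judged on the fixed effects and the *relative*
        # variance-component change; the final PIRLS polish re-tightens
        # the random-effect modes
        delta_beta = float(np.max(np.abs(sol["beta"] - beta)))
        # relative for sizeable components, absolute (0.01 scale) near zero
        delta_sigma = max(
            (abs(sigma2_new[g] - sigma2[g]) / (sigma2[g] + 1e-2) for g in names),
            default=0.0,
        )
        delta = max(delta_beta, delta_sigma)
        beta, u, sigma2 = sol["beta"], sol["u"], sigma2_new
        if delta_beta < tol and delta_sigma < 1e-3:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"PQL did not converge in {max_iter} iterations (last delta {delta:.2e}); "
            f"sigma2 trace: { {g: round(sigma2[g], 6) for g in names} }"
        )

    if laplace_refine and free:

        def neg_ll(log_s2_free):
            s2 = dict(sigma2)
            for g, v in zip(free, log_s2_free):
                s2[g] = float(np.exp(v))
            b, uu, sol2 = _pirls(mme, y, s2, beta, u, max_iter=30, tol=1e-8)
            return -_laplace_loglik(mme, y, b, uu, s2, sol2["logdet_h"])

        x0 = np.log([max(sigma2[g], 1e-4) for g in free])
        res = optimize.minimize(
            neg_ll, x0, method="Nelder-Mead",
            options={"maxfev": 60, "xatol": 1e-3, "fatol": 1e-4},
        )
        for g, v in zip(free, res.x):
            sigma2[g] = float(np.exp(v))

    beta, u, sol = _pirls(mme, y, sigma2, beta, u, max_iter=50, tol=1e-10, want_traces=False)
    boundary = {}
    for g in (g for g in names if g not in fix_sigma2):
        if sigma2[g] < 1e-4:
            boundary[g] = True
            warnings.warn(f"variance component for {g!r} estimated at the zero boundary")
    cov = sol["S_inv"][:p, :p]
    ll = _laplace_loglik(mme, y, beta, u, sigma2, sol["logdet_h"])
    return GlmmFit(
        params=beta,
        se=np.sqrt(np.diag(cov)),
        cov=cov,
        sigma2={g: float(max(sigma2[g], 0.0)) for g in names},
        u={g: u[g].copy() for g in names},
        loglik_laplace=float(ll),
        n_iter=it,
        converged=True,
        columns=columns,
        boundary=boundary,
    )
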