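"""Restricted maximum likelihood for Gaussian variance-component models.

Fits y = X beta + sum_r Z_r u_r + e with u_r ~ N(0, sigma_r^2 I) and
e ~ N(0, sigma_e^2 I), the model family behind every mixed-model fit in
this package (clone, clone-by-site, and all-random site decompositions).

The residual variance is profiled out and the REML criterion is optimised
over the variance ratios gamma_r = sigma_r^2 / sigma_e^2.  All quantities
are evaluated through Henderson's mixed-model equations, so each criterion
evaluation costs one Cholesky factorisation of a (p + q) x (p + q) matrix
(p fixed effects, q total random levels) — independent of the number of
observations.  A bounded quasi-Newton search with the analytic gradient is
followed by a Newton polish, and components pinned at the lower bound are
resolved to exactly zero by refitting without them and comparing the
restricted likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

# Lower bound for variance ratios during optimisation; ratios at the bound
# are candidates for exact-zero resolution.
_GAMMA_FLOOR = 1e-8


@dataclass
class RandomFactor:
    """One random term: integer level codes per observation plus labels."""

    name: str
    codes: np.ndarray  # (n,) int, in [0, n_levels)
    levels: list  # label per level

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def incidence(self, n: int) -> np.ndarray:
        Z = np.zeros((n, self.n_levels))
        Z[np.arange(n), self.codes] = 1.0
        return Z


@dataclass
class RemlFit:
    """Converged REML solution for one variance-component model."""

    variances: dict[str, float]  # per factor name, plus "residual"
    loglik: float
    converged: bool
    n_iter: int
    beta: dict[str, float]
    blups: dict[str, "np.ndarray"]  # per factor: value per level
    blup_levels: dict[str, list] = field(default_factory=dict)
    grad_norm: float = float("nan")


class _Workspace:
    """Cross-products and criterion evaluation for a fixed design."""

    def __init__(self, y, X, factors):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        self.n, self.p = X.shape
        if np.linalg.matrix_rank(X) < self.p:
            # Drop redundant columns once; callers build full-rank designs,
            # this is a guard for degenerate layouts (e.g. empty blocks).
            q, r, piv = _qr_col_select(X)
            self.keep = piv
            X = X[:, piv]
            self.p = X.shape[1]
        else:
            self.keep = np.arange(self.p)
        self.factors = factors
        n = self.n
        Zs = [f.incidence(n) for f in factors]
        self.q_sizes = [f.n_levels for f in factors]
        self.q = int(sum(self.q_sizes))
        Z = np.hstack(Zs) if Zs else np.zeros((n, 0))
        W = np.hstack([X, Z])
        self.WtW = W.T @ W
        self.Wty = W.T @ y
        self.yty = float(y @ y)
        self.offsets = np.concatenate([[0], np.cumsum(self.q_sizes)]).astype(int)

    def _assemble(self, gamma):
        C = self.WtW.copy()
        for r, g in enumerate(gamma):
            lo = self.p + self.offsets[r]
            hi = self.p + self.offsets[r + 1]
            idx = np.arange(lo, hi)
            C[idx, idx] += 1.0 / g
        return C

    def criterion(self, gamma, want_grad=False, want_solution=False):
        """Profiled -2 REML log-likelihood up to an additive constant.

        f(gamma) = (n-p) log r^2 + sum_r q_r log gamma_r + log|C|,
        with r^2 the weighted residual sum of squares from the MME solve.
        """
        C = self._assemble(gamma)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return (np.inf, np.full(len(gamma), np.nan)) if want_grad else np.inf
        sol = _chol_solve(L, self.Wty)
        r2 = self.yty - float(self.Wty @ sol)
        r2 = max(r2, 1e-300)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        np_ = self.n - self.p
        f = np_ * np.log(r2) + logdet
        for r, g in enumerate(gamma):
            f += self.q_sizes[r] * np.log(g)

        out = [f]
        if want_grad:
            Cinv = _chol_inverse(L)
            grad = np.empty(len(gamma))
            for r, g in enumerate(gamma):
                lo = self.p + self.offsets[r]
                hi = self.p + self.offsets[r + 1]
                u = sol[lo:hi]
                tr_block = float(np.trace(Cinv[lo:hi, lo:hi]))
                grad[r] = (
                    self.q_sizes[r] / g
                    - tr_block / g**2
                    - np_ * (u @ u) / (g**2 * r2)
                )
            out.append(grad)
        if want_solution:
            sigma_e2 = r2 / np_
            out.append((sol, sigma_e2))
        return out[0] if len(out) == 1 else tuple(out)

    def loglik_from_criterion(self, f):
        np_ = self.n - self.p
        return -0.5 * (f + np_ * (1.0 + np.log(2.0 * np.pi) - np.log(np_)))


def _qr_col_select(X):
    q, r, piv = np.linalg.qr(X, mode="reduced"), None, None
    Q, R = q
    tol = abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps if R.size else 0.0
    keep = [j for j in range(X.shape[1]) if abs(R[min(j, R.shape[0] - 1), j]) > tol]
    # Fall back to pivoted selection via scipy if the simple rule fails.
    if np.linalg.matrix_rank(X[:, keep]) < len(keep):
        from scipy.linalg import qr as sqr

        _, R, piv = sqr(X, pivoting=True, mode="economic")
        rank = int(np.sum(np.abs(np.diag(R)) > tol))
        keep = sorted(piv[:rank])
    return Q, R, np.asarray(keep, dtype=int)


def _chol_solve(L, b):
    z = np.linalg.solve(L, b)
    return np.linalg.solve(L.T, z)


def _chol_inverse(L):
    Linv = np.linalg.inv(L)
    return Linv.T @ Linv


def reml_fit(y, X, factors, beta_names=None, max_iter=500, gtol=1e-9):
    """Fit the variance-component model by profiled REML.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) fixed-effect design (full column rank expected).
    factors : list of :class:`RandomFactor`.
    beta_names : optional names for the fixed-effect columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ws = _Workspace(y, X, factors)
    R = len(factors)
    if ws.n - ws.p < 1:
        raise ValueError("not enough residual degrees of freedom")

    gamma, f_val, n_iter, converged, gnorm = _optimise(ws, R, max_iter, gtol)

    # Resolve boundary components to exactly zero: drop each pinned factor
    # and keep the reduced model if the restricted likelihood does not drop.
    active = [True] * R
    for r in range(R):
        if gamma[r] <= 10 * _GAMMA_FLOOR:
            trial_active = list(active)
            trial_active[r] = False
            sub = [f for f, a in zip(factors, trial_active) if a]
            ws_sub = _Workspace(y, X, sub)
            g_sub, f_sub, it2, conv2, gn2 = _optimise(
                ws_sub, len(sub), max_iter, gtol
            )
            if ws_sub.loglik_from_criterion(f_sub) >= ws.loglik_from_criterion(f_val) - 1e-7:
                active = trial_active
                gamma_full = np.zeros(R)
                j = 0
                for k in range(R):
                    if active[k]:
                        gamma_full[k] = g_sub[j]
                        j += 1
                gamma = gamma_full
                ws_eff, f_val = ws_sub, f_sub
                converged = conv2
                gnorm = gn2

    sub_factors = [f for f, a in zip(factors, active) if a]
    ws_eff = _Workspace(y, X, sub_factors)
    g_eff = np.asarray([g for g, a in zip(gamma, active) if a])
    if len(sub_factors):
        f_final, (sol, sigma_e2) = _eval_with_solution(ws_eff, g_eff)
    else:
        f_final, (sol, sigma_e2) = _eval_with_solution(ws_eff, np.empty(0))
    loglik = ws_eff.loglik_from_criterion(f_final)

    beta = sol[: ws_eff.p]
    if beta_names is None:
        beta_names = [f"b{j}" for j in range(X.shape[1])]
    beta_map = {}
    for j_eff, j_orig in enumerate(ws_eff.keep):
        beta_map[beta_names[j_orig]] = float(beta[j_eff])

    variances = {}
    blups = {}
    blup_levels = {}
    j = 0
    for r, fac in enumerate(factors):
        if active[r]:
            variances[fac.name] = float(g_eff[j] * sigma_e2)
            lo = ws_eff.p + ws_eff.offsets[j]
            hi = ws_eff.p + ws_eff.offsets[j + 1]
            blups[fac.name] = np.asarray(sol[lo:hi], dtype=float)
            j += 1
        else:
            variances[fac.name] = 0.0
            blups[fac.name] = np.zeros(fac.n_levels)
        blup_levels[fac.name] = fac.levels
    variances["residual"] = float(sigma_e2)

    return RemlFit(
        variances=variances,
        loglik=float(loglik),
        converged=bool(converged),
        n_iter=int(n_iter),
        beta=beta_map,
        blups=blups,
        blup_levels=blup_levels,
        grad_norm=float(gnorm),
    )


def _eval_with_solution(ws, gamma):
    if len(gamma):
        f, (sol, s2) = ws.criterion(gamma, want_solution=True)
    else:
        f, (sol, s2) = ws.criterion(np.empty(0), want_solution=True)
    return f, (sol, s2)


def _optimise(ws, R, max_iter, gtol):
    if R == 0:
        f = ws.criterion(np.empty(0))
        return np.empty(0), f, 0, True, 0.0

    def fun(g):
        f, grad = ws.criterion(g, want_grad=True)
        return f, grad

    best = None
    for start in (0.5, 0.05, 5.0):
        g0 = np.full(R, start)
        res = optimize.minimize(
            fun,
            g0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(_GAMMA_FLOOR, None)] * R,
            options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-12},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if best.fun < np.inf and start == 0.5 and res.success:
            break
    gamma = np.maximum(best.x, _GAMMA_FLOOR)
    n_iter = int(best.nit)

    # Newton polish on interior coordinates: finite-difference Hessian of
    # the analytic gradient, guarded by backtracking on the criterion.
    f_cur, grad = ws.criterion(gamma, want_grad=True)
    for _ in range(30):
        interior = gamma > 10 * _GAMMA_FLOOR
        g_int = grad[interior]
        if g_int.size == 0 or np.max(np.abs(g_int)) < gtol:
            break
        idx = np.where(interior)[0]
        h = 1e-6 * (1.0 + gamma[idx])
        H = np.zeros((len(idx), len(idx)))
        for a, ia in enumerate(idx):
            gp = gamma.copy()
            gp[ia] += h[a]
            _, grad_p = ws.criterion(gp, want_grad=True)
            H[:, a] = (grad_p[idx] - grad[idx]) / h[a]
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(len(idx)), -grad[idx])
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        scale = 1.0
        improved = False
        for _bt in range(20):
            trial = gamma.copy()
            trial[idx] = np.maximum(gamma[idx] + scale * step, _GAMMA_FLOOR)
            f_new, grad_new = ws.criterion(trial, want_grad=True)
            if f_new <= f_cur + 1e-12:
                gamma, f_cur, grad = trial, f_new, grad_new
                improved = True
                break
            scale *= 0.5
        n_iter += 1
        if not improved:
            break

    interior = gamma > 10 * _GAMMA_FLOOR
    gnorm = float(np.max(np.abs(grad[interior]))) if interior.any() else 0.0
    converged = bool(best.success or gnorm < 1e-6)
    return gamma, f_cur, n_iter, converged, gnorm
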