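"""REML estimation of Gaussian mixed models with scalar random effects.

The model is y = X b + sum_k Z_k u_k + e with u_k ~ N(0, sigma2_k I) for each
grouping factor k and e ~ N(0, sigma2_res I), so V = sum_k sigma2_k Z_k Z_k'
+ sigma2_res I.  The restricted log-likelihood

    l_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y + (n - p) log(2 pi) ],
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1,

is maximised over log-variances (an unconstrained parametrisation that avoids
boundary clamping mid-run) by L-BFGS-B with analytic gradients, then polished
with average-information Newton steps.  The asymptotic covariance of the
variance estimates is the inverse average-information matrix at the optimum,

    AI_jk = 1/2 (P y)' G_j P G_k (P y),   G_k = Z_k Z_k',

which feeds the delta-method standard errors downstream.  Fixed effects are
GLS at the optimum with covariance (X' V^-1 X)^-1.

Dense linear algebra throughout: the study-scale problems (a few hundred to a
couple of thousand observations) never need sparse solvers.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

RESIDUAL = "residual"


class ConvergenceError(RuntimeError):
    """The REML optimiser failed to reach a stationary point."""


@dataclass
class MixedModelSpec:
    """Response, fixed-effect and random-effect structure of one model.

    Fixed terms use mini-formula tokens: ``"1"`` intercept, ``"C(col)"``
    factor coding (first level dropped), ``"z(col)"`` standardised numeric,
    any other token a numeric (or object, auto-factor) column.  Random terms
    are grouping-factor column names; the measurement-level residual is
    implicit.
    """

    response: str
    fixed_terms: Sequence[str] = ("1",)
    random_terms: Sequence[str] = ("population_id",)

    def __post_init__(self) -> None:
        if len(set(self.fixed_terms)) != len(self.fixed_terms):
            raise ValueError("duplicate fixed terms")
        if len(set(self.random_terms)) != len(self.random_terms):
            raise ValueError("duplicate random terms")
        if RESIDUAL in self.random_terms:
            raise ValueError("residual is implicit; do not list it")


@dataclass
class VarianceComponents:
    """Named REML variance estimates with their covariance and the fit."""

    estimates: dict[str, float]
    vc_cov: pd.DataFrame
    reml_loglik: float
    fixed_estimates: dict[str, tuple[float, float]]
    n_obs: int
    spec: MixedModelSpec | None = None
    converged: bool = True
    dropped_fixed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if RESIDUAL not in self.estimates:
            raise ValueError("estimates must include the residual component")

    def vc_cov_block(self, terms: Sequence[str]) -> np.ndarray:
        return self.vc_cov.loc[list(terms), list(terms)].to_numpy()


_TOKEN_C = re.compile(r"C\((\w+)\)")
_TOKEN_Z = re.compile(r"z\((\w+)\)")


def build_design(
    data: pd.DataFrame, spec: MixedModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, np.ndarray]]:
    """Build (y, X, fixed column names, random factor codes) from a table.

    Rows with a missing response are dropped.  Aliased fixed columns are
    removed greedily left-to-right in declaration order.
    """
    df = data.loc[data[spec.response].notna()].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no non-missing values for response {spec.response!r}")
    y = df[spec.response].to_numpy(dtype=float)

    cols: list[np.ndarray] = []
    names: list[str] = []
    for term in spec.fixed_terms:
        if term in ("1", "intercept"):
            cols.append(np.ones(len(df)))
            names.append("intercept")
            continue
        m = _TOKEN_C.fullmatch(term)
        if m is None and term in df.columns and df[term].dtype == object:
            m = _TOKEN_C.fullmatch(f"C({term})")
        if m:
            col = m.group(1)
            levels = sorted(pd.unique(df[col]).tolist())
            for lev in levels[1:]:
                cols.append((df[col] == lev).to_numpy(dtype=float))
                names.append(f"{col}[{lev}]")
            continue
        m = _TOKEN_Z.fullmatch(term)
        if m:
            v = df[m.group(1)].to_numpy(dtype=float)
            sd = v.std(ddof=1)
            cols.append((v - v.mean()) / sd if sd > 0 else np.zeros_like(v))
            names.append(f"z({m.group(1)})")
            continue
        cols.append(df[term].to_numpy(dtype=float))
        names.append(term)

    X = np.column_stack(cols) if cols else np.ones((len(df), 1))
    keep: list[int] = []
    dropped: list[str] = []
    rank = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, keep + [j]])
        if r > rank:
            keep.append(j)
            rank = r
        else:
            dropped.append(names[j])
    if dropped:
        warnings.warn(f"dropped aliased fixed columns: {dropped}", stacklevel=2)
    X = X[:, keep]
    names = [names[j] for j in keep]

    random: dict[str, np.ndarray] = {}
    for term in spec.random_terms:
        codes, levels = pd.factorize(df[term])
        if len(levels) < 2:
            raise ValueError(f"random factor {term!r} has fewer than 2 levels")
        random[term] = codes
    return y, X, names, random


def _indicator(codes: np.ndarray) -> np.ndarray:
    q = int(codes.max()) + 1
    Z = np.zeros((len(codes), q))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


class _RemlProblem:
    def __init__(self, y: np.ndarray, X: np.ndarray, Gs: list[np.ndarray]):
        self.y = y
        self.X = X
        self.Gs = Gs  # excludes residual; G_res = I implicit
        self.n, self.p = X.shape
        self.K = len(Gs)

    def _decompose(self, s2: np.ndarray):
        n = self.n
        V = np.eye(n) * s2[-1]
        for k, G in enumerate(self.Gs):
            V += s2[k] * G
        c, low = linalg.cho_factor(V, lower=True)
        logdetV = 2.0 * np.log(np.diag(c)).sum()
        Vinv = linalg.cho_solve((c, low), np.eye(n))
        ViX = Vinv @ self.X
        XtViX = self.X.T @ ViX
        cx = linalg.cho_factor(XtViX)
        logdetX = 2.0 * np.log(np.diag(cx[0])).sum()
        beta = linalg.cho_solve(cx, ViX.T @ self.y)
        r = Vinv @ self.y - ViX @ beta  # P y
        P = Vinv - ViX @ linalg.cho_solve(cx, ViX.T)
        return logdetV, logdetX, beta, r, P, XtViX

    def loglik(self, s2: np.ndarray) -> float:
        logdetV, logdetX, _, r, _, _ = self._decompose(s2)
        yPy = float(self.y @ r)
        return -0.5 * (
            logdetV + logdetX + yPy + (self.n - self.p) * np.log(2 * np.pi)
        )

    def loglik_grad(self, s2: np.ndarray):
        logdetV, logdetX, beta, r, P, XtViX = self._decompose(s2)
        yPy = float(self.y @ r)
        ll = -0.5 * (
            logdetV + logdetX + yPy + (self.n - self.p) * np.log(2 * np.pi)
        )
        grad = np.empty(self.K + 1)
        for k, G in enumerate(self.Gs):
            grad[k] = -0.5 * (np.sum(P * G) - r @ (G @ r))
        grad[-1] = -0.5 * (np.trace(P) - r @ r)
        return ll, grad, beta, r, P, XtViX

    def average_information(self, s2: np.ndarray, r: np.ndarray, P: np.ndarray):
        s = [G @ r for G in self.Gs] + [r]
        m = len(s)
        AI = np.empty((m, m))
        for j in range(m):
            Ps = P @ s[j]
            for k in range(j, m):
                AI[j, k] = AI[k, j] = 0.5 * float(s[k] @ Ps)
        return AI


def reml_fit(
    data: pd.DataFrame,
    spec: MixedModelSpec,
    max_iter: int = 200,
    grad_tol: float = 1e-5,
) -> VarianceComponents:
    """Fit a Gaussian mixed model by REML.

    Parameters
    ----------
    data
        Table holding the response, fixed-effect columns and grouping labels
        (typically a TraitTable's frame or a per-individual means table).
    spec
        Model structure.
    max_iter, grad_tol
        Optimiser budget and gradient-norm criterion (log-variance scale).

    Returns the variance estimates (a component below 1e-10 x residual is
    reported as 0), their average-information covariance, the restricted
    log-likelihood, and GLS fixed-effect estimates with standard errors.
    """
    y, X, fixed_names, random = build_design(data, spec)
    Gs = []
    for term in spec.random_terms:
        Z = _indicator(random[term])
        Gs.append(Z @ Z.T)
    prob = _RemlProblem(y, X, Gs)
    K = prob.K

    # method-of-moments start: split the OLS residual variance
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    scale = max(float(resid.var(ddof=min(X.shape[1], len(y) - 1))), 1e-12)
    s2_0 = np.full(K + 1, scale * 0.5 / max(K, 1))
    s2_0[-1] = scale * 0.5
    lo = np.log(scale) - 23.0  # ~1e-10 x data scale
    hi = np.log(scale) + 12.0
    phi0 = np.clip(np.log(s2_0), lo + 1.0, hi - 1.0)

    def nll(phi: np.ndarray):
        s2 = np.exp(phi)
        ll, grad, *_ = prob.loglik_grad(s2)
        return -ll, -(grad * s2)

    res = optimize.minimize(
        nll,
        phi0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(lo, hi)] * (K + 1),
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9},
    )
    phi = res.x

    # average-information Newton polish (quadratic convergence near optimum)
    ll, grad, beta, r, P, XtViX = prob.loglik_grad(np.exp(phi))
    stalled = False
    for _ in range(50):
        s2 = np.exp(phi)
        g_phi = grad * s2
        free = (phi > lo + 1e-9) | (g_phi > 0)
        if np.linalg.norm(g_phi[free]) < 1e-10:
            break
        AI = prob.average_information(s2, r, P)
        AI_phi = AI * np.outer(s2, s2) + np.eye(K + 1) * 1e-12
        try:
            step = np.linalg.solve(AI_phi, g_phi)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -2.0, 2.0)
        improved = False
        for _try in range(8):
            cand = np.clip(phi + step, lo, hi)
            ll_new, grad_new, beta_n, r_n, P_n, XtViX_n = prob.loglik_grad(
                np.exp(cand)
            )
            if ll_new >= ll - 1e-13:
                phi, ll, grad = cand, ll_new, grad_new
                beta, r, P, XtViX = beta_n, r_n, P_n, XtViX_n
                improved = True
                break
            step *= 0.5
        if not improved:
            # the log-likelihood can no longer be improved at double precision
            stalled = True
            break

    s2 = np.exp(phi)
    g_phi = grad * s2
    # a component that has collapsed to (numerically) zero counts as a
    # boundary optimum unless the gradient pulls it back up
    boundary = (phi < lo + 1e-9) | (s2 < 1e-5 * scale)
    gnorm = float(
        np.linalg.norm(np.where(boundary, np.maximum(g_phi, 0), g_phi))
    )
    # a stalled line search means the log-likelihood is flat to double
    # precision; accept it if the gradient is small, if not tiny
    converged = gnorm < grad_tol or (stalled and gnorm < 1e-3)
    if not converged:
        raise ConvergenceError(
            f"REML did not converge: |grad| = {gnorm:.3e} after polish "
            f"(L-BFGS-B status: {res.message})"
        )

    AI = prob.average_information(s2, r, P)
    try:
        vc_cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        vc_cov = np.linalg.pinv(AI)

    terms = list(spec.random_terms) + [RESIDUAL]
    estimates = dict(zip(terms, s2))
    res_var = estimates[RESIDUAL]
    for t in spec.random_terms:
        if estimates[t] < 1e-10 * res_var:
            estimates[t] = 0.0

    se_beta = np.sqrt(np.diag(np.linalg.inv(XtViX)))
    fixed = {
        name: (float(b), float(se))
        for name, b, se in zip(fixed_names, beta, se_beta)
    }
    return VarianceComponents(
        estimates={k: float(v) for k, v in estimates.items()},
        vc_cov=pd.DataFrame(vc_cov, index=terms, columns=terms),
        reml_loglik=float(ll),
        fixed_estimates=fixed,
        n_obs=prob.n,
        spec=spec,
        converged=converged,
    )


def lrt_random_effect(
    full: VarianceComponents, reduced: VarianceComponents
) -> tuple[float, float]:
    """Likelihood-ratio test for one random effect, chi-square with 1 df.

    The reduced model must drop exactly one random term from the full model,
    with identical fixed effects and data.  The statistic is clipped at zero;
    no boundary correction is applied (the 1-df reference is conservative for
    a variance on the boundary).
    """
    if full.spec is None or reduced.spec is None:
        raise ValueError("fits must carry their MixedModelSpec")
    f_terms = set(full.spec.random_terms)
    r_terms = set(reduced.spec.random_terms)
    if not (r_terms < f_terms and len(f_terms - r_terms) == 1):
        raise ValueError("reduced model must drop exactly one random term")
    if tuple(full.spec.fixed_terms) != tuple(reduced.spec.fixed_terms):
        raise ValueError("fixed effects differ between models")
    if full.n_obs != reduced.n_obs:
        raise ValueError("models fit to different data")
    chi2 = max(0.0, 2.0 * (full.reml_loglik - reduced.reml_loglik))
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return chi2, p


def wald_fixed_effect(
    fit: VarianceComponents, term: str
) -> tuple[float, float]:
    """Wald chi-square test (1 df) for a fixed-effect estimate."""
    if term not in fit.fixed_estimates:
        raise ValueError(f"no fixed term {term!r} in fit")
    est, se = fit.fixed_estimates[term]
    if se == 0.0:
        raise ValueError(f"degenerate fit: zero SE for {term!r}")
    chi2 = (est / se) ** 2
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
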