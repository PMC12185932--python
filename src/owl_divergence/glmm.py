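"""Binomial logit mixed model for the colour morph, on the latent scale.

The morph (brown = 1, grey = 0; one observation per individual) is modelled
as Bernoulli with logit link, an intercept, and independent random intercepts
per grouping factor (population, year).  The marginal likelihood is
approximated by the Laplace method: for candidate variances, the joint mode
of (intercept, random effects) is found by penalised iteratively reweighted
least squares, and

    l(sigma2) ~= log f(y | mode) - 1/2 u' D^-1 u - 1/2 log|I + D Z' W Z|

is maximised over log-variances.  Standard errors for the variances come from
the numerically differentiated Hessian of the Laplace log-likelihood; the
significance of a variance is reported as the Z ratio estimate/SE with a
one-sided normal tail (the alternative is sigma2 > 0).

The latent-scale variance proportion adds the logit distribution-specific
variance pi^2/3 to the denominator, so for the focal (population) component

    prop = sigma2_pop / (sigma2_pop + sum(other sigma2) + pi^2/3).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

LOGIT_LINK_VARIANCE = math.pi**2 / 3.0


@dataclass
class LatentFit:
    """Intercept and logit-scale random-effect variances with uncertainty."""

    intercept: float
    intercept_se: float
    sigma2: dict[str, float]
    sigma2_se: dict[str, float]
    loglik: float
    n_individuals: int
    z_ratio: dict[str, float] = field(default_factory=dict)
    p_value: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.sigma2.items():
            if v < 0:
                raise ValueError(f"negative variance for {k}")
        if not self.z_ratio:
            for k in self.sigma2:
                se = self.sigma2_se.get(k, float("nan"))
                z = self.sigma2[k] / se if se and se > 0 else float("nan")
                self.z_ratio[k] = z
                self.p_value[k] = (
                    float(stats.norm.sf(z)) if np.isfinite(z) else float("nan")
                )


def _laplace_loglik(
    s2: np.ndarray,
    y: np.ndarray,
    Zs: list[np.ndarray],
    state: dict,
) -> float:
    n = len(y)
    M = np.column_stack([np.ones(n)] + [Z for Z in Zs])
    qs = [Z.shape[1] for Z in Zs]
    pen = np.concatenate([[0.0]] + [np.full(q, 1.0 / v) for q, v in zip(qs, s2)])

    delta = state.get("delta")
    if delta is None or len(delta) != M.shape[1]:
        delta = np.zeros(M.shape[1])

    def penalised(d: np.ndarray) -> float:
        eta = M @ d
        return float(y @ eta - np.logaddexp(0, eta).sum() - 0.5 * (pen * d * d).sum())

    f = penalised(delta)
    for _ in range(200):
        eta = M @ delta
        mu = special.expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        H = (M.T * w) @ M + np.diag(pen)
        g = M.T @ (y - mu) - pen * delta
        if np.max(np.abs(g)) < 1e-10:
            break
        step = np.linalg.solve(H, g)
        for _try in range(30):
            cand = delta + step
            fc = penalised(cand)
            if fc >= f - 1e-12:
                delta, f = cand, fc
                break
            step *= 0.5
        else:
            break
    state["delta"] = delta

    eta = M @ delta
    mu = special.expit(eta)
    w = mu * (1.0 - mu) + 1e-12
    u = delta[1:]
    logf = float(y @ eta - np.logaddexp(0, eta).sum())
    quad = 0.5 * float((pen[1:] * u * u).sum())
    # log|I + D Z'WZ| over the stacked random-effect block
    Zall = M[:, 1:]
    D = np.concatenate([np.full(q, v) for q, v in zip(qs, s2)])
    B = np.eye(len(D)) + (Zall.T * w) @ Zall * D[None, :]
    sign, logdet = np.linalg.slogdet(B)
    state["H"] = (M.T * w) @ M + np.diag(pen)
    return logf - quad - 0.5 * logdet


def glmm_binomial_fit(
    morph: Sequence[int] | np.ndarray,
    groups: Mapping[str, Sequence],
    max_iter: int = 200,
) -> LatentFit:
    """Fit the binomial logit mixed model by Laplace approximation.

    Parameters
    ----------
    morph
        Binary response per individual ({0, 1}).
    groups
        Mapping term name -> group label per individual (e.g. population and
        year); each term contributes one scalar random-intercept variance.

    A population entirely 0 or 1 with few individuals can push its effect to
    the boundary (complete separation); a warning is emitted and the variance
    estimate may be unstable.
    """
    y = np.asarray(morph, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("morph must be coded {0, 1}")
    if not groups:
        raise ValueError("at least one grouping factor required")
    terms = list(groups)
    Zs = []
    for t in terms:
        codes, levels = pd.factorize(pd.Series(list(groups[t])))
        if t == terms[0] and len(levels) < 2:
            raise ValueError(f"grouping factor {t!r} has fewer than 2 levels")
        Z = np.zeros((len(y), len(levels)))
        Z[np.arange(len(y)), codes] = 1.0
        Zs.append(Z)

    pop_labels = np.asarray(list(groups[terms[0]]))
    for lab in np.unique(pop_labels):
        sel = y[pop_labels == lab]
        if len(sel) <= 5 and (sel.min() == sel.max()):
            warnings.warn(
                f"group {lab!r} shows complete separation (n={len(sel)}); "
                "variance estimate may sit at the boundary",
                stacklevel=2,
            )
            break

    state: dict = {}
    lo, hi = -15.0, 5.0

    def nll(phi: np.ndarray) -> float:
        return -_laplace_loglik(np.exp(phi), y, Zs, state)

    res = optimize.minimize(
        nll,
        np.full(len(terms), -1.0),
        method="L-BFGS-B",
        bounds=[(lo, hi)] * len(terms),
        options={"maxiter": max_iter, "ftol": 1e-12},
    )
    phi = res.x
    s2 = np.exp(phi)
    ll = -nll(phi)

    # SEs from the numerical Hessian of the Laplace log-likelihood in sigma2
    se = np.full(len(terms), np.nan)
    steps = np.maximum(0.1 * s2, 1e-4)
    m = len(terms)
    H = np.zeros((m, m))
    f0 = -ll

    def f_at(v: np.ndarray) -> float:
        return -_laplace_loglik(np.maximum(v, 1e-12), y, Zs, dict(state))

    for j in range(m):
        for k in range(j, m):
            ej = np.eye(m)[j] * steps[j]
            ek = np.eye(m)[k] * steps[k]
            if j == k:
                H[j, j] = (f_at(s2 + ej) - 2 * f0 + f_at(s2 - ej)) / steps[j] ** 2
            else:
                H[j, k] = H[k, j] = (
                    f_at(s2 + ej + ek)
                    - f_at(s2 + ej - ek)
                    - f_at(s2 - ej + ek)
                    + f_at(s2 - ej - ek)
                ) / (4 * steps[j] * steps[k])
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        se = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        d = np.diag(H)
        se = np.where(d > 0, 1.0 / np.sqrt(d), np.nan)

    Hjoint = state["H"]
    try:
        intercept_se = float(np.sqrt(np.linalg.inv(Hjoint)[0, 0]))
    except np.linalg.LinAlgError:
        intercept_se = float("nan")
    intercept = float(state["delta"][0])

    return LatentFit(
        intercept=intercept,
        intercept_se=intercept_se,
        sigma2={t: float(v) for t, v in zip(terms, s2)},
        sigma2_se={t: float(v) for t, v in zip(terms, se)},
        loglik=float(ll),
        n_individuals=len(y),
    )


def latent_scale_proportion(
    sigma2_focal: float, sigma2_other: Mapping[str, float] | None = None
) -> float:
    """Proportion of latent-scale variance attributable to the focal term.

    Adds the logit distribution-specific variance pi^2/3 to the denominator,
    so the result is strictly below sigma2_focal / (sigma2_focal + others).
    """
    sigma2_other = sigma2_other or {}
    if sigma2_focal < 0 or any(v < 0 for v in sigma2_other.values()):
        raise ValueError("variances must be >= 0")
    denom = sigma2_focal + sum(sigma2_other.values()) + LOGIT_LINK_VARIANCE
    return sigma2_focal / denom


def latent_proportion_se(
    sigma2_focal: float,
    sigma2_other: Mapping[str, float],
    se_focal: float,
) -> float:
    """Delta-method SE of the latent proportion in its focal variance.

    Only the focal variance's uncertainty is propagated (the study-style
    report treats the other components as fixed in this ratio).
    """
    rest = sum(sigma2_other.values()) + LOGIT_LINK_VARIANCE
    grad = rest / (sigma2_focal + rest) ** 2
    return abs(grad) * se_focal
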