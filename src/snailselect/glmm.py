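"""Binomial (logit) mixed models with random intercepts, fitted by Laplace
approximation.

The marginal likelihood ``L(beta, sigma) = ∫ f(y | beta, u) phi(u; 0, D) du``
(with one i.i.d. Gaussian random-intercept vector per grouping factor,
``D = blockdiag(sigma_f^2 I)``) is approximated by Laplace's method around the
conditional mode of ``u``:

    log L  ≈  h(beta, u_hat) + (q/2) log 2π − ½ log det(−H_uu),

where ``h`` is the joint (penalised) log-likelihood and ``H_uu`` its Hessian
in ``u``.  The outer optimisation runs over the fixed effects and the log
random-effect SDs; the inner problem (the mode ``u_hat``) is solved by Newton
iteration, which is globally well-behaved for the Bernoulli-logit family.
Wald standard errors come from the fixed-effect block of the inverse joint
Hessian at the optimum, matching the convention of lme4's ``glmer``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_SEPARATION_BOUND = 10.0  # |logit-scale coefficient| beyond this flags separation
# inner tolerance far below the outer finite-difference step, so the Laplace
# objective is smooth to the optimiser
_INNER_TOL = 1e-10


@dataclass
class GlmmResult:
    """Coefficient table and variance components of one mixed-model fit."""

    table: pd.DataFrame  # columns: term, estimate, se, z, p
    random_variances: dict[str, float]
    converged: bool
    flags: list[str] = field(default_factory=list)
    loglik: float = float("nan")

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "se"])


def _encode_groups(groups: dict[str, np.ndarray]) -> tuple[np.ndarray, list[int], list[str]]:
    """Map grouping factors to 0-based level indices, concatenated."""
    idx_cols, sizes, names = [], [], []
    for name, g in groups.items():
        _, idx = np.unique(np.asarray(g), return_inverse=True)
        idx_cols.append(idx)
        sizes.append(int(idx.max()) + 1 if idx.size else 0)
        names.append(name)
    return np.column_stack(idx_cols) if idx_cols else np.empty((0, 0), int), sizes, names


def _linear_predictor(X, beta, u, gidx, offsets):
    eta = X @ beta
    for f in range(gidx.shape[1] if gidx.size else 0):
        eta = eta + u[offsets[f] + gidx[:, f]]
    return eta


def _pen_ll(X, y, beta, u, gidx, offsets, prec):
    eta = _linear_predictor(X, beta, u, gidx, offsets)
    return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * (prec * u * u).sum())


def _inner_mode(X, y, beta, gidx, offsets, prec, q):
    """Damped Newton iteration for the conditional mode of the random effects.

    Always starts from u = 0 so the Laplace objective is a deterministic,
    smooth function of the outer parameters.
    """
    u = np.zeros(q)
    if q == 0:
        eta = X @ beta
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        return u, ll, np.empty((0, 0)), True
    nfac = gidx.shape[1]
    ok = False
    H = np.zeros((q, q))
    obj = _pen_ll(X, y, beta, u, gidx, offsets, prec)
    for _ in range(200):
        eta = _linear_predictor(X, beta, u, gidx, offsets)
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = mu * (1.0 - mu)
        resid = y - mu
        grad = np.zeros(q)
        H[:] = 0.0
        for f in range(nfac):
            np.add.at(grad, offsets[f] + gidx[:, f], resid)
            np.add.at(H, (offsets[f] + gidx[:, f], offsets[f] + gidx[:, f]), w)
            for f2 in range(f + 1, nfac):
                np.add.at(
                    H, (offsets[f] + gidx[:, f], offsets[f2] + gidx[:, f2]), w
                )
        H = H + H.T - np.diag(np.diag(H))
        grad -= prec * u
        H += np.diag(prec)
        step = np.linalg.solve(H, grad)
        # backtracking keeps the iteration globally convergent
        scale = 1.0
        for _half in range(30):
            cand = u + scale * step
            cand_obj = _pen_ll(X, y, beta, cand, gidx, offsets, prec)
            if cand_obj >= obj - 1e-14:
                break
            scale *= 0.5
        u, obj = cand, cand_obj
        if np.max(np.abs(scale * step)) < _INNER_TOL:
            ok = True
            break
    return u, obj, H, ok


def _laplace_negloglik(params, X, y, gidx, sizes, offsets):
    p = X.shape[1]
    beta = params[:p]
    log_sd = params[p:]
    sd = np.exp(log_sd)
    prec = np.concatenate(
        [np.full(sizes[f], 1.0 / max(sd[f] ** 2, 1e-12)) for f in range(len(sizes))]
    ) if sizes else np.empty(0)
    q = int(np.sum(sizes)) if sizes else 0
    u, pen_ll, H, ok = _inner_mode(X, y, beta, gidx, offsets, prec, q)
    if q:
        # log det of the penalised Hessian and the prior normalising constant
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return 1e10
        ll = pen_ll - 0.5 * logdet - float(np.log(sd[: len(sizes)]).repeat(sizes).sum())
        # phi normalisation: -(q/2)log2pi - sum log sd; Laplace adds +(q/2)log2pi
    else:
        ll = pen_ll
    return -ll


def fit_binomial_glmm(
    X: np.ndarray,
    y: np.ndarray,
    groups: dict[str, np.ndarray],
    term_names: list[str],
) -> GlmmResult:
    """Fit a Bernoulli-logit mixed model with random intercepts.

    Parameters
    ----------
    X : (n, p) design matrix for the fixed effects (include the intercept).
    y : (n,) binary response.
    groups : mapping factor name -> length-n grouping labels; each factor
        contributes one random-intercept vector.
    term_names : names for the p fixed-effect columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    flags: list[str] = []

    if np.all(y == y[0]):
        flags.append("degenerate response: all outcomes identical (separation)")
    gidx, sizes, gnames = _encode_groups(groups)
    # drop single-level factors: their intercept is confounded with the global one
    keep = [f for f, s in enumerate(sizes) if s >= 2]
    if len(keep) < len(sizes):
        dropped = [gnames[f] for f in range(len(sizes)) if f not in keep]
        flags.append(f"random effect dropped (single level): {dropped}")
        gidx = gidx[:, keep] if gidx.size else gidx
        gnames = [gnames[f] for f in keep]
        sizes = [sizes[f] for f in keep]
    offsets = np.concatenate(([0], np.cumsum(sizes)))[: len(sizes)].astype(int) if sizes else []
    q = int(np.sum(sizes))

    x0 = np.concatenate([np.zeros(p), np.full(len(sizes), np.log(0.5))])
    res = optimize.minimize(
        _laplace_negloglik,
        x0,
        args=(X, y, gidx, sizes, offsets),
        method="L-BFGS-B",
        bounds=[(-30, 30)] * p + [(-6, 3)] * len(sizes),
        options={"maxiter": 500, "ftol": 1e-12, "eps": 1e-5},
    )
    beta = res.x[:p]
    sd = np.exp(res.x[p:])

    # Wald SEs from the fixed-effect block of the inverse joint Hessian
    prec = np.concatenate(
        [np.full(sizes[f], 1.0 / max(sd[f] ** 2, 1e-12)) for f in range(len(sizes))]
    ) if sizes else np.empty(0)
    u, _, _, _ = _inner_mode(X, y, beta, gidx, offsets, prec, q)
    eta = _linear_predictor(X, beta, u, gidx, offsets)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    Z = np.zeros((n, q))
    for f in range(len(sizes)):
        Z[np.arange(n), offsets[f] + gidx[:, f]] = 1.0
    XZ = np.hstack([X, Z])
    Hj = (XZ * w[:, None]).T @ XZ
    if q:
        Hj[p:, p:] += np.diag(prec)
    try:
        cov = np.linalg.inv(Hj)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        flags.append("singular information matrix")

    if np.any(np.abs(beta) > _SEPARATION_BOUND):
        flags.append("possible complete separation: |coefficient| > 10 on logit scale")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {"term": term_names, "estimate": beta, "se": se, "z": z, "p": pvals}
    )
    return GlmmResult(
        table=table,
        random_variances={name: float(s**2) for name, s in zip(gnames, sd)},
        converged=bool(res.success),
        flags=flags,
        loglik=-float(res.fun),
    )
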