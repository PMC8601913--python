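"""Bayesian fitting of the multistate dead-recovery selection model.

The sampler is an adaptive Metropolis-within-Gibbs scheme: correlated
parameter groups (selection gradients per stage, month-effect vectors,
demographic rates, detection intercepts and slopes) are updated as
random-walk blocks whose proposal scales adapt toward standard acceptance
targets during burn-in and are frozen afterwards; the per-individual
heterogeneity vectors are updated elementwise in a single vectorised pass
(valid because the likelihood factorises over individuals given the global
parameters); variance components are updated against their conditional
(prior x random-effect) densities, which do not involve the encounter
likelihood; the transition-rate mean has a conjugate normal Gibbs update.

The likelihood is the batch forward algorithm of
:mod:`snailselect.model.likelihood`.  All randomness flows from the config
seed through a ``numpy.random.SeedSequence`` spawn per chain, so repeated
runs are bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from snailselect.records import EncounterHistory
from snailselect.model.params import McmcConfig, PriorConfig
from snailselect.model.spline import knot_count, knot_positions, spline_basis
from snailselect.model.likelihood import loglik_all

_TARGET_BLOCK = 0.234
_TARGET_SCALAR = 0.44


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p) - np.log1p(-p)


def default_months(T: int, start_month: int = 2) -> np.ndarray:
    """Calendar months (1..12) for T consecutive monthly occasions.

    Defaults to a February start, the month the mainland survey began.
    """
    return ((np.arange(T) + start_month - 1) % 12) + 1


@dataclass
class McmcFit:
    """Posterior draws and metadata of one model fit."""

    draws: pd.DataFrame  # one row per retained draw; 'chain' column
    model: str  # "quadratic" | "spline"
    config: McmcConfig
    knots: np.ndarray | None
    colour_range: tuple[float, float]
    n_individuals: int
    converged: bool
    rhat_max: float
    param_names: list[str] = dc_field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return posterior_summary(self.draws)

    def curve(self, grid: np.ndarray, stage: str = "adult") -> pd.DataFrame:
        return spline_curve(self, grid, stage=stage)


def _split_rhat(x: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction on split chains.

    ``x`` has shape (chains, draws); each chain is split in half before
    computing the between/within variance ratio.
    """
    m, n = x.shape
    half = n // 2
    if half < 2:
        return float("nan")
    chains = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    W = chains.var(axis=1, ddof=1).mean()
    B = half * chains.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0 if B <= 1e-300 else float("inf")
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))


def posterior_summary(draws: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter median, SD, 95% BCI, split R-hat and sign fraction.

    The ``frac_negative`` column is the fraction of posterior draws below
    zero — the quantity behind statements like "94.2% of the gamma values
    were negative".
    """
    if len(draws) == 0:
        raise ValueError("no draws to summarise")
    cols = [c for c in draws.columns if c != "chain"]
    chains = draws["chain"].to_numpy() if "chain" in draws else np.zeros(len(draws))
    chain_ids = np.unique(chains)
    rows = []
    for c in cols:
        v = draws[c].to_numpy(dtype=float)
        per_chain = [v[chains == cid] for cid in chain_ids]
        n_min = min(len(p) for p in per_chain)
        stacked = np.stack([p[:n_min] for p in per_chain])
        rhat = _split_rhat(stacked) if len(chain_ids) > 1 else _split_rhat(
            stacked.reshape(1, -1)
        )
        rows.append(
            {
                "parameter": c,
                "median": float(np.median(v)),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "q2.5": float(np.quantile(v, 0.025)),
                "q97.5": float(np.quantile(v, 0.975)),
                "rhat": rhat,
                "frac_negative": float(np.mean(v < 0)),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def _prepare(histories: Sequence[EncounterHistory], months: np.ndarray):
    T = len(histories[0].codes)
    N = len(histories)
    codes = np.zeros((N, T), dtype=np.int64)
    first = np.zeros(N, dtype=np.int64)
    stage0 = np.zeros(N, dtype=np.int64)
    col = np.zeros(N)
    for i, h in enumerate(histories):
        if len(h.codes) != T:
            raise ValueError("all histories must cover the same occasions")
        codes[i] = np.asarray(h.codes, dtype=np.int64) - 1  # to 0-based
        first[i] = h.first_capture - 1
        stage0[i] = 0 if h.stage_at_first == "juvenile" else 1
        col[i] = h.colour
    month0 = np.asarray(months, dtype=np.int64) - 1
    if month0.shape != (T,):
        raise ValueError(f"months must have length {T}")
    return codes, first, stage0, month0, col


class _Chain:
    """One MCMC chain: holds state, proposal scales and the likelihood cache."""

    def __init__(self, data, model, knots, basis, priors, rng):
        self.codes, self.first, self.stage0, self.month0, self.col = data
        self.N = self.col.size
        self.model = model
        self.knots = knots
        self.basis = basis  # (N, P+K) for the spline model, else None
        self.priors = priors
        self.rng = rng
        N = self.N
        # calendar months that actually index an inter-occasion interval;
        # month parameters outside this set carry no information and are
        # pinned at zero rather than sampled from the prior
        self.mobs = np.zeros(12, dtype=bool)
        self.mobs[np.unique(self.month0[1:])] = True

        # --- initial state (modestly overdispersed across chains) ---
        nr = rng.normal
        if model == "quadratic":
            self.th = {s: np.array([nr(1.5, 0.5), nr(0, 0.3), nr(0, 0.3)]) for s in "JA"}
        else:
            ncoef = 3 + knots.size
            self.th = {
                s: np.concatenate([[nr(1.5, 0.5)], nr(0, 0.1, size=ncoef)])
                for s in "JA"
            }
            self.sig_b = {s: float(rng.uniform(0.2, 1.0)) for s in "JA"}
        self.B = {s: np.zeros(12) for s in "JA"}
        self.sig_eps = {s: float(rng.uniform(0.2, 0.8)) for s in "JA"}
        self.sig_B = {s: float(rng.uniform(0.2, 0.8)) for s in "JA"}
        self.lm = np.array([_logit(0.05), _logit(0.05), _logit(0.9)]) + nr(0, 0.3, 3)
        self.psi_l = np.where(self.mobs, nr(-1.5, 0.3, size=12), 0.0)
        self.mu_psi = float(nr(-1.5, 0.3))
        self.sig_psi = float(rng.uniform(0.2, 0.8))
        self.a = np.where(self.mobs, nr(0, 0.3, size=12), 0.0)
        self.g = np.where(self.mobs, nr(0, 0.3, size=12), 0.0)
        self.d = nr(0, 0.2, size=2)
        self.sig_rp = float(rng.uniform(0.2, 0.8))
        self.eps = {s: np.zeros(N) for s in "JA"}
        self.eps_rp = np.zeros(N)

        self.scales = {
            "th_J": 0.1, "th_A": 0.1, "B_J": 0.05, "B_A": 0.05,
            "lm": 0.2, "psi_l": 0.2, "a": 0.1, "g": 0.1, "d": 0.1,
            "eps_J": 0.5, "eps_A": 0.5, "eps_rp": 0.5,
            "sc_eps_J": 0.3, "sc_eps_A": 0.3, "sc_B_J": 0.3, "sc_B_A": 0.3,
            "sc_rp": 0.3,
        }
        self.llv = self._loglik()

    # ---- likelihood plumbing -------------------------------------------
    def _eta(self, stage, th=None):
        th = self.th[stage] if th is None else th
        if self.model == "quadratic":
            return th[0] + th[1] * self.col + 0.5 * th[2] * self.col**2
        return th[0] + self.basis @ th[1:]

    def _loglik(self, **over):
        def get(name, default):
            return over.get(name, default)

        m = _expit(get("lm", self.lm))
        return loglik_all(
            self.codes, self.first, self.stage0, self.month0,
            get("eta_J", self._eta("J")), get("eta_A", self._eta("A")),
            get("eps_J", self.eps["J"]), get("eps_A", self.eps["A"]),
            get("B_J", self.B["J"]), get("B_A", self.B["A"]),
            m[0], m[1], m[2],
            _expit(get("psi_l", self.psi_l)),
            get("a", self.a), get("g", self.g),
            get("d", self.d)[0], get("d", self.d)[1],
            self.col, get("eps_rp", self.eps_rp),
        )

    # ---- generic Metropolis moves --------------------------------------
    def _accept(self, key, log_ratio):
        acc = np.log(self.rng.uniform()) < log_ratio
        return bool(acc)

    def _adapt(self, key, acc_rate, it, target):
        step = min(0.1, 3.0 / np.sqrt(it + 10))
        self.scales[key] = float(
            np.exp(np.log(self.scales[key]) + step * (acc_rate - target))
        )

    def _block(self, key, current, logprior, make_over, it, adapting, mask=None):
        step = self.scales[key] * self.rng.normal(size=np.shape(current))
        if mask is not None:
            step = np.where(mask, step, 0.0)
        prop = current + step
        lp0, lp1 = logprior(current), logprior(prop)
        if not np.isfinite(lp1):
            acc = False
        else:
            llv1 = self._loglik(**make_over(prop))
            ratio = llv1.sum() - self.llv.sum() + lp1 - lp0
            acc = self._accept(key, ratio)
            if acc:
                self.llv = llv1
        if adapting:
            self._adapt(key, 1.0 if acc else 0.0, it, _TARGET_BLOCK)
        return prop if acc else current, acc

    def _elementwise(self, key, vec, sigma, over_name, it, adapting):
        prop = vec + self.scales[key] * self.rng.normal(size=vec.size)
        llv1 = self._loglik(**{over_name: prop})
        s2 = max(sigma, 1e-8) ** 2
        dprior = (vec**2 - prop**2) / (2.0 * s2)
        logr = llv1 - self.llv + dprior
        mask = np.log(self.rng.uniform(size=vec.size)) < logr
        vec = np.where(mask, prop, vec)
        self.llv = np.where(mask, llv1, self.llv)
        if adapting:
            self._adapt(key, float(mask.mean()), it, _TARGET_SCALAR)
        return vec

    def _scale_move(self, key, sigma, vec, over_name, it, adapting):
        """Joint rescaling (sigma, v) -> (c sigma, c v), c lognormal.

        The Gaussian random-effect density cancels the Jacobian up to one
        factor of c, so the acceptance ratio is the likelihood ratio plus
        log c (flat SD prior).  This move decorrelates the SD from its
        vector and is what keeps the variance components mixing.
        """
        xi = float(self.scales[key] * self.rng.normal())
        c = np.exp(xi)
        prop_sigma = sigma * c
        acc = False
        if 0.0 < prop_sigma < self.priors.sd_upper:
            prop_vec = vec * c
            llv1 = self._loglik(**{over_name: prop_vec})
            logr = llv1.sum() - self.llv.sum() + xi
            if np.log(self.rng.uniform()) < logr:
                acc = True
                self.llv = llv1
        if adapting:
            self._adapt(key, 1.0 if acc else 0.0, it, _TARGET_SCALAR)
        return (prop_sigma, prop_vec) if acc else (sigma, vec)

    def _sigma_update(self, sigma, values):
        """MH update of an SD against prior U(0, upper) and N(0, sigma^2) REs."""
        upper = self.priors.sd_upper
        prop = float(np.exp(np.log(sigma) + 0.3 * self.rng.normal()))
        if not 0.0 < prop < upper:
            return sigma
        n = np.size(values)
        ss = float(np.sum(np.square(values)))

        def logp(s):
            return -n * np.log(s) - ss / (2 * s * s) + np.log(s)  # + log-jacobian

        return prop if np.log(self.rng.uniform()) < logp(prop) - logp(sigma) else sigma

    # ---- one full sweep --------------------------------------------------
    def sweep(self, it, adapting):
        pr = self.priors
        loc_var = pr.loc_sd**2

        def loc_prior(x):
            return -0.5 * float(np.sum(np.square(x))) / loc_var

        for s in "JA":
            if self.model == "quadratic":
                prior = loc_prior
            else:
                sig_b = self.sig_b[s]

                def prior(th, sig_b=sig_b):
                    fixed = th[:4]  # mu + polynomial coefficients
                    b = th[4:]
                    return loc_prior(fixed) - 0.5 * float(
                        np.sum(np.square(b))
                    ) / max(sig_b, 1e-8) ** 2

            over = (lambda st: (lambda v: {f"eta_{st}": self._eta(st, v)}))(s)
            self.th[s], _ = self._block(f"th_{s}", self.th[s], prior, over, it, adapting)

            sigB = self.sig_B[s]
            self.B[s], _ = self._block(
                f"B_{s}",
                self.B[s],
                lambda B, sigB=sigB: -0.5 * float(
                    np.sum(np.square(B[self.mobs]))
                ) / max(sigB, 1e-8) ** 2,
                (lambda st: (lambda v: {f"B_{st}": v}))(s),
                it,
                adapting,
                mask=self.mobs,
            )

        def lm_prior(lm):  # uniform(0,1) on each probability scale
            return float(np.sum(np.log(_expit(lm)) + np.log(_expit(-lm))))

        self.lm, _ = self._block("lm", self.lm, lm_prior, lambda v: {"lm": v}, it, adapting)

        sig_psi, mu_psi = max(self.sig_psi, 1e-8), self.mu_psi
        self.psi_l, _ = self._block(
            "psi_l",
            self.psi_l,
            lambda x: -0.5 * float(np.sum(np.square(x[self.mobs] - mu_psi))) / sig_psi**2,
            lambda v: {"psi_l": v},
            it,
            adapting,
            mask=self.mobs,
        )

        self.a, _ = self._block(
            "a", self.a, lambda x: loc_prior(x[self.mobs]),
            lambda v: {"a": v}, it, adapting, mask=self.mobs,
        )
        self.g, _ = self._block(
            "g", self.g, lambda x: loc_prior(x[self.mobs]),
            lambda v: {"g": v}, it, adapting, mask=self.mobs,
        )
        self.d, _ = self._block("d", self.d, loc_prior, lambda v: {"d": v}, it, adapting)

        for s in "JA":
            self.eps[s] = self._elementwise(
                f"eps_{s}", self.eps[s], self.sig_eps[s], f"eps_{s}", it, adapting
            )
        self.eps_rp = self._elementwise(
            "eps_rp", self.eps_rp, self.sig_rp, "eps_rp", it, adapting
        )

        # joint (sigma, vector) rescalings, then conditional SD refreshes
        for s in "JA":
            self.sig_eps[s], self.eps[s] = self._scale_move(
                f"sc_eps_{s}", self.sig_eps[s], self.eps[s], f"eps_{s}", it, adapting
            )
            self.sig_B[s], self.B[s] = self._scale_move(
                f"sc_B_{s}", self.sig_B[s], self.B[s], f"B_{s}", it, adapting
            )
        self.sig_rp, self.eps_rp = self._scale_move(
            "sc_rp", self.sig_rp, self.eps_rp, "eps_rp", it, adapting
        )

        for s in "JA":
            self.sig_eps[s] = self._sigma_update(self.sig_eps[s], self.eps[s])
            self.sig_B[s] = self._sigma_update(self.sig_B[s], self.B[s][self.mobs])
            if self.model == "spline":
                self.sig_b[s] = self._sigma_update(self.sig_b[s], self.th[s][4:])
        self.sig_psi = self._sigma_update(
            self.sig_psi, self.psi_l[self.mobs] - self.mu_psi
        )
        self.sig_rp = self._sigma_update(self.sig_rp, self.eps_rp)

        # conjugate Gibbs for the transition-rate mean
        n_mo = int(self.mobs.sum())
        prec = n_mo / max(self.sig_psi, 1e-8) ** 2 + 1.0 / loc_var
        mean = (self.psi_l[self.mobs].sum() / max(self.sig_psi, 1e-8) ** 2) / prec
        self.mu_psi = float(self.rng.normal(mean, 1.0 / np.sqrt(prec)))

    # ---- recording -------------------------------------------------------
    def record(self) -> dict:
        m = _expit(self.lm)
        out = {}
        for s in "JA":
            if self.model == "quadratic":
                out[f"mu_{s}"] = self.th[s][0]
                out[f"beta_{s}"] = self.th[s][1]
                out[f"gamma_{s}"] = self.th[s][2]
            else:
                out[f"mu_{s}"] = self.th[s][0]
                for p in range(3):
                    out[f"beta{p + 1}_{s}"] = self.th[s][1 + p]
                for k in range(self.knots.size):
                    out[f"b{k + 1}_{s}"] = self.th[s][4 + k]
                out[f"sigma_b_{s}"] = self.sig_b[s]
            out[f"sigma_eps_{s}"] = self.sig_eps[s]
            out[f"sigma2_{s}"] = self.sig_eps[s] ** 2
            out[f"sigma_B_{s}"] = self.sig_B[s]
            out[f"S_{s}"] = float(_expit(self.th[s][0]))
            for mo in range(12):
                out[f"B{mo + 1}_{s}"] = self.B[s][mo]
        out["m_J"], out["m_A"], out["F"] = float(m[0]), float(m[1]), float(m[2])
        out["mu_psi"], out["sigma_psi"] = self.mu_psi, self.sig_psi
        for mo in range(12):
            out[f"psi{mo + 1}"] = float(_expit(self.psi_l[mo]))
            out[f"a{mo + 1}"] = self.a[mo]
            out[f"g{mo + 1}"] = self.g[mo]
        out["d_p"], out["d_r"], out["sigma_rp"] = self.d[0], self.d[1], self.sig_rp
        return out


def fit_mcmc(
    histories: Sequence[EncounterHistory],
    model: str = "quadratic",
    config: McmcConfig | None = None,
    priors: PriorConfig | None = None,
    months: np.ndarray | None = None,
) -> McmcFit:
    """Fit the multistate dead-recovery model by MCMC.

    Parameters
    ----------
    histories : encounter histories with z-standardised colour covariates.
    model : "quadratic" (selection gradients) or "spline" (P-spline surface).
    config : chains / iterations / thinning / burn-in / seed protocol.
    priors : prior hyperparameters (see :class:`PriorConfig`).
    months : calendar month (1..12) of each occasion; defaults to
        consecutive months starting in February.

    Returns
    -------
    McmcFit
        Retained draws of all global parameters with a chain id column,
        convergence flag (all split R-hat < 1.1) and model metadata.
    """
    if model not in ("quadratic", "spline"):
        raise ValueError("model must be 'quadratic' or 'spline'")
    if not histories:
        raise ValueError("no histories supplied")
    config = config or McmcConfig()
    priors = priors or PriorConfig()
    T = len(histories[0].codes)
    if months is None:
        months = default_months(T)
    data = _prepare(histories, months)
    col = data[4]
    colr = np.asarray([np.min(col), np.max(col)])
    if not np.all(np.isfinite(col)):
        raise ValueError("histories contain non-finite colour values")

    knots = basis = None
    if model == "spline":
        K = knot_count(len(histories))
        knots = knot_positions(col, K)
        basis = spline_basis(col, knots, P=3)

    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.chains)
    frames = []
    for c in range(config.chains):
        rng = np.random.default_rng(child_seeds[c])
        chain = _Chain(data, model, knots, basis, priors, rng)
        rows = []
        for it in range(config.burn_in + config.iterations):
            chain.sweep(it, adapting=it < config.burn_in)
            post = it - config.burn_in
            if post >= 0 and post % config.thin == 0:
                rows.append(chain.record())
        df = pd.DataFrame(rows)
        df.insert(0, "chain", c)
        frames.append(df)
    draws = pd.concat(frames, ignore_index=True)

    summ = posterior_summary(draws)
    key_params = [p for p in summ.index if not (p.startswith("b") and p[1].isdigit())]
    rhat_max = float(np.nanmax(summ.loc[key_params, "rhat"]))
    converged = bool(rhat_max < 1.1)
    if not converged:
        warnings.warn(
            f"maximum split R-hat {rhat_max:.3f} >= 1.1: chains have not converged",
            stacklevel=2,
        )
    return McmcFit(
        draws=draws,
        model=model,
        config=config,
        knots=knots,
        colour_range=(float(colr[0]), float(colr[1])),
        n_individuals=len(histories),
        converged=converged,
        rhat_max=rhat_max,
        param_names=[c for c in draws.columns if c != "chain"],
    )


def spline_curve(fit: McmcFit, colour_grid: np.ndarray, stage: str = "adult") -> pd.DataFrame:
    """Posterior survival-vs-colour curve (median and 95% BCI).

    Survival is evaluated at eps = 0 and month effect B = 0 (the
    population-average logit at the reference month).  A grid point outside
    the fitted colour range triggers an extrapolation warning.
    """
    grid = np.asarray(colour_grid, dtype=float)
    lo, hi = fit.colour_range
    if grid.min() < lo or grid.max() > hi:
        warnings.warn(
            "colour grid extends beyond the observed colour range: extrapolating",
            stacklevel=2,
        )
    s = "J" if stage.startswith("j") else "A"
    d = fit.draws
    if fit.model == "quadratic":
        eta = (
            d[f"mu_{s}"].to_numpy()[:, None]
            + d[f"beta_{s}"].to_numpy()[:, None] * grid[None, :]
            + 0.5 * d[f"gamma_{s}"].to_numpy()[:, None] * grid[None, :] ** 2
        )
    else:
        basis = spline_basis(grid, fit.knots, P=3)  # (G, 3+K)
        coef_cols = [f"beta{p}_{s}" for p in (1, 2, 3)] + [
            f"b{k + 1}_{s}" for k in range(fit.knots.size)
        ]
        coefs = d[coef_cols].to_numpy()  # (draws, 3+K)
        eta = d[f"mu_{s}"].to_numpy()[:, None] + coefs @ basis.T
    surv = _expit(eta)
    return pd.DataFrame(
        {
            "colour": grid,
            "median": np.median(surv, axis=0),
            "lower": np.quantile(surv, 0.025, axis=0),
            "upper": np.quantile(surv, 0.975, axis=0),
        }
    )
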