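"""Parameter containers for the multistate selection model."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_MONTHS = 12


def _as_months(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (N_MONTHS,):
        raise ValueError(f"monthly vector must have length {N_MONTHS}")
    return arr


@dataclass
class QuadraticSurvivalParams:
    """Quadratic (Lande-Arnold) survival submodel, one set per stage.

    logit S_{i,t} = mu + beta*col_i + 0.5*gamma*col_i^2 + eps_i + B_t

    ``beta`` is the linear selection gradient (directional selection);
    ``gamma`` the nonlinear gradient (gamma < 0: stabilising, gamma > 0:
    disruptive).  ``B`` holds the 12 calendar-month effects.
    """

    mu: float
    beta: float
    gamma: float
    sigma_eps: float = 0.0
    B: np.ndarray = field(default_factory=lambda: np.zeros(N_MONTHS))

    def __post_init__(self) -> None:
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be >= 0")
        self.B = _as_months(self.B)

    def eta(self, col) -> np.ndarray:
        """Colour part of the survival logit (no eps, no month effect)."""
        col = np.asarray(col, dtype=float)
        return self.mu + self.beta * col + 0.5 * self.gamma * col**2


@dataclass
class SplineSurvivalParams:
    """Penalised-spline (P-spline) survival submodel.

    logit S_{i,t} = mu + sum_p beta_p col^p + sum_k b_k (col - kappa_k)_+^3
                    + eps_i + B_t

    with ``b_k ~ Normal(0, sigma_b^2)`` shrinking the hinge coefficients.
    """

    mu: float
    beta_poly: np.ndarray  # length P (cubic: 3)
    b: np.ndarray  # length K
    knots: np.ndarray  # strictly increasing, length K
    sigma_b: float = 1.0
    sigma_eps: float = 0.0
    B: np.ndarray = field(default_factory=lambda: np.zeros(N_MONTHS))

    def __post_init__(self) -> None:
        self.beta_poly = np.asarray(self.beta_poly, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.knots = np.asarray(self.knots, dtype=float)
        if self.b.shape != self.knots.shape:
            raise ValueError("b and knots must have equal length")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if self.sigma_eps < 0 or self.sigma_b < 0:
            raise ValueError("SD parameters must be >= 0")
        self.B = _as_months(self.B)

    def eta(self, col) -> np.ndarray:
        from snailselect.model.spline import spline_basis

        col = np.atleast_1d(np.asarray(col, dtype=float))
        basis = spline_basis(col, self.knots, P=len(self.beta_poly))
        out = self.mu + basis @ np.concatenate([self.beta_poly, self.b])
        return out


@dataclass
class DemographicParams:
    """Predation, site-fidelity and stage-transition rates.

    Predation by mice is a constant per-occasion probability per stage
    (independent of colour and month); fidelity is the constant per-occasion
    probability of remaining in the study site (its complement is permanent
    emigration); the monthly juvenile-to-adult transition probabilities psi_t
    are modelled as logit(psi_t) ~ Normal(mu_psi, sigma_psi^2).
    """

    predation_juvenile: float
    predation_adult: float
    fidelity: float
    psi: np.ndarray = field(default_factory=lambda: np.full(N_MONTHS, 0.1))
    mu_psi: float = 0.0
    sigma_psi: float = 1.0

    def __post_init__(self) -> None:
        self.psi = _as_months(self.psi)
        for name in ("predation_juvenile", "predation_adult", "fidelity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if np.any(self.psi < 0) or np.any(self.psi > 1):
            raise ValueError("psi outside [0, 1]")
        if self.sigma_psi < 0:
            raise ValueError("sigma_psi must be >= 0")


@dataclass
class DetectionParams:
    """Recapture (live) and recovery (dead) detection, shared across stages.

    Month intercepts ``a_t`` (recapture) and ``g_t`` (recovery) with colour
    slopes ``d_p`` and ``d_r``, plus one shared per-individual heterogeneity
    eps_rp_i ~ Normal(0, sigma_rp^2) entering both linear predictors.
    """

    a: np.ndarray = field(default_factory=lambda: np.zeros(N_MONTHS))
    g: np.ndarray = field(default_factory=lambda: np.zeros(N_MONTHS))
    d_p: float = 0.0
    d_r: float = 0.0
    sigma_rp: float = 0.0

    def __post_init__(self) -> None:
        self.a = _as_months(self.a)
        self.g = _as_months(self.g)
        if self.sigma_rp < 0:
            raise ValueError("sigma_rp must be >= 0")


@dataclass
class McmcConfig:
    """Sampling protocol: chains, iterations kept per chain, thinning, burn-in."""

    chains: int = 3
    iterations: int = 2000
    thin: int = 5
    burn_in: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.burn_in < 0:
            raise ValueError("iterations must be > 0 and burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PriorConfig:
    """Noninformative priors: Normal(0, loc_sd^2) on logit-scale locations,
    Uniform(0, sd_upper) on SDs, Uniform(0,1) on the predation and fidelity
    probabilities."""

    loc_sd: float = 10.0
    sd_upper: float = 10.0
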