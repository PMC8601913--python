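"""Transition and observation matrices of the hidden-Markov process.

State indexing (0-based here; reports use the 1-based 12-state vocabulary):

====  ==========================================
0     alive, in site, juvenile
1     newly dead (other cause), in site, juvenile
2     newly dead (predation), in site, juvenile
3     alive, in site, adult
4     newly dead (other cause), in site, adult
5     newly dead (predation), in site, adult
6-11  the outside-site analogues of 0-5
12    long dead (internal absorbing bookkeeping state)
====  ==========================================

Within one inter-occasion interval events compose in the order
predation -> other-cause survival -> fidelity (emigration) -> stage
transition, so the survival parameter S is survival conditional on escaping
predation — the quantity on which selection excluding predation is defined.
Newly dead states are recoverable at the next occasion only, then absorb
into state 12.  Emigration is permanent; outside-site and long-dead states
are unobservable.
"""

from __future__ import annotations

import math
from typing import Union

import numpy as np

from snailselect.model.params import (
    DetectionParams,
    QuadraticSurvivalParams,
    SplineSurvivalParams,
)

N_STATES = 13
N_OBS = 7

ALIVE_J_IN, DEAD_O_J_IN, DEAD_P_J_IN = 0, 1, 2
ALIVE_A_IN, DEAD_O_A_IN, DEAD_P_A_IN = 3, 4, 5
ALIVE_J_OUT, DEAD_O_J_OUT, DEAD_P_J_OUT = 6, 7, 8
ALIVE_A_OUT, DEAD_O_A_OUT, DEAD_P_A_OUT = 9, 10, 11
LONG_DEAD = 12


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def survival_logit(
    col: float,
    month: int,
    eps_i: float,
    params: Union[QuadraticSurvivalParams, SplineSurvivalParams],
) -> float:
    """Per-interval survival probability (excluding predation) of one snail.

    ``month`` is the calendar month 1..12 of the interval; the linear
    predictor is eta(col) + eps_i + B_month, mapped through the inverse
    logit.
    """
    if not 1 <= month <= 12:
        raise ValueError("month must be in 1..12")
    eta = float(np.atleast_1d(params.eta(col))[0]) + eps_i + params.B[month - 1]
    return float(_expit(eta))


def detection_logit(
    month: int, col: float, eps_rp_i: float, params: DetectionParams
) -> dict:
    """Recapture (p) and recovery (r) probabilities for one snail and month."""
    if not 1 <= month <= 12:
        raise ValueError("month must be in 1..12")
    m = month - 1
    p = _expit(params.a[m] + params.d_p * col + eps_rp_i)
    r = _expit(params.g[m] + params.d_r * col + eps_rp_i)
    return {"p": float(p), "r": float(r)}


def _check_prob(name: str, v: float) -> float:
    v = float(v)
    if not 0.0 <= v <= 1.0 or math.isnan(v):
        raise ValueError(f"{name}={v} is not a probability")
    return v


def transition_matrix(
    S: tuple[float, float],
    predation_rate: tuple[float, float],
    fidelity: float,
    psi_t: float,
) -> np.ndarray:
    """One-interval 13x13 row-stochastic state transition matrix.

    Parameters
    ----------
    S : (S_J, S_A)
        Stage-specific survival probabilities excluding predation.
    predation_rate : (m_J, m_A)
        Stage-specific per-interval predation probabilities.
    fidelity : float
        Probability of remaining in the study site (in-site rows only).
    psi_t : float
        Juvenile-to-adult transition probability for this interval.
    """
    S_J, S_A = (_check_prob("S_J", S[0]), _check_prob("S_A", S[1]))
    m_J, m_A = (
        _check_prob("m_J", predation_rate[0]),
        _check_prob("m_A", predation_rate[1]),
    )
    F = _check_prob("fidelity", fidelity)
    psi = _check_prob("psi_t", psi_t)

    G = np.zeros((N_STATES, N_STATES))

    # alive juvenile, in site
    G[ALIVE_J_IN, DEAD_P_J_IN] = m_J
    G[ALIVE_J_IN, DEAD_O_J_IN] = (1 - m_J) * (1 - S_J)
    live = (1 - m_J) * S_J
    G[ALIVE_J_IN, ALIVE_J_IN] = live * F * (1 - psi)
    G[ALIVE_J_IN, ALIVE_A_IN] = live * F * psi
    G[ALIVE_J_IN, ALIVE_J_OUT] = live * (1 - F) * (1 - psi)
    G[ALIVE_J_IN, ALIVE_A_OUT] = live * (1 - F) * psi

    # alive adult, in site
    G[ALIVE_A_IN, DEAD_P_A_IN] = m_A
    G[ALIVE_A_IN, DEAD_O_A_IN] = (1 - m_A) * (1 - S_A)
    G[ALIVE_A_IN, ALIVE_A_IN] = (1 - m_A) * S_A * F
    G[ALIVE_A_IN, ALIVE_A_OUT] = (1 - m_A) * S_A * (1 - F)

    # alive juvenile, outside (emigration permanent: no return, no fidelity)
    G[ALIVE_J_OUT, DEAD_P_J_OUT] = m_J
    G[ALIVE_J_OUT, DEAD_O_J_OUT] = (1 - m_J) * (1 - S_J)
    G[ALIVE_J_OUT, ALIVE_J_OUT] = (1 - m_J) * S_J * (1 - psi)
    G[ALIVE_J_OUT, ALIVE_A_OUT] = (1 - m_J) * S_J * psi

    # alive adult, outside
    G[ALIVE_A_OUT, DEAD_P_A_OUT] = m_A
    G[ALIVE_A_OUT, DEAD_O_A_OUT] = (1 - m_A) * (1 - S_A)
    G[ALIVE_A_OUT, ALIVE_A_OUT] = (1 - m_A) * S_A

    # newly dead states absorb; long dead absorbs
    for s in (
        DEAD_O_J_IN, DEAD_P_J_IN, DEAD_O_A_IN, DEAD_P_A_IN,
        DEAD_O_J_OUT, DEAD_P_J_OUT, DEAD_O_A_OUT, DEAD_P_A_OUT,
    ):
        G[s, LONG_DEAD] = 1.0
    G[LONG_DEAD, LONG_DEAD] = 1.0
    return G


def emission_matrix(p: float, r: float) -> np.ndarray:
    """13x7 row-stochastic observation matrix for one occasion.

    ``p`` is the recapture probability of live in-site snails; ``r`` the
    recovery probability of newly dead in-site carcasses.  Outside-site and
    long-dead states emit "not seen" (code 7) with probability 1.
    """
    p = _check_prob("p", p)
    r = _check_prob("r", r)
    E = np.zeros((N_STATES, N_OBS))
    NOT_SEEN = 6  # 0-based code 7
    E[ALIVE_J_IN, 0] = p
    E[ALIVE_A_IN, 3] = p
    E[DEAD_O_J_IN, 1] = r
    E[DEAD_P_J_IN, 2] = r
    E[DEAD_O_A_IN, 4] = r
    E[DEAD_P_A_IN, 5] = r
    E[:, NOT_SEEN] = 1.0 - E.sum(axis=1)
    return E
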