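"""Forward-algorithm likelihood of encounter histories.

Two routes compute the same quantity:

* :func:`history_loglik` — a readable single-history implementation built
  from :func:`~snailselect.model.matrices.transition_matrix` and
  :func:`~snailselect.model.matrices.emission_matrix`; used for validation
  and small analyses.
* :func:`loglik_all` — a numba-compiled batch version over all individuals,
  hand-coding the sparse structure of the transition matrix; this is what
  the MCMC sampler calls.

The likelihood conditions on first capture: the latent state at the first
capture occasion is known (alive, in site, observed stage) and occasions
before it contribute nothing.  Individual heterogeneity values are inputs
(they are parameters handled by the sampler, not integrated here).
"""

from __future__ import annotations

from typing import Union

import numpy as np
from numba import njit

from snailselect.records import EncounterHistory
from snailselect.model.matrices import (
    emission_matrix,
    survival_logit,
    transition_matrix,
    detection_logit,
    ALIVE_A_IN,
    ALIVE_J_IN,
)
from snailselect.model.params import (
    DemographicParams,
    DetectionParams,
    QuadraticSurvivalParams,
    SplineSurvivalParams,
)

SurvivalParams = Union[QuadraticSurvivalParams, SplineSurvivalParams]


def history_loglik(
    h: EncounterHistory,
    months: np.ndarray,
    surv_j: SurvivalParams,
    surv_a: SurvivalParams,
    demog: DemographicParams,
    detect: DetectionParams,
    eps_j: float = 0.0,
    eps_a: float = 0.0,
    eps_rp: float = 0.0,
) -> float:
    """Log-probability of the codes after first capture, marginalised over
    latent state paths by the forward algorithm.

    ``months`` maps occasion index (0-based) to calendar month 1..12.
    Returns ``0.0`` for a history with no post-capture occasions and
    ``-inf`` for a history impossible under the model.
    """
    codes = np.asarray(h.codes, dtype=int)
    T = codes.size
    months = np.asarray(months, dtype=int)
    if months.size != T:
        raise ValueError("months must have one entry per occasion")
    f = h.first_capture - 1

    alpha = np.zeros(13)
    alpha[ALIVE_J_IN if h.stage_at_first == "juvenile" else ALIVE_A_IN] = 1.0

    ll = 0.0
    for t in range(f + 1, T):
        mo = months[t]
        S_J = survival_logit(h.colour, mo, eps_j, surv_j)
        S_A = survival_logit(h.colour, mo, eps_a, surv_a)
        G = transition_matrix(
            (S_J, S_A),
            (demog.predation_juvenile, demog.predation_adult),
            demog.fidelity,
            demog.psi[mo - 1],
        )
        pr = detection_logit(mo, h.colour, eps_rp, detect)
        E = emission_matrix(pr["p"], pr["r"])
        alpha = (alpha @ G) * E[:, codes[t] - 1]
        c = alpha.sum()
        if c <= 0.0:
            return float("-inf")
        alpha /= c
        ll += np.log(c)
    return float(ll)


@njit(cache=True)
def loglik_all(
    codes,  # (N, T) int64, 0-based observation codes 0..6
    first,  # (N,) int64, 0-based first-capture occasion
    stage0,  # (N,) int64, 0 juvenile / 1 adult at first capture
    month,  # (T,) int64, 0-based calendar month per occasion
    eta_j,  # (N,) colour part of juvenile survival logit
    eta_a,  # (N,)
    eps_j,  # (N,) survival heterogeneity, juvenile stage
    eps_a,  # (N,)
    B_j,  # (12,) month effects
    B_a,  # (12,)
    m_j,  # predation, juvenile
    m_a,  # predation, adult
    fid,  # site fidelity
    psi,  # (12,) monthly transition probabilities
    a,  # (12,) recapture month intercepts (logit)
    g,  # (12,) recovery month intercepts (logit)
    d_p,  # recapture colour slope
    d_r,  # recovery colour slope
    col,  # (N,) standardized colour
    eps_rp,  # (N,) shared detection heterogeneity
):
    """Per-individual forward log-likelihood (batch, sparse transitions)."""
    N, T = codes.shape
    out = np.zeros(N)
    alpha = np.zeros(13)
    new = np.zeros(13)
    for i in range(N):
        for s in range(13):
            alpha[s] = 0.0
        if stage0[i] == 0:
            alpha[0] = 1.0
        else:
            alpha[3] = 1.0
        ll = 0.0
        for t in range(first[i] + 1, T):
            mo = month[t]
            S_J = 1.0 / (1.0 + np.exp(-(eta_j[i] + eps_j[i] + B_j[mo])))
            S_A = 1.0 / (1.0 + np.exp(-(eta_a[i] + eps_a[i] + B_a[mo])))
            ps = psi[mo]
            liveJ = (1.0 - m_j) * S_J
            liveA = (1.0 - m_a) * S_A

            aJ_in = alpha[0]
            aA_in = alpha[3]
            aJ_out = alpha[6]
            aA_out = alpha[9]
            dead_mass = (
                alpha[1] + alpha[2] + alpha[4] + alpha[5]
                + alpha[7] + alpha[8] + alpha[10] + alpha[11] + alpha[12]
            )

            new[0] = aJ_in * liveJ * fid * (1.0 - ps)
            new[1] = aJ_in * (1.0 - m_j) * (1.0 - S_J)
            new[2] = aJ_in * m_j
            new[3] = aJ_in * liveJ * fid * ps + aA_in * liveA * fid
            new[4] = aA_in * (1.0 - m_a) * (1.0 - S_A)
            new[5] = aA_in * m_a
            new[6] = aJ_in * liveJ * (1.0 - fid) * (1.0 - ps) + aJ_out * liveJ * (1.0 - ps)
            new[7] = aJ_out * (1.0 - m_j) * (1.0 - S_J)
            new[8] = aJ_out * m_j
            new[9] = (
                aJ_in * liveJ * (1.0 - fid) * ps
                + aA_in * liveA * (1.0 - fid)
                + aJ_out * liveJ * ps
                + aA_out * liveA
            )
            new[10] = aA_out * (1.0 - m_a) * (1.0 - S_A)
            new[11] = aA_out * m_a
            new[12] = dead_mass

            p = 1.0 / (1.0 + np.exp(-(a[mo] + d_p * col[i] + eps_rp[i])))
            r = 1.0 / (1.0 + np.exp(-(g[mo] + d_r * col[i] + eps_rp[i])))
            o = codes[i, t]
            if o == 6:  # not seen
                new[0] *= 1.0 - p
                new[3] *= 1.0 - p
                new[1] *= 1.0 - r
                new[2] *= 1.0 - r
                new[4] *= 1.0 - r
                new[5] *= 1.0 - r
                # outside / long-dead emit 7 with probability 1
            else:
                if o == 0:
                    keep, pk = 0, p
                elif o == 3:
                    keep, pk = 3, p
                elif o == 1:
                    keep, pk = 1, r
                elif o == 2:
                    keep, pk = 2, r
                elif o == 4:
                    keep, pk = 4, r
                else:  # o == 5
                    keep, pk = 5, r
                kept = new[keep] * pk
                for s in range(13):
                    new[s] = 0.0
                new[keep] = kept
            c = 0.0
            for s in range(13):
                alpha[s] = new[s]
                c += new[s]
            if c <= 0.0:
                ll = -np.inf
                break
            for s in range(13):
                alpha[s] /= c
            ll += np.log(c)
        out[i] = ll
    return out
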