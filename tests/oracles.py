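"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the implementation's code paths: the forward
algorithm is checked against explicit enumeration of latent state paths,
and Fisher's exact test against integer-arithmetic hypergeometric
enumeration.
"""

from fractions import Fraction
from itertools import product
from math import comb

import numpy as np

from snailselect.model import emission_matrix, survival_logit, transition_matrix


def brute_force_history_loglik(h, months, surv_j, surv_a, demog, detect,
                               eps_j=0.0, eps_a=0.0, eps_rp=0.0):
    """Sum over every latent state path explicitly (feasible for T <= 5)."""
    from snailselect.model import detection_logit
    from snailselect.model.matrices import ALIVE_A_IN, ALIVE_J_IN

    codes = np.asarray(h.codes, int)
    T = codes.size
    f = h.first_capture - 1
    steps = T - 1 - f
    if steps <= 0:
        return 0.0
    Gs, Es = [], []
    for t in range(f + 1, T):
        mo = months[t]
        S_J = survival_logit(h.colour, mo, eps_j, surv_j)
        S_A = survival_logit(h.colour, mo, eps_a, surv_a)
        Gs.append(
            transition_matrix(
                (S_J, S_A),
                (demog.predation_juvenile, demog.predation_adult),
                demog.fidelity,
                demog.psi[mo - 1],
            )
        )
        pr = detection_logit(mo, h.colour, eps_rp, detect)
        Es.append(emission_matrix(pr["p"], pr["r"]))
    s0 = ALIVE_J_IN if h.stage_at_first == "juvenile" else ALIVE_A_IN
    total = 0.0
    for path in product(range(13), repeat=steps):
        prob = 1.0
        prev = s0
        for k, s in enumerate(path):
            prob *= Gs[k][prev, s] * Es[k][s, codes[f + 1 + k] - 1]
            if prob == 0.0:
                break
            prev = s
        total += prob
    return float(np.log(total)) if total > 0 else float("-inf")


def fisher_exact_p_enumeration(a, b, c, d):
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    probs = {
        x: Fraction(comb(row1, x) * comb(n - row1, col1 - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))
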