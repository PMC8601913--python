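"""Predation and microhabitat field statistics.

Covers the contingency-table comparisons (Fisher's exact test, with
Benjamini-Hochberg false-discovery-rate control across the pairwise
site x stage microhabitat tests) and the two binomial mixed models:
predated-vs-other cause of death on colour, stage and their interaction
(random intercept on recovery month), and arboreal-vs-ground microhabitat
use on colour (random intercepts on month and individual).  Hibernating
snails are excluded from all microhabitat analyses, since every snail is
under the leaf litter when hibernating.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from snailselect.glmm import GlmmResult, fit_binomial_glmm
from snailselect.records import SnailRecord


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows = groups, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("at least one margin must be positive")


def fisher_exact(t: ContingencyTable2x2, conditional_or: bool = True) -> dict:
    """Fisher's exact test on a 2x2 table.

    The two-sided p value sums hypergeometric probabilities of all tables
    (at fixed margins) no more probable than the observed one.  Reports the
    sample (unconditional) odds ratio ``ad/bc`` — +inf or 0 with a flag when
    a zero cell makes it degenerate — alongside the conditional MLE (skipped
    when ``conditional_or`` is False; the MLE is comparatively costly).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    # support of the (1,1) cell given the margins
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    # tolerance guards against ties broken by floating-point noise
    p_two = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))

    flag = None
    if b * c == 0 and a * d == 0:
        odds, flag = np.nan, "odds ratio undefined (zero in both diagonals)"
    elif b * c == 0:
        odds, flag = np.inf, "zero cell: sample odds ratio infinite"
    elif a * d == 0:
        odds, flag = 0.0, "zero cell: sample odds ratio zero"
    else:
        odds = (a * d) / (b * c)
    out = {"odds_ratio": float(odds), "p_two_sided": p_two, "flag": flag}
    if conditional_or:
        cond = stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
        out["odds_ratio_conditional"] = float(cond.statistic)
    return out


def bh_fdr(pvals: Sequence[float], alpha: float = 0.05) -> dict:
    """Benjamini-Hochberg step-up FDR control.

    Returns q values (``q_i = min_{j >= rank(i)} m p_(j) / j``, capped at 1)
    and rejection flags at level ``alpha``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return {"q_values": p, "reject_flags": np.zeros(0, bool)}
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return {"q_values": q, "reject_flags": reject}


def _records_frame(records: Sequence[SnailRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "calendar_month": [r.calendar_month for r in records],
            "site": [r.site for r in records],
            "stage": [r.stage for r in records],
            "microhabitat": [r.microhabitat for r in records],
            "status": [r.status for r in records],
            "col": [r.colour for r in records],
        }
    )


def predation_glmm(dead_records: Sequence[SnailRecord]) -> GlmmResult:
    """Mixed logit model of cause of death: predated (1) vs. other (0).

    Fixed effects: shell colour, growth stage (adult 1, juvenile 0) and
    their interaction; random intercept on the recovery month.  With a
    single recovery month the random effect is dropped with a warning flag.
    """
    df = _records_frame(dead_records)
    if df.empty:
        raise ValueError("no dead records supplied")
    if (df["status"] == "live").any():
        raise ValueError("predation_glmm expects dead records only")
    y = (df["status"] == "dead_predated").to_numpy(float)
    colour = df["col"].to_numpy(float)
    stage = (df["stage"] == "adult").to_numpy(float)
    X = np.column_stack([np.ones_like(y), colour, stage, colour * stage])
    groups = {}
    if df["calendar_month"].nunique() >= 2:
        groups["month"] = df["calendar_month"].to_numpy()
    res = fit_binomial_glmm(
        X, y, groups, ["intercept", "colour", "stage", "colour:stage"]
    )
    if not groups:
        res.flags.append("single recovery month: random effect dropped")
    return res


def microhabitat_glmm(
    records: Sequence[SnailRecord], stage: str, site: str
) -> GlmmResult:
    """Mixed logit model of microhabitat use: arboreal (1) vs. ground (0).

    Fixed effect: shell colour; random intercepts on survey month and
    individual id.  ``records`` must contain no hibernation rows; the
    analysis is restricted to one stage x site subset.
    """
    df = _records_frame(records)
    if (df["microhabitat"] == "hibernation").any():
        raise ValueError("hibernation records must be removed before this analysis")
    df = df[(df["stage"] == stage) & (df["site"] == site)]
    if df.empty:
        raise ValueError(f"no records for stage={stage}, site={site}")
    y = (df["microhabitat"] == "arboreal").to_numpy(float)
    colour = df["col"].to_numpy(float)
    flags = []
    if np.ptp(colour) == 0:
        raise ValueError("colour is constant: slope inestimable")
    X = np.column_stack([np.ones_like(y), colour])
    groups = {}
    if df["calendar_month"].nunique() >= 2:
        groups["month"] = df["calendar_month"].to_numpy()
    if df["individual_id"].nunique() >= 2:
        groups["individual"] = df["individual_id"].to_numpy()
    res = fit_binomial_glmm(X, y, groups, ["intercept", "colour"])
    res.flags.extend(flags)
    return res


def microhabitat_pairwise(records: Sequence[SnailRecord]) -> pd.DataFrame:
    """Fisher tests of ground/arboreal use across all site x stage pairs.

    All 6 pairwise comparisons of the 4 (site, stage) groups, with
    Benjamini-Hochberg q values at alpha = 0.05.  Groups without records
    are skipped with a note.
    """
    df = _records_frame(records)
    if (df["microhabitat"] == "hibernation").any():
        raise ValueError("hibernation records must be removed before this analysis")
    counts = {}
    for site in ("mainland", "island"):
        for stage in ("juvenile", "adult"):
            sub = df[(df["site"] == site) & (df["stage"] == stage)]
            counts[(site, stage)] = (
                int((sub["microhabitat"] == "ground").sum()),
                int((sub["microhabitat"] == "arboreal").sum()),
            )
    rows = []
    for g1, g2 in combinations(counts, 2):
        (a, b), (c, d) = counts[g1], counts[g2]
        label = f"{g1[0]}-{g1[1]} vs {g2[0]}-{g2[1]}"
        if a + b == 0 or c + d == 0:
            rows.append(
                {"comparison": label, "odds_ratio": np.nan, "p": np.nan,
                 "note": "group with zero records: skipped"}
            )
            continue
        res = fisher_exact(ContingencyTable2x2(a, b, c, d))
        rows.append(
            {"comparison": label, "odds_ratio": res["odds_ratio"],
             "p": res["p_two_sided"], "note": ""}
        )
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["q"] = np.nan
    out["reject"] = False
    if tested.any():
        fdr = bh_fdr(out.loc[tested, "p"].to_numpy(), alpha=0.05)
        out.loc[tested, "q"] = fdr["q_values"]
        out.loc[tested, "reject"] = fdr["reject_flags"]
    return out
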