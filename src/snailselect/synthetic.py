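"""Synthetic mark-recapture datasets with the structure the analysis assumes.

The generator emulates the study design end to end: staggered first captures
of marked snails over monthly occasions, a unimodal-bright (mainland-like)
or bimodal (island-like) shell-colour distribution, colour-dependent
survival through the quadratic or spline submodel, stage-dependent constant
predation, permanent emigration, monthly stage transitions, and
month/colour-dependent recapture and recovery with shared individual
heterogeneity.  Latent state paths and the full truth parameter set are
retained so that fits can be scored by parameter recovery.

All randomness flows from the single scenario seed through a
``numpy.random.SeedSequence`` spawning scheme, so the colour, demographic
and observation layers are independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from snailselect import records as rec
from snailselect.model.matrices import emission_matrix, transition_matrix
from snailselect.model.params import (
    DemographicParams,
    DetectionParams,
    QuadraticSurvivalParams,
    SplineSurvivalParams,
)
from snailselect.model.mcmc import default_months, _expit

_GREY_Y = 140.0  # grey-card luminance used when rendering ratios back to RGB

#: state index -> (stage, status, in_site, alive) for the 13-state chain
_STATE_STAGE = np.array([0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1, -1])
_OBS_FOR_STATE = {0: 1, 1: 2, 2: 3, 3: 4, 4: 5, 5: 6}


@dataclass
class ColourProfile:
    """Normal-mixture shell-colour (Y/Y' ratio) distribution."""

    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if len(self.means) != len(self.sds) or len(self.means) != len(self.weights):
            raise ValueError("means, sds, weights must have equal length")


#: Mainland-like: most snails bright, one component (ratio median ~1.07).
MAINLAND_UNIMODAL = ColourProfile(means=(1.07,), sds=(0.23,), weights=(1.0,))
#: Island-like: dark and bright morphs with near-equal frequency.
ISLAND_BIMODAL = ColourProfile(
    means=(0.50, 1.05), sds=(0.15, 0.15), weights=(0.5, 0.5)
)

_PROFILES = {"mainland_unimodal": MAINLAND_UNIMODAL, "island_bimodal": ISLAND_BIMODAL}


@dataclass
class SimulationScenario:
    """Study conditions for one simulated dataset.

    Defaults mirror the mainland survey: ~1,700 marked individuals over 13
    monthly occasions (February start), first captures spread over the first
    10 occasions, sparse field detection.
    """

    N: int = 1700
    T: int = 13
    colour_profile: str = "mainland_unimodal"
    surv_j: QuadraticSurvivalParams | SplineSurvivalParams = field(
        default_factory=lambda: QuadraticSurvivalParams(
            mu=1.99, beta=-0.16, gamma=-0.34, sigma_eps=1.0
        )
    )
    surv_a: QuadraticSurvivalParams | SplineSurvivalParams = field(
        default_factory=lambda: QuadraticSurvivalParams(
            mu=0.80, beta=0.01, gamma=-1.05, sigma_eps=1.0
        )
    )
    demog: DemographicParams = field(
        default_factory=lambda: DemographicParams(
            predation_juvenile=0.02,
            predation_adult=0.06,
            fidelity=0.95,
            psi=np.full(12, 0.08),
        )
    )
    detect: DetectionParams = field(
        default_factory=lambda: DetectionParams(
            a=np.full(12, -3.0), g=np.full(12, -3.3), sigma_rp=0.5
        )
    )
    entry_span: int = 10  # first captures spread uniformly over these occasions
    p_juvenile_at_entry: float = 0.5
    start_month: int = 2
    winter_months: tuple[int, ...] = (12, 1, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1 or self.T < 2:
            raise ValueError("need N >= 1 and T >= 2")
        if self.colour_profile not in _PROFILES:
            raise ValueError(f"unknown colour_profile {self.colour_profile!r}")
        self.entry_span = min(self.entry_span, self.T)

    @property
    def months(self) -> np.ndarray:
        return default_months(self.T, start_month=self.start_month)


def recovery_scenario(seed: int = 0, N: int = 400, T: int = 10) -> SimulationScenario:
    """Desk-scale parameter-recovery conditions: stabilising selection
    (gamma = -1, beta = 0) in both stages, moderate detection."""
    return SimulationScenario(
        N=N,
        T=T,
        surv_j=QuadraticSurvivalParams(mu=1.4, beta=0.0, gamma=-1.0, sigma_eps=0.4),
        surv_a=QuadraticSurvivalParams(mu=1.4, beta=0.0, gamma=-1.0, sigma_eps=0.4),
        demog=DemographicParams(
            predation_juvenile=0.03,
            predation_adult=0.05,
            fidelity=0.95,
            psi=np.full(12, 0.10),
        ),
        detect=DetectionParams(
            a=np.full(12, 0.0), g=np.full(12, -0.4), sigma_rp=0.3
        ),
        entry_span=5,
        seed=seed,
    )


@dataclass
class SimulatedDataset:
    """Records, latent truth and parameter dump of one simulation."""

    records: pd.DataFrame  # the records-module CSV schema (+ col column)
    histories: list  # list[EncounterHistory]
    latent_states: np.ndarray  # (N, T), 0-based states, -1 before entry
    truth: dict  # parameter name -> true value
    scenario: SimulationScenario

    def truth_json(self) -> str:
        return json.dumps(self.truth, indent=1, sort_keys=True)


def simulate_colours(scenario: SimulationScenario, rng=None) -> dict:
    """Draw shell-colour ratios from the scenario mixture; z-standardise.

    Returns raw ``ratio`` values (Y/Y' scale) and the standardised ``col``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(scenario.seed).spawn(1)[0])
    prof = _PROFILES[scenario.colour_profile]
    comp = rng.choice(len(prof.weights), size=scenario.N, p=np.asarray(prof.weights))
    ratio = rng.normal(np.asarray(prof.means)[comp], np.asarray(prof.sds)[comp])
    ratio = np.clip(ratio, 0.02, 1.80)  # keep Y/Y' physical (renders to RGB <= 255)
    col = (ratio - ratio.mean()) / ratio.std(ddof=1)
    return {"ratio": ratio, "col": col}


def _truth_dump(s: SimulationScenario) -> dict:
    out = {}
    for tag, sp in (("J", s.surv_j), ("A", s.surv_a)):
        if isinstance(sp, QuadraticSurvivalParams):
            out[f"mu_{tag}"] = sp.mu
            out[f"beta_{tag}"] = sp.beta
            out[f"gamma_{tag}"] = sp.gamma
        else:
            out[f"mu_{tag}"] = sp.mu
        out[f"sigma_eps_{tag}"] = sp.sigma_eps
    out["m_J"] = s.demog.predation_juvenile
    out["m_A"] = s.demog.predation_adult
    out["F"] = s.demog.fidelity
    for mo in range(12):
        out[f"psi{mo + 1}"] = float(s.demog.psi[mo])
        out[f"a{mo + 1}"] = float(s.detect.a[mo])
        out[f"g{mo + 1}"] = float(s.detect.g[mo])
    out["d_p"] = s.detect.d_p
    out["d_r"] = s.detect.d_r
    out["sigma_rp"] = s.detect.sigma_rp
    return out


def simulate_population(scenario: SimulationScenario) -> SimulatedDataset:
    """Simulate marked individuals through the full state-space process."""
    s = scenario
    ss = np.random.SeedSequence(s.seed)
    rng_col, rng_entry, rng_eps, rng_path, rng_obs = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )
    colours = simulate_colours(s, rng_col)
    ratio, col = colours["ratio"], colours["col"]
    months = s.months
    site = "mainland" if s.colour_profile == "mainland_unimodal" else "island"

    entry = rng_entry.integers(0, s.entry_span, size=s.N)
    stage0 = (rng_entry.uniform(size=s.N) >= s.p_juvenile_at_entry).astype(int)
    eps_j = rng_eps.normal(0.0, s.surv_j.sigma_eps, size=s.N)
    eps_a = rng_eps.normal(0.0, s.surv_a.sigma_eps, size=s.N)
    eps_rp = rng_eps.normal(0.0, s.detect.sigma_rp, size=s.N)

    states = np.full((s.N, s.T), -1, dtype=np.int64)
    codes = np.full((s.N, s.T), 7, dtype=np.int64)
    rows = []
    for i in range(s.N):
        e = entry[i]
        state = 0 if stage0[i] == 0 else 3
        states[i, e] = state
        codes[i, e] = 1 if state == 0 else 4
        rows.append((i, e, "live", state))
        for t in range(e + 1, s.T):
            mo = months[t]
            S_J = _expit(
                float(np.atleast_1d(s.surv_j.eta(col[i]))[0])
                + eps_j[i] + s.surv_j.B[mo - 1]
            )
            S_A = _expit(
                float(np.atleast_1d(s.surv_a.eta(col[i]))[0])
                + eps_a[i] + s.surv_a.B[mo - 1]
            )
            G = transition_matrix(
                (S_J, S_A),
                (s.demog.predation_juvenile, s.demog.predation_adult),
                s.demog.fidelity,
                s.demog.psi[mo - 1],
            )
            state = int(rng_path.choice(13, p=G[state]))
            states[i, t] = state
            p = _expit(s.detect.a[mo - 1] + s.detect.d_p * col[i] + eps_rp[i])
            r = _expit(s.detect.g[mo - 1] + s.detect.d_r * col[i] + eps_rp[i])
            E = emission_matrix(p, r)
            obs = int(rng_obs.choice(7, p=E[state])) + 1
            codes[i, t] = obs
            if obs != 7:
                status = (
                    "live" if obs in (1, 4)
                    else "dead_predated" if obs in (3, 6)
                    else "dead_other"
                )
                rows.append((i, t, status, state))
            if state == 12 or obs in (2, 3, 5, 6):
                break

    grey = np.round(ratio * _GREY_Y).astype(int)
    recs = pd.DataFrame(
        {
            "individual_id": [f"s{i:05d}" for i, _, _, _ in rows],
            "occasion": [t + 1 for _, t, _, _ in rows],
            "calendar_month": [int(months[t]) for _, t, _, _ in rows],
            "site": site,
            "stage": ["juvenile" if _STATE_STAGE[st] == 0 else "adult"
                      for _, _, _, st in rows],
            "microhabitat": "ground",
            "status": [status for _, _, status, _ in rows],
            "R_mean": [int(grey[i]) for i, _, _, _ in rows],
            "G_mean": [int(grey[i]) for i, _, _, _ in rows],
            "B_mean": [int(grey[i]) for i, _, _, _ in rows],
            "Y_grey": _GREY_Y,
            "col": [float(col[i]) for i, _, _, _ in rows],
        }
    ).sort_values(["individual_id", "occasion"], kind="stable").reset_index(drop=True)

    histories = []
    for i in range(s.N):
        histories.append(
            rec.EncounterHistory(
                individual_id=f"s{i:05d}",
                first_capture=int(entry[i]) + 1,
                codes=codes[i],
                colour=float(col[i]),
                stage_at_first="juvenile" if stage0[i] == 0 else "adult",
                site=site,
            )
        )
    return SimulatedDataset(
        records=recs,
        histories=histories,
        latent_states=states,
        truth=_truth_dump(s),
        scenario=s,
    )


def simulate_microhabitat(
    records: pd.DataFrame,
    colour_slope: float,
    stage_offsets: dict[str, float] | None = None,
    seed: int = 0,
    winter_months: Sequence[int] = (12, 1, 2),
    month_sd: float = 0.5,
    individual_sd: float = 0.5,
) -> pd.DataFrame:
    """Fill the microhabitat column of live records from a logit model.

    Arboreal use is drawn with probability
    ``logit^-1(offset_stage + slope * col + u_month + u_individual)``;
    records in winter months are set to hibernation regardless (hibernating
    snails are always under the leaf litter).  Dead records keep their
    microhabitat untouched.
    """
    stage_offsets = stage_offsets or {"juvenile": 2.0, "adult": 1.0}
    rng = np.random.default_rng(seed)
    out = records.copy()
    u_month = {m: rng.normal(0, month_sd) for m in range(1, 13)}
    u_ind = {i: rng.normal(0, individual_sd) for i in out["individual_id"].unique()}
    live = out["status"] == "live"
    eta = np.array(
        [
            stage_offsets[st] + colour_slope * c + u_month[m] + u_ind[i]
            for st, c, m, i in zip(
                out["stage"], out["col"], out["calendar_month"], out["individual_id"]
            )
        ]
    )
    arboreal = rng.uniform(size=len(out)) < _expit(eta)
    out.loc[live, "microhabitat"] = np.where(arboreal[live], "arboreal", "ground")
    winter = out["calendar_month"].isin(winter_months) & live
    out.loc[winter, "microhabitat"] = "hibernation"
    return out


def truth_report(dataset: SimulatedDataset, summary: pd.DataFrame) -> pd.DataFrame:
    """Score a posterior summary against the simulation truth.

    One row per parameter present in both the truth dump and the summary:
    truth, posterior median, 95% BCI, coverage flag and the standardised
    error (median - truth) / posterior SD.
    """
    if len(summary) == 0:
        raise ValueError("empty posterior summary")
    rows = []
    for name, truth in dataset.truth.items():
        if name not in summary.index:
            continue
        r = summary.loc[name]
        sd = float(r["sd"])
        rows.append(
            {
                "parameter": name,
                "truth": truth,
                "median": float(r["median"]),
                "lower": float(r["q2.5"]),
                "upper": float(r["q97.5"]),
                "covered": bool(r["q2.5"] <= truth <= r["q97.5"]),
                "std_error": (float(r["median"]) - truth) / sd if sd > 0 else np.nan,
            }
        )
    if not rows:
        raise ValueError("no parameter names shared between truth and summary")
    return pd.DataFrame(rows).set_index("parameter")
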