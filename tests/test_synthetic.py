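"""Synthetic-data generator: colour mixtures, state-space simulation,
microhabitat layer and parameter-recovery scoring."""

import numpy as np
import pandas as pd
import pytest

from snailselect import records as rec
from snailselect.field_stats import microhabitat_glmm
from snailselect.model import DemographicParams, DetectionParams, QuadraticSurvivalParams
from snailselect.model.likelihood import loglik_all
from snailselect.model.matrices import transition_matrix
from snailselect.model.mcmc import _prepare
from snailselect.synthetic import (
    SimulationScenario,
    SimulatedDataset,
    recovery_scenario,
    simulate_colours,
    simulate_microhabitat,
    simulate_population,
    truth_report,
)


class TestSimulateColours:
    def test_mainland_unimodal_symmetry(self):
        scen = SimulationScenario(N=5000, seed=1)
        col = simulate_colours(scen)["col"]
        from scipy.stats import skew

        assert abs(skew(col)) < 0.1
        assert col.mean() == pytest.approx(0, abs=1e-12)
        assert col.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_island_bimodal_structure(self):
        scen = SimulationScenario(N=5000, colour_profile="island_bimodal", seed=2)
        ratio = simulate_colours(scen)["ratio"]
        hist, edges = np.histogram(ratio, bins=30)
        centers = (edges[:-1] + edges[1:]) / 2
        # modes near the two components, separated by a dip
        lo_peak = hist[centers < 0.78].max()
        hi_peak = hist[centers >= 0.78].max()
        dip = hist[(centers > 0.70) & (centers < 0.85)].min()
        assert dip < 0.5 * min(lo_peak, hi_peak)

    def test_seed_determinism(self):
        scen = SimulationScenario(N=100, seed=9)
        c1 = simulate_colours(scen)["col"]
        c2 = simulate_colours(scen)["col"]
        assert np.array_equal(c1, c2)


class TestSimulatePopulation:
    def test_deterministic_limit_everyone_observed(self):
        scen = SimulationScenario(
            N=40, T=6,
            surv_j=QuadraticSurvivalParams(mu=30, beta=0, gamma=0),
            surv_a=QuadraticSurvivalParams(mu=30, beta=0, gamma=0),
            demog=DemographicParams(
                predation_juvenile=0, predation_adult=0, fidelity=1,
                psi=np.zeros(12),
            ),
            detect=DetectionParams(a=np.full(12, 30.0), g=np.full(12, 30.0)),
            entry_span=3, seed=5,
        )
        ds = simulate_population(scen)
        for h in ds.histories:
            post = h.codes[h.first_capture - 1 :]
            assert np.all(np.isin(post, [1, 4]))  # alive and seen every time

    def test_predated_fraction_binomial(self):
        m = 0.05
        scen = SimulationScenario(
            N=10_000, T=2,
            surv_j=QuadraticSurvivalParams(mu=2, beta=0, gamma=0),
            surv_a=QuadraticSurvivalParams(mu=2, beta=0, gamma=0),
            demog=DemographicParams(
                predation_juvenile=m, predation_adult=m, fidelity=1.0,
                psi=np.zeros(12),
            ),
            entry_span=1, seed=6,
        )
        ds = simulate_population(scen)
        predated = np.isin(ds.latent_states[:, 1], [2, 5]).mean()
        se = np.sqrt(m * (1 - m) / scen.N)
        assert abs(predated - m) < 3 * se

    def test_transition_frequencies_match_matrix(self):
        scen = recovery_scenario(seed=8, N=4000, T=4)
        ds = simulate_population(scen)
        months = scen.months
        # pool intervals that share a calendar month and start from alive-J-in
        for t in (1, 2, 3):
            mo = months[t]
            prev = ds.latent_states[:, t - 1]
            cur = ds.latent_states[:, t]
            mask = prev == 0
            if mask.sum() < 500:
                continue
            col = np.array([h.colour for h in ds.histories])[mask]
            # expected cell probabilities vary with colour; compare to the mean
            eps = 0.0
            probs = []
            for c in col:
                S_J = 1 / (1 + np.exp(-(float(scen.surv_j.eta(c)) + scen.surv_j.B[mo - 1])))
                S_A = 1 / (1 + np.exp(-(float(scen.surv_a.eta(c)) + scen.surv_a.B[mo - 1])))
                G = transition_matrix(
                    (S_J, S_A),
                    (scen.demog.predation_juvenile, scen.demog.predation_adult),
                    scen.demog.fidelity, scen.demog.psi[mo - 1],
                )
                probs.append(G[0])
            expected = np.mean(probs, axis=0)
            for dest in range(13):
                obs = np.mean(cur[mask] == dest)
                # heterogeneity widens the spread slightly: allow 4 SE + eps
                se = np.sqrt(max(expected[dest] * (1 - expected[dest]), 1e-6) / mask.sum())
                assert abs(obs - expected[dest]) < 4 * se + 0.02

    def test_histories_validate_cleanly(self, small_dataset):
        violations = [
            v for h in small_dataset.histories for v in rec.validate_history(h)
        ]
        assert violations == []

    def test_records_roundtrip_through_builder(self, small_dataset):
        """Records written by the simulator rebuild into the simulated codes."""
        df = small_dataset.records
        parsed = rec.read_records(_csv_io(df))
        built = rec.build_histories(parsed, T=small_dataset.scenario.T)
        built_by_id = {h.individual_id: h for h in built}
        for h in small_dataset.histories:
            if h.individual_id not in built_by_id:
                continue
            b = built_by_id[h.individual_id]
            # builder sees only observed events; codes must agree exactly
            assert np.array_equal(b.codes, h.codes)
            assert b.first_capture == h.first_capture


def _csv_io(df: pd.DataFrame):
    import io

    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return buf


class TestSimulateMicrohabitat:
    def test_winter_months_hibernate(self, small_dataset):
        out = simulate_microhabitat(
            small_dataset.records, colour_slope=0.0, seed=1,
            winter_months=(12, 1, 2),
        )
        winter_live = out[(out["calendar_month"].isin([12, 1, 2])) & (out["status"] == "live")]
        assert (winter_live["microhabitat"] == "hibernation").all()

    def test_zero_slope_recovered_within_two_se(self):
        scen = SimulationScenario(N=600, T=10, seed=3, entry_span=6)
        ds = simulate_population(scen)
        out = simulate_microhabitat(ds.records, colour_slope=0.0, seed=4,
                                    winter_months=())
        recs = [r for r in rec.read_records(_csv_io(out))
                if r.status == "live" and r.microhabitat != "hibernation"]
        res = microhabitat_glmm(
            [r for r in recs if r.stage == "adult"], stage="adult", site="mainland"
        )
        assert abs(res.coef("colour")) < 2 * res.se("colour") + 0.05

    def test_negative_slope_sign_power(self):
        """A slope like the island adult fit is detected with the right sign
        in most replicates."""
        hits = 0
        for rep in range(10):
            scen = SimulationScenario(N=500, T=10, seed=100 + rep, entry_span=6)
            ds = simulate_population(scen)
            out = simulate_microhabitat(ds.records, colour_slope=-0.8,
                                        seed=200 + rep, winter_months=())
            recs = [r for r in rec.read_records(_csv_io(out))
                    if r.status == "live" and r.stage == "adult"]
            res = microhabitat_glmm(recs, stage="adult", site="mainland")
            hits += res.coef("colour") < 0
        assert hits >= 8


class TestTruthReport:
    def test_coverage_flag(self, small_dataset):
        summ = pd.DataFrame(
            {
                "median": [0.01, 2.0],
                "sd": [0.5, 0.5],
                "q2.5": [-1.0, 1.5],
                "q97.5": [1.0, 2.5],
            },
            index=["beta_A", "gamma_A"],
        )
        rep = truth_report(small_dataset, summ)
        assert bool(rep.loc["beta_A", "covered"]) is True  # truth beta_A = 0
        assert bool(rep.loc["gamma_A", "covered"]) is False  # truth gamma_A = -1

    def test_empty_summary_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            truth_report(small_dataset, pd.DataFrame())

    def test_no_shared_names_rejected(self, small_dataset):
        summ = pd.DataFrame({"median": [1.0], "sd": [1.0], "q2.5": [0.0],
                             "q97.5": [2.0]}, index=["nonexistent"])
        with pytest.raises(ValueError):
            truth_report(small_dataset, summ)


def test_local_identifiability_at_perfect_detection(rng):
    """With detection and recovery certain, the truth parameters sit at a
    local optimum: random perturbations rarely raise the likelihood."""
    scen = SimulationScenario(
        N=600, T=8,
        surv_j=QuadraticSurvivalParams(mu=1.2, beta=0.2, gamma=-0.8, sigma_eps=0.0),
        surv_a=QuadraticSurvivalParams(mu=1.0, beta=-0.2, gamma=-0.8, sigma_eps=0.0),
        demog=DemographicParams(
            predation_juvenile=0.05, predation_adult=0.08, fidelity=0.92,
            psi=np.full(12, 0.15),
        ),
        detect=DetectionParams(a=np.full(12, 12.0), g=np.full(12, 12.0)),
        entry_span=4, seed=17,
    )
    ds = simulate_population(scen)
    codes, first, stage0, month0, col = _prepare(ds.histories, scen.months)
    N = col.size
    z = np.zeros(N)

    def total_ll(mu_j, b_j, g_j, mu_a, b_a, g_a, lm_j, lm_a, lf):
        eta_j = mu_j + b_j * col + 0.5 * g_j * col**2
        eta_a = mu_a + b_a * col + 0.5 * g_a * col**2
        return loglik_all(
            codes, first, stage0, month0, eta_j, eta_a, z, z,
            scen.surv_j.B, scen.surv_a.B,
            1 / (1 + np.exp(-lm_j)), 1 / (1 + np.exp(-lm_a)),
            1 / (1 + np.exp(-lf)), scen.demog.psi,
            scen.detect.a, scen.detect.g, 0.0, 0.0, col, z,
        ).sum()

    truth = np.array([
        1.2, 0.2, -0.8, 1.0, -0.2, -0.8,
        np.log(0.05 / 0.95), np.log(0.08 / 0.92), np.log(0.92 / 0.08),
    ])
    ll0 = total_ll(*truth)
    wins = 0
    n_dir = 40
    for _ in range(n_dir):
        direction = rng.normal(size=truth.size)
        direction /= np.linalg.norm(direction)
        ll1 = total_ll(*(truth + 0.5 * direction))
        wins += ll0 >= ll1
    assert wins >= int(0.95 * n_dir)
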