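"""Fisher exact tests, FDR control and the binomial mixed models."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snailselect import field_stats as fs
from snailselect.glmm import fit_binomial_glmm
from snailselect.records import SnailRecord


class TestFisherExact:
    def test_symmetric_table(self):
        res = fs.fisher_exact(fs.ContingencyTable2x2(1, 1, 1, 1))
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p_two_sided"] == pytest.approx(1.0)

    def test_sample_odds_ratio(self):
        res = fs.fisher_exact(fs.ContingencyTable2x2(10, 10, 1, 10))
        assert res["odds_ratio"] == pytest.approx(10.0)

    def test_full_enumeration_extreme_table(self):
        # (5,0;0,5): only 2 of the C(10,5)=252 margin-consistent tables are
        # as improbable as the observed one
        res = fs.fisher_exact(fs.ContingencyTable2x2(5, 0, 0, 5))
        assert res["p_two_sided"] == pytest.approx(2 / 252)
        assert np.isinf(res["odds_ratio"])
        assert res["flag"] is not None

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, size=4)
            if a + b + c + d == 0:
                continue
            ours = fs.fisher_exact(fs.ContingencyTable2x2(a, b, c, d))
            ref = stats.fisher_exact([[a, b], [c, d]])
            assert ours["p_two_sided"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_row_and_column_swap_invariance(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 20, size=4) + 1
            p1 = fs.fisher_exact(fs.ContingencyTable2x2(a, b, c, d))["p_two_sided"]
            p2 = fs.fisher_exact(fs.ContingencyTable2x2(d, c, b, a))["p_two_sided"]
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fs.ContingencyTable2x2(-1, 2, 3, 4)


def _bh_oracle(p, alpha):
    """Literal step-up definition, independent of statsmodels."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    k = 0
    for rank in range(1, m + 1):
        if p[order[rank - 1]] <= rank * alpha / m:
            k = rank
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return q, reject


class TestBhFdr:
    def test_single_p(self):
        res = fs.bh_fdr([0.03])
        assert res["q_values"][0] == pytest.approx(0.03)
        assert res["reject_flags"][0]

    def test_step_up_by_hand(self):
        res = fs.bh_fdr([0.01, 0.02, 0.04, 0.5])
        # thresholds k*0.05/4: 0.0125, 0.025, 0.0375, 0.05 -> reject first two
        assert list(res["reject_flags"]) == [True, True, False, False]

    def test_all_ones(self):
        res = fs.bh_fdr([1.0, 1.0, 1.0])
        assert not res["reject_flags"].any()
        assert np.all(res["q_values"] == 1.0)

    def test_against_oracle_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 15))
            res = fs.bh_fdr(p, alpha=0.05)
            q_ref, rej_ref = _bh_oracle(p, 0.05)
            assert res["q_values"] == pytest.approx(q_ref, abs=1e-12)
            assert np.array_equal(res["reject_flags"], rej_ref)

    def test_rejection_monotonicity(self, rng):
        p = rng.uniform(size=10)
        base = fs.bh_fdr(p)["reject_flags"]
        p2 = p.copy()
        p2[3] = p2[3] / 2
        lowered = fs.bh_fdr(p2)["reject_flags"]
        assert lowered.sum() >= base.sum()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fs.bh_fdr([0.5, 1.5])


def _dead_records(rng, n=600, months=6, stage_lor=1.5, colour_lor=0.0):
    recs = []
    u = rng.normal(0, 0.5, months)
    for i in range(n):
        month = int(rng.integers(1, months + 1))
        col = float(rng.normal())
        adult = int(rng.integers(0, 2))
        eta = -1.0 + colour_lor * col + stage_lor * adult + u[month - 1]
        predated = rng.uniform() < 1 / (1 + np.exp(-eta))
        recs.append(
            SnailRecord(
                f"d{i}", 2, month, "mainland",
                "adult" if adult else "juvenile", "ground",
                "dead_predated" if predated else "dead_other", colour=col,
            )
        )
    return recs


class TestPredationGlmm:
    def test_recovers_stage_effect(self, rng):
        res = fs.predation_glmm(_dead_records(rng))
        assert abs(res.coef("stage") - 1.5) < 0.5
        assert abs(res.coef("colour") / res.se("colour")) < 3.0
        assert res.converged

    def test_all_same_outcome_flagged(self):
        recs = [
            SnailRecord(f"d{i}", 2, 1 + i % 3, "mainland", "adult", "ground",
                        "dead_other", colour=float(i % 5 - 2))
            for i in range(30)
        ]
        res = fs.predation_glmm(recs)
        assert any("separation" in f for f in res.flags)

    def test_zero_variance_matches_pooled_logistic(self, rng):
        # single-month data: random effect is dropped, and the fit must match
        # an ordinary logistic regression
        import statsmodels.api as sm

        recs = _dead_records(rng, n=400, months=1)
        res = fs.predation_glmm(recs)
        y = np.array([r.status == "dead_predated" for r in recs], float)
        col = np.array([r.colour for r in recs])
        ad = np.array([r.stage == "adult" for r in recs], float)
        X = np.column_stack([np.ones_like(y), col, ad, col * ad])
        ref = sm.Logit(y, X).fit(disp=0)
        assert res.table["estimate"].to_numpy() == pytest.approx(ref.params, abs=0.05)

    def test_live_records_rejected(self):
        with pytest.raises(ValueError):
            fs.predation_glmm(
                [SnailRecord("x", 1, 1, "mainland", "adult", "ground", "live")]
            )


def _habitat_records(rng, n_ind=300, slope=-0.3, site="island", stage="adult"):
    recs = []
    u_ind = rng.normal(0, 0.5, n_ind)
    u_month = rng.normal(0, 0.5, 12)
    for i in range(n_ind):
        col = float(rng.normal())
        for _ in range(int(rng.integers(1, 5))):
            month = int(rng.integers(3, 12))
            eta = 1.0 + slope * col + u_ind[i] + u_month[month - 1]
            arboreal = rng.uniform() < 1 / (1 + np.exp(-eta))
            recs.append(
                SnailRecord(
                    f"i{i}", 2, month, site, stage,
                    "arboreal" if arboreal else "ground", "live", colour=col,
                )
            )
    return recs


class TestMicrohabitatGlmm:
    def test_recovers_colour_slope(self, rng):
        res = fs.microhabitat_glmm(
            _habitat_records(rng), stage="adult", site="island"
        )
        est, se = res.coef("colour"), res.se("colour")
        assert abs(est - (-0.3)) < 2 * se

    def test_hibernation_rows_rejected(self):
        recs = [SnailRecord("a", 1, 1, "mainland", "adult", "hibernation", "live")]
        with pytest.raises(ValueError, match="hibernation"):
            fs.microhabitat_glmm(recs, stage="adult", site="mainland")

    def test_constant_colour_rejected(self):
        recs = [
            SnailRecord(f"a{i}", 1, 1 + i % 3, "mainland", "adult",
                        "ground" if i % 2 else "arboreal", "live", colour=0.0)
            for i in range(20)
        ]
        with pytest.raises(ValueError, match="constant"):
            fs.microhabitat_glmm(recs, stage="adult", site="mainland")


class TestMicrohabitatPairwise:
    @staticmethod
    def _group(site, stage, ground, arboreal, rng):
        out = []
        for k in range(ground + arboreal):
            out.append(
                SnailRecord(
                    f"{site}-{stage}-{k}", 1, 5, site, stage,
                    "ground" if k < ground else "arboreal", "live",
                    colour=float(rng.normal()),
                )
            )
        return out

    def test_six_comparisons_and_fdr(self, rng):
        recs = []
        for site in ("mainland", "island"):
            for stage in ("juvenile", "adult"):
                recs += self._group(site, stage, 20, 20, rng)
        out = fs.microhabitat_pairwise(recs)
        assert len(out) == 6
        assert not out["reject"].any()  # identical groups: all p = 1
        assert np.allclose(out["p"], 1.0)

    def test_strong_contrast_rejected(self, rng):
        recs = (
            self._group("mainland", "adult", 90, 10, rng)
            + self._group("island", "adult", 10, 90, rng)
            + self._group("mainland", "juvenile", 50, 50, rng)
            + self._group("island", "juvenile", 50, 50, rng)
        )
        out = fs.microhabitat_pairwise(recs).set_index("comparison")
        key = "mainland-adult vs island-adult"
        assert out.loc[key, "p"] < 1e-10
        assert out.loc[key, "reject"]

    def test_empty_group_skipped(self, rng):
        recs = self._group("mainland", "adult", 10, 10, rng) + self._group(
            "island", "adult", 10, 10, rng
        )
        out = fs.microhabitat_pairwise(recs)
        assert len(out) == 6
        assert out["p"].notna().sum() == 1  # only the one testable pair


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_glmm_matches_lme4_oracle(tmp_path, rng):
    """Cross-check the Laplace GLMM against lme4::glmer on one dataset."""
    n = 500
    col = rng.normal(size=n)
    month = rng.integers(1, 8, size=n)
    u = rng.normal(0, 0.7, 7)
    eta = -0.5 + 0.6 * col + u[month - 1]
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
    df = pd.DataFrame({"y": y, "col": col, "month": month})
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = (
        "suppressMessages(library(lme4));"
        f"d <- read.csv('{csv}');"
        "f <- glmer(y ~ col + (1|month), data=d, family=binomial);"
        "cat(fixef(f), sqrt(diag(vcov(f))), sep=',')"
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    b0, b1, se0, se1 = map(float, out.stdout.strip().split(","))
    X = np.column_stack([np.ones(n), col])
    res = fit_binomial_glmm(X, y, {"month": month}, ["intercept", "col"])
    assert res.coef("intercept") == pytest.approx(b0, abs=0.02)
    assert res.coef("col") == pytest.approx(b1, abs=0.02)
    assert res.se("col") == pytest.approx(se1, rel=0.1)
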