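import numpy as np
import pandas as pd
import pytest

from cernet.datatypes import SurvivalTable
from cernet.survival import (
    cox_fit,
    km_cumhaz,
    nelson_aalen,
    signature_zscore,
    stratify_median,
)
from cernet.synthetic import SimulationConfig, simulate_survival

from conftest import make_dataset


def surv_table(times, events, samples=None):
    samples = samples or [f"P{i}" for i in range(len(times))]
    return SurvivalTable(
        data=pd.DataFrame(
            {"time": times, "event": events}, index=pd.Index(samples, name="sample")
        )
    )


class TestSignatureZscore:
    def test_single_gene_signature_is_that_genes_zscores(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(3, 20))
        ds = make_dataset(vals)
        res = signature_zscore(ds, ["G1"])
        row = vals[1]
        expected = (row - row.mean()) / row.std()
        np.testing.assert_allclose(res.scores.to_numpy(), expected, atol=1e-12)

    def test_scores_have_zero_mean(self, toy_dataset):
        res = signature_zscore(toy_dataset, ["G1", "G2", "G3"])
        assert abs(res.scores.mean()) < 1e-10

    def test_two_gene_hand_computation(self):
        ds = make_dataset([[0, 0, 0, 0], [1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        res = signature_zscore(ds, ["G1", "G2"])
        # the two genes' z-scores are mirror images: mean is identically 0
        np.testing.assert_allclose(res.scores.to_numpy(), np.zeros(4), atol=1e-12)
        z1 = (np.array([1, 2, 3, 4]) - 2.5) / np.std([1, 2, 3, 4])
        res1 = signature_zscore(ds, ["G1"])
        np.testing.assert_allclose(res1.scores.to_numpy(), z1, atol=1e-12)

    def test_absent_signature_is_error(self, toy_dataset):
        with pytest.raises(KeyError, match="mystery"):
            signature_zscore(toy_dataset, ["NOPE"], signature_name="mystery")

    def test_zero_variance_gene_excluded_with_warning(self):
        ds = make_dataset([[0, 0, 0, 0], [5.0, 5.0, 5.0, 5.0], [1.0, 2.0, 3.0, 4.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            res = signature_zscore(ds, ["G1", "G2"])
        assert res.n_genes_used == 1


class TestStratifyMedian:
    def test_even_split(self):
        scores = pd.Series([-1.0, 0.0, 1.0, 2.0], index=list("abcd"))
        groups = stratify_median(scores)
        assert list(groups) == ["low", "low", "high", "high"]

    def test_median_tie_goes_low(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        groups = stratify_median(scores)
        assert groups["b"] == "low" and groups["c"] == "high"

    def test_all_identical_is_error(self):
        with pytest.raises(ValueError, match="cannot stratify"):
            stratify_median(pd.Series([1.0, 1.0, 1.0]))

    def test_distinct_scores_balanced_within_one(self):
        rng = np.random.default_rng(1)
        for n in (5, 6, 17, 40):
            scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
            g = stratify_median(scores)
            assert abs((g == "high").sum() - (g == "low").sum()) <= 1


class TestNelsonAalen:
    def test_single_subject_event(self):
        na = nelson_aalen(np.array([5.0]), np.array([1]))
        assert len(na) == 1
        assert na.loc[0, "increment"] == 1.0 and na.loc[0, "cumhaz"] == 1.0

    def test_all_censored_flat_zero(self):
        na = nelson_aalen(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))
        assert len(na) == 0

    def test_six_subject_fixture_increments(self):
        na = nelson_aalen(
            np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]), np.array([1, 1, 0, 1, 0, 1])
        )
        np.testing.assert_array_equal(na["increment"], [1 / 6, 1 / 5, 1 / 3, 1 / 1])
        assert na["cumhaz"].iloc[-1] == pytest.approx(1 / 6 + 1 / 5 + 1 / 3 + 1)

    def test_tied_events_use_d_over_n(self):
        na = nelson_aalen(np.array([2.0, 2.0, 5.0]), np.array([1, 1, 1]))
        np.testing.assert_allclose(na["increment"], [2 / 3, 1.0])


class TestKmCumhaz:
    def _groups(self, labels, samples=None):
        samples = samples or [f"P{i}" for i in range(len(labels))]
        return pd.Series(labels, index=samples, name="group")

    def test_per_group_curves_and_logrank(self):
        rng = np.random.default_rng(5)
        n = 120
        groups = self._groups(["high"] * (n // 2) + ["low"] * (n // 2))
        times = np.concatenate([rng.exponential(5, n // 2), rng.exponential(20, n // 2)])
        table = surv_table(times, np.ones(n, dtype=int))
        out = km_cumhaz(groups, table)
        assert set(out["curves"]) == {"high", "low"}
        assert out["logrank_p"] < 0.01

        # the high-hazard group accumulates more hazard by any common time
        def at(curve, t):
            past = curve[curve["time"] <= t]
            return past["cumhaz"].iloc[-1] if len(past) else 0.0

        assert at(out["curves"]["high"], 5.0) > at(out["curves"]["low"], 5.0)

    def test_logrank_invariant_to_monotone_time_transform(self):
        rng = np.random.default_rng(6)
        n = 60
        groups = self._groups(["high"] * 30 + ["low"] * 30)
        times = rng.exponential(10, n)
        events = rng.integers(0, 2, n)
        events[0] = 1
        t1 = km_cumhaz(groups, surv_table(times, events))
        t2 = km_cumhaz(groups, surv_table(np.log1p(times), events))
        assert t1["logrank_stat"] == pytest.approx(t2["logrank_stat"], rel=1e-9)

    def test_no_events_anywhere_is_error(self):
        groups = self._groups(["high", "low", "high", "low"])
        with pytest.raises(ValueError, match="no events"):
            km_cumhaz(groups, surv_table([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0]))

    def test_zero_event_group_is_flat_but_comparable(self):
        groups = self._groups(["high"] * 10 + ["low"] * 10)
        times = list(range(1, 11)) + list(range(1, 11))
        events = [1] * 10 + [0] * 10
        out = km_cumhaz(groups, surv_table(times, events))
        assert len(out["curves"]["low"]) == 0
        assert np.isfinite(out["logrank_p"])


class TestCoxFit:
    def _sim(self, seed, n=2000, beta=0.7):
        rng = np.random.default_rng(seed)
        z = pd.Series(rng.normal(size=n), index=[f"P{i}" for i in range(n)])
        cfg = SimulationConfig(seed=seed, hazard_beta=beta)
        table = simulate_survival(cfg, z)
        return z, table

    def test_recovers_generative_log_hazard(self):
        z, table = self._sim(seed=100)
        est = cox_fit(table, pd.DataFrame({"z": z}), mode="univariable")[0]
        assert np.log(est.hr) == pytest.approx(0.7, abs=0.1)
        assert est.ci_low <= est.hr <= est.ci_high

    def test_null_predictor_small_effect(self):
        z, table = self._sim(seed=101, beta=0.0)
        est = cox_fit(table, pd.DataFrame({"z": z}), mode="univariable")[0]
        assert abs(np.log(est.hr)) < 0.1

    def test_time_scale_invariance(self):
        z, table = self._sim(seed=102, n=500)
        est1 = cox_fit(table, pd.DataFrame({"z": z}), mode="univariable")[0]
        doubled = SurvivalTable(data=table.data.assign(time=table.data["time"] * 2))
        est2 = cox_fit(doubled, pd.DataFrame({"z": z}), mode="univariable")[0]
        assert est1.hr == pytest.approx(est2.hr, rel=1e-6)

    def test_multivariable_joint_fit(self):
        z, table = self._sim(seed=103, n=1000)
        rng = np.random.default_rng(9)
        noise = pd.Series(rng.normal(size=len(z)), index=z.index)
        ests = cox_fit(
            table, pd.DataFrame({"z": z, "noise": noise}), mode="multivariable"
        )
        by_var = {e.variable: e for e in ests}
        assert set(by_var) == {"z", "noise"}
        assert np.log(by_var["z"].hr) == pytest.approx(0.7, abs=0.15)
        assert abs(np.log(by_var["noise"].hr)) < 0.15

    def test_constant_predictor_is_error(self):
        _, table = self._sim(seed=104, n=50)
        const = pd.Series(1.0, index=table.data.index)
        with pytest.raises(ValueError, match="constant predictor"):
            cox_fit(table, pd.DataFrame({"c": const}))

    def test_few_events_warns(self):
        table = surv_table([1, 2, 3, 4, 5, 6, 7, 8], [1, 0, 0, 0, 1, 0, 0, 0])
        z = pd.Series(
            [0.1, -0.2, 0.3, 0.5, -0.4, 0.2, -0.1, 0.6], index=table.data.index
        )
        with pytest.warns(UserWarning, match="events"):
            cox_fit(table, pd.DataFrame({"z": z}))
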