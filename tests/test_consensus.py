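import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernet.consensus import (
    build_consensus,
    combined_correlation_score,
    consensus_pipeline,
    correlate_with_anchor,
    detect_correlated,
    quartile_subset,
    single_cohort_partners,
    spearman_rho_p,
)
from cernet.synthetic import SimulationConfig, simulate_study

from conftest import make_dataset


def brute_force_spearman(x, y):
    """Rank-formula oracle: Pearson correlation of average ranks."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestSpearman:
    def test_identical_values_give_rho_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0, 6.0, 5.3, 5.8, 9.7, 9.3])
        rho, p, n = spearman_rho_p(x, x)
        assert rho == pytest.approx(1.0)
        assert n == len(x)

    def test_rank_reversal_over_8_samples_exact_p(self):
        x = np.arange(8.0)
        rho, p, _ = spearman_rho_p(x, x[::-1])
        assert rho == pytest.approx(-1.0)
        # only the two extreme permutations reach |rho| = 1
        assert p == pytest.approx(2 / math.factorial(8))

    def test_five_sample_toy_matches_rank_formula(self):
        anchor = [1.0, 2.0, 3.0, 4.0, 5.0]
        gene = [2.0, 1.0, 4.0, 3.0, 5.0]
        rho, _, _ = spearman_rho_p(np.array(anchor), np.array(gene))
        # d^2 = 1+1+1+1+0 -> 1 - 6*4/(5*24) = 0.8
        assert rho == pytest.approx(0.8)
        assert rho == pytest.approx(brute_force_spearman(anchor, gene))

    def test_exact_p_matches_enumeration_counting(self):
        # enumerate the n=5 null directly and compare the returned p
        anchor = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        gene = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        rho_obs, p, _ = spearman_rho_p(anchor, gene)
        count = sum(
            abs(brute_force_spearman(anchor, perm)) >= abs(rho_obs) - 1e-12
            for perm in itertools.permutations(gene)
        )
        assert p == pytest.approx(count / math.factorial(5))

    def test_pairwise_complete_uses_only_shared_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, np.nan, 6.0, 7.0, 8.0, 9.0, 1.5, 2.5, 3.5])
        y = np.array([np.nan, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 1.1, 2.1, 3.1])
        rho, _, n = spearman_rho_p(x, y)
        assert n == 10
        mask = ~(np.isnan(x) | np.isnan(y))
        assert rho == pytest.approx(brute_force_spearman(x[mask], y[mask]))

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            spearman_rho_p(np.array([1.0, 2.0]), np.array([2.0, 1.0]))

    def test_constant_anchor_is_error(self):
        ds = make_dataset([[1.0] * 12, list(range(12))])
        with pytest.raises(ValueError, match="zero variance"):
            correlate_with_anchor(ds)


class TestDetection:
    def test_thresholds_are_strict(self):
        records = pd.DataFrame(
            {
                "gene": ["AT_RHO", "AT_P", "PASS", "NEG"],
                "rho": [0.25, 0.5, 0.5, -0.9],
                "p": [0.01, 0.05, 0.01, 1e-9],
            }
        )
        assert detect_correlated(records) == {"PASS"}

    def test_high_rho_high_p_excluded(self):
        records = pd.DataFrame({"gene": ["G"], "rho": [0.9], "p": [0.2]})
        assert detect_correlated(records) == set()

    def test_null_cohort_pass_fraction_within_joint_bound(self):
        # Monte-Carlo: under independence the pass rate must respect the
        # joint bound P(p<0.05 and rho>0.25) <= P(rho>0.25)
        rng = np.random.default_rng(42)
        n_genes, n_samples = 1000, 30
        ds = make_dataset(rng.normal(size=(n_genes + 1, n_samples)))
        records = correlate_with_anchor(ds)
        passed = len(detect_correlated(records))
        from scipy import stats

        t0 = 0.25 * np.sqrt((n_samples - 2) / (1 - 0.25**2))
        bound = float(stats.t.sf(t0, df=n_samples - 2))
        assert passed / n_genes <= bound + 3 * math.sqrt(bound * (1 - bound) / n_genes)


class TestConsensus:
    def _records(self, gene_rhos):
        rows = []
        for ds, pairs in gene_rhos.items():
            for gene, rho in pairs.items():
                rows.append({"gene": gene, "dataset_id": ds, "rho": rho, "p": 0.01, "n_pairs": 50})
        return pd.DataFrame(rows)

    def test_four_of_six_is_consensus_three_is_not(self):
        datasets = [f"D{i}" for i in range(1, 7)]
        detected = {ds: set() for ds in datasets}
        rhos = {ds: {} for ds in datasets}
        for ds in datasets[:4]:
            detected[ds].add("HIT4")
            rhos[ds]["HIT4"] = 0.4
        for ds in datasets[:3]:
            detected[ds].add("HIT3")
            rhos[ds]["HIT3"] = 0.5
        table = build_consensus(detected, self._records(rhos), min_datasets=4)
        assert table.consensus_genes() == ["HIT4"]
        assert table.n_detected()["HIT3"] == 3

    def test_too_few_datasets_is_error(self):
        with pytest.raises(ValueError, match="need >="):
            build_consensus({"D1": set()}, self._records({"D1": {"G": 0.3}}), min_datasets=4)

    def test_consensus_invariant_to_dataset_order(self):
        cfg = SimulationConfig(seed=5, n_samples=40, n_partners=8, n_decoys=30, n_decoy_mirnas=4)
        study = simulate_study(cfg)
        t1 = consensus_pipeline(study["datasets"])
        t2 = consensus_pipeline(list(reversed(study["datasets"])))
        assert t1.consensus_genes() == t2.consensus_genes()
        pd.testing.assert_series_equal(t1.ccs(), t2.ccs())

    def test_raising_thresholds_never_enlarges_consensus(self):
        cfg = SimulationConfig(seed=6, n_samples=60, n_partners=10, n_decoys=40, n_decoy_mirnas=4)
        study = simulate_study(cfg)
        loose = set(consensus_pipeline(study["datasets"], rho_min=0.25).consensus_genes())
        tight_rho = set(consensus_pipeline(study["datasets"], rho_min=0.4).consensus_genes())
        tight_k = set(
            consensus_pipeline(study["datasets"], rho_min=0.25, min_datasets=6).consensus_genes()
        )
        assert tight_rho <= loose and tight_k <= loose


class TestCCS:
    def test_constant_rhos(self):
        assert combined_correlation_score([0.4, 0.4, 0.4, 0.4]) == pytest.approx(0.4)

    def test_mean_and_sum_modes(self):
        assert combined_correlation_score([0.3, 0.5], mode="mean") == pytest.approx(0.4)
        assert combined_correlation_score([0.3, 0.5], mode="sum") == pytest.approx(0.8)

    def test_single_dataset_modes_coincide(self):
        assert combined_correlation_score([0.7], mode="mean") == combined_correlation_score(
            [0.7], mode="sum"
        )

    def test_no_detections_is_nan(self):
        assert math.isnan(combined_correlation_score([]))

    @settings(max_examples=20, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.26, max_value=1.0), min_size=1, max_size=6)
    )
    def test_mean_mode_matches_hand_arithmetic(self, rhos):
        assert combined_correlation_score(rhos, "mean") == pytest.approx(sum(rhos) / len(rhos))
        assert combined_correlation_score(rhos, "sum") == pytest.approx(sum(rhos))


class TestQuartiles:
    def test_eight_distinct_values(self):
        ds = make_dataset(
            np.vstack([np.arange(1.0, 9.0), np.arange(8.0, 0.0, -1.0)]),
        )
        top = quartile_subset(ds, "top")
        # 75th percentile of 1..8 is 6.25 -> samples with values 7, 8
        assert sorted(top.anchor_values()) == [7.0, 8.0]
        bottom = quartile_subset(ds, "bottom")
        assert sorted(bottom.anchor_values()) == [1.0, 2.0]

    def test_constant_anchor_is_error(self):
        ds = make_dataset(np.vstack([np.ones(10), np.arange(10.0)]))
        with pytest.raises(ValueError, match="zero variance"):
            quartile_subset(ds, "top")

    def test_too_few_samples_is_error(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(2, 7)))
        with pytest.raises(ValueError, match=">= 8"):
            quartile_subset(ds, "top")

    def test_quartile_sizes_on_100_samples(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(rng.normal(size=(2, 100)))
        top = quartile_subset(ds, "top")
        bottom = quartile_subset(ds, "bottom")
        assert len(top.samples) >= 25 and len(bottom.samples) >= 25
        assert len(top.samples) + len(bottom.samples) <= 100
        assert not set(top.samples) & set(bottom.samples)


class TestSingleCohortPartners:
    def test_boundaries_and_planted_subset(self):
        cfg = SimulationConfig(seed=9, n_samples=100, n_partners=10, n_decoys=40,
                               n_decoy_mirnas=4, contamination_rate=0.0)
        study = simulate_study(cfg)
        inter = study["interactome"].consensus()
        partners = single_cohort_partners(
            study["datasets"][0], inter, rho_min=0.5, min_shared_mres=4
        )
        assert partners <= study["truth"].partner_genes

    def test_shared_mre_boundary(self, small_interactome):
        # GENE_A shares exactly 2 families with the anchor: passes at
        # min_shared_mres=2, fails at 3, regardless of correlation
        rng = np.random.default_rng(0)
        anchor = rng.normal(size=40)
        values = np.vstack([anchor, anchor + 0.1 * rng.normal(size=40), rng.normal(size=40)])
        ds = make_dataset(values, genes=["ONECUT2", "GENE_A", "GENE_B"])
        assert single_cohort_partners(ds, small_interactome, min_shared_mres=2) == {"GENE_A"}
        assert single_cohort_partners(ds, small_interactome, min_shared_mres=3) == set()
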