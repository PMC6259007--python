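"""Generator faithfulness: precision construction, copula sampling, presets."""
from dataclasses import replace

import numpy as np
import pytest

import symnet as sn
from symnet.simulate import (
    _TABLE2_MOMENTS,
    preset_partials,
    thresholds_for_moments,
)


class TestBuildPrecision:
    def test_zero_partials_give_identity(self):
        K, factor = sn.build_precision(np.zeros((4, 4)))
        np.testing.assert_array_equal(K, np.eye(4))
        assert factor == 1.0

    def test_two_node_closed_form(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        K, factor = sn.build_precision(P)
        assert factor == 1.0
        net = sn.precision_to_partial(K)
        assert net.weights[0, 1] == pytest.approx(0.5)

    def test_chain_partials_recovered_through_inversion(self):
        P = np.zeros((6, 6))
        for i in range(5):
            P[i, i + 1] = P[i + 1, i] = 0.3
        K, factor = sn.build_precision(P)
        net = sn.precision_to_partial(K)
        np.testing.assert_allclose(net.weights, P * factor, atol=1e-6)

    def test_inflation_recorded_when_not_pd(self):
        # near-saturated equicorrelated partials force diagonal inflation
        p = 5
        P = np.full((p, p), 0.3)
        np.fill_diagonal(P, 0.0)
        K, factor = sn.build_precision(P)
        assert factor < 1.0
        assert np.linalg.eigvalsh(K).min() > 0
        net = sn.precision_to_partial(K)
        np.testing.assert_allclose(net.weights, P * factor, atol=1e-9)


class TestThresholds:
    @pytest.mark.parametrize("mean,sd", [(0.47, 0.95), (2.92, 1.22), (2.0, 1.3)])
    def test_marginal_mean_matched_in_expectation(self, mean, sd):
        thr = thresholds_for_moments(mean, sd)
        assert np.all(np.diff(thr) > 0)
        from scipy import stats

        probs = np.diff(np.concatenate([[0.0], stats.norm.cdf(thr), [1.0]]))
        assert probs @ np.arange(5) == pytest.approx(mean, abs=1e-9)

    def test_degenerate_targets_rejected(self):
        with pytest.raises(sn.ValidationError):
            thresholds_for_moments(0.0, 1.0)
        with pytest.raises(sn.ValidationError):
            thresholds_for_moments(2.0, 0.0)


class TestSampleOrdinal:
    def test_null_generator_produces_uncorrelated_items(self):
        p = 5
        spec = sn.ScenarioSpec(
            items=tuple(f"V{i}" for i in range(p)),
            partials=np.zeros((p, p)),
            thresholds=np.tile(thresholds_for_moments(2.0, 1.3), (p, 1)),
            n=20_000, seed=70,
        )
        X = sn.sample_ordinal(spec).scores
        R = np.corrcoef(X, rowvar=False)
        off = np.abs(R[np.triu_indices(p, 1)])
        assert off.max() < 0.03

    def test_table_marginal_mean_reproduced(self):
        spec = sn.preset_ptsd17("clinical", n=20_000, seed=71)
        X = sn.sample_ordinal(spec)
        e6 = X.scores[:, list(X.items).index("E6")]
        assert e6.mean() == pytest.approx(2.92, abs=0.05)

    def test_deterministic_given_seed(self):
        spec = sn.preset_ptsd17("clinical", n=100, seed=72)
        a = sn.sample_ordinal(spec)
        b = sn.sample_ordinal(spec)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_latent_correlations_converge_to_model(self):
        spec = sn.preset_ptsd17("clinical", n=50_000, seed=73)
        K, _ = sn.build_precision(spec.partials)
        C = sn.latent_correlation(K)
        Z = sn.sample_latent(spec)
        err = np.abs(np.corrcoef(Z, rowvar=False) - C).max()
        assert err <= 0.02

    def test_ordinal_scores_attenuate_latent_correlations(self):
        spec = sn.preset_ptsd17("clinical", n=50_000, seed=74)
        K, _ = sn.build_precision(spec.partials)
        C = sn.latent_correlation(K)
        X = sn.sample_ordinal(spec).scores
        R = np.corrcoef(X, rowvar=False)
        iu = np.triu_indices(len(spec.items), 1)
        strong = np.abs(C[iu]) > 0.1
        assert np.all(np.sign(R[iu][strong]) == np.sign(C[iu][strong]))
        assert np.all(np.abs(R[iu][strong]) < np.abs(C[iu][strong]))


class TestTwoGroupScenario:
    def test_unit_scale_shares_generator(self):
        spec = replace(sn.preset_ptsd17("clinical", n=50, seed=75))
        a, b = sn.two_group_scenario(spec)
        assert a.n_cases == b.n_cases == 50
        assert set(a.group) == {"A"} and set(b.group) == {"B"}

    def test_zero_scale_makes_second_group_independent(self):
        spec = replace(
            sn.preset_ptsd17("clinical", n=20_000, seed=76), connectivity_scale=0.0
        )
        _, b = sn.two_group_scenario(spec)
        R = np.corrcoef(b.scores, rowvar=False)
        assert np.abs(R[np.triu_indices(17, 1)]).max() < 0.03

    def test_scaled_group_has_lower_estimated_strength(self):
        wins = 0
        for s in range(10):
            spec = replace(
                sn.preset_ptsd17("clinical", n=2000, seed=80 + s),
                connectivity_scale=0.5,
            )
            a, b = sn.two_group_scenario(spec)
            na = sn.unregularized_partials(a)
            nb = sn.unregularized_partials(b)
            wins += np.abs(na.upper_weights()).sum() > np.abs(nb.upper_weights()).sum()
        assert wins >= 9

    def test_first_group_unchanged_by_scale(self):
        base = sn.preset_ptsd17("clinical", n=60, seed=77)
        a1, _ = sn.two_group_scenario(replace(base, connectivity_scale=1.0))
        a2, _ = sn.two_group_scenario(replace(base, connectivity_scale=0.2))
        np.testing.assert_array_equal(a1.scores, a2.scores)


class TestPresets:
    @pytest.mark.parametrize("group", list(_TABLE2_MOMENTS))
    def test_all_presets_valid_and_pd(self, group):
        spec = sn.preset_ptsd17(group)
        K, factor = sn.build_precision(spec.partials)
        assert np.linalg.eigvalsh(K).min() > 0
        assert factor == 1.0  # presets are PD without inflation
        assert np.all(np.diff(spec.thresholds, axis=1) > 0)

    def test_hypervigilance_startle_edge_is_strongest(self):
        P = preset_partials("clinical")
        iu = np.triu_indices(17, 1)
        i = int(np.argmax(P[iu]))
        labels = sn.PTSD17_ITEMS
        pair = {labels[iu[0][i]], labels[iu[1][i]]}
        assert pair == {"E3", "E4"}

    def test_amnesia_node_least_connected(self):
        P = preset_partials("clinical")
        strength = np.abs(P).sum(axis=1)
        assert np.argmin(strength) == sn.PTSD17_ITEMS.index("D1")

    def test_high_combat_boosts_intrusion_irritability_edge(self):
        lo = preset_partials("low_combat")
        hi = preset_partials("high_combat")
        i, j = sn.PTSD17_ITEMS.index("B1"), sn.PTSD17_ITEMS.index("E1")
        assert hi[i, j] > lo[i, j]

    def test_strongest_edge_recovered_from_samples(self):
        hits = 0
        for s in range(10):
            data = sn.sample_ordinal(sn.preset_ptsd17("clinical", n=5000, seed=200 + s))
            fit = sn.estimate_network(data, sn.EstimationConfig(n_lambda=40))
            uw = np.abs(fit.network.upper_weights())
            top3 = np.argsort(uw)[-3:]
            names = [set(fit.network.edge_labels()[k]) for k in top3]
            hits += {"E3", "E4"} in names
        assert hits >= 9


class TestTable1Fixture:
    def test_published_summary_records(self):
        fx = sn.table1_fixture()
        assert (fx.ces["subthreshold"].mean, fx.ces["subthreshold"].sd,
                fx.ces["subthreshold"].n) == (12.54, 9.62, 138)
        assert fx.gender["full"] == {"female": 170, "male": 742}
        assert (fx.age["low_combat"].mean, fx.age["low_combat"].sd,
                fx.age["low_combat"].n) == (37.00, 9.66, 639)

    def test_group_counts_consistent(self):
        fx = sn.table1_fixture()
        assert fx.gender["subthreshold"]["female"] + fx.gender["subthreshold"]["male"] == 138
        assert fx.gender["full"]["female"] + fx.gender["full"]["male"] == 912
        assert fx.race["low_combat"]["caucasian"] + fx.race["low_combat"]["non_caucasian"] == 639
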