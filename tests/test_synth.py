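import numpy as np
import pytest

from cytofingerprint import CommunitySpec, Component, SeriesSpec
from cytofingerprint.synth import (
    DNA_DOUBLING_SHIFT,
    simulate_community,
    simulate_groups,
    simulate_series,
    operator_gate_sets,
)
from conftest import iso_cov


class TestCommunitySpec:
    def test_fractions_must_sum_to_one(self):
        spec = CommunitySpec([Component((0.5, 0.5), iso_cov(0.01), 0.9, 0.0)])
        with pytest.raises(ValueError, match="sum"):
            spec.validate()

    @pytest.mark.parametrize("bad_cov", [
        ((1e-4, 1e-5), (0.0, 1e-4)),        # asymmetric
        ((1e-4, 2e-4), (2e-4, 1e-4)),       # not positive-definite
    ])
    def test_covariance_validation(self, bad_cov):
        spec = CommunitySpec([Component((0.5, 0.5), bad_cov, 1.0, 0.0)])
        with pytest.raises(ValueError):
            spec.validate()

    def test_proliferation_fraction_bounds(self):
        spec = CommunitySpec([Component((0.5, 0.5), iso_cov(0.01), 1.0, 1.5)])
        with pytest.raises(ValueError, match="proliferation"):
            spec.validate()

    def test_json_round_trip(self, two_component_spec, tmp_path):
        p = tmp_path / "spec.json"
        two_component_spec.to_json(p)
        back = CommunitySpec.from_json(p)
        assert back == two_component_spec


class TestSimulateCommunity:
    def test_degenerate_variance_concentrates_events(self):
        spec = CommunitySpec([Component((0.5, 0.5), iso_cov(1e-3), 1.0, 0.0)])
        t = simulate_community(spec, 1000, seed=7)
        assert np.all(np.abs(t.values - 0.5) < 0.02)

    def test_component_counts_within_binomial_bounds(self, two_component_spec):
        n = 10_000
        _, labels = simulate_community(two_component_spec, n, seed=3,
                                       return_labels=True)
        n1 = int(np.sum(labels == 0))
        sd = np.sqrt(n * 0.7 * 0.3)
        assert abs(n1 - 7000) <= 3 * sd
        assert n1 + int(np.sum(labels == 1)) == n  # multinomial conservation

    def test_seed_determinism(self, two_component_spec):
        a = simulate_community(two_component_spec, 500, seed=42)
        b = simulate_community(two_component_spec, 500, seed=42)
        assert a.values.tobytes() == b.values.tobytes()

    def test_different_seeds_differ(self, two_component_spec):
        a = simulate_community(two_component_spec, 500, seed=1)
        b = simulate_community(two_component_spec, 500, seed=2)
        assert not np.array_equal(a.values, b.values)

    def test_values_clamped_to_unit_square(self):
        spec = CommunitySpec([Component((0.98, 0.98), iso_cov(0.05), 1.0, 0.5)])
        t = simulate_community(spec, 2000, seed=0)
        assert t.values.min() >= 0 and t.values.max() <= 1

    def test_proliferation_satellite_at_doubled_dna(self):
        spec = CommunitySpec([Component((0.4, 0.3), iso_cov(1e-3), 1.0, 0.5)])
        t = simulate_community(spec, 4000, seed=5)
        dna = t.channel("DNA")
        hi = dna > 0.3 + DNA_DOUBLING_SHIFT / 2
        # a binomial(4000, 0.5) fraction ends up in the satellite
        assert abs(hi.mean() - 0.5) < 3 * np.sqrt(0.25 / 4000)
        assert abs(dna[hi].mean() - (0.3 + DNA_DOUBLING_SHIFT)) < 0.01

    def test_mean_recovery_large_sample(self, two_component_spec):
        t, labels = simulate_community(two_component_spec, 20_000, seed=9,
                                       return_labels=True)
        for k, comp in enumerate(two_component_spec.components):
            got = t.values[labels == k].mean(axis=0)
            se = 0.02 / np.sqrt(np.sum(labels == k))
            assert np.all(np.abs(got - np.asarray(comp.mean)) < 3 * se)

    def test_invalid_inputs(self, two_component_spec):
        with pytest.raises(ValueError):
            simulate_community(two_component_spec, 0, seed=1)


class TestSimulateSeries:
    def test_constant_schedule(self, two_component_spec):
        spec = SeriesSpec(two_component_spec, n_steps=5)
        res = simulate_series(spec, 200, seed=1)
        assert len(res.tables) == 5
        assert np.allclose(res.abundances, [0.7, 0.3])

    def test_changepoint_swaps_fractions(self):
        base = CommunitySpec([
            Component((0.3, 0.3), iso_cov(0.02), 0.8, 0.0),
            Component((0.7, 0.7), iso_cov(0.02), 0.2, 0.0),
        ])
        spec = SeriesSpec(base, n_steps=6, changepoint=3, replacement=(0.2, 0.8))
        res = simulate_series(spec, 100, seed=2)
        assert np.allclose(res.abundances[:3], [0.8, 0.2])
        assert np.allclose(res.abundances[3:], [0.2, 0.8])

    def test_drift_arithmetic(self):
        base = CommunitySpec([
            Component((0.3, 0.3), iso_cov(0.02), 0.2, 0.0),
            Component((0.7, 0.7), iso_cov(0.02), 0.8, 0.0),
        ])
        spec = SeriesSpec(base, n_steps=4, drift=(0.05, 0.0))
        raw = [0.2 + 0.05 * t for t in range(4)]
        expect = np.array([[f, 0.8] for f in raw])
        expect /= expect.sum(axis=1, keepdims=True)
        res = simulate_series(spec, 50, seed=0)
        assert np.allclose(res.abundances, expect)

    def test_negative_schedule_rejected(self, two_component_spec):
        spec = SeriesSpec(two_component_spec, n_steps=10, drift=(-0.1, 0.0))
        with pytest.raises(ValueError, match="negative"):
            simulate_series(spec, 50, seed=0)

    def test_determinism(self, two_component_spec):
        spec = SeriesSpec(two_component_spec, n_steps=3)
        a = simulate_series(spec, 100, seed=11)
        b = simulate_series(spec, 100, seed=11)
        for ta, tb in zip(a.tables, b.tables):
            assert np.array_equal(ta.values, tb.values)


class TestSimulateGroups:
    def test_null_case_allowed(self, two_component_spec):
        res = simulate_groups(two_component_spec, two_component_spec,
                              reps=3, n_events=100, seed=1)
        assert len(res.tables) == 6
        assert res.labels == ["A"] * 3 + ["B"] * 3
        ids = [t.sample_id for t in res.tables]
        assert len(set(ids)) == 6

    def test_replicates_vary_by_resampling_only(self, two_component_spec):
        res = simulate_groups(two_component_spec, two_component_spec,
                              reps=2, n_events=100, seed=4)
        a1, a2 = res.by_group("A")
        assert not np.array_equal(a1.values, a2.values)

    def test_reps_validation(self, two_component_spec):
        with pytest.raises(ValueError):
            simulate_groups(two_component_spec, two_component_spec,
                            reps=1, n_events=10, seed=0)

    def test_determinism(self, two_component_spec):
        a = simulate_groups(two_component_spec, two_component_spec, 2, 100, 8)
        b = simulate_groups(two_component_spec, two_component_spec, 2, 100, 8)
        for ta, tb in zip(a.tables, b.tables):
            assert np.array_equal(ta.values, tb.values)


class TestOperatorGateSets:
    def test_rare_components_go_ungated(self):
        spec = CommunitySpec([
            Component((0.3, 0.3), iso_cov(0.02), 0.97, 0.0),
            Component((0.7, 0.7), iso_cov(0.02), 0.03, 0.0),
        ])
        t, labels = simulate_community(spec, 5000, seed=1, return_labels=True)
        sets = operator_gate_sets([t], spec, labels=[labels], min_fraction=0.05)
        assert [g.name for g in sets[0].gates] == ["C1"]

    def test_gates_capture_their_clusters(self, two_component_spec):
        t, labels = simulate_community(two_component_spec, 5000, seed=2,
                                       return_labels=True)
        sets = operator_gate_sets([t], two_component_spec, labels=[labels])
        from cytofingerprint import count_in_gate

        for k, g in enumerate(sets[0].gates):
            frac = count_in_gate(t, g) / t.n_events
            truth = float(np.mean(labels == k))
            assert abs(frac - truth) < 0.02  # 3-sigma ellipse captures ~98.9%
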