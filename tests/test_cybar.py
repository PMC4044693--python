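import numpy as np
import pandas as pd
import pytest

from cytofingerprint import (
    AbundanceMatrix,
    ExternalParameters,
    Gate,
    GateTemplate,
    abundance_table,
    correlate_gates,
    cybar_matrix,
    normalize_cybar,
    simulate_community,
)
from cytofingerprint.synth import component_gate
from conftest import table
from oracles import brute_bray_curtis


def abund(values, samples=None, gates=None, n_events=None):
    values = np.asarray(values, float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    gates = gates or [f"g{j}" for j in range(values.shape[1])]
    return AbundanceMatrix(samples, gates, values,
                           n_events=np.asarray(n_events)
                           if n_events is not None else None)


def params(d, samples):
    return ExternalParameters.from_frame(pd.DataFrame(d, index=samples))


class TestAbundanceTable:
    def test_all_covering_gate_gives_ones(self, rng):
        tables = [table(rng.uniform(size=(50, 2)), sample_id=f"s{i}")
                  for i in range(3)]
        tpl = GateTemplate([Gate(name="all", shape="rectangle",
                                 x0=0.0, x1=1.0, y0=0.0, y1=1.0)])
        a = abundance_table(tables, tpl)
        assert np.all(a.values == 1.0)

    def test_unhit_gate_warns_and_zeroes(self, rng, caplog):
        tables = [table(rng.uniform(0.5, 1.0, size=(50, 2)), sample_id=f"s{i}")
                  for i in range(2)]
        tpl = GateTemplate([Gate(name="empty", shape="rectangle",
                                 x0=0.0, x1=0.2, y0=0.0, y1=0.2)])
        with caplog.at_level("WARNING"):
            a = abundance_table(tables, tpl)
        assert np.all(a.values == 0)
        assert any("empty" in r.message for r in caplog.records)

    def test_recovers_cluster_fractions(self, six_cluster_spec):
        n = 20_000
        tables = [simulate_community(six_cluster_spec, n, seed=s,
                                     sample_id=f"s{s}") for s in range(3)]
        tpl = GateTemplate([component_gate(c, f"G{k}")
                            for k, c in enumerate(six_cluster_spec.components)])
        a = abundance_table(tables, tpl)
        for k, c in enumerate(six_cluster_spec.components):
            f = c.abundance_fraction * 0.989  # 3-sigma ellipse coverage
            sd = np.sqrt(f * (1 - f) / n)
            assert np.all(np.abs(a.values[:, k] - f) < 3 * sd + 0.005)


class TestNormalizeCybar:
    def test_constant_column_maps_to_zero(self):
        b = normalize_cybar(abund([[0.2, 0.5], [0.2, 0.1]]), epsilon=1e-3)
        assert np.allclose(b.values[:, 0], 0.0)

    def test_double_the_gmean_gives_plus_one(self):
        # column [v, v/4] has geometric mean v/2, so sample 0 sits at 2x it
        b = normalize_cybar(abund([[0.4], [0.1]]), epsilon=1e-12)
        assert b.values[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_scale_invariance_per_gate(self):
        a1 = abund([[0.1, 0.3], [0.2, 0.2], [0.4, 0.1]])
        a2 = abund(a1.values * np.array([2.0, 1.0]) / 2)  # halve then re-double gate 0
        b1 = normalize_cybar(a1, epsilon=1e-12)
        b2 = normalize_cybar(abund(np.column_stack([a1.values[:, 0] * 2 / 2,
                                                    a1.values[:, 1]])),
                             epsilon=1e-12)
        assert np.allclose(b1.values, b2.values)

    def test_columns_centered_in_log_space(self, rng):
        a = abund(rng.uniform(0.01, 0.9, size=(6, 5)))
        b = normalize_cybar(a)
        assert np.all(np.abs(b.values.mean(axis=0)) < 1e-9)

    def test_epsilon_default_one_cell_in_largest_sample(self):
        a = abund([[0.0, 0.5], [0.1, 0.5]], n_events=[1000, 4000])
        b = normalize_cybar(a)
        assert b.epsilon == pytest.approx(1 / 4000)


class TestCybarMatrix:
    def test_identical_rows_zero(self):
        d = cybar_matrix(abund([[0.2, 0.3], [0.2, 0.3]]))
        assert np.all(d.values == 0)

    def test_disjoint_support_is_one(self):
        d = cybar_matrix(abund([[0.5, 0.0], [0.0, 0.5]]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        vals = rng.uniform(0, 0.3, size=(6, 8))
        d = cybar_matrix(abund(vals))
        for i in range(6):
            for j in range(i + 1, 6):
                assert d.values[i, j] == pytest.approx(
                    brute_bray_curtis(vals[i], vals[j]), rel=1e-12)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="s1"):
            cybar_matrix(abund([[0.5, 0.1], [0.0, 0.0]]))

    def test_gate_order_invariance(self, rng):
        vals = rng.uniform(0, 0.3, size=(4, 5))
        d1 = cybar_matrix(abund(vals))
        d2 = cybar_matrix(abund(vals[:, ::-1]))
        assert np.allclose(d1.values, d2.values)


class TestCorrelateGates:
    def test_perfect_monotone_gate(self):
        n = 8
        vals = np.column_stack([np.linspace(0.1, 0.8, n),
                                np.full(n, 0.2)])
        a = abund(vals)
        p = params({"jmax": np.arange(n, dtype=float)}, a.samples)
        res = correlate_gates(a, p, n_perm=999, seed=7)
        r0 = next(r for r in res if r.gate == "g0")
        assert r0.rho == pytest.approx(1.0)
        assert r0.p_value == pytest.approx(1 / 1000)

    def test_constant_gate_reported_missing(self):
        a = abund(np.column_stack([np.full(6, 0.2), np.linspace(0.1, 0.6, 6)]))
        p = params({"ce": np.arange(6, dtype=float)}, a.samples)
        res = correlate_gates(a, p, n_perm=99, seed=0)
        r0 = next(r for r in res if r.gate == "g0")
        assert r0.rho is None and "constant" in r0.reason

    def test_sign_flip_symmetry(self, rng):
        vals = rng.uniform(0.05, 0.5, size=(8, 3))
        a = abund(vals)
        y = rng.normal(size=8)
        r_pos = correlate_gates(a, params({"y": y}, a.samples), 999, seed=3)
        r_neg = correlate_gates(a, params({"y": -y}, a.samples), 999, seed=3)
        for rp, rn in zip(r_pos, r_neg):
            assert rp.rho == pytest.approx(-rn.rho)
            assert rp.p_value == rn.p_value

    def test_index_gate_attains_largest_rho(self, rng):
        # one gate's abundance tracks the covariate; others are noise
        n = 12
        cov = np.linspace(0, 1, n)
        vals = rng.uniform(0.1, 0.3, size=(n, 5))
        vals[:, 2] = 0.1 + 0.4 * cov + rng.normal(0, 0.01, n)
        res = correlate_gates(abund(vals), params({"c": cov}, [f"s{i}" for i in range(n)]),
                              n_perm=99, seed=1)
        best = max(res, key=lambda r: abs(r.rho))
        assert best.gate == "g2"

    def test_determinism(self, rng):
        vals = rng.uniform(0.05, 0.5, size=(8, 3))
        a = abund(vals)
        p = params({"y": rng.normal(size=8)}, a.samples)
        r1 = correlate_gates(a, p, 999, seed=5)
        r2 = correlate_gates(a, p, 999, seed=5)
        assert [r.p_value for r in r1] == [r.p_value for r in r2]

    def test_missing_values_excluded(self, rng):
        vals = rng.uniform(0.05, 0.5, size=(8, 2))
        y = rng.normal(size=8)
        y[0] = np.nan
        res = correlate_gates(abund(vals), params({"y": y},
                                                  [f"s{i}" for i in range(8)]),
                              n_perm=99, seed=0)
        assert all(r.n == 7 for r in res)
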