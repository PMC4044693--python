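import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from cytofingerprint import (
    DissimilarityMatrix,
    ExternalParameters,
    Ordination,
    envfit,
    nmds,
    procrustes,
    within_between,
)
from cytofingerprint.stats import kruskal_stress
from oracles import brute_stress1


def dmat(values, ids=None):
    values = np.asarray(values, float)
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return DissimilarityMatrix(ids, values)


def euclidean_dmat(pts):
    return dmat(squareform(pdist(pts)))


def params(d, samples):
    return ExternalParameters.from_frame(pd.DataFrame(d, index=samples))


class TestKruskalStress:
    def test_matches_brute_force_pava(self, rng):
        pts = rng.uniform(size=(9, 2))
        d = squareform(pdist(pts)) ** 1.5  # monotone distortion
        coords = rng.uniform(size=(9, 2))
        iu = np.triu_indices(9, k=1)
        dist = squareform(pdist(coords))
        expect = brute_stress1(d[iu].tolist(), dist[iu].tolist())
        assert kruskal_stress(d, coords) == pytest.approx(expect, rel=1e-10)


class TestNmds:
    def test_equilateral_triangle(self):
        o = nmds(dmat([[0, 1, 1], [1, 0, 1], [1, 1, 0]]), n_starts=5, seed=0)
        assert o.stress < 1e-6
        pd_ = pdist(o.coords)
        assert np.ptp(pd_) / pd_.mean() < 1e-4
        assert np.allclose(o.coords.mean(axis=0), 0, atol=1e-9)

    def test_self_recovery_of_euclidean_configuration(self, rng):
        pts = rng.uniform(size=(12, 2))
        o = nmds(euclidean_dmat(pts), n_starts=10, seed=1)
        assert o.stress < 0.01
        orig = Ordination(o.ids, pts - pts.mean(0), 0.0)
        pr = procrustes(o, orig, n_perm=0)
        assert pr.correlation > 0.99

    def test_two_samples_collinear_zero_stress(self):
        o = nmds(dmat([[0, 0.8], [0.8, 0]]))
        assert o.stress == 0.0
        assert np.allclose(o.coords[:, 1], 0)

    def test_monotone_transform_invariance(self, rng):
        pts = rng.uniform(size=(10, 2))
        base = euclidean_dmat(pts)
        o1 = nmds(base, n_starts=10, seed=2)
        for f in (np.square, np.sqrt):
            d2 = dmat(f(base.values))
            o2 = nmds(d2, n_starts=10, seed=2)
            assert abs(o1.stress - o2.stress) < 0.01
            assert procrustes(o1, o2, n_perm=0).correlation > 0.99

    def test_degenerate_all_zero_matrix(self):
        with pytest.warns(UserWarning, match="degenerate"):
            o = nmds(dmat(np.zeros((5, 5))))
        assert o.stress == 0.0

    def test_seed_determinism(self, rng):
        v = squareform(rng.uniform(0.2, 1.0, size=15))
        o1 = nmds(dmat(v), n_starts=5, seed=9)
        o2 = nmds(dmat(v), n_starts=5, seed=9)
        assert np.array_equal(o1.coords, o2.coords)

    def test_k_must_be_less_than_n(self):
        with pytest.raises(ValueError, match="k"):
            nmds(dmat([[0, 1, 1], [1, 0, 1], [1, 1, 0]]), k=3)

    def test_tsv_round_trip(self, rng, tmp_path):
        o = nmds(euclidean_dmat(rng.uniform(size=(6, 2))), n_starts=3, seed=0)
        p = tmp_path / "ord.tsv"
        o.to_tsv(p)
        back = Ordination.from_tsv(p)
        assert back.ids == o.ids
        assert np.allclose(back.coords, o.coords)
        assert back.stress == pytest.approx(o.stress)


class TestEnvfit:
    def test_perfect_covariate(self, rng):
        o = nmds(euclidean_dmat(rng.uniform(size=(10, 2))), n_starts=5, seed=0)
        r = envfit(o, params({"c": o.coords[:, 0]}, o.ids), 999, seed=1)[0]
        assert r.r_squared == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1 / 1000)
        assert np.linalg.norm(r.direction) == pytest.approx(1.0)

    def test_sign_symmetry(self, rng):
        o = nmds(euclidean_dmat(rng.uniform(size=(10, 2))), n_starts=5, seed=0)
        y = rng.normal(size=10)
        r1 = envfit(o, params({"c": y}, o.ids), 999, seed=4)[0]
        r2 = envfit(o, params({"c": -y}, o.ids), 999, seed=4)[0]
        assert r1.r_squared == pytest.approx(r2.r_squared)
        assert r1.p_value == r2.p_value
        assert np.allclose(r1.direction, -r2.direction)

    def test_constant_covariate_reported_missing(self, rng):
        o = nmds(euclidean_dmat(rng.uniform(size=(8, 2))), n_starts=3, seed=0)
        r = envfit(o, params({"c": np.ones(8)}, o.ids), 99, seed=0)[0]
        assert r.r_squared is None and "constant" in r.reason

    def test_missing_samples_excluded(self, rng):
        o = nmds(euclidean_dmat(rng.uniform(size=(8, 2))), n_starts=3, seed=0)
        y = rng.normal(size=8)
        y[2] = np.nan
        r = envfit(o, params({"c": y}, o.ids), 99, seed=0)[0]
        assert r.n_used == 7

    def test_determinism(self, rng):
        o = nmds(euclidean_dmat(rng.uniform(size=(8, 2))), n_starts=3, seed=0)
        y = rng.normal(size=8)
        p1 = envfit(o, params({"c": y}, o.ids), 999, seed=6)[0].p_value
        p2 = envfit(o, params({"c": y}, o.ids), 999, seed=6)[0].p_value
        assert p1 == p2


class TestProcrustes:
    def _ord(self, pts):
        return Ordination([f"s{i}" for i in range(len(pts))],
                          np.asarray(pts, float), 0.0)

    def test_rotation_and_scale_recovered(self, rng):
        pts = rng.uniform(size=(8, 2))
        th = np.deg2rad(37)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        b = 3.0 * pts @ rot.T + [5.0, -2.0]
        res = procrustes(self._ord(pts), self._ord(b), n_perm=0)
        assert res.m_squared < 1e-10
        assert res.correlation > 0.99999

    def test_self_comparison_exact_zero(self, rng):
        o = self._ord(rng.uniform(size=(6, 2)))
        res = procrustes(o, o, n_perm=0)
        assert res.m_squared == 0.0

    def test_matches_scipy_statistic(self, rng):
        from scipy.spatial import procrustes as scipy_procrustes

        a = rng.uniform(size=(9, 2))
        b = rng.uniform(size=(9, 2))
        _, _, disparity = scipy_procrustes(a, b)
        res = procrustes(self._ord(a), self._ord(b), n_perm=0)
        assert res.m_squared == pytest.approx(disparity, rel=1e-9)

    def test_id_mismatch_rejected(self, rng):
        a = self._ord(rng.uniform(size=(5, 2)))
        b = Ordination([f"x{i}" for i in range(5)], rng.uniform(size=(5, 2)), 0.0)
        with pytest.raises(ValueError, match="ids"):
            procrustes(a, b)

    def test_id_order_irrelevant(self, rng):
        pts_a = rng.uniform(size=(6, 2))
        pts_b = rng.uniform(size=(6, 2))
        a = self._ord(pts_a)
        b = self._ord(pts_b)
        perm = [3, 1, 5, 0, 2, 4]
        b_shuffled = Ordination([b.ids[i] for i in perm], pts_b[perm], 0.0)
        r1 = procrustes(a, b, n_perm=0)
        r2 = procrustes(a, b_shuffled, n_perm=0)
        assert r1.m_squared == pytest.approx(r2.m_squared, rel=1e-12)

    def test_permutation_determinism(self, rng):
        a = self._ord(rng.uniform(size=(8, 2)))
        b = self._ord(rng.uniform(size=(8, 2)))
        p1 = procrustes(a, b, n_perm=999, seed=2).p_value
        p2 = procrustes(a, b, n_perm=999, seed=2).p_value
        assert p1 == p2


class TestWithinBetween:
    def test_block_matrix(self):
        v = np.array([
            [0.0, 0.1, 0.9, 0.9],
            [0.1, 0.0, 0.9, 0.9],
            [0.9, 0.9, 0.0, 0.1],
            [0.9, 0.9, 0.1, 0.0],
        ])
        d = dmat(v, ids=["a1", "a2", "b1", "b2"])
        w, b = within_between(d, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert w == pytest.approx(0.1)
        assert b == pytest.approx(0.9)


class TestVeganCrossCheck:
    """Agreement with the R vegan package on a fixed configuration."""

    def test_protest_statistic_matches_vegan(self, rng, tmp_path):
        a = rng.uniform(size=(8, 2))
        b = rng.uniform(size=(8, 2))
        np.savetxt(tmp_path / "a.txt", a)
        np.savetxt(tmp_path / "b.txt", b)
        script = (
            "suppressMessages(library(vegan));"
            f"a <- as.matrix(read.table('{tmp_path}/a.txt'));"
            f"b <- as.matrix(read.table('{tmp_path}/b.txt'));"
            "p <- procrustes(a, b, symmetric=TRUE);"
            "cat(sprintf('%.12f', p$ss))"
        )
        proc = subprocess.run(["Rscript", "-e", script],
                              capture_output=True, text=True, timeout=120)
        assert proc.returncode == 0, proc.stderr
        vegan_m2 = float(proc.stdout.strip())
        ids = [f"s{i}" for i in range(8)]
        mine = procrustes(Ordination(ids, a, 0.0), Ordination(ids, b, 0.0),
                          n_perm=0)
        assert mine.m_squared == pytest.approx(vegan_m2, rel=1e-6)
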