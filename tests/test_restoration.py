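"""Distance-threshold clone restoration and Moran's I."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

import clonesense as cs
from clonesense.restoration import _row_standardize


class TestWStar:
    def test_vanishes_with_alpha(self):
        w_large = cs.w_star(0.5, 100.0, 10, alpha=0.5, d=2).w_star
        w_small = cs.w_star(0.5, 100.0, 10, alpha=1e-9, d=2).w_star
        assert w_small < 1e-3 * w_large

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_scales_linearly_in_volume_per_cluster(self, d):
        base = cs.w_star(0.5, 100.0, 10, alpha=0.5, d=d).w_star
        doubled = cs.w_star(0.5, 200.0, 10, alpha=0.5, d=d).w_star
        assert doubled**d / base**d == pytest.approx(2.0, rel=1e-9)

    def test_decreases_in_f_and_k(self):
        f_grid = [0.2, 0.5, 1.0, 2.0, 4.0]
        w_f = [cs.w_star(f, 100.0, 10, 0.5, 2).w_star for f in f_grid]
        assert all(a > b for a, b in zip(w_f, w_f[1:]))
        k_grid = [1, 3, 10, 30, 100]
        w_k = [cs.w_star(0.5, 100.0, k, 0.5, 2).w_star for k in k_grid]
        assert all(a > b for a, b in zip(w_k, w_k[1:]))

    def test_domain_checks(self):
        with pytest.raises(cs.DomainError):
            cs.w_star(0.0, 100.0, 10)
        with pytest.raises(cs.DomainError):
            cs.w_star(0.5, 100.0, 10, alpha=1.5)


class TestClonalDistanceProbability:
    def test_at_zero_distance(self):
        res = cs.clonal_distance_probability(0.0, rho=0.1, f=0.5, d=2)
        assert res.p_distance_given_clonal == 1.0
        assert res.alpha_level == 0.0

    @pytest.mark.parametrize("d", [1, 2, 3])
    @pytest.mark.parametrize("f,alpha", [(0.3, 0.5), (1.0, 0.2), (2.0, 0.8)])
    def test_root_reproduces_w_star(self, d, f, alpha):
        volume, k = 500.0, 25
        thr = cs.w_star(f, volume, k, alpha, d)
        g = lambda w: cs.clonal_distance_probability(w, k / volume, f, d).alpha_level - alpha
        root = brentq(g, 1e-12, 1e4)
        assert root == pytest.approx(thr.w_star, rel=1e-6)


class TestRestoreClones:
    def _table(self, rows):
        return cs.ClusterTable(pd.DataFrame(rows))

    def test_close_same_color_pair_joins(self):
        table = self._table([
            {"sample_id": "A", "cluster_id": "c1", "color": "R", "x": 0.0,
             "y": 0.0, "size": 1},
            {"sample_id": "A", "cluster_id": "c2", "color": "R", "x": 1.0,
             "y": 0.0, "size": 1},
        ])
        part = cs.restore_clones(table, 2.0)
        assert part.n_clones() == 1
        assert part.assignment["c1"] == part.assignment["c2"] == "c1"
        assert len(part.links) == 1

    def test_different_colors_never_join(self):
        table = self._table([
            {"sample_id": "A", "cluster_id": "c1", "color": "R", "x": 0.0,
             "y": 0.0, "size": 1},
            {"sample_id": "A", "cluster_id": "c2", "color": "Y", "x": 0.1,
             "y": 0.0, "size": 1},
        ])
        part = cs.restore_clones(table, 10.0)
        assert part.n_clones() == 2

    def test_dimension_mismatch(self, small_table):
        thr = cs.w_star(0.5, 100.0, 3, d=3)
        with pytest.raises(cs.DomainError):
            cs.restore_clones(small_table, thr)

    def test_invariant_under_row_order_and_rigid_motion(self, rng):
        n = 40
        df = pd.DataFrame({
            "sample_id": "A",
            "cluster_id": [f"c{i:02d}" for i in range(n)],
            "color": rng.choice(["R", "Y"], n),
            "x": rng.uniform(0, 20, n),
            "y": rng.uniform(0, 20, n),
            "size": 1,
        })
        base = cs.restore_clones(cs.ClusterTable(df), 2.5).assignment
        shuffled = cs.restore_clones(
            cs.ClusterTable(df.sample(frac=1.0, random_state=3)), 2.5).assignment
        assert shuffled == base
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        xy = df[["x", "y"]].to_numpy() @ rot.T + np.array([5.0, -3.0])
        moved = df.assign(x=xy[:, 0], y=xy[:, 1])
        assert cs.restore_clones(cs.ClusterTable(moved), 2.5).assignment == base

    def test_clone_count_monotone_in_threshold(self, rng):
        n = 60
        df = pd.DataFrame({
            "sample_id": "A", "cluster_id": [f"c{i:02d}" for i in range(n)],
            "color": "R", "x": rng.uniform(0, 30, n), "y": rng.uniform(0, 30, n),
            "size": 1,
        })
        table = cs.ClusterTable(df)
        counts = [cs.restore_clones(table, w).n_clones()
                  for w in (0.5, 1.5, 3.0, 6.0, 12.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_recovers_simulated_partition(self):
        """Low fragmentation, low density: Rand index against the true
        clonal partition exceeds 0.9."""
        from sklearn.metrics import rand_score

        cfg = cs.SimConfig(seed=5, d=2, volume=2500.0, m0=3.0,
                           scheme=cs.ColorScheme(("R", "Y"), (0.5, 0.5)),
                           size_model=cs.SizeModel("fixed", 5), f=0.3,
                           dispersal=1.0, n_samples=200, periodic=False)
        table, truth = cs.simulate(cfg)
        k_per_sample = max(1, round(len(table) / cfg.n_samples))
        thr = cs.w_star(cfg.f, cfg.volume, k_per_sample, alpha=0.5, d=2)
        part = cs.restore_clones(table, thr)
        ids = table.df["cluster_id"].tolist()
        predicted = [part.assignment[c] for c in ids]
        assert rand_score(truth.true_partition(ids), predicted) > 0.9


class TestMoransI:
    def brute_force(self, x, W):
        x = np.asarray(x, float)
        n = len(x)
        z = x - x.mean()
        num = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
        return n / W.sum() * num / (z @ z)

    def test_path_graph_two_blocks(self):
        W = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            W[i, j] = W[j, i] = 1.0
        x = [1, 1, 0, 0]
        assert cs.morans_i(x, W) == pytest.approx(self.brute_force(x, W))
        assert cs.morans_i(x, W) == pytest.approx(1 / 3, abs=1e-12)
        Wr = _row_standardize(W)
        assert cs.morans_i(x, Wr) == pytest.approx(0.5, abs=1e-12)

    def test_alternating_cycle_is_negative(self):
        n = 8
        W = np.zeros((n, n))
        for i in range(n):
            W[i, (i + 1) % n] = W[(i + 1) % n, i] = 1.0
        assert cs.morans_i([i % 2 for i in range(n)], W) < 0

    def test_equals_brute_force_on_random_instances(self, rng):
        for _ in range(5):
            n = 25
            coords = rng.uniform(0, 10, (n, 2))
            W = cs.knn_weights(coords, 4)
            x = rng.normal(size=n)
            assert cs.morans_i(x, W) == pytest.approx(
                self.brute_force(x, W), abs=1e-12)

    def test_null_expectation(self, rng):
        """I for i.i.d. values concentrates near -1/(n-1); the normality
        variance formula supplies sigma."""
        n = 500
        coords = rng.uniform(0, 100, (n, 2))
        W = cs.knn_weights(coords, 6)
        x = rng.normal(size=n)
        i_value = cs.morans_i(x, W)
        s0 = W.sum()
        s1 = 0.5 * ((W + W.T) ** 2).sum()
        s2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
        e_i = -1.0 / (n - 1)
        var = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - e_i**2
        assert abs(i_value - e_i) < 3 * math.sqrt(var)

    def test_constant_values_undefined(self):
        W = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(cs.DomainError):
            cs.morans_i([2.0, 2.0, 2.0], W)


def test_annotate_clones_adds_column(small_table):
    part = cs.restore_clones(small_table, 2.0)
    annotated = cs.annotate_clones(small_table, part)
    assert "clone_id" in annotated.df.columns
    assert annotated.df["clone_id"].notna().all()
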