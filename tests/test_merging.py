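"""Merging-probability estimators."""

import math

import numpy as np
import pandas as pd
import pytest

import clonesense as cs
from clonesense.merging import ball_volume, radius_sum_pmf


class TestCorrectionFactor:
    @pytest.mark.parametrize("freqs,expected", [
        ((0.3, 0.3, 0.3, 0.1), 0.72),
        ((0.73, 0.17, 0.09, 0.01), 0.43),
        ((0.5, 0.5), 0.5),
    ])
    def test_known_schemes(self, freqs, expected):
        scheme = cs.ColorScheme(tuple(f"c{i}" for i in range(len(freqs))), freqs)
        assert cs.correction_factor(scheme) == pytest.approx(expected, abs=1e-12)

    def test_single_color_inapplicable(self):
        scheme = cs.ColorScheme(("G",), (1.0,))
        assert cs.correction_factor(scheme) == 0.0
        with pytest.raises(cs.DomainError):
            cs.unicolor_merger_fraction(1, 10, "G", scheme)


class TestUnicolorMergerFraction:
    def test_no_bicolor_contacts(self, confetti):
        est = cs.unicolor_merger_fraction(0, 50, "RFP", confetti)
        assert est.p_merge == 0.0

    def test_direct_substitution(self, confetti):
        est = cs.unicolor_merger_fraction(10, 100, "RFP", confetti)
        assert est.p_merge == pytest.approx(0.1 * 0.3 / 0.72, rel=1e-12)
        assert est.details["stderr"] > 0

    def test_two_equal_colors_recover_heuristic(self):
        """With two equal colors the unicolor merger rate equals the bicolor
        contact fraction times r_c / 0.5 = the contact fraction itself."""
        scheme = cs.ColorScheme(("A", "B"), (0.5, 0.5))
        est = cs.unicolor_merger_fraction(20, 100, "A", scheme)
        assert est.p_merge == pytest.approx(0.2, rel=1e-12)

    def test_simulator_ground_truth_equal_colors(self):
        """Bicolor contacts rescaled by Eq.-3 recover the true unicolor
        merger fraction within Monte Carlo noise."""
        scheme = cs.ColorScheme.equal(("A", "B", "C", "D"))
        cfg = cs.SimConfig(seed=31, d=2, volume=3000.0, m0=12.0, scheme=scheme,
                           size_model=cs.SizeModel("fixed", 6), f=0.0,
                           dispersal=0.0, n_samples=600)
        table, truth = cs.simulate(cfg)
        # ground truth: fraction of clusters in same-color geometric contact
        # (equals the per-color fraction under color symmetry)
        in_merger = {c for pair in truth.merger_pairs for c in pair}
        true_frac = len(in_merger) / len(table)
        r_contact = 2 * cs.clone_radius(6, 1.0, 2)
        contacts = cs.count_bicolor_contacts(table, r_contact)
        estimates = [cs.unicolor_merger_fraction(kb, k, color, scheme)
                     for color, (kb, k) in contacts.items()]
        pooled = np.mean([e.p_merge for e in estimates])
        se = np.mean([e.details["stderr"] for e in estimates]) / 2
        assert abs(pooled - true_frac) < 3 * se


class TestBicolorContacts:
    def test_two_clusters_different_colors_in_contact(self):
        df = pd.DataFrame({"sample_id": ["A", "A"], "cluster_id": ["c1", "c2"],
                           "color": ["R", "Y"], "x": [0.0, 1.0], "size": [1, 1]})
        contacts = cs.count_bicolor_contacts(cs.ClusterTable(df), 2.0)
        assert contacts == {"R": (1, 1), "Y": (1, 1)}

    def test_same_color_never_bicolor(self):
        df = pd.DataFrame({"sample_id": ["A", "A"], "cluster_id": ["c1", "c2"],
                           "color": ["R", "R"], "x": [0.0, 1.0], "size": [1, 1]})
        contacts = cs.count_bicolor_contacts(cs.ClusterTable(df), 2.0)
        assert contacts == {"R": (0, 2)}

    def test_contacts_only_within_samples(self):
        df = pd.DataFrame({"sample_id": ["A", "B"], "cluster_id": ["c1", "c2"],
                           "color": ["R", "Y"], "x": [0.0, 0.1], "size": [1, 1]})
        contacts = cs.count_bicolor_contacts(cs.ClusterTable(df), 2.0)
        assert contacts == {"R": (0, 1), "Y": (0, 1)}

    def test_matches_brute_force_all_pairs(self, rng):
        n = 200
        df = pd.DataFrame({
            "sample_id": rng.choice(["A", "B"], n),
            "cluster_id": [f"c{i}" for i in range(n)],
            "color": rng.choice(["R", "Y", "C"], n),
            "x": rng.uniform(0, 20, n), "y": rng.uniform(0, 20, n),
            "size": 1,
        })
        radius = 1.5
        table = cs.ClusterTable(df)
        fast = cs.count_bicolor_contacts(table, radius)
        # brute force all-pairs scan
        kb = {c: 0 for c in df["color"].unique()}
        k = dict(df["color"].value_counts())
        pos = table.coords()
        for i in range(n):
            hit = False
            for j in range(n):
                if i == j or df["sample_id"][i] != df["sample_id"][j]:
                    continue
                if df["color"][i] != df["color"][j] and \
                        np.linalg.norm(pos[i] - pos[j]) < radius:
                    hit = True
            kb[df["color"][i]] += hit
        assert fast == {c: (kb[c], k[c]) for c in kb}


class TestAreaFraction:
    def test_endpoints(self):
        assert cs.merge_prob_area_fraction(0.0, 10.0).p_merge == 0.0
        assert cs.merge_prob_area_fraction(1.0, 10.0).p_merge == pytest.approx(0.1)

    def test_tracks_realized_merging_within_factor_two(self):
        """Sparse 2D disks: the labelled-area heuristic lands within about
        a factor 2 of the realized polyclonal-cluster fraction (the
        point-clone assumption biases it low; order-of-magnitude check)."""
        cfg = cs.SimConfig(seed=13, d=2, volume=2000.0, m0=10.0,
                           scheme=cs.ColorScheme(("G",), (1.0,)),
                           size_model=cs.SizeModel("fixed", 8), f=0.0,
                           dispersal=0.0, n_samples=1500)
        report = cs.merging_inflation_experiment(cfg)
        labelled_fraction = 10.0 * 8 * 1.0 / 2000.0  # E[m] * s * cell_vol / V
        est = cs.merge_prob_area_fraction(labelled_fraction, 1.0)
        ratio = est.p_merge / report["p_merge_realized"]
        assert 0.4 < ratio < 2.5


class TestMergeProb1d:
    def test_zero_induction(self):
        sizes = cs.CloneSizeDistribution.fixed(5)
        assert cs.merge_prob_1d(0.0, sizes).p_merge == 0.0

    def test_unit_clones(self):
        sizes = cs.CloneSizeDistribution.fixed(1)
        assert cs.merge_prob_1d(0.2, sizes).p_merge == pytest.approx(0.2, rel=1e-12)

    @pytest.mark.parametrize("p,q", [(0.05, 0.5), (0.2, 0.8), (0.01, 0.9)])
    def test_geometric_closed_form(self, p, q):
        # sum_s (1-p)^s (1-q) q^(s-1) = (1-p)(1-q) / (1 - q(1-p))
        mean = 1.0 / (1.0 - q)
        sizes = cs.CloneSizeDistribution.geometric(mean, tail_tol=1e-16)
        expected = 1.0 - (1 - p) * (1 - q) / (1 - q * (1 - p))
        assert cs.merge_prob_1d(p, sizes).p_merge == pytest.approx(expected, abs=1e-10)


class TestMergeProbGeneral:
    def test_empty_tissue_limit(self):
        sizes = cs.CloneSizeDistribution.fixed(4)
        est = cs.merge_prob_general(1e-9, 1e6, 2, sizes)
        assert est.p_merge < 1e-10

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_delta_sizes_closed_form(self, d):
        sizes = cs.CloneSizeDistribution.fixed(9)
        m0, volume = 3.0, 1000.0
        est = cs.merge_prob_general(m0, volume, d, sizes)
        r0 = cs.clone_radius(9, 1.0, d)
        exact = 1 - math.exp(-(m0 / volume) * float(ball_volume(2 * r0, d)))
        assert est.p_merge == pytest.approx(exact, rel=1e-12)

    def test_invalid_dimension(self):
        with pytest.raises(cs.DomainError):
            cs.merge_prob_general(1.0, 10.0, 4, cs.CloneSizeDistribution.fixed(2))

    def test_monotone_in_density(self):
        sizes = cs.CloneSizeDistribution.geometric(4)
        values = [cs.merge_prob_general(m0, 1000.0, 2, sizes).p_merge
                  for m0 in (0.5, 2.0, 8.0, 32.0)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_smoothed_quadrature_agrees_with_discrete_sum(self):
        sizes = cs.CloneSizeDistribution.geometric(5)
        exact = cs.merge_prob_general(10.0, 2000.0, 2, sizes)
        smooth = cs.merge_prob_general(10.0, 2000.0, 2, sizes, smoothing=0.02)
        assert smooth.p_merge == pytest.approx(exact.p_merge, rel=5e-3)
        assert smooth.details["quadrature_error"] < 1e-6

    def test_agrees_with_1d_formula_for_fixed_sizes(self):
        """In 1D with fixed clone sizes the nearest-neighbour integral and
        the per-cell geometric argument describe the same linear density:
        1 - exp(-2 rho s0) vs 1 - (1-p)^s0 with rho = p/2, to O(p^2)."""
        p, s0 = 0.01, 6
        sizes = cs.CloneSizeDistribution.fixed(s0)
        one_d = cs.merge_prob_1d(p, sizes).p_merge
        general = cs.merge_prob_general(p / 2, 1.0, 1, sizes).p_merge
        assert general == pytest.approx(one_d, abs=2 * p**2 * s0)

    def test_matches_disk_overlap_monte_carlo(self, rng):
        """2D oracle: Poisson-placed disks, nearest-neighbour overlap count,
        at low density rho * V_d(2 rbar) ~ 0.1."""
        sizes = cs.CloneSizeDistribution.geometric(5)
        m0, volume = 20.0, 4000.0
        est = cs.merge_prob_general(m0, volume, 2, sizes)
        L = math.sqrt(volume)
        support, probs = sizes.support(), sizes.probs()
        hits = total = 0
        for _ in range(400):
            m = rng.poisson(m0)
            if m < 2:
                continue
            pos = rng.uniform(0, L, (m, 2))
            s = rng.choice(support, size=m, p=probs)
            r = cs.clone_radius(s, 1.0, 2)
            delta = pos[:, None, :] - pos[None, :, :]
            delta -= L * np.round(delta / L)
            dist = np.linalg.norm(delta, axis=2)
            np.fill_diagonal(dist, np.inf)
            nn = dist.argmin(axis=1)
            hits += int(np.sum(dist[np.arange(m), nn] < r + r[nn]))
            total += m
        phat = hits / total
        sigma = math.sqrt(phat * (1 - phat) / total)
        assert abs(est.p_merge - phat) < 3 * sigma


def test_radius_sum_pmf_is_a_distribution():
    sizes = cs.CloneSizeDistribution.geometric(3)
    r, w = radius_sum_pmf(sizes, 1.0, 2)
    assert w.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(r) >= 0)
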