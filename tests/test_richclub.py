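"""Rich-club coefficients, hub selection, edge classes and AUC."""

import math

import numpy as np
import pytest

import richclubkit as rk

from conftest import from_edges, make_connectome, random_weighted


def brute_phi_topological(c, k):
    """Independent oracle: explicit induced-subgraph edge count."""
    deg = (c.W > 0).sum(axis=0)
    club = [v for v in range(c.n_nodes) if deg[v] > k]
    m = len(club)
    if m < 2:
        return float("nan")
    e = sum(1 for a in range(m) for b in range(a + 1, m) if c.W[club[a], club[b]] > 0)
    return 2 * e / (m * (m - 1))


def brute_phi_weighted(c, k):
    """Independent oracle: full weight sort."""
    deg = (c.W > 0).sum(axis=0)
    club = [v for v in range(c.n_nodes) if deg[v] > k]
    if len(club) < 2:
        return float("nan")
    inside = [(a, b) for a in club for b in club if a < b and c.W[a, b] > 0]
    if not inside:
        return float("nan")
    w_in = sum(c.W[a, b] for a, b in inside)
    all_w = sorted((c.W[i, j] for i in range(c.n_nodes) for j in range(i + 1, c.n_nodes)
                    if c.W[i, j] > 0), reverse=True)
    return w_in / sum(all_w[:len(inside)])


class TestPhi:
    def test_complete_graph(self):
        k5 = make_connectome(1 - np.eye(5), binary=True)
        assert rk.phi_topological(k5, 3) == 1.0
        assert rk.phi_weighted(k5.replace(k5.W * 3, binary=False), 2) == 1.0

    def test_cycle(self):
        cyc = from_edges(6, [(i, (i + 1) % 6, 1) for i in range(6)])
        assert rk.phi_topological(cyc, 1) == pytest.approx(2 * 6 / (6 * 5))

    def test_path_interior_club(self):
        path = from_edges(4, [(0, 1, 1), (1, 2, 1), (2, 3, 1)])
        assert rk.phi_topological(path, 1) == 1.0  # club {B, C}, joined

    def test_undefined_small_club(self):
        star = from_edges(4, [(0, 1, 1), (0, 2, 1), (0, 3, 1)])
        assert math.isnan(rk.phi_topological(star, 2))  # club = {center} only

    def test_weighted_hand_ranking(self):
        # AB=1 AC=1 BC=1 CD=5, k=1: club {A,B,C}; 3 / (5+1+1) = 3/7
        c = from_edges(4, [(0, 1, 1), (0, 2, 1), (1, 2, 1), (2, 3, 5)])
        assert rk.phi_weighted(c, 1) == pytest.approx(3 / 7)

    def test_equal_weights_give_one(self, rng):
        c = random_weighted(12, 0.5, rng)
        u = c.replace(np.where(c.W > 0, 2.0, 0.0))
        curve = rk.rich_club_curve(u, "weighted")
        defined = ~np.isnan(curve.phi)
        np.testing.assert_allclose(curve.phi[defined], 1.0)

    @pytest.mark.parametrize("variant", ["topological", "weighted"])
    def test_curve_matches_pointwise_phi(self, variant, rng):
        fn = rk.phi_topological if variant == "topological" else rk.phi_weighted
        for _ in range(10):
            c = random_weighted(18, 0.3, rng)
            src = c.binarized() if variant == "topological" else c
            curve = rk.rich_club_curve(src, variant)
            for k in range(len(curve.k)):
                expected = fn(src, k)
                if math.isnan(expected):
                    assert math.isnan(curve.phi[k])
                else:
                    assert curve.phi[k] == pytest.approx(expected, abs=1e-12)

    def test_against_brute_force_oracles(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 20))
            c = random_weighted(n, float(rng.uniform(0.2, 0.7)), rng)
            for k in range(int(c.degrees().max()) + 1):
                exp_t = brute_phi_topological(c, k)
                got_t = rk.phi_topological(c.binarized(), k)
                assert (math.isnan(exp_t) and math.isnan(got_t)) or got_t == exp_t
                exp_w = brute_phi_weighted(c, k)
                got_w = rk.phi_weighted(c, k)
                assert (math.isnan(exp_w) and math.isnan(got_w)) or \
                    got_w == pytest.approx(exp_w, abs=1e-12)


class TestNormalizedCurve:
    def test_self_ensemble_gives_unit_norm(self, rng):
        c = random_weighted(15, 0.4, rng).binarized()
        ens = rk.NullEnsemble(source_id=c.subject_id, n_nulls=1, seed=0, members=[c])
        curve = rk.normalized_curve(c, ens, "topological")
        defined = ~np.isnan(curve.phi)
        np.testing.assert_allclose(curve.phi_norm[defined], 1.0)
        np.testing.assert_allclose(curve.p_emp[defined], 1.0)

    def test_mismatched_ensemble_rejected(self, rng):
        c = random_weighted(10, 0.4, rng)
        ens = rk.build_ensemble(c, 2, seed=0)
        other = random_weighted(10, 0.4, rng)
        other.subject_id = "other"
        with pytest.raises(ValueError, match="different network"):
            rk.normalized_curve(other, ens, "topological")

    def test_planted_core_detected(self, small_cohort):
        # thresholding strips the weak background, exposing the planted core
        built, _, _ = small_cohort
        c = built.connectomes[0]
        ens = rk.build_ensemble(c.binarized(), 100, seed=5)
        curve = rk.normalized_curve(c.binarized(), ens, "topological")
        sig = (np.nan_to_num(curve.phi_norm) > 1) & (np.nan_to_num(curve.p_emp, nan=1) < 0.05)
        ks = np.flatnonzero(sig)
        # a contiguous run of significant levels at least 3 long must exist
        runs = np.split(ks, np.flatnonzero(np.diff(ks) > 1) + 1)
        assert max((len(r) for r in runs), default=0) >= 3


class TestSignificantRange:
    def _curves(self, norm_rows):
        out = []
        for r, row in enumerate(norm_rows):
            arr = np.asarray(row, dtype=float)
            out.append(rk.RichClubCurve(subject_id=f"s{r}", variant="topological",
                                        k=np.arange(len(arr)), phi=arr, phi_norm=arr))
        return out

    def test_all_subjects_above(self):
        rows = [[0.5] * 10 + [1.5] * 11] * 4
        assert rk.significant_range(self._curves(rows), 0.97) == (10, 20)

    def test_single_failure_splits_range(self):
        # 28 subjects, coverage .97 -> zero failures allowed
        base = [0.0] * 10 + [1.5] * 11
        rows = [list(base) for _ in range(28)]
        rows[0][15] = 0.9
        assert rk.significant_range(self._curves(rows), 0.97) in [(10, 14), (16, 20)]
        assert rk.significant_range(self._curves(rows), 0.97) == (16, 20) or \
            rk.significant_range(self._curves(rows), 0.97) == (10, 14)

    def test_no_level_qualifies(self):
        rows = [[0.5] * 8] * 3
        assert rk.significant_range(self._curves(rows), 0.97) is None


class TestHubs:
    def test_count_is_ceil(self):
        spec = rk.SyntheticSpec(n_nodes=250)
        c = rk.generate_connectome(spec, "HC", subject_seed=0)
        assert len(rk.select_hubs(c, 0.16)) == 40  # ceil(0.16 * 250)

    def test_star_center_selected(self):
        star = from_edges(5, [(0, i, 1) for i in range(1, 5)])
        assert rk.select_hubs(star, 0.2) == frozenset({0})

    def test_tie_break_deterministic(self):
        cyc = from_edges(6, [(i, (i + 1) % 6, i + 1) for i in range(6)])
        # all degrees equal -> decided by strength then index
        h1 = rk.select_hubs(cyc, 0.3)
        h2 = rk.select_hubs(cyc, 0.3)
        assert h1 == h2 and len(h1) == 2

    def test_common_hubs_monotone(self, small_cohort):
        built, _, _ = small_cohort
        hp_all = rk.common_hubs(built, 0.16)
        fewer = rk.Cohort(built.connectomes[:3], built.group_levels, nodes=built.nodes)
        hp_few = rk.common_hubs(fewer, 0.16)
        assert hp_all.common_set <= hp_few.common_set
        for s in hp_all.per_subject.values():
            assert hp_all.common_set <= s

    def test_identical_networks_full_intersection(self, rng):
        c = random_weighted(20, 0.3, rng)
        twins = [c.replace(c.W) for _ in range(3)]
        for t, sid in zip(twins, "abc"):
            t.subject_id = sid
        hp = rk.common_hubs(rk.Cohort(twins, ("HC",)), 0.2)
        assert hp.common_set == rk.select_hubs(c, 0.2)


class TestEdgeClasses:
    def test_labels_by_membership(self):
        c = from_edges(4, [(0, 1, 5), (1, 2, 10), (2, 3, 30)])
        labels = rk.classify_edges(c, {0, 1})
        assert labels["rich_club"][0, 1] and labels["feeder"][1, 2] and labels["local"][2, 3]

    def test_strengths_and_densities(self):
        # RC {5,5}, feeder {10}, local {30}
        c = from_edges(5, [(0, 1, 5), (0, 2, 5), (1, 3, 10), (3, 4, 30)])
        summ = rk.class_connectivity(c, rk.classify_edges(c, {0, 1, 2}))
        assert summ.strength == {"rich_club": 10, "feeder": 10, "local": 30}
        assert summ.density["rich_club"] == pytest.approx(0.2)
        assert summ.density["local"] == pytest.approx(0.6)

    def test_all_nodes_rich_club(self, rng):
        c = random_weighted(8, 0.5, rng)
        summ = rk.class_connectivity(c, rk.classify_edges(c, set(range(8))))
        assert summ.density["rich_club"] == 1.0
        assert summ.density["feeder"] == 0.0 and summ.density["local"] == 0.0

    def test_empty_hub_set(self, rng):
        c = random_weighted(8, 0.5, rng)
        summ = rk.class_connectivity(c, rk.classify_edges(c, set()))
        assert summ.density["local"] == 1.0

    def test_conservation(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 25))
            c = random_weighted(n, 0.4, rng)
            if c.W.sum() == 0:
                continue
            R = set(int(v) for v in rng.choice(n, size=int(rng.integers(0, n + 1)), replace=False))
            summ = rk.class_connectivity(c, rk.classify_edges(c, R))
            assert sum(summ.strength.values()) == pytest.approx(summ.strength_total, abs=0)
            assert sum(summ.density.values()) == pytest.approx(1.0, abs=1e-12)

    def test_zero_strength_rejected(self):
        c = make_connectome(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="zero total strength"):
            rk.class_connectivity(c, rk.classify_edges(c, {0}))


class TestAUC:
    def test_constant_and_trapezoid(self):
        vals = np.zeros(30)
        vals[10:21] = 1.0
        assert rk.auc_over_k(vals, (10, 20)) == pytest.approx(10.0)
        vals2 = np.array([0, 1, 2, 3], dtype=float)
        assert rk.auc_over_k(vals2, (1, 3)) == pytest.approx(4.0)

    def test_single_k_degenerate(self):
        assert rk.auc_over_k(np.array([1.0, 2.0]), (1, 1)) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rk.auc_over_k(np.array([1.0, 2.0]), (0, 5))
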