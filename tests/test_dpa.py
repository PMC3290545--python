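import math

import numpy as np
import pytest
from scipy import integrate, stats

from leapfs import dpa
from conftest import make_domain, make_residue


class TestBuildEnm:
    def test_two_node_spectrum(self):
        """Two nodes 5 A apart: one stretching mode 2*gamma, five zero modes."""
        enm = dpa.build_enm(np.array([[0.0, 0, 0], [5.0, 0, 0]]), gamma=1.0)
        w = np.sort(np.linalg.eigvalsh(enm.hessian))
        np.testing.assert_allclose(w[:5], 0, atol=1e-12)
        np.testing.assert_allclose(w[5], 2.0, rtol=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        nodes = rng.uniform(0, 15, (8, 3))
        h1 = dpa.build_enm(nodes).hessian
        h2 = dpa.build_enm(nodes + [100.0, -40.0, 7.0]).hessian
        np.testing.assert_allclose(h1, h2, atol=1e-9)

    def test_collinear_nodes_extra_zero_modes(self):
        nodes = np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
        w = np.linalg.eigvalsh(dpa.build_enm(nodes).hessian)
        assert np.sum(np.abs(w) < 1e-9) >= 7

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            dpa.build_enm(np.array([[0.0, 0, 0]]))


class TestPerturbedHessian:
    def test_far_point_unchanged(self):
        enm = dpa.build_enm(np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        h, k = dpa.perturbed_hessian(enm, [100.0, 0, 0])
        assert k == 0
        np.testing.assert_array_equal(h, enm.hessian)

    def test_single_node_rank_one_block(self):
        enm = dpa.ElasticNetwork(np.array([[0.0, 0, 0]]), gamma=1.0,
                                 r_c=10.5, hessian=np.zeros((3, 3)))
        h, k = dpa.perturbed_hessian(enm, [3.0, 0, 0])
        assert k == 1
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(h)),
                                   [0, 0, 12.0], atol=1e-12)

    def test_symmetric_points_equal_dx(self):
        enm = dpa.build_enm(np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        eng = dpa.DPAEngine(enm)
        assert eng.dx([2.5, 6.0, 0.0]) == pytest.approx(eng.dx([2.5, -6.0, 0.0]))


class TestRelativeEntropy:
    def test_identical_hessians(self):
        enm = dpa.build_enm(np.random.default_rng(1).uniform(0, 12, (6, 3)))
        assert dpa.relative_entropy(enm.hessian, enm.hessian) == pytest.approx(0, abs=1e-10)

    def test_one_dim_two_variances(self):
        """1-D precision 1 vs 2 (variances 1 and 0.5): closed form 0.0966."""
        h0 = np.array([[1.0]])
        hm = np.array([[2.0]])
        expected = 0.5 * (0.5 - 1 + math.log(2.0))
        assert dpa.relative_entropy(h0, hm) == pytest.approx(expected, rel=1e-12)

    def test_one_dim_matches_numeric_integration(self):
        s0sq, smsq = 1.0, 0.5
        pm = lambda x: math.exp(-x * x / (2 * smsq)) / math.sqrt(2 * math.pi * smsq)
        p0 = lambda x: math.exp(-x * x / (2 * s0sq)) / math.sqrt(2 * math.pi * s0sq)
        oracle, _ = integrate.quad(
            lambda x: pm(x) * math.log(pm(x) / p0(x)), -12, 12)
        got = dpa.relative_entropy(np.array([[1 / s0sq]]), np.array([[1 / smsq]]))
        assert got == pytest.approx(oracle, rel=1e-6)

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            dpa.relative_entropy(np.eye(3), np.eye(6))

    def test_monotone_in_spring_strength(self):
        enm = dpa.build_enm(np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        point = [2.5, 4.0, 0.0]
        vals = []
        for ratio in (1.0, 4.0, 12.0, 30.0):
            hm, _ = dpa.perturbed_hessian(enm, point, gamma_s_ratio=ratio)
            vals.append(dpa.relative_entropy(enm.hessian, hm))
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_engine_agrees_with_full_matrices(self):
        rng = np.random.default_rng(7)
        nodes = rng.uniform(0, 14, (10, 3))
        enm = dpa.build_enm(nodes)
        eng = dpa.DPAEngine(enm)
        for point in rng.uniform(-5, 20, (5, 3)):
            hm, k = dpa.perturbed_hessian(enm, point)
            if k == 0:
                continue
            full = dpa.relative_entropy(enm.hessian, hm)
            assert eng.dx(point) == pytest.approx(full, rel=1e-8, abs=1e-10)

    def test_both_directions_nonnegative(self):
        rng = np.random.default_rng(3)
        enm = dpa.build_enm(rng.uniform(0, 12, (6, 3)))
        for direction in ("m_to_0", "0_to_m"):
            eng = dpa.DPAEngine(enm, direction=direction)
            assert all(eng.dx(p) >= 0 for p in rng.uniform(-5, 17, (10, 3)))


class TestSurfacePoints:
    def test_single_atom_sphere(self):
        atom = make_residue("A", 1, "ALA", [[0, 0, 0]]).atoms
        pts = dpa.generate_surface_points(atom)
        r = 1.70 + 2 * 1.5
        expected_count = math.ceil(4 * math.pi * r * r)
        assert len(pts) == expected_count
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), r, rtol=1e-9)

    def test_no_point_buried(self):
        coords = [[0, 0, 0], [2.0, 0, 0]]
        pts = dpa.generate_surface_points(coords, ["C", "C"])
        r = 1.70 + 3.0
        for c in coords:
            assert np.all(np.linalg.norm(pts - c, axis=1) >= r - 1e-6)

    def test_density_doubling(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 8, (5, 3)).tolist()
        n1 = len(dpa.generate_surface_points(coords, ["C"] * 5, density=1.0))
        n2 = len(dpa.generate_surface_points(coords, ["C"] * 5, density=2.0))
        assert n2 == pytest.approx(2 * n1, rel=0.1)

    def test_zero_atoms(self):
        with pytest.raises(ValueError):
            dpa.generate_surface_points([], [])


class TestThreshold:
    def test_gumbel_sample_selects_four_percent(self):
        rng = np.random.default_rng(11)
        dx = stats.gumbel_r.rvs(loc=3.0, scale=1.2, size=10_000, random_state=rng)
        frac = dpa.select_high_dx(dx).mean()
        assert frac == pytest.approx(0.04, abs=0.01)

    def test_constant_field_errors(self):
        with pytest.raises(dpa.DegenerateFieldError):
            dpa.select_high_dx(np.full(100, 2.0))

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        dx = stats.gumbel_r.rvs(loc=1.0, scale=0.5, size=2000, random_state=rng)
        m1 = dpa.select_high_dx(dx)
        m2 = dpa.select_high_dx(dx + 7.5)
        np.testing.assert_array_equal(m1, m2)


class TestClustering:
    def test_three_close_points_one_cluster(self):
        pts = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0.0]])
        labels = dpa.cluster_points(pts)
        assert set(labels) == {0}

    def test_two_isolated_points_unclustered(self):
        labels = dpa.cluster_points(np.array([[0, 0, 0], [1, 0, 0.0]]))
        assert list(labels) == [-1, -1]

    def test_two_separated_groups(self):
        g1 = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0.0]])
        g2 = g1 + [20.0, 0, 0]
        labels = dpa.cluster_points(np.vstack([g1, g2]))
        assert len(set(labels) - {-1}) == 2


class TestDefineSites:
    def _domain(self):
        return make_domain([
            make_residue("A", i, "ALA", [[i * 3.8, 0, 0]]) for i in range(10, 15)
        ])

    def test_site_residues_and_ranking(self):
        dom = self._domain()
        pts = np.array([[38.0, 3, 0], [41.0, 3, 0], [39.5, 4, 0],      # near 10-11
                        [53.2, 4.5, 0], [53.2, 4.6, 0], [53.2, 4.7, 0.0]])  # near 14
        dx = np.array([2.0, 2.0, 2.0, 3.0, 3.0, 3.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        sites = dpa.define_sites(dom, pts, dx, labels)
        assert [s.site_label for s in sites] == ["O", "P"]
        assert sites[0].mean_dx == 3.0
        assert {k[1] for k in sites[0].residues} == {14}
        assert {k[1] for k in sites[1].residues} == {10, 11}

    def test_residue_in_two_sites(self):
        dom = self._domain()
        pts = np.array([[45.6, 3, 0], [45.6, -3, 0.0]])
        dx = np.array([1.0, 2.0])
        labels = np.array([0, 1])
        sites = dpa.define_sites(dom, pts, dx, labels)
        shared = set(sites[0].residues) & set(sites[1].residues)
        assert shared  # appears in both sites
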