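"""kPCA, convex hulls, candidate pools, noise resampling, rank statistics."""
from __future__ import annotations

import numpy as np
import pytest

from helpers import lp_dressed_energies
from molkernel import (
    HullModel,
    baseline_pools,
    build_hull,
    build_kernel_matrix,
    candidate_pool_from_known,
    compare_ensembles,
    kpca,
    normalize,
    rank_correlation,
    resample_pools,
)
from molkernel.errors import KernelIntegrityError
from molkernel.kernels import KernelMatrix


class TestKPCA:
    def test_identity_kernel_closed_form(self):
        """Double-centering the identity gives the centering projector H,
        whose nonzero eigenvalues are all exactly 1 (multiplicity n - 1),
        and an equilateral point configuration."""
        n = 3
        res = kpca(np.eye(n))
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == n - 1
        assert np.allclose(pos, 1.0)
        d01 = np.linalg.norm(res.coords[0] - res.coords[1])
        d02 = np.linalg.norm(res.coords[0] - res.coords[2])
        d12 = np.linalg.norm(res.coords[1] - res.coords[2])
        assert d01 == pytest.approx(d02) == pytest.approx(d12)

    def test_gram_matrix_reproduces_centered_kernel(self, tri_setup):
        land, params = tri_setup["land"], tri_setup["params"]
        K = normalize(build_kernel_matrix(land.structures, params, "adapted",
                                          mset=tri_setup["mset"],
                                          envs=tri_setup["envs"]))
        res = kpca(K)
        v = K.values
        centered = v - v.mean(0)[None] - v.mean(1)[:, None] + v.mean()
        assert np.abs(res.coords @ res.coords.T - centered).max() < 1e-8

    def test_duplicate_structures_have_identical_coordinates(self):
        base = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.4], [0.5, 0.4, 1.0]])
        K = np.ones((4, 4))
        K[:3, :3] = base
        K[3, :3] = base[0]
        K[:3, 3] = base[0]
        K[3, 3] = 1.0
        res = kpca(K)
        assert np.allclose(res.coords[0], res.coords[3], atol=1e-10)

    def test_indefinite_kernel_raises(self):
        K = np.array([[1.0, 0.99], [0.99, 1.0]])
        # make it badly non-PSD after centering by an antisymmetric-style bump
        K = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(KernelIntegrityError):
            kpca(K)

    def test_eigenvalues_descending(self, tri_setup):
        land, params = tri_setup["land"], tri_setup["params"]
        K = normalize(build_kernel_matrix(land.structures, params, "adapted",
                                          mset=tri_setup["mset"],
                                          envs=tri_setup["envs"]))
        ev = kpca(K).eigenvalues
        assert np.all(np.diff(ev) <= 1e-12)


class TestHull:
    def test_three_point_geometry(self):
        hull = build_hull(np.array([[0.0], [1.0], [2.0]]),
                          np.array([0.0, 1.0, 0.0]))
        assert np.allclose(hull.dressed_energy, [0.0, 1.0, 0.0], atol=1e-9)

    def test_vertices_have_zero_dressed_energy(self):
        rng = np.random.default_rng(0)
        desc = rng.uniform(-1, 1, (30, 2))
        e = rng.uniform(0, 5, 30)
        hull = build_hull(desc, e)
        assert hull.dressed_energy.min() >= 0
        assert hull.dressed_energy[np.argmin(e)] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed,d", [(0, 1), (1, 1), (2, 2), (3, 2)])
    def test_dressed_energies_match_lp_oracle(self, seed, d):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 30))
        desc = rng.uniform(-2, 2, (n, d))
        e = rng.uniform(0, 10, n)
        hull = build_hull(desc, e)
        oracle = lp_dressed_energies(desc, e)
        assert np.abs(hull.dressed_energy - oracle).max() < 1e-8

    def test_degenerate_descriptor_fallback(self):
        desc = np.zeros((5, 2))  # no descriptor spread at all
        e = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        with pytest.warns(UserWarning):
            hull = build_hull(desc, e)
        assert np.allclose(hull.dressed_energy, e - e.min())

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            build_hull(np.array([[0.0], [1.0]]), np.array([0.0, 1.0]))


class TestPools:
    def _demo_hull(self, dressed):
        d = np.asarray(dressed, float)
        return HullModel(dim=1, points=np.zeros((len(d), 2)),
                         lower_facets=np.zeros((0, 2)), dressed_energy=d)

    def test_known_all_returns_everything(self):
        hull = self._demo_hull([0.0, 1.0, 2.0, 3.0])
        labels = list("abcd")
        pool = candidate_pool_from_known(hull, labels, labels)
        assert pool.size == 4

    def test_known_on_hull_gives_zero_window(self):
        hull = self._demo_hull([0.0, 1.0, 0.0, 2.0])
        pool = candidate_pool_from_known(hull, list("abcd"), ["a"])
        assert pool.window == 0.0
        assert set(pool.members) == {"a", "c"}

    def test_pool_equals_brute_force_threshold_scan(self):
        rng = np.random.default_rng(4)
        dressed = rng.uniform(0, 5, 20)
        labels = [f"s{i}" for i in range(20)]
        known = [labels[3], labels[11], labels[17]]
        hull = self._demo_hull(dressed)
        pool = candidate_pool_from_known(hull, labels, known)
        window = max(dressed[i] for i in (3, 11, 17))
        expected = {labels[i] for i in range(20) if dressed[i] <= window}
        assert set(pool.members) == expected

    def test_window_monotonicity_at_fixed_dimension(self):
        rng = np.random.default_rng(5)
        dressed = rng.uniform(0, 5, 50)
        hull = self._demo_hull(dressed)
        labels = [str(i) for i in range(50)]
        sizes = []
        for w in np.linspace(0, 5, 11):
            sizes.append(int(np.sum(dressed <= w + 1e-12)))
        assert all(s2 >= s1 for s1, s2 in zip(sizes, sizes[1:]))

    def test_empty_known_raises(self):
        hull = self._demo_hull([0.0, 1.0])
        with pytest.raises(ValueError):
            candidate_pool_from_known(hull, ["a", "b"], [])


class TestBaselines:
    def test_energy_cutoff_window_zero_for_global_minimum(self):
        e = np.array([5.0, 1.0, 3.0])
        pools = baseline_pools(list("abc"), e, known=["b"])
        assert pools["energy_cutoff"].window == 0.0
        assert pools["energy_cutoff"].size == 1

    def test_constant_density_degenerates_gracefully(self):
        e = np.array([2.0, 0.0, 1.0, 3.0])
        with pytest.warns(UserWarning):
            pools = baseline_pools(list("abcd"), e, known=["b"],
                                   densities=np.ones(4))
        assert pools["energy_density"].size >= 1

    def test_density_explained_known_gives_smaller_pool(self):
        """A low-density high-energy known structure sits on the
        energy-density hull edge, so the density baseline needs no energy
        window while the pure cutoff needs a large one."""
        densities = np.array([1.0, 0.9, 0.8, 0.7, 0.5, 0.95, 0.85])
        energies = np.array([0.0, 1.0, 2.5, 4.0, 7.0, 0.5, 1.8])
        labels = [f"s{i}" for i in range(7)]
        known = ["s0", "s4"]  # global minimum + porous outlier
        pools = baseline_pools(labels, energies, known, densities)
        assert pools["energy_density"].size < pools["energy_cutoff"].size

    def test_missing_density_warns(self):
        with pytest.warns(UserWarning):
            pools = baseline_pools(["a", "b", "c"],
                                   np.array([0.0, 1.0, 2.0]), ["a"])
        assert pools["energy_density"] is None


class TestNoiseResampling:
    def _setup(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        desc = rng.uniform(-1, 1, (n, 1))
        e = 3.0 * desc[:, 0] ** 2 + rng.uniform(0, 1, n)
        labels = [f"s{i}" for i in range(n)]
        known = [labels[int(np.argmin(e))], labels[5]]
        return desc, e, labels, known

    def test_zero_noise_returns_constant_pool_size(self):
        desc, e, labels, known = self._setup()
        ens = resample_pools(desc, e, labels, known, noise_sd=0.0,
                             iterations=20, seed=1)
        assert len(set(ens.pool_sizes.tolist())) == 1
        hull = build_hull(desc, e)
        assert ens.pool_sizes[0] == candidate_pool_from_known(
            hull, labels, known).size

    def test_fixed_seed_is_bitwise_reproducible(self):
        desc, e, labels, known = self._setup()
        e1 = resample_pools(desc, e, labels, known, 0.5, iterations=25, seed=7)
        e2 = resample_pools(desc, e, labels, known, 0.5, iterations=25, seed=7)
        assert np.array_equal(e1.pool_sizes, e2.pool_sizes)

    def test_empirical_noise_sd_matches_request(self):
        desc, e, labels, known = self._setup()
        ens = resample_pools(desc, e, labels, known, noise_sd=1.3,
                             iterations=250, seed=3)
        assert ens.noise_draws_sd == pytest.approx(1.3, rel=0.1)


class TestEnsembleComparison:
    def _ens(self, sizes):
        from molkernel import NoiseEnsemble
        sizes = np.asarray(sizes)
        return NoiseEnsemble(iterations=len(sizes), noise_sd=0.0, seed=0,
                             pool_sizes=sizes)

    def test_identical_samples_give_p_near_one(self):
        a = self._ens([5] * 30 + [6] * 30)
        b = self._ens([5] * 30 + [6] * 30)
        u, p = compare_ensembles(a, b)
        assert p > 0.95

    def test_fully_separated_samples(self):
        a = self._ens(np.arange(1, 251))
        b = self._ens(np.arange(251, 501))
        u, p = compare_ensembles(a, b)
        assert p < 1e-10

    def test_shuffle_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.integers(3, 10, 100)
        y = rng.integers(4, 11, 100)
        _, p1 = compare_ensembles(self._ens(x), self._ens(y))
        _, p2 = compare_ensembles(self._ens(rng.permutation(x)), self._ens(y))
        assert p1 == pytest.approx(p2)


class TestRankCorrelation:
    def _hull(self, dressed):
        return HullModel(dim=1, points=np.zeros((len(dressed), 2)),
                         lower_facets=np.zeros((0, 2)),
                         dressed_energy=np.asarray(dressed, float))

    def test_identical_rankings_give_tau_one(self):
        dressed = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        e = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        labels = list("abcde")
        tau, _ = rank_correlation(self._hull(dressed), e, labels, labels)
        assert tau == pytest.approx(1.0)

    def test_reversed_rankings_give_tau_minus_one(self):
        dressed = np.array([4.0, 3.0, 2.0, 1.0, 0.0])
        e = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        labels = list("abcde")
        tau, _ = rank_correlation(self._hull(dressed), e, labels, labels)
        assert tau == pytest.approx(-1.0)

    def test_single_transposition_tau(self):
        # 5 items, one adjacent swap: tau = 1 - 2 * 1/10 = 0.8
        dressed = np.array([0.0, 1.0, 3.0, 2.0, 4.0])
        e = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        labels = list("abcde")
        tau, _ = rank_correlation(self._hull(dressed), e, labels, labels)
        assert tau == pytest.approx(0.8)

    def test_fewer_than_three_known_raises(self):
        with pytest.raises(ValueError):
            rank_correlation(self._hull([0.0, 1.0]), np.array([0.0, 1.0]),
                             ["a", "b"], ["a", "b"])


def test_downstream_results_invariant_to_component_sign_flips(tri_setup):
    """Hulls, pools and R^2 do not depend on kPCA sign conventions."""
    from molkernel import density_r2

    land, params = tri_setup["land"], tri_setup["params"]
    K = normalize(build_kernel_matrix(land.structures, params, "adapted",
                                      mset=tri_setup["mset"],
                                      envs=tri_setup["envs"]))
    res = kpca(K)
    flipped = res.coords * np.where(np.arange(res.coords.shape[1]) % 2, -1, 1)
    e = land.energies
    h1 = build_hull(res.coords[:, :2], e)
    h2 = build_hull(flipped[:, :2], e)
    assert np.allclose(h1.dressed_energy, h2.dressed_energy, atol=1e-8)
    r2a, ca = density_r2(res.coords, land.densities)
    r2b, cb = density_r2(flipped, land.densities)
    assert r2a == pytest.approx(r2b) and ca == cb
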