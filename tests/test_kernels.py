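"""Global kernels: oracle agreement, reduction identities, PSD, normalization."""
from __future__ import annotations

import numpy as np
import pytest

from helpers import brute_force_adapted, brute_force_average
from molkernel import (
    Crystal,
    LandscapeSpec,
    Molecule,
    adapted_pair,
    average_pair,
    build_kernel_matrix,
    check_psd,
    compute_environments,
    find_mappings,
    identity_mapping_set,
    load_kernel,
    make_landscape,
    normalize,
    partition_molecules,
    save_kernel,
)
from molkernel.errors import (
    DegenerateStructureError,
    InvalidSetError,
    ParameterMismatchError,
)
from molkernel.kernels import KernelMatrix
from molkernel.soap import RadialBasis
from conftest import small_soap_params


class TestPairOracles:
    @pytest.mark.parametrize("setup_name", ["tri_setup", "ab4_setup"])
    def test_adapted_matches_brute_force(self, setup_name, request):
        """Vectorized analogous-atom kernel equals explicit enumeration."""
        setup = request.getfixturevalue(setup_name)
        envs, mset = setup["envs"], setup["mset"]
        rng = np.random.default_rng(42)
        n = len(envs)
        for _ in range(12):
            i, j = rng.integers(0, n, 2)
            fast = adapted_pair(envs[i], envs[j], mset)
            slow = brute_force_adapted(envs[i], envs[j], mset)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_average_matches_brute_force(self, tri_setup):
        envs = tri_setup["envs"]
        for i, j in [(0, 1), (2, 5), (3, 3)]:
            assert average_pair(envs[i], envs[j]) == \
                pytest.approx(brute_force_average(envs[i], envs[j]), abs=1e-10)

    def test_pair_symmetry(self, ab4_setup):
        envs, mset = ab4_setup["envs"], ab4_setup["mset"]
        assert adapted_pair(envs[0], envs[1], mset) == \
            pytest.approx(adapted_pair(envs[1], envs[0], mset), abs=1e-12)


class TestReductionIdentities:
    def test_single_atom_molecule_adapted_equals_average(self):
        """At N = 1 the analogous-atom restriction is vacuous."""
        mol = Molecule(["O"], [], np.zeros((1, 3)))
        rng = np.random.default_rng(5)
        envs = []
        for k in range(4):
            n_copies = int(rng.integers(1, 4))
            pos = (rng.uniform(0.2, 0.8, (n_copies, 3))
                   * (6.0 * n_copies)).reshape(-1, 3)
            c = Crystal(lattice=np.eye(3) * (6.0 * n_copies), positions=pos,
                        elements=["O"] * n_copies, label=f"m{k}")
            c = partition_molecules(c, mol)
            params = small_soap_params({"O"})
            envs.append(compute_environments(c, params))
        mset = identity_mapping_set(1)
        for i in range(4):
            for j in range(4):
                assert adapted_pair(envs[i], envs[j], mset) == \
                    average_pair(envs[i], envs[j])

    def test_c1_molecule_reduces_to_matched_index_sum(self, tri_setup):
        """With Q = 1 and Z' = 1 the kernel is the mean over matched indices."""
        envs, mset = tri_setup["envs"], tri_setup["mset"]
        assert mset.Q == 1
        a, b = envs[0], envs[1]
        if a.shape[0] == b.shape[0] == 1:
            direct = np.mean([float(a[0, i] @ b[0, i])
                              for i in range(a.shape[1])])
            assert adapted_pair(a, b, mset) == pytest.approx(direct, abs=1e-12)


class TestSymmetryInvariance:
    def test_relabeling_by_group_element_leaves_kernel_unchanged(self, ab4_setup):
        """Reindexing one structure by any q in Q is invisible to the kernel."""
        envs, mset = ab4_setup["envs"], ab4_setup["mset"]
        base = adapted_pair(envs[0], envs[1], mset)
        for mapping in mset.mappings:
            relabeled = envs[1][:, list(mapping.perm), :]
            assert abs(adapted_pair(envs[0], relabeled, mset) - base) < 1e-12


class TestKernelMatrix:
    def test_matrix_equals_pairwise_evaluation(self, tri_setup):
        land, params = tri_setup["land"], tri_setup["params"]
        envs, mset = tri_setup["envs"], tri_setup["mset"]
        K = build_kernel_matrix(land.structures[:5], params, "adapted",
                                mset=mset, envs=envs[:5])
        for i in range(5):
            for j in range(5):
                assert K.values[i, j] == pytest.approx(
                    adapted_pair(envs[i], envs[j], mset), abs=1e-10)
        Ka = build_kernel_matrix(land.structures[:5], params, "average",
                                 envs=envs[:5])
        for i in range(5):
            for j in range(5):
                assert Ka.values[i, j] == pytest.approx(
                    average_pair(envs[i], envs[j]), abs=1e-10)

    def test_single_structure_matrix(self, tri_setup):
        land, params = tri_setup["land"], tri_setup["params"]
        K = build_kernel_matrix(land.structures[:1], params, "adapted",
                                mset=tri_setup["mset"], envs=tri_setup["envs"][:1])
        assert K.values.shape == (1, 1)
        assert K.values[0, 0] > 0

    def test_duplicate_structure_gives_identical_rows(self, tri_setup):
        land, params = tri_setup["land"], tri_setup["params"]
        envs = [tri_setup["envs"][0], tri_setup["envs"][1], tri_setup["envs"][0]]
        structures = [land.structures[0], land.structures[1], land.structures[0]]
        K = build_kernel_matrix(structures, params, "adapted",
                                mset=tri_setup["mset"], envs=envs)
        assert np.allclose(K.values[0], K.values[2], atol=1e-12)

    def test_exact_symmetry(self, tri_setup):
        land, params = tri_setup["land"], tri_setup["params"]
        K = build_kernel_matrix(land.structures, params, "adapted",
                                mset=tri_setup["mset"], envs=tri_setup["envs"])
        assert np.array_equal(K.values, K.values.T)

    def test_mixed_zprime_symmetric_molecule_refused(self):
        land = make_landscape(LandscapeSpec(
            n_structures=6, molecule_template="symmetric_AB2",
            density_range=(0.25, 0.5), zprime_choices=(1, 2), seed=3))
        zps = {s.zprime for s in land.structures}
        assert zps == {1, 2}
        params = small_soap_params(set(land.molecule.elements))
        mset = find_mappings(land.molecule)
        with pytest.raises(InvalidSetError):
            build_kernel_matrix(land.structures, params, "adapted",
                                mset=mset, molecule=land.molecule)


class TestNormalization:
    def test_hand_arithmetic(self):
        K = KernelMatrix(np.array([[4.0, 2.0], [2.0, 9.0]]), ["a", "b"])
        Kn = normalize(K)
        assert np.allclose(Kn.values, [[1.0, 1 / 3], [1 / 3, 1.0]])

    def test_diagonal_exactly_one(self, tri_setup):
        land, params = tri_setup["land"], tri_setup["params"]
        K = build_kernel_matrix(land.structures, params, "adapted",
                                mset=tri_setup["mset"], envs=tri_setup["envs"])
        Kn = normalize(K)
        assert np.abs(np.diag(Kn.values) - 1.0).max() < 1e-10

    def test_scaled_identity_normalizes_to_identity(self):
        K = KernelMatrix(3.7 * np.eye(4), list("abcd"))
        assert np.allclose(normalize(K).values, np.eye(4))

    def test_nonpositive_diagonal_raises(self):
        K = KernelMatrix(np.array([[0.0, 0.0], [0.0, 1.0]]), ["a", "b"])
        with pytest.raises(DegenerateStructureError):
            normalize(K)


class TestPSD:
    def test_identity_passes(self):
        lam, ok = check_psd(np.eye(3))
        assert lam == pytest.approx(1.0) and ok

    def test_indefinite_fails(self):
        lam, ok = check_psd(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert lam == pytest.approx(-1.0) and not ok

    def test_adapted_kernel_on_symmetric_consistent_set_is_psd(self, ab4_setup):
        land, params = ab4_setup["land"], ab4_setup["params"]
        K = normalize(build_kernel_matrix(
            land.structures, params, "adapted", mset=ab4_setup["mset"],
            molecule=land.molecule, envs=ab4_setup["envs"]))
        lam, ok = check_psd(K)
        assert ok, f"min eigenvalue {lam}"

    def test_adapted_kernel_on_mixed_zprime_asymmetric_set_is_psd(self):
        land = make_landscape(LandscapeSpec(
            n_structures=8, density_range=(0.3, 0.6),
            zprime_choices=(1, 2), seed=9))
        params = small_soap_params(set(land.molecule.elements))
        mset = find_mappings(land.molecule)
        K = normalize(build_kernel_matrix(land.structures, params, "adapted",
                                          mset=mset, molecule=land.molecule))
        lam, ok = check_psd(K)
        assert ok, f"min eigenvalue {lam}"


def test_save_load_round_trip(tmp_path, tri_setup):
    land, params = tri_setup["land"], tri_setup["params"]
    K = normalize(build_kernel_matrix(land.structures[:4], params, "adapted",
                                      mset=tri_setup["mset"],
                                      envs=tri_setup["envs"][:4]))
    save_kernel(K, tmp_path / "K.npz")
    back = load_kernel(tmp_path / "K.npz")
    assert np.array_equal(back.values, K.values)
    assert back.labels == K.labels
    assert back.normalized and back.kernel_type == "adapted"


def test_mismatched_environments_raise(tri_setup):
    envs = tri_setup["envs"]
    bad = envs[0][:, :, :10]
    with pytest.raises(ParameterMismatchError):
        average_pair(envs[0], bad)
    with pytest.raises(ParameterMismatchError):
        adapted_pair(envs[0], bad, tri_setup["mset"])
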