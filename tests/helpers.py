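"""Independent oracles used across the test suite.

Every function here recomputes a quantity by a route deliberately different
from the implementation under test: explicit loops instead of vectorized
contractions, direct numerical integration instead of closed forms, linear
programming instead of facet geometry.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from molkernel.soap import SoapParams, local_kernel, real_spherical_harmonics
from molkernel.symmetry import MappingSet


def brute_force_average(envs_a: np.ndarray, envs_b: np.ndarray) -> float:
    """Mean local kernel over every atom pair, by explicit enumeration."""
    total, count = 0.0, 0
    for a in range(envs_a.shape[0]):
        for i in range(envs_a.shape[1]):
            for b in range(envs_b.shape[0]):
                for j in range(envs_b.shape[1]):
                    total += local_kernel(envs_a[a, i], envs_b[b, j])
                    count += 1
    return total / count


def brute_force_adapted(envs_a: np.ndarray, envs_b: np.ndarray,
                        mset: MappingSet) -> float:
    """Analogous-atom kernel by explicit enumeration of mappings, molecule
    copy pairs and atoms."""
    S, N = envs_a.shape[0], envs_a.shape[1]
    T = envs_b.shape[0]
    per_mapping = []
    for mapping in mset.mappings:
        acc = 0.0
        for a in range(S):
            for b in range(T):
                for i in range(N):
                    acc += local_kernel(envs_a[a, i], envs_b[b, mapping.perm[i]])
        per_mapping.append(acc / (N * S * T))
    return float(np.mean(per_mapping))


def quadrature_coefficients(rel_positions: np.ndarray,
                            species_indices: np.ndarray,
                            params: SoapParams, basis) -> np.ndarray:
    """Density expansion coefficients by direct angular quadrature.

    Evaluates the summed neighbor Gaussian density on a product grid
    (Gauss-Legendre in cos(theta), uniform in phi, the basis quadrature in r)
    and projects numerically onto g_n(r) Y_lm — no Bessel-function closed
    form anywhere.
    """
    L, n = params.l_max, params.n_max
    ct, wt = np.polynomial.legendre.leggauss(40)
    theta = np.arccos(ct)
    nphi = 80
    phi = np.arange(nphi) * 2 * np.pi / nphi
    wphi = 2 * np.pi / nphi
    TH, PH = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack([np.sin(TH) * np.cos(PH), np.sin(TH) * np.sin(PH),
                     np.cos(TH)], axis=-1).reshape(-1, 3)
    wang = (wt[:, None] * np.ones(nphi)[None, :] * wphi).ravel()
    Y = real_spherical_harmonics(L, dirs)
    grid, wr = basis.grid, basis.weights
    g = basis.values
    c = np.zeros((params.n_species, n, L + 1, 2 * L + 1))
    pts = grid[:, None, None] * dirs[None, :, :]
    for s in range(params.n_species):
        atoms = rel_positions[species_indices == s]
        if len(atoms) == 0:
            continue
        rho = np.zeros((len(grid), len(dirs)))
        for a in atoms:
            d2 = ((pts - a) ** 2).sum(-1)
            rho += np.exp(-d2 / (2 * params.sigma_atom ** 2))
        radial_w = wr * grid ** 2
        for l in range(L + 1):
            for mi in range(2 * L + 1):
                ang = (rho * (Y[:, l, mi] * wang)[None, :]).sum(1)
                c[s, :, l, mi] = (g * (ang * radial_w)[None, :]).sum(1)
    return c


def lp_dressed_energies(descriptors: np.ndarray, energies: np.ndarray) -> np.ndarray:
    """Dressed energies by linear programming.

    The lower-envelope energy at point x is the minimum of sum(lambda_k E_k)
    over convex combinations of all points reproducing x.  Exhaustive and
    facet-free; exact for any dimension.
    """
    desc = np.atleast_2d(descriptors)
    if desc.shape[0] != len(energies):
        desc = desc.T
    n, d = desc.shape
    dressed = np.zeros(n)
    A_eq_base = np.vstack([desc.T, np.ones(n)])
    for i in range(n):
        b_eq = np.concatenate([desc[i], [1.0]])
        res = linprog(energies, A_eq=A_eq_base, b_eq=b_eq,
                      bounds=[(0, None)] * n, method="highs")
        assert res.success, res.message
        dressed[i] = energies[i] - res.fun
    return dressed


def rigid_permutation_check(coords: np.ndarray, perm, tol: float) -> bool:
    """Accept a permutation iff it is realized by an O(3) transform (oracle
    route: work directly from the distance matrix rather than superposition)."""
    D = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    Dp = D[np.ix_(perm, perm)]
    return bool(np.abs(D - Dp).max() < tol)
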