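"""Smooth Overlap of Atomic Positions (SOAP) power spectra and local kernels.

Each atomic environment is the sum of Gaussian-smeared densities of the
neighbors (including the central atom) within a cutoff radius, one density
channel per chemical species.  The density of species s is expanded in an
orthonormal radial basis and real spherical harmonics,

    rho_s(r) = sum_{nlm} c^s_{nlm} g_n(r) Y_lm(r_hat),

and contracted into the rotation-invariant power spectrum

    p_{b1 b2 l}^{ab} = pi * sqrt(8 / (2l + 1)) * sum_m c^a_{b1 l m} c^b_{b2 l m},

stored as a flat vector ordered by (species pair a <= b, b1, b2, l), with
cross terms weighted by sqrt(2) so that the plain dot product of two vectors
equals the full double sum over species and radial pairs.  The local kernel
between two environments is that dot product.

Radial basis: Gaussian primitives equispaced on [0, r_cut], symmetrically
(Löwdin) orthonormalized under the r^2 measure; all radial integrals are done
by fixed Gauss-Legendre quadrature.  The expansion coefficients use the
closed-form spherical-harmonic expansion of a displaced Gaussian, which
involves exponentially scaled modified spherical Bessel functions — numerically
stable at all neighbor distances.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ive, sph_harm_y

from .errors import ParameterMismatchError
from .structures import Crystal


@dataclass(frozen=True)
class SoapParams:
    """Parameters of the SOAP descriptor.

    r_cut        cutoff radius (Å) of the neighbor sphere
    n_max        number of radial basis functions
    l_max        maximum spherical-harmonic degree
    sigma_atom   Gaussian smearing width (Å) of each atomic density
    species      ordered element symbols defining the density channels
    n_quad       Gauss-Legendre points for radial integrals
    """

    r_cut: float
    n_max: int = 8
    l_max: int = 6
    sigma_atom: float = 0.5
    species: tuple[str, ...] = ()
    n_quad: int = 100

    def __post_init__(self):
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if self.n_max < 1 or self.l_max < 0:
            raise ValueError("n_max >= 1 and l_max >= 0 required")
        if self.sigma_atom <= 0:
            raise ValueError("sigma_atom must be positive")
        object.__setattr__(self, "species", tuple(self.species))

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_features(self) -> int:
        same = self.n_max * (self.n_max + 1) // 2
        cross = self.n_max * self.n_max
        ns = self.n_species
        n_pairs_same = ns
        n_pairs_cross = ns * (ns - 1) // 2
        return (n_pairs_same * same + n_pairs_cross * cross) * (self.l_max + 1)

    def params_hash(self) -> str:
        key = repr((self.r_cut, self.n_max, self.l_max, self.sigma_atom,
                    self.species, self.n_quad))
        return hashlib.sha256(key.encode()).hexdigest()[:16]


def real_spherical_harmonics(l_max: int, directions: np.ndarray) -> np.ndarray:
    """Real spherical harmonics Y_lm on unit vectors.

    Returns array of shape (M, l_max+1, 2*l_max+1); entry [:, l, m + l_max]
    holds Y_lm.  Unset (l, m) slots are zero.
    """
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    u = directions / np.where(norms > 0, norms, 1.0)
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    phi = np.arctan2(u[:, 1], u[:, 0])
    M = len(u)
    out = np.zeros((M, l_max + 1, 2 * l_max + 1))
    for l in range(l_max + 1):
        out[:, l, l_max] = np.real(sph_harm_y(l, 0, theta, phi))
        for m in range(1, l + 1):
            y = sph_harm_y(l, m, theta, phi)
            out[:, l, l_max + m] = np.sqrt(2.0) * (-1) ** m * np.real(y)
            out[:, l, l_max - m] = np.sqrt(2.0) * (-1) ** m * np.imag(y)
    return out


class RadialBasis:
    """Löwdin-orthonormalized equispaced Gaussian radial basis on [0, r_cut]."""

    def __init__(self, params: SoapParams):
        self.params = params
        rc, n = params.r_cut, params.n_max
        nodes, weights = np.polynomial.legendre.leggauss(params.n_quad)
        self.grid = 0.5 * rc * (nodes + 1.0)
        self.weights = 0.5 * rc * weights
        self.centers = np.linspace(0.0, rc, n) if n > 1 else np.array([0.0])
        self.width = (rc / (n - 1)) if n > 1 else rc / 2.0
        prim = np.exp(-((self.grid[None, :] - self.centers[:, None]) ** 2)
                      / (2.0 * self.width ** 2))  # (n, G)
        w = self.weights * self.grid ** 2
        overlap = prim @ (prim * w).T
        evals, evecs = np.linalg.eigh(overlap)
        if evals.min() <= 0:
            raise ValueError("radial basis overlap not positive definite")
        s_inv_half = evecs @ np.diag(evals ** -0.5) @ evecs.T
        #: orthonormal basis evaluated on the quadrature grid, shape (n, G)
        self.values = s_inv_half @ prim
        self._s_inv_half = s_inv_half
        self._prim_centers = self.centers

    def evaluate(self, r: np.ndarray) -> np.ndarray:
        """Orthonormal basis functions g_n at arbitrary radii; shape (n, len(r))."""
        r = np.atleast_1d(np.asarray(r, dtype=float))
        prim = np.exp(-((r[None, :] - self._prim_centers[:, None]) ** 2)
                      / (2.0 * self.width ** 2))
        return self._s_inv_half @ prim


def _scaled_bessel_profile(grid: np.ndarray, r_i: np.ndarray, sigma: float,
                           l_max: int) -> np.ndarray:
    """exp(-(r^2 + r_i^2) / 2 sigma^2) * i_l(r * r_i / sigma^2) on the grid.

    Shape (len(r_i), l_max+1, len(grid)).  Written with exponentially scaled
    Bessel functions so large arguments cannot overflow.
    """
    r_i = np.atleast_1d(r_i)
    out = np.zeros((len(r_i), l_max + 1, len(grid)))
    envelope = np.exp(-((grid[None, :] - r_i[:, None]) ** 2)
                      / (2.0 * sigma ** 2))  # includes the e^{+z} factor
    z = np.outer(r_i, grid) / sigma ** 2
    central = r_i < 1e-12
    zs = np.where(z > 0, z, 1.0)
    pref = np.sqrt(np.pi / (2.0 * zs))
    for l in range(l_max + 1):
        scaled_il = pref * ive(l + 0.5, zs)  # = e^{-z} i_l(z)
        out[:, l, :] = envelope * scaled_il
    if central.any():
        # the central atom contributes only to l = 0: i_l(0) = delta_l0
        out[central, :, :] = 0.0
        out[central, 0, :] = np.exp(-grid ** 2 / (2.0 * sigma ** 2))
    return out


def expansion_coefficients(
    rel_positions: np.ndarray,
    species_indices: np.ndarray,
    params: SoapParams,
    basis: RadialBasis | None = None,
) -> np.ndarray:
    """Density expansion coefficients c[s, n, l, m] of one environment.

    ``rel_positions`` are neighbor positions relative to the central atom
    (the central atom itself should be included as a zero row);
    ``species_indices`` index into ``params.species``.  Returned shape is
    (n_species, n_max, l_max+1, 2*l_max+1) with real coefficients.
    """
    basis = basis or RadialBasis(params)
    L, n = params.l_max, params.n_max
    c = np.zeros((params.n_species, n, L + 1, 2 * L + 1))
    if len(rel_positions) == 0:
        return c
    rel_positions = np.atleast_2d(np.asarray(rel_positions, dtype=float))
    species_indices = np.asarray(species_indices)
    dists = np.linalg.norm(rel_positions, axis=1)
    within = dists <= params.r_cut  # atoms beyond the cutoff do not contribute
    rel_positions = rel_positions[within]
    species_indices = species_indices[within]
    dists = dists[within]
    if len(rel_positions) == 0:
        return c
    Y = real_spherical_harmonics(L, rel_positions)
    w = basis.weights * basis.grid ** 2
    for s in range(params.n_species):
        sel = np.where(species_indices == s)[0]
        if sel.size == 0:
            continue
        prof = _scaled_bessel_profile(basis.grid, dists[sel], params.sigma_atom, L)
        # radial integrals I[neighbor, n, l]
        I = np.einsum("g,ng,mlg->mnl", w, basis.values, prof, optimize=True)
        c[s] = 4.0 * np.pi * np.einsum("mnl,mlk->nlk", I, Y[sel], optimize=True)
    return c


def power_spectrum(c: np.ndarray, params: SoapParams) -> np.ndarray:
    """Contract expansion coefficients into the invariant power spectrum.

    Flat vector ordered by (species pair a <= b, b1, b2, l); same-species
    blocks keep b1 <= b2 and cross terms carry sqrt(2) so the dot product of
    two spectra equals the full sum over all species and radial index pairs.
    """
    L, n, ns = params.l_max, params.n_max, params.n_species
    pref = np.pi * np.sqrt(8.0 / (2.0 * np.arange(L + 1) + 1.0))
    # p[a, b, n1, n2, l] = sum_m c[a, n1, l, m] c[b, n2, l, m]
    diag = np.einsum("anlm,bplm->abnpl", c, c, optimize=True)
    diag = diag * pref[None, None, None, None, :]
    parts: list[np.ndarray] = []
    for a in range(ns):
        for b in range(a, ns):
            block = diag[a, b]  # (n, n, L+1)
            if a == b:
                iu = np.triu_indices(n)
                weights = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
                parts.append((block[iu] * weights[:, None]).ravel())
            else:
                parts.append((np.sqrt(2.0) * block).ravel())
    return np.concatenate(parts)


def _image_shifts(lattice: np.ndarray, r_cut: float) -> np.ndarray:
    """Integer lattice translations whose images can reach into the cutoff
    sphere around any atom of the home cell."""
    inv = np.linalg.inv(lattice)
    heights = 1.0 / np.linalg.norm(inv, axis=0)
    nmax = np.ceil(r_cut / heights).astype(int) + 1
    grids = np.meshgrid(*(np.arange(-m, m + 1) for m in nmax), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def compute_environments(crystal: Crystal, params: SoapParams,
                         basis: RadialBasis | None = None) -> np.ndarray:
    """Per-atom power spectra for one asymmetric-unit copy of each molecule.

    Returns array of shape (zprime, N, n_features): spectra for the atoms of
    the first ``zprime`` molecule copies of the partition, each row ordered by
    intramolecular index.  Neighbor densities include all periodic images
    within ``r_cut`` and the central atom's own density.  Comparisons between
    structures need only one copy of the asymmetric unit; symmetry-equivalent
    copies would give identical spectra.
    """
    if crystal.molecule_partition is None:
        raise ValueError("crystal must be partitioned before computing environments")
    sp_index = {el: i for i, el in enumerate(params.species)}
    for el in crystal.elements:
        if el not in sp_index:
            raise ParameterMismatchError(
                f"element {el!r} not in SoapParams.species {params.species}")
    basis = basis or RadialBasis(params)
    shifts = _image_shifts(crystal.lattice, params.r_cut) @ crystal.lattice
    # all candidate neighbor positions: (n_images * n_atoms, 3)
    all_pos = (crystal.positions[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    all_species = np.tile(
        np.array([sp_index[e] for e in crystal.elements]), len(shifts))

    zp = crystal.zprime or len(crystal.molecule_partition)
    N = len(crystal.molecule_partition[0])
    spectra = np.zeros((zp, N, params.n_features))
    for mi in range(zp):
        for ai, atom in enumerate(crystal.molecule_partition[mi]):
            center = crystal.positions[atom]
            rel = all_pos - center
            within = np.einsum("ij,ij->i", rel, rel) <= params.r_cut ** 2
            c = expansion_coefficients(rel[within], all_species[within],
                                       params, basis)
            spectra[mi, ai] = power_spectrum(c, params)
    return spectra


def local_kernel(a: np.ndarray, b: np.ndarray) -> float:
    """Local environment similarity k(a, b): the spectrum dot product."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ParameterMismatchError(
            f"power-spectrum length mismatch ({a.size} vs {b.size})")
    return float(a @ b)
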