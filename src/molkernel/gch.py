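"""Generalized convex hull landscape analysis.

Pipeline: a normalized similarity kernel is double-centered and
eigen-decomposed (kernel PCA); the leading components become machine-learned
descriptors; a convex hull is built over (descriptors, energy); each
structure's *dressed energy* is its vertical distance above the lower hull
envelope.  Structures within the smallest dressed-energy window containing
all known polymorphs form the *candidate pool* — the subset a screening
campaign would carry forward.  Energy-noise resampling quantifies how
sensitive pool sizes are to random errors in the computed energies.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import kendalltau, mannwhitneyu

from .errors import KernelIntegrityError
from .kernels import KernelMatrix


# ---------------------------------------------------------------------------
# Kernel principal component analysis
# ---------------------------------------------------------------------------

@dataclass
class KPCAResult:
    """Descriptor coordinates from a centered-kernel eigendecomposition.

    ``coords[:, j]`` is the projection on component j (0-based; component 0
    has the largest eigenvalue).  Coordinates are scaled so their Gram matrix
    reproduces the centered kernel.  Components are defined only up to sign.
    """

    eigenvalues: np.ndarray
    coords: np.ndarray
    centering_row_means: np.ndarray
    centering_grand_mean: float

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


def kpca(K: KernelMatrix | np.ndarray, neg_tol: float = 1e-8) -> KPCAResult:
    """Kernel PCA of a normalized similarity matrix.

    The kernel is double-centered (row means and column means subtracted,
    grand mean added back) and eigen-decomposed.  Eigenvalues more negative
    than ``-neg_tol * lambda_max`` indicate a non-PSD kernel and raise;
    tiny negatives are clipped to zero and their components dropped.
    """
    vals = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    n = vals.shape[0]
    if not np.allclose(vals, vals.T, atol=1e-10):
        raise KernelIntegrityError("kernel matrix is not symmetric")
    row = vals.mean(axis=1)
    grand = vals.mean()
    centered = vals - row[None, :] - row[:, None] + grand
    eigval, eigvec = np.linalg.eigh(centered)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    lam_max = max(float(eigval[0]), 0.0)
    if eigval[-1] < -neg_tol * max(lam_max, 1e-300):
        raise KernelIntegrityError(
            f"centered kernel has negative eigenvalue {eigval[-1]:.3e} "
            f"(lambda_max {lam_max:.3e}); not positive semidefinite")
    floor = 1e-12 * max(lam_max, 1e-300)
    keep = eigval > floor
    eigval = np.where(keep, eigval, 0.0)
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])[None, :]
    return KPCAResult(eigenvalues=eigval, coords=coords,
                      centering_row_means=row, centering_grand_mean=float(grand))


# ---------------------------------------------------------------------------
# Convex hull over (descriptors, energy)
# ---------------------------------------------------------------------------

@dataclass
class HullModel:
    """Lower convex hull over (descriptor coordinates, energy).

    ``dressed_energy[i]`` is structure i's energy above the lower-hull
    envelope at its descriptor coordinates (kJ/mol, >= 0; 0 on the hull).
    """

    dim: int
    points: np.ndarray              # (n, dim_used + 1); last column = energy
    lower_facets: np.ndarray        # hyperplane rows (normal..., offset)
    dressed_energy: np.ndarray
    effective_dim: int = 0          # after any degenerate-geometry fallback

    def envelope(self, descriptors: np.ndarray) -> np.ndarray:
        """Lower-envelope energy at given descriptor coordinates."""
        x = np.atleast_2d(descriptors)
        if self.lower_facets.size == 0:
            return np.full(len(x), self.points[:, -1].min())
        normals = self.lower_facets[:, :-1]
        offsets = self.lower_facets[:, -1]
        a, b = normals[:, :-1], normals[:, -1]
        # facet hyperplane: a . x + b * E + offset = 0, with b < 0 for lower
        # facets; the convex lower envelope is the max over those planes
        planes = -(x @ a.T + offsets[None, :]) / b[None, :]
        return planes.max(axis=1)


def _affine_subspace(desc: np.ndarray, tol: float = 1e-9):
    """Orthonormal basis of the affine span of the descriptor points."""
    center = desc.mean(axis=0)
    X = desc - center
    if X.size == 0:
        return center, np.zeros((desc.shape[1], 0))
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scale = s[0] if s.size and s[0] > 0 else 1.0
    rank = int(np.sum(s > tol * scale))
    return center, Vt[:rank].T


def build_hull(descriptors: np.ndarray, energies: np.ndarray) -> HullModel:
    """Convex hull in (descriptor, energy) space with per-structure
    dressed energies.

    Lower facets are those whose outward normal points down in energy
    (component < -1e-12); vertical facets are excluded.  Degenerate
    descriptor geometry (affinely dependent points) falls back to the
    spanned subspace with a warning; with no descriptor spread at all the
    envelope is the constant global-minimum energy.
    """
    desc = np.atleast_2d(np.asarray(descriptors, dtype=float))
    if desc.ndim == 1:
        desc = desc[:, None]
    energies = np.asarray(energies, dtype=float)
    n, d = desc.shape
    if len(energies) != n:
        raise ValueError("energies length does not match descriptor rows")

    center, basis = _affine_subspace(desc)
    eff_dim = basis.shape[1]
    if eff_dim < d:
        warnings.warn(
            f"descriptor points span only {eff_dim} of {d} dimensions; "
            "building the hull in the spanned affine subspace")
    reduced = (desc - center) @ basis

    if eff_dim == 0:
        dressed = energies - energies.min()
        points = np.column_stack([reduced, energies])
        return HullModel(dim=d, points=points, lower_facets=np.zeros((0, 2)),
                         dressed_energy=dressed, effective_dim=0)

    pts = np.column_stack([reduced, energies])
    if n < eff_dim + 2:
        raise ValueError(
            f"need at least dim + 2 = {eff_dim + 2} points, got {n}")
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # flat in the energy direction as well: joggle via qhull option
        hull = ConvexHull(pts, qhull_options="QJ")
    eqs = hull.equations  # rows: normal components then offset
    lower = eqs[eqs[:, eff_dim] < -1e-12]
    model = HullModel(dim=d, points=pts, lower_facets=lower,
                      dressed_energy=np.zeros(n), effective_dim=eff_dim)
    dressed = energies - model.envelope(reduced)
    model.dressed_energy = np.where(np.abs(dressed) < 1e-9, 0.0,
                                    np.maximum(dressed, 0.0))
    return model


# ---------------------------------------------------------------------------
# Candidate pools
# ---------------------------------------------------------------------------

@dataclass
class CandidatePool:
    """Structures within a dressed-energy window of the hull."""

    window: float
    members: list[str]
    size: int


def candidate_pool_from_known(
    hull: HullModel,
    labels: Sequence[str],
    known: Sequence[str],
) -> CandidatePool:
    """Smallest dressed-energy window containing every known polymorph.

    The window is the largest dressed energy among the known structures;
    the pool is every structure whose dressed energy is <= that window
    (ties at the boundary included).
    """
    if not known:
        raise ValueError("known structure set must be nonempty")
    index = {lab: i for i, lab in enumerate(labels)}
    missing = [k for k in known if k not in index]
    if missing:
        raise ValueError(f"known labels absent from the set: {missing}")
    window = max(hull.dressed_energy[index[k]] for k in known)
    members = [lab for i, lab in enumerate(labels)
               if hull.dressed_energy[i] <= window + 1e-12]
    return CandidatePool(window=float(window), members=members, size=len(members))


def baseline_pools(
    labels: Sequence[str],
    energies: np.ndarray,
    known: Sequence[str],
    densities: np.ndarray | None = None,
) -> dict[str, CandidatePool | None]:
    """Traditional landscape baselines for pool selection.

    ``energy_cutoff``: smallest relative-energy window above the global
    minimum containing all known structures.  ``energy_density``: candidate
    pool from a hull built with density as the single descriptor (skipped
    with a warning when densities are absent).  The same machinery accepts
    any user-supplied intuitive descriptor in place of density.
    """
    if not known:
        raise ValueError("known structure set must be nonempty")
    energies = np.asarray(energies, dtype=float)
    index = {lab: i for i, lab in enumerate(labels)}
    rel = energies - energies.min()
    window = max(rel[index[k]] for k in known)
    members = [lab for i, lab in enumerate(labels) if rel[i] <= window + 1e-12]
    pools: dict[str, CandidatePool | None] = {
        "energy_cutoff": CandidatePool(float(window), members, len(members))
    }
    if densities is None:
        warnings.warn("densities missing; skipping energy-density baseline")
        pools["energy_density"] = None
    else:
        hull = build_hull(np.asarray(densities, float)[:, None], energies)
        pools["energy_density"] = candidate_pool_from_known(hull, labels, known)
    return pools


# ---------------------------------------------------------------------------
# Energy-noise resampling
# ---------------------------------------------------------------------------

@dataclass
class NoiseEnsemble:
    """Candidate-pool sizes under resampled energy noise."""

    iterations: int
    noise_sd: float
    seed: int
    pool_sizes: np.ndarray
    noise_draws_sd: float = 0.0     # empirical sd of all drawn noise values


def resample_pools(
    descriptors: np.ndarray,
    energies: np.ndarray,
    labels: Sequence[str],
    known: Sequence[str],
    noise_sd: float,
    iterations: int = 250,
    seed: int = 0,
) -> NoiseEnsemble:
    """Rebuild hull and candidate pool under uniform energy noise.

    Per iteration, i.i.d. noise uniform on [-noise_sd*sqrt(3),
    +noise_sd*sqrt(3)] — a uniform distribution with standard deviation
    ``noise_sd`` — is added to every energy, the hull is rebuilt over the
    fixed descriptors, and the pool size recorded.  Descriptors come from a
    single kPCA: energies do not enter the kernel, so the embedding is not
    recomputed.  Draw order is fixed (one array per iteration) so a given
    seed is bitwise reproducible.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    half_width = noise_sd * np.sqrt(3.0)
    energies = np.asarray(energies, dtype=float)
    sizes = np.zeros(iterations, dtype=int)
    all_draws = []
    for it in range(iterations):
        noise = rng.uniform(-half_width, half_width, size=len(energies)) \
            if half_width > 0 else np.zeros(len(energies))
        all_draws.append(noise)
        hull = build_hull(descriptors, energies + noise)
        pool = candidate_pool_from_known(hull, labels, known)
        sizes[it] = pool.size
    draws = np.concatenate(all_draws)
    return NoiseEnsemble(iterations=iterations, noise_sd=noise_sd, seed=seed,
                         pool_sizes=sizes,
                         noise_draws_sd=float(draws.std(ddof=1)) if half_width > 0 else 0.0)


def compare_ensembles(e1: NoiseEnsemble, e2: NoiseEnsemble) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test on pool-size samples (tie-corrected)."""
    if len(e1.pool_sizes) == 0 or len(e2.pool_sizes) == 0:
        raise ValueError("ensembles must be nonempty")
    res = mannwhitneyu(e1.pool_sizes, e2.pool_sizes, alternative="two-sided",
                       method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def rank_correlation(
    hull: HullModel,
    energies: np.ndarray,
    labels: Sequence[str],
    known: Sequence[str],
) -> tuple[float, float]:
    """Kendall tau between hull-based and energetic rankings of known
    structures (dressed energy vs relative lattice energy)."""
    if len(known) < 3:
        raise ValueError("need at least 3 known structures for a rank correlation")
    index = {lab: i for i, lab in enumerate(labels)}
    idx = [index[k] for k in known]
    energies = np.asarray(energies, dtype=float)
    res = kendalltau(hull.dressed_energy[idx], energies[idx] - energies.min())
    return float(res.statistic), float(res.pvalue)
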