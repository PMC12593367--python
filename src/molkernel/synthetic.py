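"""Synthetic molecules and crystal landscapes with planted structure.

These generators produce toy molecular crystals whose density, conformation
and energy relationships are controlled, so every stage of the analysis —
partitioning, symmetry mappings, kernels, hulls, interpretability and energy
regression — can be exercised and its planted signal recovered without any
external data.  The landscapes are NOT physical crystal-structure-prediction
minima: packings are random subject to a clash constraint and energies come
from a declared functional form, not a force field.

Molecule templates (ground-truth mapping counts in parentheses):

* ``asymmetric_triatomic`` — bent C-N-O chain, point group C1 (Q = 1)
* ``symmetric_AB2``        — bent water-like OH2, C2v on atoms (Q = 2)
* ``square_AB4``           — square-planar CO4 toy, C4v on atoms (Q = 8)
* ``chain_ABCD``           — asymmetric 4-atom C-N-O-F chain with a rotatable
                             terminal torsion (Q = 1); used to plant
                             conformational classes
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structures import Crystal, Molecule, partition_molecules, write_crystal

_AVOGADRO = 6.02214076e23

TEMPLATES = ("asymmetric_triatomic", "symmetric_AB2", "square_AB4", "chain_ABCD")

#: ground-truth number of analogous-atom mappings per template
TEMPLATE_Q = {
    "asymmetric_triatomic": 1,
    "symmetric_AB2": 2,
    "square_AB4": 8,
    "chain_ABCD": 1,
}


def _place_dihedral(p0, p1, p2, bond, angle_deg, torsion_deg):
    """Place the next chain atom from bond length, bond angle and torsion."""
    b1 = p1 - p0
    b2 = p2 - p1
    b2u = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    nu = n / np.linalg.norm(n)
    mu = np.cross(nu, b2u)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d = bond * np.array([-np.cos(ang), np.sin(ang) * np.cos(tor),
                         np.sin(ang) * np.sin(tor)])
    frame = np.column_stack([b2u, mu, nu])
    return p2 + frame @ d


def make_molecule(template: str, torsion_deg: float = 60.0) -> Molecule:
    """Build a template molecule; ``torsion_deg`` applies to ``chain_ABCD``."""
    if template == "asymmetric_triatomic":
        # bent C-N-O with unequal bond lengths -> no symmetry
        ang = np.radians(115.0)
        coords = np.array([
            [1.35, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [1.25 * np.cos(ang), 1.25 * np.sin(ang), 0.0],
        ])
        return Molecule(["C", "N", "O"], [(0, 1), (1, 2)], coords)
    if template == "symmetric_AB2":
        half = np.radians(104.5 / 2.0)
        coords = np.array([
            [0.0, 0.0, 0.0],
            [0.96 * np.sin(half), 0.96 * np.cos(half), 0.0],
            [-0.96 * np.sin(half), 0.96 * np.cos(half), 0.0],
        ])
        return Molecule(["O", "H", "H"], [(0, 1), (0, 2)], coords)
    if template == "square_AB4":
        r = 1.40
        coords = np.array([
            [0.0, 0.0, 0.0],
            [r, 0.0, 0.0], [0.0, r, 0.0], [-r, 0.0, 0.0], [0.0, -r, 0.0],
        ])
        return Molecule(["C", "O", "O", "O", "O"],
                        [(0, 1), (0, 2), (0, 3), (0, 4)], coords)
    if template == "chain_ABCD":
        p0 = np.array([1.40, 0.0, 0.0])
        p1 = np.zeros(3)
        ang = np.radians(110.0)
        p2 = np.array([1.36 * np.cos(ang), 1.36 * np.sin(ang), 0.0])
        p3 = _place_dihedral(p0, p1, p2, 1.38, 108.0, torsion_deg)
        coords = np.array([p0, p1, p2, p3])
        return Molecule(["C", "N", "O", "F"],
                        [(0, 1), (1, 2), (2, 3)], coords)
    raise ValueError(f"unknown molecule template {template!r}; "
                     f"choose from {TEMPLATES}")


@dataclass
class LandscapeSpec:
    """Recipe for a synthetic crystal landscape.

    Energies (kJ/mol) follow
    ``e0 + density_coeff * density + sine_amp * sin(2 pi density / period)
    + torsion_coeff * |torsion|/180 + noise``
    with Gaussian noise of sd ``energy_noise_sd``; the optional sine term
    adds smooth short-scale structure so regression tasks are not trivially
    linear.  When ``torsion_classes``
    is set (two target angles in degrees), each structure's conformation is
    drawn from one of the two classes — the planted binary classification.
    """

    n_structures: int = 60
    molecule_template: str = "asymmetric_triatomic"
    density_range: tuple[float, float] = (0.35, 0.85)   # g/cm^3, toy packings
    zprime_choices: tuple[int, ...] = (1,)
    torsion_classes: tuple[float, float] | None = None   # (class0, class1) deg
    torsion_jitter_deg: float = 5.0
    orientation_jitter_deg: float = 10.0
    energy_e0: float = 0.0
    energy_density_coeff: float = -30.0   # denser packings bind more strongly
    energy_torsion_coeff: float = 0.0
    energy_sine_amp: float = 0.0          # optional smooth nonlinear term
    energy_sine_period: float = 0.15      # g/cm^3 period of the sine term
    energy_noise_sd: float = 1.0          # comparable to lattice-energy noise
    min_intermolecular: float = 2.0       # Å clash floor (> any bond cutoff)
    max_retries: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_structures < 4:
            raise ValueError("n_structures must be >= 4")
        if self.energy_noise_sd < 0:
            raise ValueError("energy_noise_sd must be >= 0")
        if self.molecule_template not in TEMPLATES:
            raise ValueError(f"unknown template {self.molecule_template!r}")


@dataclass
class Landscape:
    """Generated structure set with its planted ground truth."""

    structures: list[Crystal]
    molecule: Molecule
    energies: np.ndarray
    densities: np.ndarray
    labels: list[str]
    torsions: np.ndarray | None = None
    class_labels: np.ndarray | None = None


def _min_intermolecular_distance(positions_per_mol, lattice) -> float:
    shifts = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                       for k in (-1, 0, 1)]) @ lattice
    best = np.inf
    n_mol = len(positions_per_mol)
    for a in range(n_mol):
        for b in range(a, n_mol):
            for sh in shifts:
                if a == b and not sh.any():
                    continue
                d = np.linalg.norm(
                    positions_per_mol[a][:, None, :]
                    - (positions_per_mol[b] + sh)[None, :, :], axis=2)
                best = min(best, float(d.min()))
    return best


def _pack_cell(molecule, conformer_coords, zp, volume, spec, rng):
    """Random rigid packing of zp molecule copies into a cubic cell."""
    a = volume ** (1.0 / 3.0)
    lattice = np.eye(3) * a
    # copies spaced along the body diagonal to start from a clash-free grid
    centers = (np.arange(zp)[:, None] + 0.5) / zp @ np.ones((1, 3)) * a
    jitter_rad = np.radians(spec.orientation_jitter_deg)
    for _ in range(spec.max_retries):
        mols = []
        for m in range(zp):
            centered = conformer_coords - conformer_coords.mean(axis=0)
            if jitter_rad > 0:
                axis = rng.standard_normal(3)
                axis /= np.linalg.norm(axis)
                R = Rotation.from_rotvec(axis * rng.normal(0.0, jitter_rad))
                centered = centered @ R.as_matrix().T
            offset = rng.normal(0.0, 0.05 * a, size=3)
            mols.append(centered + centers[m] + offset)
        if _min_intermolecular_distance(mols, lattice) >= spec.min_intermolecular:
            return lattice, np.vstack(mols)
    raise RuntimeError(
        f"could not pack {zp} molecules at volume {volume:.1f} Å^3 without "
        f"clashes below {spec.min_intermolecular} Å")


def make_landscape(spec: LandscapeSpec) -> Landscape:
    """Generate a deterministic synthetic landscape from ``spec``.

    Every returned structure is already partitioned against the template
    molecule; energies and densities are attached to the crystals and also
    returned as arrays, alongside any planted torsions and class labels.
    """
    rng = np.random.default_rng(spec.seed)
    molecule = make_molecule(spec.molecule_template)
    has_torsion = (spec.torsion_classes is not None
                   and spec.molecule_template == "chain_ABCD")
    if spec.torsion_classes is not None and not has_torsion:
        raise ValueError("torsion_classes requires the chain_ABCD template")

    structures, energies, densities, labels = [], [], [], []
    torsions = [] if has_torsion else None
    classes = [] if has_torsion else None
    for idx in range(spec.n_structures):
        zp = int(rng.choice(spec.zprime_choices))
        target_density = rng.uniform(*spec.density_range)
        if has_torsion:
            cls = int(rng.integers(0, 2))
            base = spec.torsion_classes[cls]
            tor = base + rng.normal(0.0, spec.torsion_jitter_deg)
            conformer = make_molecule("chain_ABCD", torsion_deg=tor).reference_coords
            classes.append(cls)
            torsions.append(tor)
        else:
            conformer = molecule.reference_coords
        mass_g = zp * molecule.mass / _AVOGADRO
        volume = mass_g / target_density * 1e24  # Å^3
        lattice, positions = _pack_cell(molecule, conformer, zp, volume, spec, rng)
        label = f"s{idx:04d}"
        crystal = Crystal(lattice=lattice, positions=positions,
                          elements=list(molecule.elements) * zp, label=label)
        crystal = partition_molecules(crystal, molecule)
        density = crystal.computed_density()
        energy = (spec.energy_e0
                  + spec.energy_density_coeff * density
                  + spec.energy_sine_amp
                  * np.sin(2.0 * np.pi * density / spec.energy_sine_period)
                  + (spec.energy_torsion_coeff * abs(tor) / 180.0
                     if has_torsion else 0.0)
                  + (rng.normal(0.0, spec.energy_noise_sd)
                     if spec.energy_noise_sd > 0 else 0.0))
        crystal.energy = float(energy)
        crystal.density = float(density)
        if has_torsion:
            crystal.class_label = cls
        structures.append(crystal)
        energies.append(float(energy))
        densities.append(float(density))
        labels.append(label)
    return Landscape(
        structures=structures,
        molecule=molecule,
        energies=np.array(energies),
        densities=np.array(densities),
        labels=labels,
        torsions=np.array(torsions) if has_torsion else None,
        class_labels=np.array(classes) if has_torsion else None,
    )


def write_landscape(landscape: Landscape, directory: str | Path) -> None:
    """Write extxyz structure files plus a properties CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in landscape.structures:
        write_crystal(s, directory / f"{s.label}.xyz", format="extxyz")
        rows.append({
            "label": s.label,
            "energy_kjmol": s.energy,
            "density_gcm3": s.density,
            "class": s.class_label,
        })
    pd.DataFrame(rows).to_csv(directory / "properties.csv", index=False)
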