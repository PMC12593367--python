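"""Containers and I/O for periodic molecular crystal structures.

A :class:`Molecule` is the reference topology (elements + covalent bond
graph + one representative geometry) shared by every crystal in a landscape.
A :class:`Crystal` is a periodic structure whose atoms, once partitioned,
are grouped into molecule copies with a consistent intramolecular indexing.
That consistent indexing is what makes "analogous atom" comparisons between
two crystals of the same molecule meaningful.

Supported file formats: extended XYZ (with a ``Lattice=...`` header) and CIF
(read through :mod:`gemmi`; symmetry-expanded to P1 on input).  Energies,
densities and class labels travel either in extxyz comment fields or in a
sidecar CSV with columns ``label, energy_kjmol, density_gcm3, class``.
"""
from __future__ import annotations

import re
import shlex
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    DifferentMoleculeError,
    FormatError,
    InconsistentMoleculeError,
)
from .geometry import superpose_rmsd

# Covalent radii (Å), Cordero-style consensus values for the elements the
# package is routinely used with.  Extend as needed.
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}

ATOMIC_MASSES = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Si": 28.085, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "Br": 79.904, "I": 126.904,
}

#: default extra margin on top of summed covalent radii when detecting bonds
DEFAULT_BOND_TOLERANCE = 0.4

_AVOGADRO = 6.02214076e23


@dataclass
class Molecule:
    """Reference molecular topology and one representative conformation."""

    elements: list[str]
    bonds: list[tuple[int, int]]
    reference_coords: np.ndarray

    def __post_init__(self) -> None:
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        n = len(self.elements)
        if self.reference_coords.shape != (n, 3):
            raise ValueError("reference_coords must be (N, 3)")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond index ({i},{j}) out of range")
        if not nx.is_connected(self.bond_graph()):
            raise ValueError("molecular bond graph must be connected")

    @property
    def N(self) -> int:
        return len(self.elements)

    def bond_graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, el in enumerate(self.elements):
            g.add_node(i, element=el)
        g.add_edges_from(self.bonds)
        return g

    @property
    def mass(self) -> float:
        """Molecular mass in g/mol."""
        return float(sum(ATOMIC_MASSES[e] for e in self.elements))


@dataclass
class Crystal:
    """A periodic crystal structure with optional molecule partition.

    ``lattice`` holds row vectors in Å; ``positions`` are Cartesian Å.
    ``molecule_partition`` lists atom indices per molecule copy, each copy
    ordered by intramolecular index.  ``zprime`` is the number of molecules
    in the asymmetric unit and ``n_asym_copies`` the number of copies of the
    asymmetric unit in the cell (1 for P1 structures).
    """

    lattice: np.ndarray
    positions: np.ndarray
    elements: list[str]
    molecule_partition: list[list[int]] | None = None
    zprime: int | None = None
    n_asym_copies: int = 1
    energy: float | None = None
    density: float | None = None
    label: str = ""
    class_label: int | None = None

    def __post_init__(self) -> None:
        self.lattice = np.asarray(self.lattice, dtype=float).reshape(3, 3)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.positions):
            raise ValueError("elements and positions length mismatch")
        if abs(np.linalg.det(self.lattice)) < 1e-10:
            raise ValueError("lattice matrix is singular")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.lattice)))

    def fractional(self) -> np.ndarray:
        return self.positions @ np.linalg.inv(self.lattice)

    def computed_density(self) -> float:
        """Mass density in g/cm^3 from cell contents."""
        mass_g = sum(ATOMIC_MASSES[e] for e in self.elements) / _AVOGADRO
        return mass_g / (self.volume * 1e-24)

    def copy(self) -> "Crystal":
        return replace(
            self,
            lattice=self.lattice.copy(),
            positions=self.positions.copy(),
            elements=list(self.elements),
            molecule_partition=None if self.molecule_partition is None
            else [list(m) for m in self.molecule_partition],
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _parse_extxyz_comment(line: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for token in shlex.split(line):
        if "=" in token:
            k, v = token.split("=", 1)
            out[k] = v
    return out


def _read_extxyz(path: Path) -> Crystal:
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise FormatError(f"{path}: truncated extxyz file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: bad atom-count line") from exc
    fields = _parse_extxyz_comment(lines[1])
    if "Lattice" not in fields:
        raise FormatError(f"{path}: extxyz missing Lattice= header")
    lat = np.array([float(x) for x in fields["Lattice"].split()])
    if lat.size != 9:
        raise FormatError(f"{path}: Lattice must contain 9 numbers")
    lattice = lat.reshape(3, 3)
    elements: list[str] = []
    positions = np.zeros((natoms, 3))
    if len(lines) < 2 + natoms:
        raise FormatError(f"{path}: fewer atom lines than declared")
    for i in range(natoms):
        parts = lines[2 + i].split()
        el = parts[0]
        if el not in ATOMIC_MASSES:
            raise FormatError(f"{path}: unknown element symbol {el!r}")
        elements.append(el)
        positions[i] = [float(x) for x in parts[1:4]]

    def _opt_float(key: str) -> float | None:
        return float(fields[key]) if key in fields else None

    return Crystal(
        lattice=lattice,
        positions=positions,
        elements=elements,
        energy=_opt_float("energy_kjmol"),
        density=_opt_float("density_gcm3"),
        label=fields.get("label", path.stem),
        class_label=int(fields["class"]) if "class" in fields else None,
    )


def _write_extxyz(crystal: Crystal, path: Path) -> None:
    lat = " ".join(f"{x:.12f}" for x in crystal.lattice.ravel())
    comment = [f'Lattice="{lat}"', "Properties=species:S:1:pos:R:3"]
    if crystal.energy is not None:
        comment.append(f"energy_kjmol={crystal.energy:.10f}")
    if crystal.density is not None:
        comment.append(f"density_gcm3={crystal.density:.10f}")
    if crystal.class_label is not None:
        comment.append(f"class={crystal.class_label}")
    if crystal.label:
        comment.append(f"label={crystal.label}")
    lines = [str(crystal.n_atoms), " ".join(comment)]
    for el, pos in zip(crystal.elements, crystal.positions):
        lines.append(f"{el} {pos[0]:.12f} {pos[1]:.12f} {pos[2]:.12f}")
    path.write_text("\n".join(lines) + "\n")


def _read_cif(path: Path) -> Crystal:
    import gemmi

    try:
        small = gemmi.read_small_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on parse failure
        raise FormatError(f"{path}: CIF parse failure: {exc}") from exc
    cell = small.cell
    if cell.volume <= 0 or cell.a <= 0:
        raise FormatError(f"{path}: CIF missing or invalid cell")
    orth = np.array(cell.orth.mat.tolist())  # column-vector convention
    lattice = orth.T  # row vectors
    elements: list[str] = []
    frac: list[list[float]] = []
    sites = small.get_all_unit_cell_sites()
    if not sites:
        sites = small.sites
    for site in sites:
        symbol = site.element.name
        if symbol not in ATOMIC_MASSES:
            raise FormatError(f"{path}: unknown element symbol {symbol!r}")
        elements.append(symbol)
        frac.append([site.fract.x, site.fract.y, site.fract.z])
    if not elements:
        raise FormatError(f"{path}: CIF contains no atom sites")
    positions = np.asarray(frac) @ lattice
    return Crystal(lattice=lattice, positions=positions, elements=elements,
                   label=small.name or path.stem)


def _write_cif(crystal: Crystal, path: Path) -> None:
    """Minimal P1 CIF writer (cell + fractional atom sites)."""
    a, b, c = (np.linalg.norm(v) for v in crystal.lattice)
    def angle(u, v):
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    alpha = angle(crystal.lattice[1], crystal.lattice[2])
    beta = angle(crystal.lattice[0], crystal.lattice[2])
    gamma = angle(crystal.lattice[0], crystal.lattice[1])
    name = re.sub(r"\W+", "_", crystal.label) or "crystal"
    lines = [
        f"data_{name}",
        "_symmetry_space_group_name_H-M 'P 1'",
        f"_cell_length_a {a:.8f}",
        f"_cell_length_b {b:.8f}",
        f"_cell_length_c {c:.8f}",
        f"_cell_angle_alpha {alpha:.8f}",
        f"_cell_angle_beta {beta:.8f}",
        f"_cell_angle_gamma {gamma:.8f}",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    frac = crystal.fractional()
    for i, (el, f) in enumerate(zip(crystal.elements, frac)):
        lines.append(f"{el}{i+1} {el} {f[0]:.10f} {f[1]:.10f} {f[2]:.10f}")
    path.write_text("\n".join(lines) + "\n")


def read_crystal(path: str | Path, format: str | None = None) -> Crystal:
    """Read a crystal from ``path`` (``cif`` or ``extxyz``, inferred from suffix)."""
    path = Path(path)
    fmt = format or ("cif" if path.suffix.lower() == ".cif" else "extxyz")
    if fmt == "extxyz":
        return _read_extxyz(path)
    if fmt == "cif":
        return _read_cif(path)
    raise FormatError(f"unknown format {fmt!r}")


def write_crystal(crystal: Crystal, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("cif" if path.suffix.lower() == ".cif" else "extxyz")
    if fmt == "extxyz":
        _write_extxyz(crystal, path)
    elif fmt == "cif":
        _write_cif(crystal, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")


def attach_properties(structures: Sequence[Crystal], csv_path: str | Path) -> None:
    """Attach energies/densities/class labels from a sidecar CSV in place.

    Expected columns: ``label`` plus any of ``energy_kjmol``, ``density_gcm3``,
    ``class``.
    """
    df = pd.read_csv(csv_path).set_index("label")
    for s in structures:
        if s.label not in df.index:
            continue
        row = df.loc[s.label]
        if "energy_kjmol" in df.columns and pd.notna(row["energy_kjmol"]):
            s.energy = float(row["energy_kjmol"])
        if "density_gcm3" in df.columns and pd.notna(row["density_gcm3"]):
            s.density = float(row["density_gcm3"])
        if "class" in df.columns and pd.notna(row["class"]):
            s.class_label = int(row["class"])


# ---------------------------------------------------------------------------
# Molecule partitioning
# ---------------------------------------------------------------------------

def _periodic_bonds(crystal: Crystal, bond_tolerance: float):
    """All covalent bonds (i, j, image_shift) under periodic boundary conditions.

    ``image_shift`` is the integer lattice translation applied to atom j so
    that it bonds to atom i.
    """
    n = crystal.n_atoms
    radii = np.array([COVALENT_RADII[e] for e in crystal.elements])
    max_cut = 2 * radii.max() + bond_tolerance
    # shifts to search: enough images to cover max_cut along each axis
    inv = np.linalg.inv(crystal.lattice)
    heights = 1.0 / np.linalg.norm(inv, axis=0)  # perpendicular cell widths
    nmax = np.maximum(1, np.ceil(max_cut / heights).astype(int))
    shifts = np.array([
        (i, j, k)
        for i in range(-nmax[0], nmax[0] + 1)
        for j in range(-nmax[1], nmax[1] + 1)
        for k in range(-nmax[2], nmax[2] + 1)
    ])
    shift_cart = shifts @ crystal.lattice
    bonds = []
    pos = crystal.positions
    for i in range(n):
        cut = radii[i] + radii + bond_tolerance  # (n,)
        # distances from atom i to every atom in every image
        for s_idx, sc in enumerate(shift_cart):
            d = np.linalg.norm(pos + sc - pos[i], axis=1)
            close = np.where(d < cut)[0]
            for j in close:
                if j == i and not shifts[s_idx].any():
                    continue
                bonds.append((i, int(j), tuple(shifts[s_idx])))
    return bonds


def _connected_groups(crystal: Crystal, bonds) -> list[tuple[list[int], np.ndarray]]:
    """Connected components of the periodic bond graph with unwrapped coords."""
    n = crystal.n_atoms
    adj: dict[int, list[tuple[int, tuple[int, int, int]]]] = {i: [] for i in range(n)}
    for i, j, shift in bonds:
        adj[i].append((j, shift))
    seen = [False] * n
    groups = []
    for start in range(n):
        if seen[start]:
            continue
        comp = [start]
        shifts = {start: np.zeros(3)}
        seen[start] = True
        queue = [start]
        while queue:
            i = queue.pop()
            for j, sh in adj[i]:
                target = shifts[i] + np.array(sh)
                if not seen[j]:
                    seen[j] = True
                    shifts[j] = target
                    comp.append(j)
                    queue.append(j)
        coords = np.array([
            crystal.positions[i] + shifts[i] @ crystal.lattice for i in comp
        ])
        groups.append((comp, coords))
    return groups


def _best_isomorphism(group_elements, group_bonds, group_coords, molecule: Molecule):
    """Element-preserving isomorphism from reference indices to group slots.

    When the reference graph has automorphisms there are several valid
    mappings; pick the one whose permuted coordinates best superpose onto the
    reference conformation (RMSD over O(3)), breaking exact ties
    lexicographically so the choice is deterministic.
    """
    g = nx.Graph()
    for idx, el in enumerate(group_elements):
        g.add_node(idx, element=el)
    g.add_edges_from(group_bonds)
    ref = molecule.bond_graph()
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        ref, g, node_match=lambda a, b: a["element"] == b["element"])
    best = None
    for mapping in matcher.isomorphisms_iter():
        perm = tuple(mapping[i] for i in range(molecule.N))
        coords = group_coords[list(perm)]
        rmsd = round(superpose_rmsd(coords, molecule.reference_coords), 8)
        key = (rmsd, perm)
        if best is None or key < best[0]:
            best = (key, perm)
    if best is None:
        raise DifferentMoleculeError(
            "bonded group is not isomorphic to the reference molecule")
    return best[1]


def partition_molecules(
    crystal: Crystal,
    molecule: Molecule,
    bond_tolerance: float = DEFAULT_BOND_TOLERANCE,
) -> Crystal:
    """Group atoms into whole molecules with reference-consistent indexing.

    Bonds are detected when an interatomic distance (including periodic
    images) is below the sum of covalent radii plus ``bond_tolerance``.
    Molecules split across cell boundaries are unwrapped so each copy is
    geometrically contiguous.  Returns a new :class:`Crystal` whose
    ``molecule_partition`` is filled and whose positions are the unwrapped
    ones; ``zprime`` is set to the number of molecules per asymmetric unit.
    """
    N = molecule.N
    if crystal.n_atoms % N != 0:
        raise InconsistentMoleculeError(
            f"{crystal.n_atoms} atoms is not a multiple of molecule size {N}")
    bonds = _periodic_bonds(crystal, bond_tolerance)
    groups = _connected_groups(crystal, bonds)
    for comp, _ in groups:
        if len(comp) != N:
            raise InconsistentMoleculeError(
                f"bonded group of {len(comp)} atoms, expected {N} "
                f"(structure {crystal.label!r})")

    out = crystal.copy()
    partition: list[tuple[tuple[float, ...], list[int]]] = []
    for comp, coords in groups:
        group_elements = [crystal.elements[i] for i in comp]
        local = {atom: slot for slot, atom in enumerate(comp)}
        group_bonds = set()
        for i, j, _ in bonds:
            if i in local and j in local:
                group_bonds.add((min(local[i], local[j]), max(local[i], local[j])))
        perm = _best_isomorphism(group_elements, sorted(group_bonds), coords, molecule)
        ordered_atoms = [comp[p] for p in perm]
        for slot, atom in enumerate(ordered_atoms):
            if crystal.elements[atom] != molecule.elements[slot]:
                raise DifferentMoleculeError("element mismatch after mapping")
            out.positions[atom] = coords[perm[slot]]
        # deterministic copy order: sort by centroid folded into the cell
        centroid = coords.mean(axis=0) @ np.linalg.inv(crystal.lattice) % 1.0
        partition.append((tuple(np.round(centroid, 6)), ordered_atoms))
    partition.sort(key=lambda t: t[0])
    out.molecule_partition = [atoms for _, atoms in partition]
    n_mols = len(out.molecule_partition)
    if n_mols % out.n_asym_copies != 0:
        raise InconsistentMoleculeError(
            "molecule count not divisible by n_asym_copies")
    out.zprime = n_mols // out.n_asym_copies
    return out


def validate_set(
    structures: Sequence[Crystal],
    molecule: Molecule,
    symmetric: bool,
) -> dict:
    """Check a structure set's suitability for the adapted kernel.

    The analogous-atom kernel is positive semidefinite on sets of consistent
    Z' and on any set whose molecule is asymmetric; sets mixing Z' values
    with a symmetric molecule are flagged invalid.
    """
    zprimes = sorted({s.zprime for s in structures})
    if any(z is None for z in zprimes):
        raise ValueError("all structures must be partitioned before validation")
    consistent = len(zprimes) == 1
    valid = consistent or not symmetric
    messages = []
    if not consistent:
        messages.append(f"mixed Z' values {zprimes}")
        if symmetric:
            messages.append(
                "symmetric molecule with mixed Z': adapted kernel is not "
                "guaranteed positive semidefinite; set rejected")
    return {
        "zprimes": zprimes,
        "consistent_zprime": consistent,
        "symmetric_molecule": symmetric,
        "valid_for_adapted": valid,
        "messages": messages,
    }
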