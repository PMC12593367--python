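"""Molecular point-group operators realized as atom permutations.

Two atoms of a molecule are "analogous" when some point-group operator maps
one onto the other; such atoms have identical intramolecular environments in
a given conformation.  This module finds the full set Q of atom mappings: the
element-preserving automorphisms of the covalent bond graph whose permutation
can be realized by a proper or improper rigid rotation of the reference
conformation.  Mappings are computed from a single reference conformation,
which is appropriate for rigid or asymmetric molecules; structure sets of
flexible symmetric molecules are outside this construction's guarantees.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .geometry import superpose_rmsd
from .structures import Molecule

#: default RMSD (Å) below which a permutation counts as geometrically realized
DEFAULT_RMSD_TOLERANCE = 0.1


@dataclass(frozen=True)
class AtomMapping:
    """A single atom-atom mapping q, with q(i) = perm[i]."""

    perm: tuple[int, ...]
    operator_label: str = ""

    def __post_init__(self):
        if sorted(self.perm) != list(range(len(self.perm))):
            raise ValueError("perm must be a permutation of 0..N-1")

    def __call__(self, i: int) -> int:
        return self.perm[i]

    def compose(self, other: "AtomMapping") -> tuple[int, ...]:
        """Permutation of self∘other: i -> self(other(i))."""
        return tuple(self.perm[other.perm[i]] for i in range(len(self.perm)))

    def inverse(self) -> tuple[int, ...]:
        inv = [0] * len(self.perm)
        for i, j in enumerate(self.perm):
            inv[j] = i
        return tuple(inv)


@dataclass
class MappingSet:
    """The set of analogous-atom mappings for one molecule; Q = len(mappings)."""

    mappings: list[AtomMapping] = field(default_factory=list)

    @property
    def Q(self) -> int:
        return len(self.mappings)

    @property
    def N(self) -> int:
        return len(self.mappings[0].perm) if self.mappings else 0

    def permutations(self) -> list[tuple[int, ...]]:
        return [m.perm for m in self.mappings]


def identity_mapping_set(n_atoms: int) -> MappingSet:
    return MappingSet([AtomMapping(tuple(range(n_atoms)), "E")])


def find_mappings(
    molecule: Molecule,
    rmsd_tolerance: float = DEFAULT_RMSD_TOLERANCE,
) -> MappingSet:
    """All analogous-atom mappings of ``molecule``.

    Enumerates element-preserving automorphisms of the bond graph and keeps
    those realizable by a rigid (proper or improper) rotation: best-fit
    superposition of the permuted reference coordinates onto the originals
    must give RMSD below ``rmsd_tolerance``.  The identity is always
    included; an asymmetric molecule yields Q = 1.  Distinct point-group
    operators inducing the same permutation collapse to one mapping.
    """
    ref = molecule.bond_graph()
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        ref, ref, node_match=lambda a, b: a["element"] == b["element"])
    coords = molecule.reference_coords
    seen: set[tuple[int, ...]] = set()
    accepted: list[AtomMapping] = []
    for mapping in matcher.isomorphisms_iter():
        perm = tuple(mapping[i] for i in range(molecule.N))
        if perm in seen:
            continue
        seen.add(perm)
        rmsd = superpose_rmsd(coords[list(perm)], coords)
        if rmsd < rmsd_tolerance:
            label = "E" if perm == tuple(range(molecule.N)) else f"q{len(accepted)}"
            accepted.append(AtomMapping(perm, label))
    # identity is an automorphism, always realized with RMSD 0
    accepted.sort(key=lambda m: m.perm)
    return MappingSet(accepted)


def verify_closure(mset: MappingSet) -> bool:
    """True iff the mapping set is closed under composition and inversion."""
    perms = set(mset.permutations())
    if tuple(range(mset.N)) not in perms:
        return False
    for a in mset.mappings:
        if a.inverse() not in perms:
            return False
        for b in mset.mappings:
            if a.compose(b) not in perms:
                return False
    return True


def save_mappings(mset: MappingSet, path: str | Path) -> None:
    """Write mappings as plain text, one space-separated permutation per line."""
    lines = [" ".join(str(j) for j in m.perm) for m in mset.mappings]
    Path(path).write_text("\n".join(lines) + "\n")


def load_mappings(path: str | Path) -> MappingSet:
    mappings = []
    for k, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        perm = tuple(int(x) for x in line.split())
        mappings.append(AtomMapping(perm, f"q{k}"))
    if not mappings:
        raise ValueError(f"{path}: no mappings found")
    return MappingSet(mappings)
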