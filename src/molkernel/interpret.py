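"""Relating machine-learned descriptors to intuitive structural features.

The kPCA components are abstract; their value for screening comes from how
clearly they track features a crystallographer can act on — density,
molecular conformation, hydrogen bonding.  This module quantifies those
relationships: linear R^2 against density for each leading component, and
balanced-accuracy of a linear support vector classifier predicting binary
structural classes from one or several components.  Class labels can be
built from an intramolecular torsion angle, or consumed from input data
(e.g. hydrogen-bond motif assignments); a simple geometric hydrogen-bond
detector is provided as an approximate convenience.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .geometry import dihedral
from .structures import Crystal

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class ClassLabels:
    """Per-structure binary class assignment with provenance text."""

    labels: np.ndarray
    definition: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("class labels must be 0 or 1")


def torsion_class(
    structures: Sequence[Crystal],
    atom_indices: tuple[int, int, int, int],
    threshold_deg: float = 90.0,
) -> ClassLabels:
    """Binary conformational classes from an intramolecular torsion angle.

    For each structure the dihedral over the four intramolecular atom indices
    is computed for every molecule copy in the asymmetric unit; copies are
    averaged (the convention for Z' > 1).  Class 1 when the absolute averaged
    angle is >= ``threshold_deg``, else class 0.
    """
    labels = np.zeros(len(structures), dtype=int)
    for si, s in enumerate(structures):
        if s.molecule_partition is None:
            raise ValueError(f"structure {s.label!r} is not partitioned")
        zp = s.zprime or len(s.molecule_partition)
        angles = []
        for copy in s.molecule_partition[:zp]:
            pts = [s.positions[copy[i]] for i in atom_indices]
            angles.append(dihedral(*pts))
        mean_angle = float(np.mean(angles))
        labels[si] = 1 if abs(mean_angle) >= threshold_deg else 0
    return ClassLabels(labels, definition=(
        f"|mean dihedral over atoms {atom_indices}| >= {threshold_deg} deg"))


def hbond_class(
    structures: Sequence[Crystal],
    acceptor_index: int,
    max_ha_dist: float = 2.5,
    min_dha_angle: float = 120.0,
) -> ClassLabels:
    """Approximate geometric hydrogen-bond classes.

    Class 1 when the given intramolecular acceptor atom receives at least one
    intermolecular D-H...A contact with H...A distance below ``max_ha_dist``
    Å and D-H...A angle above ``min_dha_angle`` degrees, counting periodic
    images.  A geometric stand-in for motif-based assignment; approximate by
    nature.
    """
    labels = np.zeros(len(structures), dtype=int)
    for si, s in enumerate(structures):
        if s.molecule_partition is None:
            raise ValueError(f"structure {s.label!r} is not partitioned")
        donors = []  # (H position, donor position, molecule id)
        for mi, copy in enumerate(s.molecule_partition):
            for local, atom in enumerate(copy):
                if s.elements[atom] != "H":
                    continue
                # the bonded heavy atom is the donor: nearest non-H in copy
                heavy = [a for a in copy if s.elements[a] != "H"]
                d = min(heavy, key=lambda a: np.linalg.norm(
                    s.positions[a] - s.positions[atom]))
                donors.append((s.positions[atom], s.positions[d], mi))
        shifts = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                           for k in (-1, 0, 1)]) @ s.lattice
        found = False
        for mi, copy in enumerate(s.molecule_partition):
            acc = s.positions[copy[acceptor_index]]
            for hpos, dpos, mj in donors:
                for sh in shifts:
                    if mj == mi and not sh.any():
                        continue  # intramolecular
                    a = acc + sh
                    ha = np.linalg.norm(a - hpos)
                    if ha > max_ha_dist or ha < 1e-6:
                        continue
                    v1 = dpos - hpos
                    v2 = a - hpos
                    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if ang > min_dha_angle:
                        found = True
                        break
                if found:
                    break
            if found:
                break
        labels[si] = int(found)
    return ClassLabels(labels, definition=(
        f"intermolecular H-bond to acceptor atom {acceptor_index} "
        f"(H...A < {max_ha_dist} A, D-H...A > {min_dha_angle} deg)"))


def density_r2(
    coords: np.ndarray,
    densities: np.ndarray,
    n_components: int = 32,
) -> tuple[float, int]:
    """Strongest linear density relationship among leading components.

    Ordinary least-squares R^2 of density against each of the first
    ``n_components`` kPCA components individually; returns the maximum and
    its 1-based component index.  R^2 of a single-regressor fit equals the
    squared Pearson correlation, so the result is invariant to component
    sign flips.
    """
    densities = np.asarray(densities, dtype=float)
    if np.ptp(densities) == 0:
        raise ValueError("density is constant; R^2 undefined")
    m = min(n_components, coords.shape[1])
    best_r2, best_comp = -1.0, 0
    for j in range(m):
        x = coords[:, j]
        if np.ptp(x) == 0:
            continue
        r = np.corrcoef(x, densities)[0, 1]
        r2 = float(r * r)
        if r2 > best_r2:
            best_r2, best_comp = r2, j + 1
    return best_r2, best_comp


def _nonempty_subsets(items):
    return chain.from_iterable(
        combinations(items, k) for k in range(1, len(items) + 1))


def svc_accuracy(
    coords: np.ndarray,
    labels: ClassLabels | np.ndarray,
    mode: str = "single_best_of_32",
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, tuple[int, ...], float]:
    """Best linear-SVC balanced accuracy over a feature/C search.

    Modes: ``single_best_of_32`` assesses each of the first 32 components
    individually; ``best_subset_of_top5`` assesses every nonempty subset of
    the five top-ranked components.  Each candidate feature set is evaluated
    at every C in ``c_grid`` by stratified k-fold cross-validation; the
    maximum mean balanced accuracy is returned together with the winning
    1-based component tuple and C.
    """
    y = labels.labels if isinstance(labels, ClassLabels) else np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if mode == "single_best_of_32":
        m = min(32, coords.shape[1])
        candidates = [(j,) for j in range(m)]
    elif mode == "best_subset_of_top5":
        m = min(5, coords.shape[1])
        candidates = [tuple(s) for s in _nonempty_subsets(range(m))]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    best = (-1.0, (0,), 0.0)
    for feats in candidates:
        X = coords[:, list(feats)]
        for C in c_grid:
            clf = SVC(kernel="linear", C=C)
            score = float(np.mean(cross_val_score(
                clf, X, y, cv=cv, scoring="balanced_accuracy")))
            if score > best[0]:
                best = (score, tuple(f + 1 for f in feats), C)
    return best
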