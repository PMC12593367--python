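"""Global structure-structure similarity kernels.

Two constructions over the per-atom SOAP spectra:

* **average** — the arithmetic mean of all atom-atom local kernels between
  the compared cell contents, with no restriction on which atoms may be
  compared.
* **adapted** — the analogous-atom kernel: only atoms that occupy the same
  intramolecular position, up to a molecular point-group mapping q, are
  compared.  For each mapping q, with molecule copies a in A and b in B,

      K_q(A, B) = 1 / (N S T) * sum_{a, b} sum_i k(A_{a,i}, B_{b,q(i)}),

  where N is the molecule size and S, T the Z' of the two structures; the
  final kernel is the mean of K_q over all Q mappings.  Averaging (rather
  than maximizing) over the group keeps the kernel positive semidefinite on
  valid structure sets: consistent Z', or any Z' mix when the molecule is
  asymmetric.

Kernel matrices are normalized so self-similarities equal one:
K'(A,B) = K(A,B) / sqrt(K(A,A) K(B,B)).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateStructureError,
    InvalidSetError,
    ParameterMismatchError,
)
from .soap import RadialBasis, SoapParams, compute_environments
from .structures import Crystal, Molecule, validate_set
from .symmetry import MappingSet, identity_mapping_set


@dataclass
class KernelMatrix:
    """Symmetric pairwise structure-similarity matrix with provenance."""

    values: np.ndarray
    labels: list[str]
    kernel_type: str = "adapted"
    normalized: bool = False
    params_hash: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("kernel shape does not match label count")

    @property
    def n(self) -> int:
        return len(self.labels)

    def submatrix(self, rows: Sequence[int], cols: Sequence[int] | None = None) -> np.ndarray:
        cols = rows if cols is None else cols
        return self.values[np.ix_(rows, cols)]


def average_pair(envs_a: np.ndarray, envs_b: np.ndarray) -> float:
    """Average kernel between two structures from their environment arrays.

    ``envs_*`` have shape (S, N, n_features): SOAP spectra for each molecule
    copy of the asymmetric unit.  Returns the mean local kernel over all atom
    pairs between the compared contents.
    """
    if envs_a.shape[-1] != envs_b.shape[-1]:
        raise ParameterMismatchError("environments built with different SoapParams")
    ga = envs_a.reshape(-1, envs_a.shape[-1]).sum(axis=0)
    gb = envs_b.reshape(-1, envs_b.shape[-1]).sum(axis=0)
    ma = envs_a.shape[0] * envs_a.shape[1]
    mb = envs_b.shape[0] * envs_b.shape[1]
    return float(ga @ gb) / (ma * mb)


def adapted_pair(envs_a: np.ndarray, envs_b: np.ndarray, mset: MappingSet) -> float:
    """Analogous-atom kernel between two structures.

    Restricts local-kernel comparisons to atoms with the same intramolecular
    index up to a mapping q, averages over all molecule-copy pairs of the
    asymmetric units (S x T pairs) and over the Q mappings.
    """
    if envs_a.shape[-1] != envs_b.shape[-1]:
        raise ParameterMismatchError("environments built with different SoapParams")
    N = envs_a.shape[1]
    if envs_b.shape[1] != N:
        raise ParameterMismatchError("structures contain different molecules")
    if mset.N != N:
        raise ParameterMismatchError(
            f"mapping length {mset.N} does not match molecule size {N}")
    S, T = envs_a.shape[0], envs_b.shape[0]
    fa = envs_a.sum(axis=0)  # (N, D)
    fb = envs_b.sum(axis=0)
    M = fa @ fb.T  # M[i, j] = sum_{a,b} k(A_{a,i}, B_{b,j})
    total = 0.0
    for mapping in mset.mappings:
        total += sum(M[i, mapping.perm[i]] for i in range(N))
    return total / (mset.Q * N * S * T)


def build_kernel_matrix(
    structures: Sequence[Crystal],
    params: SoapParams,
    kernel_type: str = "adapted",
    mset: MappingSet | None = None,
    molecule: Molecule | None = None,
    envs: Sequence[np.ndarray] | None = None,
) -> KernelMatrix:
    """Raw (unnormalized) pairwise kernel matrix over a structure set.

    Environments are computed per structure unless supplied.  For the adapted
    kernel the set is validated first: a symmetric molecule (Q > 1) with
    mixed Z' is refused because positive semidefiniteness is not guaranteed
    there.  The upper triangle is computed and mirrored so the result is
    exactly symmetric.
    """
    if kernel_type not in ("adapted", "average"):
        raise ValueError(f"unknown kernel_type {kernel_type!r}")
    if envs is None:
        basis = RadialBasis(params)
        envs = [compute_environments(s, params, basis) for s in structures]
    envs = list(envs)
    if kernel_type == "adapted":
        if mset is None:
            mset = identity_mapping_set(envs[0].shape[1])
        if molecule is not None:
            report = validate_set(structures, molecule, symmetric=mset.Q > 1)
            if not report["valid_for_adapted"]:
                raise InvalidSetError("; ".join(report["messages"]))
    n = len(envs)
    K = np.zeros((n, n))
    same_shape = len({e.shape for e in envs}) == 1
    if kernel_type == "average":
        G = np.stack([e.reshape(-1, e.shape[-1]).sum(axis=0) for e in envs]) \
            if same_shape else None
        m = np.array([e.shape[0] * e.shape[1] for e in envs], dtype=float)
        if G is not None:
            K = (G @ G.T) / np.outer(m, m)
        else:
            sums = [e.reshape(-1, e.shape[-1]).sum(axis=0) for e in envs]
            for i in range(n):
                for j in range(i, n):
                    K[i, j] = float(sums[i] @ sums[j]) / (m[i] * m[j])
    else:
        # molecule-summed spectra scaled by 1/S give K_q sums directly
        fbar = [e.sum(axis=0) / e.shape[0] for e in envs]  # each (N, D)
        N = fbar[0].shape[0]
        F = np.stack(fbar)  # (n, N, D)
        for mapping in mset.mappings:
            perm = list(mapping.perm)
            K += np.einsum("xid,yid->xy", F, F[:, perm, :], optimize=True)
        K /= mset.Q * N
    K = np.triu(K) + np.triu(K, 1).T  # exact symmetry
    labels = [s.label or str(i) for i, s in enumerate(structures)] \
        if structures else [str(i) for i in range(n)]
    return KernelMatrix(K, labels, kernel_type=kernel_type,
                        normalized=False, params_hash=params.params_hash())


def normalize(K: KernelMatrix) -> KernelMatrix:
    """Normalize so every self-similarity equals one."""
    d = np.diag(K.values)
    if np.any(d <= 0):
        bad = [K.labels[i] for i in np.where(d <= 0)[0]]
        raise DegenerateStructureError(
            f"nonpositive self-similarity for structures {bad}")
    scale = 1.0 / np.sqrt(d)
    vals = K.values * np.outer(scale, scale)
    np.fill_diagonal(vals, 1.0)
    vals = np.triu(vals) + np.triu(vals, 1).T
    return KernelMatrix(vals, list(K.labels), kernel_type=K.kernel_type,
                        normalized=True, params_hash=K.params_hash)


def check_psd(K: KernelMatrix | np.ndarray, tol: float = 1e-8) -> tuple[float, bool]:
    """Smallest eigenvalue and whether it clears -tol * largest eigenvalue."""
    vals = K.values if isinstance(K, KernelMatrix) else np.asarray(K)
    eigs = np.linalg.eigvalsh(vals)
    lam_min, lam_max = float(eigs[0]), float(eigs[-1])
    return lam_min, lam_min >= -tol * max(lam_max, 1e-300)


def save_kernel(K: KernelMatrix, path: str | Path) -> None:
    """Dense array file plus a JSON sidecar of labels and provenance."""
    path = Path(path)
    np.savez_compressed(path, values=K.values)
    meta = {
        "labels": K.labels,
        "kernel_type": K.kernel_type,
        "normalized": K.normalized,
        "params_hash": K.params_hash,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_kernel(path: str | Path) -> KernelMatrix:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    values = np.load(path)["values"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return KernelMatrix(values, meta["labels"], kernel_type=meta["kernel_type"],
                        normalized=meta["normalized"],
                        params_hash=meta["params_hash"])
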