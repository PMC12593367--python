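"""Shared fixtures: small synthetic landscapes and their SOAP environments.

Session-scoped so the (moderately expensive) environment computations are
shared across test modules.  All randomness is seeded.
"""
from __future__ import annotations

import numpy as np
import pytest

from molkernel import (
    LandscapeSpec,
    SoapParams,
    compute_environments,
    find_mappings,
    make_landscape,
    make_molecule,
)
from molkernel.soap import RadialBasis


def small_soap_params(species) -> SoapParams:
    """Reduced-size SOAP parameters used throughout the unit tests."""
    return SoapParams(r_cut=4.0, n_max=3, l_max=2, sigma_atom=0.5,
                      species=tuple(sorted(species)))


@pytest.fixture(scope="session")
def tri_landscape():
    """16 asymmetric-triatomic crystals with density-driven energies."""
    return make_landscape(LandscapeSpec(n_structures=16, seed=11,
                                        energy_noise_sd=0.5))


@pytest.fixture(scope="session")
def tri_setup(tri_landscape):
    """Landscape plus environments, params and mapping set."""
    land = tri_landscape
    params = small_soap_params(set(land.molecule.elements))
    basis = RadialBasis(params)
    envs = [compute_environments(s, params, basis) for s in land.structures]
    mset = find_mappings(land.molecule)
    return {"land": land, "params": params, "envs": envs, "mset": mset}


@pytest.fixture(scope="session")
def ab4_setup():
    """Square-planar AB4 crystals (Q = 8) with environments."""
    land = make_landscape(LandscapeSpec(
        n_structures=8, molecule_template="square_AB4",
        density_range=(0.4, 0.8), seed=23))
    params = small_soap_params(set(land.molecule.elements))
    basis = RadialBasis(params)
    envs = [compute_environments(s, params, basis) for s in land.structures]
    mset = find_mappings(land.molecule)
    return {"land": land, "params": params, "envs": envs, "mset": mset}


@pytest.fixture(scope="session")
def chain_class_landscape():
    """chain_ABCD landscape with planted separable torsion classes."""
    return make_landscape(LandscapeSpec(
        n_structures=60, molecule_template="chain_ABCD",
        density_range=(0.55, 0.65), torsion_classes=(40.0, 140.0),
        energy_torsion_coeff=20.0, energy_noise_sd=0.5, seed=5))
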