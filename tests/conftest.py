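"""Shared fixtures: toy receptor-ligand complex and the two-state sampling toy."""

import numpy as np
import pytest

from mrdock.energy import EnergyModel
from mrdock.gomodel import build_native_contacts
from mrdock.system import SimulationSettings
from mrdock.toys import (
    ToySpec,
    attach_ligand,
    make_toy_ligand,
    make_toy_receptor,
    make_two_state_toy,
)


@pytest.fixture(scope="session")
def toy_complex():
    """Helix receptor + chain ligand, contacts and a compiled energy model."""
    spec = ToySpec(n_residues=20, n_atomistic_residues=6, ligand_size=5,
                   n_rotatable_bonds=2, rng_seed=0)
    receptor = make_toy_receptor(spec)
    ligand = make_toy_ligand(spec)
    system = attach_ligand(receptor["system"], ligand, receptor["site_center"])
    contacts = build_native_contacts(system)
    settings = SimulationSettings()
    model = EnergyModel(system, contacts=contacts, settings=settings)
    return {
        "spec": spec,
        "system": system,
        "ligand": ligand,
        "contacts": contacts,
        "model": model,
        "settings": settings,
        "site_center": receptor["site_center"],
    }


@pytest.fixture(scope="session")
def two_state():
    """Two-pocket cage toy with quadrature-exact basin weights."""
    return make_two_state_toy()


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
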