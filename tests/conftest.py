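import numpy as np
import pytest

from mdoc.synthetic import (
    generate_reference_ensemble,
    make_toy_molecule,
    synthesize_constraints,
)

SAUPE = (8.0e-4, 3.0e-4, 2.0e-4, -1.5e-4, 1.0e-4)


@pytest.fixture(scope="session")
def toy():
    """Single-rotor toy molecule (system, starting conformation)."""
    return make_toy_molecule("single-rotor")


@pytest.fixture(scope="session")
def study(toy):
    """Reference 70/30 ensemble plus forward-modeled constraint tables."""
    system, start = toy
    ens = generate_reference_ensemble(
        system, {"trans": 0.7, "gauche-": 0.3, "gauche+": 0.0}, 5000, seed=3
    )
    cons = synthesize_constraints(ens, system, SAUPE, seed=4)
    return system, start, ens, cons


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def ethane_like_table():
    """8-atom two-carbon table used across topology tests."""
    atoms = [dict(name="Ca", element="C", mass=12.0, charge=-0.09),
             dict(name="Cb", element="C", mass=12.0, charge=-0.09)]
    for c in "ab":
        for t in "123":
            atoms.append(dict(name=f"H{c}{t}", element="H", mass=1.0, charge=0.03))
    names = [a["name"] for a in atoms]
    idx = {n: i for i, n in enumerate(names)}
    bonds = [(idx["Ca"], idx["Cb"], 1.53, 2000.0)]
    for c, parent in (("a", "Ca"), ("b", "Cb")):
        for t in "123":
            bonds.append((idx[f"H{c}{t}"], idx[parent], 1.09, 1500.0))
    return dict(atoms=atoms, bonds=bonds)
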