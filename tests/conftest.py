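"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest

from bindfold import (
    GeneratorSpec,
    StructureEnsemble,
    gen_complex,
    native_contact_set,
)
from bindfold.ensemble_io import Atom, element_mass

BINDING_GROUPS = (("P",), ("D", "R"))


def make_atom(chain, resi, resname, name, element):
    return Atom(chain_id=chain, residue_index=resi, residue_name=resname,
                atom_name=name, element=element, mass=element_mass(element))


def make_ensemble(rows, frames, times=None):
    """rows: (chain, resi, resname, atom_name, element); frames: list of
    (n_atoms, 3) arrays."""
    atoms = [make_atom(*r) for r in rows]
    return StructureEnsemble(atoms=atoms, coords=np.asarray(frames, float),
                             times=times)


@pytest.fixture(scope="session")
def folded_complex():
    """Folded reference ensemble with its construction ground truth.

    Low thermal noise so the derived native set equals the planted
    topology; noisier ensembles are generated per test where the noise
    itself is under study.
    """
    return gen_complex(GeneratorSpec(seed=1, n_frames=50, noise_sigma=0.05))


@pytest.fixture(scope="session")
def native_set(folded_complex):
    ens, _ = folded_complex
    return native_contact_set(ens, binding_groups=BINDING_GROUPS)
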