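"""Shared fixtures: hand-built PDB text and tiny in-memory complexes."""

from __future__ import annotations

import numpy as np
import pytest

from voxelppi.structure_io import Chain, ComplexStructure
from voxelppi.synthetic import FixtureSpec, build_fixture_complex


def atom_line(serial, name, resname, chain, resid, x, y, z, b=90.0,
              element=None, altloc=" ", record="ATOM"):
    """One fixed-column PDB ATOM/HETATM line."""
    element = element if element is not None else name.strip()[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:>3s} "
            f"{chain}{resid:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.00:6.2f}{b:6.2f}          {element:>2s}")


def pdb_text(lines):
    return "\n".join(lines + ["END"]) + "\n"


def make_chain(chain_id, atoms):
    """Build a Chain from (element, resid, (x, y, z), plddt, is_ca) tuples."""
    return Chain(
        chain_id=chain_id,
        element=np.array([a[0] for a in atoms], dtype="U2"),
        residue_index=np.array([a[1] for a in atoms], dtype=int),
        residue_name=np.array(["ALA"] * len(atoms), dtype="U3"),
        coords=np.array([a[2] for a in atoms], dtype=float),
        plddt=np.array([a[3] for a in atoms], dtype=float),
        is_ca=np.array([a[4] for a in atoms], dtype=bool),
    )


def make_complex(atoms_a, atoms_b):
    return ComplexStructure([make_chain("A", atoms_a),
                             make_chain("B", atoms_b)])


def ca(resid, xyz, plddt=90.0, element="C"):
    return (element, resid, xyz, plddt, True)


@pytest.fixture(scope="session")
def small_fixture_complex():
    """A parsed medium-size synthetic complex shared across tests."""
    return build_fixture_complex(
        FixtureSpec(n_res_a=40, n_res_b=40, gap=5.0, seed=11))


@pytest.fixture(scope="session")
def minimal_pdb():
    """Two chains, one CA each, 10 Angstrom apart."""
    return pdb_text([
        atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, b=90.0),
        "TER",
        atom_line(2, "CA", "GLY", "B", 1, 10.0, 0.0, 0.0, b=85.0),
        "TER",
    ])
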