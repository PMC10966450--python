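"""PDB input/output for two-chain protein complexes.

AlphaFold-Multimer-style complexes arrive as fixed-column PDB files with
per-residue pLDDT confidence scores stored in the B-factor column.  Parsing
reduces each complex to the four heavy-atom elements that make up the protein
main structure (C, N, O, S); hydrogens and heteroatoms are discarded.  The
resulting :class:`ComplexStructure` is the unit that flows through
preprocessing and tensorization.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

#: Heavy-atom elements retained after parsing, in channel order.
ELEMENTS = ("C", "N", "O", "S")


class StructureError(ValueError):
    """Raised for structurally invalid input (wrong chain count, bad records)."""


@dataclass(frozen=True)
class Atom:
    """A single heavy atom of a protein chain.

    ``plddt`` is the per-residue AlphaFold confidence in [0, 100], read from
    the PDB B-factor column.  ``is_ca`` marks the alpha carbon (PDB atom name
    ``CA``, remoteness indicator "alpha"), the atom used for interface
    distance calculations.
    """

    element: str
    chain_id: str
    residue_index: int
    residue_name: str
    coords: tuple[float, float, float]
    plddt: float
    is_ca: bool = False

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise StructureError(f"unsupported element {self.element!r}")
        if not 0.0 <= self.plddt <= 100.0:
            raise StructureError(f"pLDDT {self.plddt} outside [0, 100]")


@dataclass
class Chain:
    """Struct-of-arrays storage for one chain's heavy atoms."""

    chain_id: str
    element: np.ndarray        # (n,) unicode
    residue_index: np.ndarray  # (n,) int
    residue_name: np.ndarray   # (n,) unicode
    coords: np.ndarray         # (n, 3) float
    plddt: np.ndarray          # (n,) float
    is_ca: np.ndarray          # (n,) bool

    def __len__(self) -> int:
        return len(self.element)

    def atoms(self):
        for i in range(len(self)):
            yield Atom(
                element=str(self.element[i]),
                chain_id=self.chain_id,
                residue_index=int(self.residue_index[i]),
                residue_name=str(self.residue_name[i]),
                coords=tuple(float(x) for x in self.coords[i]),
                plddt=float(self.plddt[i]),
                is_ca=bool(self.is_ca[i]),
            )

    @property
    def ca_coords(self) -> np.ndarray:
        return self.coords[self.is_ca]

    @property
    def ca_residue_index(self) -> np.ndarray:
        return self.residue_index[self.is_ca]

    def residue_plddt(self) -> dict[int, float]:
        """Per-residue pLDDT: the CA value if present, else the first atom's.

        AlphaFold writes a constant B-factor per residue; the CA rule only
        matters if atoms of a residue disagree.
        """
        out: dict[int, float] = {}
        for i in range(len(self)):
            ri = int(self.residue_index[i])
            if ri not in out or self.is_ca[i]:
                out[ri] = float(self.plddt[i])
        return out

    def subset(self, mask: np.ndarray) -> "Chain":
        return Chain(
            chain_id=self.chain_id,
            element=self.element[mask],
            residue_index=self.residue_index[mask],
            residue_name=self.residue_name[mask],
            coords=self.coords[mask],
            plddt=self.plddt[mask],
            is_ca=self.is_ca[mask],
        )


@dataclass
class ComplexStructure:
    """A two-chain protein complex.

    Chain order is stable: the first chain maps onto the first channel block
    (channels C_A..S_A), the second onto the second (C_B..S_B).
    """

    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.chains) != 2:
            raise StructureError(
                f"a complex must have exactly two chains, got "
                f"{[c.chain_id for c in self.chains]}"
            )

    @property
    def chain_ids(self) -> tuple[str, str]:
        return (self.chains[0].chain_id, self.chains[1].chain_id)

    @property
    def n_atoms(self) -> int:
        return sum(len(c) for c in self.chains)

    def all_coords(self) -> np.ndarray:
        return np.concatenate([c.coords for c in self.chains], axis=0)

    def translate(self, shift) -> "ComplexStructure":
        shift = np.asarray(shift, dtype=float)
        chains = []
        for c in self.chains:
            chains.append(
                Chain(c.chain_id, c.element.copy(), c.residue_index.copy(),
                      c.residue_name.copy(), c.coords + shift, c.plddt.copy(),
                      c.is_ca.copy())
            )
        return ComplexStructure(chains)

    def transform(self, matrix, about) -> "ComplexStructure":
        """Apply a rotation ``matrix`` about the point ``about``."""
        matrix = np.asarray(matrix, dtype=float)
        about = np.asarray(about, dtype=float)
        chains = []
        for c in self.chains:
            coords = (c.coords - about) @ matrix.T + about
            chains.append(
                Chain(c.chain_id, c.element.copy(), c.residue_index.copy(),
                      c.residue_name.copy(), coords, c.plddt.copy(),
                      c.is_ca.copy())
            )
        return ComplexStructure(chains)


def _element_from_atom_name(name: str) -> str:
    name = name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def parse_structure(pdb_text: str) -> ComplexStructure:
    """Parse fixed-column PDB text into a :class:`ComplexStructure`.

    Hydrogens and HETATM records are dropped; elements outside {C, N, O, S}
    are dropped with a warning.  The B-factor column is exposed as pLDDT.
    Alternate locations other than '' / 'A' are discarded.  Exactly two
    chains must remain after filtering.
    """
    try:
        pdb = PDBFile.read(io.StringIO(pdb_text))
        arr = pdb.get_structure(model=1, altloc="first",
                                extra_fields=["b_factor"])
    except Exception as exc:  # biotite raises several types for bad records
        raise StructureError(f"could not parse PDB text: {exc}") from exc

    if arr.array_length() == 0:
        raise StructureError("no ATOM records found")

    arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise StructureError("no non-HETATM ATOM records found")

    elements = np.asarray(arr.element, dtype="U2")
    # Fall back to atom-name leading character where the element column is blank.
    blank = elements == ""
    if blank.any():
        names = np.asarray(arr.atom_name, dtype="U4")
        elements = elements.copy()
        elements[blank] = [_element_from_atom_name(n) for n in names[blank]]
    elements = np.char.upper(elements)

    keep_h = elements != "H"
    known = np.isin(elements, ELEMENTS)
    odd = keep_h & ~known
    if odd.any():
        dropped = sorted(set(elements[odd]))
        logger.warning("dropping %d atoms with elements outside C/N/O/S: %s",
                       int(odd.sum()), dropped)
    mask = keep_h & known
    arr = arr[mask]
    elements = elements[mask]
    if arr.array_length() == 0:
        raise StructureError("no heavy atoms left after element filtering")

    chain_ids = np.asarray(arr.chain_id, dtype="U4")
    unique_chains = list(dict.fromkeys(chain_ids))  # preserves file order
    if len(unique_chains) != 2:
        raise StructureError(
            f"a complex must have exactly two chains, found "
            f"{len(unique_chains)}: {unique_chains}"
        )

    plddt = np.asarray(arr.b_factor, dtype=float)
    if plddt.min() < 0.0 or plddt.max() > 100.0:
        raise StructureError(
            "B-factor column is not a pLDDT score (values outside [0, 100])"
        )

    chains = []
    atom_names = np.asarray(arr.atom_name, dtype="U4")
    for cid in unique_chains:
        sel = chain_ids == cid
        res_idx = np.asarray(arr.res_id[sel], dtype=int)
        chains.append(
            Chain(
                chain_id=str(cid),
                element=elements[sel],
                residue_index=res_idx,
                residue_name=np.asarray(arr.res_name[sel], dtype="U3"),
                coords=np.asarray(arr.coord[sel], dtype=float),
                plddt=plddt[sel],
                is_ca=atom_names[sel] == "CA",
            )
        )
    return ComplexStructure(chains)


def write_structure(s: ComplexStructure) -> str:
    """Serialize a complex as fixed-column PDB ATOM/TER records.

    pLDDT goes to the B-factor column (2 decimals), coordinates to the
    standard 3-decimal columns.
    """
    for c in s.chains:
        if len(c) == 0:
            raise StructureError(
                f"cannot serialize chain {c.chain_id!r} with no atoms"
            )

    n = s.n_atoms
    arr = struc.AtomArray(n)
    i = 0
    for c in s.chains:
        m = len(c)
        sl = slice(i, i + m)
        arr.coord[sl] = c.coords
        arr.chain_id[sl] = c.chain_id
        arr.res_id[sl] = c.residue_index
        arr.res_name[sl] = c.residue_name
        arr.element[sl] = c.element
        names = np.where(c.is_ca, "CA", c.element)
        arr.atom_name[sl] = names
        i += m
    arr.hetero[:] = False
    arr.set_annotation("b_factor", np.concatenate([c.plddt for c in s.chains]))
    arr.set_annotation("occupancy", np.ones(n))

    pdb = PDBFile()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pdb.set_structure(arr)
    buf = io.StringIO()
    pdb.write(buf)
    lines = [ln for ln in buf.getvalue().splitlines() if ln.strip()]
    # insert TER records at chain boundaries (biotite omits them)
    out, prev_chain = [], None
    for ln in lines:
        chain = ln[21] if ln.startswith("ATOM") else None
        if prev_chain is not None and chain != prev_chain:
            out.append("TER")
        out.append(ln)
        prev_chain = chain
    out.append("TER")
    out.append("END")
    return "\n".join(out) + "\n"
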