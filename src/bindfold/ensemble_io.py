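"""Conformational-ensemble I/O and named atom selections.

A :class:`StructureEnsemble` is the in-memory form of a multi-model PDB
trajectory: one ordered atom table shared by all frames plus an
``(n_frames, n_atoms, 3)`` coordinate array in Å.  Reading goes through
Biopython's PDB parser; writing emits fixed-column MODEL/ENDMDL records so a
round trip preserves coordinates to the format's 3-decimal precision.

Selections are ordered, unique index lists into the atom table.  The
selectors implemented here (``calpha``, ``c5prime``, ``backbone_sites``,
``polar_heavy``, per-residue side chains and phosphates) are the only atom
subsets the downstream analyses use: every distance criterion in the
pipeline operates on mass centers of these sets.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import atom_weights
from Bio.PDB import PDBParser

from .errors import (
    EmptyInputError,
    FormatError,
    LookupError_,
    SelectionError,
)

__all__ = [
    "Atom",
    "StructureEnsemble",
    "Selection",
    "read_ensemble",
    "write_ensemble",
    "select",
    "write_table",
    "read_table",
]

# Residue-name vocabularies.  Author numbering is preserved throughout; the
# nucleotide names cover both one-letter RNA and D-prefixed DNA conventions.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
NUCLEOTIDES = {
    "A", "C", "G", "U", "I",
    "DA", "DC", "DG", "DT", "DI", "DU",
    "RA", "RC", "RG", "RU",
}

PROTEIN_BACKBONE = {"N", "CA", "C", "O", "OXT"}
# Sugar + phosphate atoms of a nucleotide; everything else heavy is "base".
NUCLEIC_BACKBONE = {
    "P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'",
    "C3'", "O3'", "C2'", "O2'", "C1'",
}
PHOSPHATE_ATOMS = ("P", "OP1", "OP2")
POLAR_ELEMENTS = {"N", "O", "S"}

# Polar heavy atoms that carry at least one hydrogen in the standard residue
# templates (donor capability is decided from these names, never from explicit
# hydrogens, which are optional in the input).
_PROTEIN_DONORS = {
    "N",      # backbone amide (PRO excluded below)
    "OG", "OG1", "OH", "SG",
    "NZ", "NE", "NH1", "NH2", "ND1", "NE2", "ND2", "NE1",
}
_NUCLEIC_DONORS = {
    "O2'",                    # ribose 2'-OH
    "N1", "N2", "N3", "N4", "N6",  # base amino / imino nitrogens
    "O3'", "O5'",             # terminal hydroxyls (conservative inclusion)
}


def is_amino_acid(residue_name: str) -> bool:
    return residue_name.upper() in AMINO_ACIDS


def is_nucleotide(residue_name: str) -> bool:
    return residue_name.upper() in NUCLEOTIDES


def element_mass(element: str) -> float:
    """Standard atomic weight in Da for an element symbol."""
    key = element.capitalize()
    if key not in atom_weights:
        raise SelectionError(f"unknown element symbol {element!r}")
    return float(atom_weights[key])


def _guess_element(atom_name: str) -> str:
    """Element from a PDB atom label (first alphabetic character that is not
    a prime/digit; two-letter symbols are not needed for biomolecules here)."""
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise FormatError(f"cannot infer element for atom name {atom_name!r}")


@dataclass(frozen=True)
class Atom:
    """One row of the atom table, shared by every frame.

    ``residue_index`` keeps the author numbering from the input file;
    contiguous 0-based indices are derived where needed, never stored.
    """

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    mass: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise FormatError(
                f"atom {self.atom_name} of {self.residue_name} has mass "
                f"{self.mass} <= 0"
            )

    @property
    def is_polar_heavy(self) -> bool:
        return self.element in POLAR_ELEMENTS

    @property
    def site(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_index)

    def is_template_donor(self) -> bool:
        """Whether this polar heavy atom carries a hydrogen in the standard
        residue template (heavy-atom H-bond criterion)."""
        if not self.is_polar_heavy:
            return False
        name = self.atom_name.strip()
        if is_amino_acid(self.residue_name):
            if name == "N" and self.residue_name.upper() == "PRO":
                return False
            return name in _PROTEIN_DONORS
        if is_nucleotide(self.residue_name):
            res = self.residue_name.upper()
            if name == "O2'" and res.startswith("D"):
                return False  # deoxyribose has no 2'-OH
            # Base-specific imino/amino donors; names shared across bases are
            # accepted generically -- template tables at this granularity are
            # all the heavy-atom criterion needs.
            return name in _NUCLEIC_DONORS
        # Unknown residue class: treat any N/O/S as potential donor.
        return True


@dataclass
class Selection:
    """Named, ordered, unique atom-index list into an ensemble's atom table."""

    name: str
    atom_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.atom_indices, dtype=int)
        if idx.size and (np.any(np.diff(idx) <= 0)):
            raise SelectionError(f"selection {self.name!r} indices must be "
                                 "strictly increasing")
        self.atom_indices = idx

    def __len__(self) -> int:
        return int(self.atom_indices.size)


@dataclass
class StructureEnsemble:
    """Ordered frames over a fixed atom table.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å; ``times`` (ns) is
    optional and must be strictly increasing when present.
    """

    atoms: list[Atom]
    coords: np.ndarray
    times: np.ndarray | None = None
    name: str = "ensemble"
    _site_index: dict[tuple[str, int], list[int]] = field(
        default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None, :, :]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise FormatError(
                f"{self.coords.shape[1]} coordinates per frame for "
                f"{len(self.atoms)} atoms")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates in ensemble")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.n_frames,):
                raise FormatError("times length must equal frame count")
            if self.n_frames > 1 and np.any(np.diff(self.times) <= 0):
                raise FormatError("frame times must be strictly increasing")
        self._site_index = None

    # -- basic accessors -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residues(self) -> list[tuple[str, int, str]]:
        """(chain, residue_index, residue_name) in first-appearance order."""
        out: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            out.setdefault(a.site, a.residue_name)
        return [(c, r, n) for (c, r), n in out.items()]

    def site_atoms(self, chain: str, residue_index: int) -> list[int]:
        if self._site_index is None:
            idx: dict[tuple[str, int], list[int]] = {}
            for i, a in enumerate(self.atoms):
                idx.setdefault(a.site, []).append(i)
            self._site_index = idx
        key = (chain, residue_index)
        if key not in self._site_index:
            raise LookupError_(f"no residue {residue_index} in chain {chain}")
        return self._site_index[key]

    def residue_name(self, chain: str, residue_index: int) -> str:
        return self.atoms[self.site_atoms(chain, residue_index)[0]].residue_name

    def subset(self, selection: Selection, name: str | None = None
               ) -> "StructureEnsemble":
        """New ensemble restricted to the selected atoms (frames shared)."""
        atoms = [self.atoms[i] for i in selection.atom_indices]
        return StructureEnsemble(
            atoms=atoms,
            coords=self.coords[:, selection.atom_indices, :].copy(),
            times=None if self.times is None else self.times.copy(),
            name=name or f"{self.name}:{selection.name}",
        )

    def filter_chains(self, chains: Iterable[str], name: str | None = None
                      ) -> "StructureEnsemble":
        keep = {c for c in chains}
        idx = np.array([i for i, a in enumerate(self.atoms)
                        if a.chain_id in keep], dtype=int)
        if idx.size == 0:
            raise EmptyInputError(f"no atoms left after chain filter {sorted(keep)}")
        return self.subset(Selection("chains:" + ",".join(sorted(keep)), idx),
                           name=name)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def read_ensemble(path: str | Path,
                  chain_filter: set[str] | None = None,
                  stride: int = 1) -> StructureEnsemble:
    """Read a (multi-model) PDB file into a :class:`StructureEnsemble`.

    Frames follow MODEL order; the atom table is taken from the first model
    and every later model must present the same atoms in the same order,
    otherwise a :class:`FormatError` names the offending model.  A file
    without MODEL records is a single-frame ensemble.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise FormatError(f"{path}: no models found")

    def model_rows(model):
        rows = []
        for chain in model:
            for residue in chain:
                het, resseq, _icode = residue.id
                if het.strip():
                    continue  # skip HETATM/water records
                for atom in residue:
                    if atom.element == "H" or atom.get_name().startswith("H"):
                        continue  # hydrogens optional, analyses are heavy-atom
                    rows.append((chain.id, resseq, residue.resname.strip(),
                                 atom.get_name(), atom))
        return rows

    first = model_rows(models[0])
    if chain_filter is not None:
        first = [r for r in first if r[0] in chain_filter]
    if not first:
        raise EmptyInputError(
            f"{path}: empty atom set"
            + (f" after chain filter {sorted(chain_filter)}" if chain_filter else ""))

    key0 = [(c, r, rn, an) for c, r, rn, an, _ in first]
    atoms = []
    for c, r, rn, an, at in first:
        elem = (at.element or "").strip().upper() or _guess_element(an)
        atoms.append(Atom(chain_id=c, residue_index=int(r), residue_name=rn,
                          atom_name=an, element=elem, mass=element_mass(elem)))

    frames = []
    for m_i, model in enumerate(models):
        rows = model_rows(model)
        if chain_filter is not None:
            rows = [r for r in rows if r[0] in chain_filter]
        key = [(c, r, rn, an) for c, r, rn, an, _ in rows]
        if key != key0:
            raise FormatError(
                f"{path}: model {model.id + 1 if isinstance(model.id, int) else m_i + 1} "
                f"atom list differs from model 1 "
                f"({len(key)} vs {len(key0)} atoms)")
        frames.append(np.array([at.coord for *_, at in rows], dtype=float))

    coords = np.stack(frames)[::stride]
    return StructureEnsemble(atoms=atoms, coords=coords, name=path.stem)


def write_ensemble(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write a multi-model PDB (fixed columns, MODEL/ENDMDL per frame)."""
    path = Path(path)
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            serial = 1
            prev_chain = None
            for a, (x, y, z) in zip(ensemble.atoms, ensemble.coords[f]):
                if prev_chain is not None and a.chain_id != prev_chain:
                    fh.write("TER\n")
                prev_chain = a.chain_id
                name = a.atom_name
                # PDB column 13-16 convention: 1-letter elements start col 14
                name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
                fh.write(
                    "ATOM  {serial:5d} {name} {res:>3s} {chain}{resi:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                    "{elem:>2s}\n".format(
                        serial=serial, name=name_field, res=a.residue_name[:3],
                        chain=a.chain_id[:1], resi=a.residue_index,
                        x=x, y=y, z=z, occ=1.0, b=0.0, elem=a.element[:2]))
                serial += 1
            fh.write("TER\nENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def _sidechain_names(ensemble: StructureEnsemble, chain: str, resi: int
                     ) -> list[int]:
    """Side-chain heavy atoms of one residue.

    Amino acids: heavy atoms outside the N/CA/C/O backbone (Cβ onward); Gly,
    having none, contributes its Cα so the mass-center criteria always have a
    site.  Nucleotides: base heavy atoms (everything outside the
    sugar-phosphate backbone).
    """
    idx = ensemble.site_atoms(chain, resi)
    resname = ensemble.atoms[idx[0]].residue_name
    if is_amino_acid(resname):
        side = [i for i in idx
                if ensemble.atoms[i].atom_name not in PROTEIN_BACKBONE]
        if not side:  # GLY (or CA-only coarse model)
            side = [i for i in idx if ensemble.atoms[i].atom_name == "CA"]
    elif is_nucleotide(resname):
        side = [i for i in idx
                if ensemble.atoms[i].atom_name not in NUCLEIC_BACKBONE]
    else:
        raise SelectionError(
            f"unknown residue template {resname!r} at {chain}:{resi}")
    if not side:
        raise SelectionError(
            f"empty side-chain selection for {resname} {chain}:{resi}")
    return side


def select(ensemble: StructureEnsemble, kind: str,
           residue: tuple[str, int] | None = None) -> Selection:
    """Named atom selection.

    ``kind`` is one of ``calpha``, ``c5prime``, ``backbone_sites`` (Cα for
    protein + C5' for nucleic acids, one site per residue in chain-then-
    residue order), ``polar_heavy``, ``sidechain`` (requires ``residue``),
    ``phosphate`` (requires ``residue``; {P, OP1, OP2}).
    """
    idx: list[int] = []
    if kind == "calpha":
        idx = [i for i, a in enumerate(ensemble.atoms)
               if a.atom_name == "CA" and is_amino_acid(a.residue_name)]
    elif kind == "c5prime":
        idx = [i for i, a in enumerate(ensemble.atoms)
               if a.atom_name == "C5'" and is_nucleotide(a.residue_name)]
    elif kind == "backbone_sites":
        idx = [i for i, a in enumerate(ensemble.atoms)
               if (a.atom_name == "CA" and is_amino_acid(a.residue_name))
               or (a.atom_name == "C5'" and is_nucleotide(a.residue_name))]
    elif kind == "polar_heavy":
        idx = [i for i, a in enumerate(ensemble.atoms) if a.is_polar_heavy]
    elif kind == "sidechain":
        if residue is None:
            raise SelectionError("sidechain selector needs a residue")
        idx = _sidechain_names(ensemble, *residue)
    elif kind == "phosphate":
        if residue is None:
            raise SelectionError("phosphate selector needs a residue")
        site = ensemble.site_atoms(*residue)
        idx = [i for i in site
               if ensemble.atoms[i].atom_name in PHOSPHATE_ATOMS]
    else:
        raise SelectionError(f"unknown selector kind {kind!r}")
    if not idx:
        raise SelectionError(f"selector {kind!r} matched no atoms")
    label = kind if residue is None else f"{kind}:{residue[0]}:{residue[1]}"
    return Selection(label, np.array(sorted(idx), dtype=int))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(records, path: str | Path) -> None:
    """Write any tabular result as TSV (header row, floats at 6 sig. digits)."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if df.empty:
        raise EmptyInputError("refusing to write an empty table")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
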