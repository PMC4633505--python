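"""Interaction classification and native-contact sets.

Four residue-level interaction types are assigned from mass-center
distances, all with strict ("closer than") thresholds:

* hydrophobic  — side-chain mass centers closer than 6.5 Å;
* electrostatic — positively charged group (Arg/Lys/His) mass center closer
  than 11 Å to a nucleotide's phosphate-group mass center;
* hydrogen bond — two polar heavy atoms, at least one a template donor,
  closer than 3.5 Å (heavy-atom criterion, hydrogens not required);
* native — non-adjacent residue/nucleotide side-chain centers closer than
  7.5 Å; the set of native contacts that persist in at least half of the
  folded-state frames defines Qf/Qb and the Φ-value counts downstream.

Populations over an ensemble use the 30 % stability cut (strictly greater).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import BindfoldError, EmptyInputError, LookupError_
from .ensemble_io import (
    PHOSPHATE_ATOMS,
    Selection,
    StructureEnsemble,
    is_amino_acid,
    is_nucleotide,
    select,
)
from .geometry import mass_center_coords

__all__ = [
    "SitePair",
    "ContactRecord",
    "NativeContactSet",
    "HYDROPHOBIC_CUTOFF",
    "ELECTROSTATIC_CUTOFF",
    "HBOND_CUTOFF",
    "NATIVE_CUTOFF",
    "POPULATION_CUT",
    "sidechain_centers",
    "classify_hydrophobic",
    "classify_electrostatic",
    "classify_hbond",
    "native_contact_set",
    "contact_population",
    "scan_contacts",
]

HYDROPHOBIC_CUTOFF = 6.5     # Å, side-chain mass centers
ELECTROSTATIC_CUTOFF = 11.0  # Å, charged group to phosphate group
HBOND_CUTOFF = 3.5           # Å, polar heavy atoms
NATIVE_CUTOFF = 7.5          # Å, side-chain mass centers
POPULATION_CUT = 0.30        # stable contact: population strictly above

POSITIVE_RESIDUES = ("ARG", "LYS", "HIS")
# Charged-moiety atoms; when absent (coarse models) the side-chain center
# stands in for the charged-group center.
_CHARGE_GROUP = {
    "ARG": ("NE", "CZ", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "CE1", "NE2"),
}


@dataclass(frozen=True, order=True)
class SitePair:
    """Canonically ordered residue-level pair (a < b lexicographically)."""

    site_a: tuple[str, int]
    site_b: tuple[str, int]

    def __post_init__(self):
        if self.site_a == self.site_b:
            raise BindfoldError("a site cannot contact itself")
        if self.site_a > self.site_b:
            a, b = self.site_a, self.site_b
            object.__setattr__(self, "site_a", b)
            object.__setattr__(self, "site_b", a)

    @property
    def interchain(self) -> bool:
        return self.site_a[0] != self.site_b[0]

    def involves(self, site: tuple[str, int]) -> bool:
        return site == self.site_a or site == self.site_b


@dataclass
class ContactRecord:
    pair: SitePair
    kind: str  # hydrophobic | electrostatic | hbond | native
    population: float
    detail: str = ""

    def __post_init__(self):
        if not 0.0 <= self.population <= 1.0:
            raise BindfoldError(f"population {self.population} outside [0,1]")

    @property
    def stable(self) -> bool:
        return self.population > POPULATION_CUT


@dataclass
class NativeContactSet:
    """Stable folded-state contacts, partitioned for Qf/Qb.

    ``binding_groups = (receptor_chains, ligand_chains)`` optionally
    redefines the Qf/Qb partition at the molecule level: ``inter`` is then
    the binding contacts crossing the group boundary, ``intra`` the
    tertiary contacts *within the ligand group* (the folding observables
    concern the ligand; receptor-internal contacts belong to neither
    subset and are exposed as ``receptor_internal``).  Without groups the
    partition follows the raw chain identity.
    """

    contacts: frozenset[SitePair]
    source: str = ""
    binding_groups: tuple[frozenset[str], frozenset[str]] | None = None

    def _group_of(self, chain: str) -> int:
        g0, g1 = self.binding_groups
        if chain in g0:
            return 0
        if chain in g1:
            return 1
        raise BindfoldError(f"chain {chain!r} not covered by binding groups")

    @property
    def inter_chain_subset(self) -> frozenset[SitePair]:
        if self.binding_groups is None:
            return frozenset(p for p in self.contacts if p.interchain)
        return frozenset(
            p for p in self.contacts
            if self._group_of(p.site_a[0]) != self._group_of(p.site_b[0]))

    @property
    def intra_chain_subset(self) -> frozenset[SitePair]:
        if self.binding_groups is None:
            return frozenset(p for p in self.contacts if not p.interchain)
        return frozenset(
            p for p in self.contacts
            if self._group_of(p.site_a[0]) == self._group_of(p.site_b[0]) == 1)

    @property
    def receptor_internal(self) -> frozenset[SitePair]:
        if self.binding_groups is None:
            return frozenset()
        return frozenset(
            p for p in self.contacts
            if self._group_of(p.site_a[0]) == self._group_of(p.site_b[0]) == 0)

    def scoped(self, scope: str) -> frozenset[SitePair]:
        if scope == "inter":
            return self.inter_chain_subset
        if scope == "intra":
            return self.intra_chain_subset
        if scope == "all":
            return self.contacts
        raise BindfoldError(f"unknown scope {scope!r}")

    def pairs_of(self, site: tuple[str, int]) -> list[SitePair]:
        return [p for p in self.contacts if p.involves(site)]

    def to_json_dict(self) -> dict:
        return {
            "source": self.source,
            "binding_groups": (None if self.binding_groups is None else
                               [sorted(g) for g in self.binding_groups]),
            "contacts": sorted(
                [[list(p.site_a), list(p.site_b)] for p in self.contacts]),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "NativeContactSet":
        pairs = frozenset(
            SitePair((a[0], int(a[1])), (b[0], int(b[1])))
            for a, b in d["contacts"])
        groups = d.get("binding_groups")
        return cls(pairs, source=d.get("source", ""),
                   binding_groups=None if groups is None else
                   (frozenset(groups[0]), frozenset(groups[1])))


# ---------------------------------------------------------------------------
# Per-frame geometry caches
# ---------------------------------------------------------------------------

def sidechain_centers(ensemble: StructureEnsemble
                      ) -> dict[tuple[str, int], np.ndarray]:
    """Side-chain mass center per residue site, all frames: (n_frames, 3)."""
    masses = ensemble.masses
    out = {}
    for chain, resi, _name in ensemble.residues():
        sel = select(ensemble, "sidechain", residue=(chain, resi))
        idx = sel.atom_indices
        out[(chain, resi)] = mass_center_coords(
            ensemble.coords[:, idx, :], masses[idx])
    return out


def _charge_center(ensemble: StructureEnsemble, site: tuple[str, int]
                   ) -> np.ndarray:
    idx = ensemble.site_atoms(*site)
    resname = ensemble.atoms[idx[0]].residue_name.upper()
    group = _CHARGE_GROUP.get(resname, ())
    chosen = [i for i in idx if ensemble.atoms[i].atom_name in group]
    if not chosen:  # coarse model: side-chain center stands in
        chosen = list(select(ensemble, "sidechain", residue=site).atom_indices)
    masses = ensemble.masses[chosen]
    return mass_center_coords(ensemble.coords[:, chosen, :], masses)


def _phosphate_center(ensemble: StructureEnsemble, site: tuple[str, int]
                      ) -> np.ndarray | None:
    idx = ensemble.site_atoms(*site)
    chosen = [i for i in idx
              if ensemble.atoms[i].atom_name in PHOSPHATE_ATOMS]
    if not chosen:
        return None  # 5'-terminal nucleotide without a phosphate
    masses = ensemble.masses[chosen]
    return mass_center_coords(ensemble.coords[:, chosen, :], masses)


# ---------------------------------------------------------------------------
# Classifiers (single frame)
# ---------------------------------------------------------------------------

def classify_hydrophobic(ensemble: StructureEnsemble,
                         res_a: tuple[str, int], res_b: tuple[str, int],
                         frame: int,
                         cutoff: float = HYDROPHOBIC_CUTOFF) -> bool:
    """Side-chain mass centers strictly closer than the 6.5 Å cutoff."""
    ca = _site_center_frame(ensemble, res_a, frame)
    cb = _site_center_frame(ensemble, res_b, frame)
    return bool(np.linalg.norm(ca - cb) < cutoff)


def _site_center_frame(ensemble, site, frame):
    sel = select(ensemble, "sidechain", residue=site)
    idx = sel.atom_indices
    return mass_center_coords(ensemble.coords[frame, idx, :],
                              ensemble.masses[idx])


def classify_electrostatic(ensemble: StructureEnsemble,
                           charged_residue: tuple[str, int],
                           nucleotide: tuple[str, int],
                           frame: int,
                           cutoff: float = ELECTROSTATIC_CUTOFF) -> bool:
    """Positive-group center to phosphate-group center strictly < 11 Å.

    Raises if the residue is not Arg/Lys/His; a phosphate-less 5'-terminal
    nucleotide yields ``False`` with a warning (no electrostatic site).
    """
    resname = ensemble.residue_name(*charged_residue).upper()
    if resname not in POSITIVE_RESIDUES:
        raise BindfoldError(
            f"{resname} is not a positively charged residue "
            f"(expected one of {POSITIVE_RESIDUES})")
    if not is_nucleotide(ensemble.residue_name(*nucleotide)):
        raise BindfoldError(f"{nucleotide} is not a nucleotide")
    pc = _phosphate_center(ensemble, nucleotide)
    if pc is None:
        warnings.warn(
            f"nucleotide {nucleotide} has no phosphate atoms "
            "(5'-terminus): no electrostatic site", stacklevel=2)
        return False
    cc = _charge_center(ensemble, charged_residue)
    return bool(np.linalg.norm(cc[frame] - pc[frame]) < cutoff)


def classify_hbond(ensemble: StructureEnsemble, frame: int,
                   cutoff: float = HBOND_CUTOFF,
                   interchain_only: bool = False) -> list[dict]:
    """All inter-residue polar-heavy pairs < 3.5 Å with a donor on either side.

    Returns one record per atom pair with site and atom detail; intra-residue
    pairs are excluded.
    """
    atoms = ensemble.atoms
    polar = [i for i, a in enumerate(atoms) if a.is_polar_heavy]
    if not polar:
        return []  # nothing polar, nothing to report
    coords = ensemble.coords[frame, polar, :]
    donors = np.array([atoms[i].is_template_donor() for i in polar])
    sites = [atoms[i].site for i in polar]

    from scipy.spatial import cKDTree
    tree = cKDTree(coords)
    out = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        if sites[i] == sites[j]:
            continue
        if interchain_only and sites[i][0] == sites[j][0]:
            continue
        if not (donors[i] or donors[j]):
            continue
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        if dist >= cutoff:  # strict inequality at the boundary
            continue
        ai, aj = atoms[polar[i]], atoms[polar[j]]
        pair = SitePair(ai.site, aj.site)
        out.append({
            "pair": pair,
            "atom_a": ai.atom_name if ai.site == pair.site_a else aj.atom_name,
            "atom_b": aj.atom_name if ai.site == pair.site_a else ai.atom_name,
            "distance_A": dist,
        })
    return out


# ---------------------------------------------------------------------------
# Native contacts & populations
# ---------------------------------------------------------------------------

def _chain_residue_positions(ensemble: StructureEnsemble
                             ) -> dict[tuple[str, int], int]:
    """0-based contiguous position of each residue within its chain."""
    pos, counters = {}, {}
    for chain, resi, _ in ensemble.residues():
        counters.setdefault(chain, 0)
        pos[(chain, resi)] = counters[chain]
        counters[chain] += 1
    return pos


def native_contact_set(reference_ensemble: StructureEnsemble,
                       stability_threshold: float = 0.5,
                       cutoff: float = NATIVE_CUTOFF,
                       binding_groups: tuple[Iterable[str], Iterable[str]] | None = None,
                       ) -> NativeContactSet:
    """Stable native contacts of a folded-state reference ensemble.

    A pair is native when its side-chain mass-center distance is strictly
    below 7.5 Å in at least ``stability_threshold`` of the frames.  Sequence
    neighbours (|i - j| < 2 within a chain, contiguous numbering) are never
    native; inter-chain pairs are never sequence-excluded.
    """
    centers = sidechain_centers(reference_ensemble)
    sites = list(centers)
    pos = _chain_residue_positions(reference_ensemble)
    n_frames = reference_ensemble.n_frames
    arr = np.stack([centers[s] for s in sites])  # (n_sites, n_frames, 3)

    found = set()
    for i in range(len(sites)):
        d = np.linalg.norm(arr[i + 1:] - arr[i], axis=2)  # (n_rest, n_frames)
        frac = (d < cutoff).sum(axis=1) / n_frames
        for off in np.nonzero(frac >= stability_threshold)[0]:
            j = i + 1 + off
            a, b = sites[i], sites[j]
            if a[0] == b[0] and abs(pos[a] - pos[b]) < 2:
                continue
            found.add(SitePair(a, b))
    if not found:
        warnings.warn("native contact set is empty", stacklevel=2)
    groups = (None if binding_groups is None else
              (frozenset(binding_groups[0]), frozenset(binding_groups[1])))
    return NativeContactSet(frozenset(found),
                            source=reference_ensemble.name,
                            binding_groups=groups)


def contact_population(ensemble: StructureEnsemble,
                       classifier: Callable[[StructureEnsemble, int], bool],
                       pair: SitePair, kind: str = "custom") -> ContactRecord:
    """Fraction of frames in which ``classifier(ensemble, frame)`` holds."""
    if ensemble.n_frames == 0:
        raise EmptyInputError("empty ensemble")
    hits = sum(bool(classifier(ensemble, f)) for f in range(ensemble.n_frames))
    return ContactRecord(pair, kind, hits / ensemble.n_frames)


def scan_contacts(ensemble: StructureEnsemble,
                  kinds: Sequence[str] = ("hydrophobic", "electrostatic", "hbond"),
                  interchain_only: bool = True,
                  min_population: float = 0.0) -> list[ContactRecord]:
    """Ensemble-wide population scan over residue pairs, vectorised per type.

    The workhorse behind the interaction-histogram analysis: every
    inter-chain pair is tested in every frame and records at or above
    ``min_population`` are returned (use 0.30 for the stable-only view).
    """
    n_frames = ensemble.n_frames
    records: list[ContactRecord] = []
    sites = ensemble.residues()

    if "hydrophobic" in kinds or "native" in kinds:
        centers = sidechain_centers(ensemble)
        keys = list(centers)
        arr = np.stack([centers[s] for s in keys])
        pos = _chain_residue_positions(ensemble)
        for i in range(len(keys)):
            d = np.linalg.norm(arr[i + 1:] - arr[i], axis=2)
            for kind, cutoff in (("hydrophobic", HYDROPHOBIC_CUTOFF),
                                 ("native", NATIVE_CUTOFF)):
                if kind not in kinds:
                    continue
                pops = (d < cutoff).sum(axis=1) / n_frames
                for off in np.nonzero(pops >= max(min_population, 1e-12))[0]:
                    j = i + 1 + off
                    a, b = keys[i], keys[j]
                    if a[0] == b[0] and abs(pos[a] - pos[b]) < 2:
                        continue
                    if interchain_only and a[0] == b[0]:
                        continue
                    records.append(ContactRecord(SitePair(a, b), kind,
                                                 float(pops[off])))

    if "electrostatic" in kinds:
        charged = [(c, r) for c, r, n in sites
                   if n.upper() in POSITIVE_RESIDUES]
        nucs = [(c, r) for c, r, n in sites if is_nucleotide(n)]
        for cr in charged:
            cc = _charge_center(ensemble, cr)
            for nt in nucs:
                pc = _phosphate_center(ensemble, nt)
                if pc is None:
                    continue
                d = np.linalg.norm(cc - pc, axis=1)
                popn = float((d < ELECTROSTATIC_CUTOFF).sum() / n_frames)
                if popn >= max(min_population, 1e-12):
                    records.append(
                        ContactRecord(SitePair(cr, nt), "electrostatic", popn))

    if "hbond" in kinds:
        counts: dict[tuple, list] = {}
        for f in range(n_frames):
            for rec in classify_hbond(ensemble, f,
                                      interchain_only=interchain_only):
                key = (rec["pair"], rec["atom_a"], rec["atom_b"])
                counts.setdefault(key, []).append(f)
        for (pair, aa, ab), frames in sorted(
                counts.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])):
            popn = len(frames) / n_frames
            if popn >= max(min_population, 1e-12):
                records.append(ContactRecord(pair, "hbond", popn,
                                             detail=f"{aa}-{ab}"))
    return records


def records_to_frame(records: list[ContactRecord]):
    import pandas as pd
    return pd.DataFrame([
        {
            "chain_a": r.pair.site_a[0], "res_a": r.pair.site_a[1],
            "chain_b": r.pair.site_b[0], "res_b": r.pair.site_b[1],
            "kind": r.kind, "population": r.population,
            "stable": r.stable, "detail": r.detail,
        } for r in records])
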