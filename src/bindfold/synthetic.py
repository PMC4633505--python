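"""Synthetic conformational ensembles with known ground truth.

Every downstream stage is exercised on fixtures built here: an idealized
duplex-plus-helix complex (a DNA strand and an RNA strand on a common
helical curve packed against an α-helical pseudo-protein), unfolding
trajectories with exponential contact survival, Boltzmann-sigmoid committor
series, and apo/bound ensemble pairs with either induced-fit or
conformational-selection structure.

Resolution is deliberately coarse: one backbone pseudo-atom per residue
(Cα or P/C5') plus one side-chain/base centroid, because every analysis
criterion in the pipeline operates on mass centers of exactly these sets.
There is no physics here -- no sterics, no energetics -- only geometry with
planted, recoverable statistical structure.

Unfolding realization.  Independent per-contact exponential breaking cannot
be realized geometrically when contacts share a residue, so breaking is
generated at the residue level: each residue draws an escape time from an
exponential whose rate is chosen per molecular group such that a contact
(which breaks when either partner escapes, i.e. at the minimum of two
exponentials) has exactly the requested class lifetime -- tau_qb for
binding (protein-nucleic) contacts, tau_qf for tertiary (intra-hybrid)
contacts.  An escaped residue jumps 17 + U(0, 8) Å along its own random
direction and keeps drifting outward with time constant tau_rg, which
drives the radius of gyration up; the Rg relaxation is therefore only
approximately single-exponential (effective time constant >= tau_rg),
which preserves the tau_qb < tau_qf < tau_rg ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .contacts import (
    ELECTROSTATIC_CUTOFF,
    HYDROPHOBIC_CUTOFF,
    NATIVE_CUTOFF,
    NativeContactSet,
    SitePair,
)
from .ensemble_io import Atom, StructureEnsemble, element_mass, is_nucleotide
from .errors import ConfigError
from .kinetics import TimeSeries

__all__ = [
    "GeneratorSpec",
    "gen_complex",
    "gen_unfolding",
    "gen_committor",
    "gen_phi_ensembles",
    "gen_mechanism_pair",
]

PROTEIN_CHAIN, DNA_CHAIN, RNA_CHAIN = "P", "D", "R"

# Helix geometry constants: plumbing, not physics.  The duplex uses a
# 3.6 Å rise / 34° twist so that cross-strand neighbour base contacts sit
# comfortably inside the 7.5 Å native cutoff while |i-j| = 2 pairs sit
# comfortably outside it (margins ~0.5 Å, several noise SDs at the default
# jitter).
_DUPLEX_RISE = 3.6
_DUPLEX_TWIST = np.deg2rad(34.0)
_BACKBONE_R = 9.3   # P radius
_C5P_R = 8.0        # C5' radius
_BASE_R = 3.0       # base-centroid radius
_PAIR_OFFSET = np.deg2rad(140.0)  # RNA base angular offset from its DNA mate
# The pseudo-helix twist/rise are chosen so that no planted pair distance
# falls close to any classification cutoff (all margins >= 0.08 Å; scanned
# over the full pair census), keeping the construction census sharp.
_HELIX_RISE = 1.7
_HELIX_TWIST = np.deg2rad(110.0)
_HELIX_R = 2.3
_HELIX_AXIS_X = 9.5  # distance of the protein helix axis from the duplex axis

# 38-residue bridge-helix-like sequence: hydrophobic core with basic
# residues on the duplex-facing stretch and one glycine for selector edge
# cases.
_PROTEIN_SEQ = (
    "THR GLN GLU PHE ARG ALA LEU GLY LYS ALA LEU ARG VAL ALA LEU LYS ALA "
    "ILE ARG GLU LEU VAL LYS ALA LEU ARG ALA ILE LEU LYS ALA VAL GLU ARG "
    "ALA LEU GLU ALA"
).split()
_PROTEIN_START = 809  # author numbering of the first helix residue

_DNA_SEQ = "DC DT DA DC DC DT DC DT DC DC DT DC".split()   # 12 nt
_RNA_SEQ = "A U G G C G C G G A G".split()                   # 11 nt


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs of the generators; a pure function of this spec + nothing.

    ``tau_map`` holds the class lifetimes in ns (defaults are the bound-
    hybrid half-times the pipeline is designed around: unbinding 1.21,
    tertiary unfolding 1.71, extension 4.24, with tau_qb < tau_qf < tau_rg).
    ``deformation`` is (radius Å, magnitude Å) for the induced-fit scenario;
    ``n_conformers`` sizes the conformational-selection apo pool.
    """

    seed: int = 0
    n_frames: int = 200
    noise_sigma: float = 0.3
    scenario: str = "folded"  # folded | unfold | IF | CS
    tau_map: dict = field(default_factory=lambda: {
        "qb": 1.21, "qf": 1.71, "rg": 4.24})
    t_max: float = 10.0
    phi_star: dict | None = None
    deformation: tuple[float, float] = (12.0, 3.0)
    n_conformers: int = 5
    cs_spread: float = 2.5       # Å, conformer-to-conformer displacement
    tau_ts: float = 5.0          # ns, committor sigmoid midpoint
    tau_trans: float = 0.4       # ns, committor sigmoid width parameter
    committor_noise: float = 0.05
    unbreakable_core: tuple = ()  # residue sites that never escape

    def validate(self):
        for k, v in self.tau_map.items():
            if v <= 0:
                raise ConfigError(f"tau_map[{k!r}] must be > 0, got {v}")
        if self.noise_sigma < 0 or self.deformation[1] < 0:
            raise ConfigError("noise and deformation magnitude must be >= 0")
        if self.phi_star is not None:
            bad = {k: v for k, v in self.phi_star.items() if not 0 <= v <= 1}
            if bad:
                raise ConfigError(f"phi_star outside [0,1]: {bad}")


# ---------------------------------------------------------------------------
# Ideal geometry
# ---------------------------------------------------------------------------

def _atom(chain, resi, resname, name, element):
    return Atom(chain_id=chain, residue_index=resi, residue_name=resname,
                atom_name=name, element=element, mass=element_mass(element))


def _ideal_complex() -> tuple[list[Atom], np.ndarray]:
    """Noise-free atom table + coordinates of the three-chain complex."""
    atoms: list[Atom] = []
    xyz: list[np.ndarray] = []

    def add(atom, pos):
        atoms.append(atom)
        xyz.append(np.asarray(pos, dtype=float))

    n_dna = len(_DNA_SEQ)
    # DNA strand: 5'->3' down the duplex axis (z).  The 5'-terminal
    # nucleotide carries no phosphate (explicit terminal handling).
    for i, resname in enumerate(_DNA_SEQ):
        ang = i * _DUPLEX_TWIST
        z = i * _DUPLEX_RISE
        resi = i + 1
        if i > 0:
            add(_atom(DNA_CHAIN, resi, resname, "P", "P"),
                (_BACKBONE_R * np.cos(ang), _BACKBONE_R * np.sin(ang), z))
        add(_atom(DNA_CHAIN, resi, resname, "C5'", "C"),
            (_C5P_R * np.cos(ang + 0.12), _C5P_R * np.sin(ang + 0.12), z))
        add(_atom(DNA_CHAIN, resi, resname, "N1", "N"),
            (_BASE_R * np.cos(ang), _BASE_R * np.sin(ang), z))

    # RNA strand, antiparallel: base i pairs with DNA base i (same z),
    # rotated by the pairing offset about the axis.
    for i, resname in enumerate(_RNA_SEQ):
        ang = i * _DUPLEX_TWIST + _PAIR_OFFSET
        z = i * _DUPLEX_RISE
        resi = i + 1
        if i > 0:
            add(_atom(RNA_CHAIN, resi, resname, "P", "P"),
                (_BACKBONE_R * np.cos(ang), _BACKBONE_R * np.sin(ang), z))
        add(_atom(RNA_CHAIN, resi, resname, "C5'", "C"),
            (_C5P_R * np.cos(ang + 0.12), _C5P_R * np.sin(ang + 0.12), z))
        add(_atom(RNA_CHAIN, resi, resname, "N1", "N"),
            (_BASE_R * np.cos(ang), _BASE_R * np.sin(ang), z))

    # Protein helix along z at a lateral offset, centred on the duplex span.
    n_res = len(_PROTEIN_SEQ)
    z0 = 0.5 * (n_dna - 1) * _DUPLEX_RISE - 0.5 * (n_res - 1) * _HELIX_RISE
    for i, resname in enumerate(_PROTEIN_SEQ):
        ang = i * _HELIX_TWIST
        z = z0 + i * _HELIX_RISE
        resi = _PROTEIN_START + i
        ca = np.array([_HELIX_AXIS_X + _HELIX_R * np.cos(ang),
                       _HELIX_R * np.sin(ang), z])
        add(_atom(PROTEIN_CHAIN, resi, resname, "CA", "C"), ca)
        if resname != "GLY":
            # side-chain centroid 1.6 Å further out from the helix axis
            out = np.array([np.cos(ang), np.sin(ang), 0.0])
            add(_atom(PROTEIN_CHAIN, resi, resname, "CB", "C"), ca + 1.6 * out)

    return atoms, np.stack(xyz)


def _planted_contacts(atoms: list[Atom], xyz: np.ndarray) -> dict:
    """Construction-side contact census on the ideal geometry.

    Independent of the contacts module: plain loops over mass centers,
    the oracle the pipeline's classifiers are tested against.
    """
    sites: dict[tuple[str, int], dict] = {}
    order: dict[str, list[int]] = {}
    for i, a in enumerate(atoms):
        s = sites.setdefault(a.site, {"name": a.residue_name, "side": [],
                                      "phos": [], "mass_side": [],
                                      "mass_phos": []})
        if a.atom_name in ("N1", "CB") or (
                a.atom_name == "CA" and a.residue_name == "GLY"):
            s["side"].append(xyz[i])
            s["mass_side"].append(a.mass)
        if a.atom_name in ("P", "OP1", "OP2"):
            s["phos"].append(xyz[i])
            s["mass_phos"].append(a.mass)
        order.setdefault(a.chain_id, [])
        if a.residue_index not in order[a.chain_id]:
            order[a.chain_id].append(a.residue_index)

    def center(vs, ms):
        vs, ms = np.asarray(vs), np.asarray(ms)
        return (vs * ms[:, None]).sum(axis=0) / ms.sum()

    keys = sorted(sites)
    native, hydrophobic, electrostatic = set(), set(), set()
    for x in range(len(keys)):
        for y in range(x + 1, len(keys)):
            a, b = keys[x], keys[y]
            if a[0] == b[0]:
                pa = order[a[0]].index(a[1])
                pb = order[b[0]].index(b[1])
                if abs(pa - pb) < 2:
                    continue
            d = np.linalg.norm(center(sites[a]["side"], sites[a]["mass_side"])
                               - center(sites[b]["side"], sites[b]["mass_side"]))
            if d < NATIVE_CUTOFF:
                native.add((a, b))
            if d < HYDROPHOBIC_CUTOFF:
                hydrophobic.add((a, b))
    positives = {k for k, s in sites.items()
                 if s["name"] in ("ARG", "LYS", "HIS")}
    nucs = {k for k, s in sites.items() if is_nucleotide(s["name"])}
    for p in sorted(positives):
        cp = center(sites[p]["side"], sites[p]["mass_side"])
        for n in sorted(nucs):
            if not sites[n]["phos"]:
                continue
            d = np.linalg.norm(
                cp - center(sites[n]["phos"], sites[n]["mass_phos"]))
            if d < ELECTROSTATIC_CUTOFF:
                electrostatic.add(tuple(sorted((p, n))))

    inter = {pr for pr in native
             if (pr[0][0] == PROTEIN_CHAIN) != (pr[1][0] == PROTEIN_CHAIN)}
    intra_ligand = {pr for pr in native
                    if pr[0][0] != PROTEIN_CHAIN and pr[1][0] != PROTEIN_CHAIN}
    return {
        "native": native,
        "native_inter_group": inter,
        "native_intra_group": intra_ligand,
        "hydrophobic": hydrophobic,
        "electrostatic": electrostatic,
    }


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_complex(spec: GeneratorSpec, chains: str = "PDR"
                ) -> tuple[StructureEnsemble, dict]:
    """Folded-state ensemble of the duplex+helix complex.

    Frames are the ideal geometry plus isotropic Gaussian jitter of
    ``noise_sigma`` Å per coordinate; byte-identical for identical seeds.
    Returns the ensemble and a ground-truth dict with the planted contact
    census of the ideal geometry.
    """
    spec.validate()
    atoms, base = _ideal_complex()
    keep = [i for i, a in enumerate(atoms) if a.chain_id in set(chains)]
    atoms = [atoms[i] for i in keep]
    base = base[keep]
    rng = np.random.default_rng(spec.seed)
    coords = base[None, :, :] + rng.normal(
        0.0, spec.noise_sigma, size=(spec.n_frames, len(atoms), 3))
    ens = StructureEnsemble(atoms=atoms, coords=coords,
                            name=f"synthetic-complex-{spec.seed}")
    truth = _planted_contacts(atoms, base)
    truth["ideal_coords"] = base
    return ens, truth


def _escape_rates(native_set: NativeContactSet, sites, tau_map) -> dict:
    """Per-site escape rates so contact lifetimes hit the class taus.

    A contact breaks at min(escape_i, escape_j) ~ Exp(rate_i + rate_j).
    Nucleic sites share one rate a_n with 2 a_n = 1/tau_qf; protein sites
    get a_p = 1/tau_qb - a_n (requires tau_qb < 2 tau_qf).
    """
    tau_qf, tau_qb = tau_map["qf"], tau_map.get("qb")
    a_n = 1.0 / (2.0 * tau_qf)
    rates = {}
    has_protein = any(c == PROTEIN_CHAIN for c, _ in sites)
    if has_protein:
        if tau_qb is None:
            raise ConfigError("tau_map needs 'qb' for a bound complex")
        a_p = 1.0 / tau_qb - a_n
        if a_p <= 0:
            raise ConfigError(
                f"tau_qb={tau_qb} must be < 2*tau_qf={2 * tau_qf} for "
                "positive protein escape rates")
    for site in sites:
        rates[site] = a_p if site[0] == PROTEIN_CHAIN else a_n
    return rates


def gen_unfolding(spec: GeneratorSpec, native_set: NativeContactSet,
                  reference: StructureEnsemble | None = None,
                  chains: str = "PDR") -> tuple[StructureEnsemble, dict]:
    """High-temperature unfolding trajectory with planted kinetics.

    Contacts survive exponentially (class lifetimes from ``tau_map``);
    escaped residues jump along per-residue random directions and relax
    outward with time constant ``tau_rg``.  Ground truth carries escape
    times, per-contact break times, and the intended intact matrix.
    """
    spec.validate()
    if reference is None:
        atoms, base = _ideal_complex()
        keep = [i for i, a in enumerate(atoms) if a.chain_id in set(chains)]
        atoms = [atoms[i] for i in keep]
        base = base[keep]
    else:
        atoms = reference.atoms
        base = reference.coords[0]

    sites = []
    for a in atoms:
        if a.site not in sites:
            sites.append(a.site)
    site_atoms = {s: [i for i, a in enumerate(atoms) if a.site == s]
                  for s in sites}
    rates = _escape_rates(native_set, sites, spec.tau_map)

    rng = np.random.default_rng(spec.seed)
    escape = {}
    for s in sites:
        if s in set(spec.unbreakable_core):
            escape[s] = np.inf
        else:
            escape[s] = rng.exponential(1.0 / rates[s])
    # per-residue escape direction and jump magnitude
    direction, jump = {}, {}
    for s in sites:
        v = rng.normal(size=3)
        direction[s] = v / np.linalg.norm(v)
        jump[s] = 17.0 + rng.uniform(0.0, 8.0)

    t = np.linspace(0.0, spec.t_max, spec.n_frames)
    tau_rg = spec.tau_map.get("rg", 4.24)
    coords = np.empty((spec.n_frames, len(atoms), 3))
    for f, tf in enumerate(t):
        frame = base.copy()
        for s in sites:
            if escape[s] <= tf:
                drift = 25.0 * (1.0 - np.exp(-(tf - escape[s]) / tau_rg))
                frame[site_atoms[s]] += direction[s] * (jump[s] + drift)
        coords[f] = frame
    coords += rng.normal(0.0, spec.noise_sigma, size=coords.shape)

    pairs = sorted(native_set.contacts)
    break_times = {p: min(escape[p.site_a], escape[p.site_b]) for p in pairs}
    intact = np.array([[break_times[p] > tf for p in pairs] for tf in t])
    truth = {
        "escape_times": escape,
        "break_times": break_times,
        "intact_matrix": intact,  # (n_frames, n_pairs), pairs sorted
        "pairs": pairs,
        "tau_map": dict(spec.tau_map),
    }
    ens = StructureEnsemble(atoms=list(atoms), coords=coords, times=t,
                            name=f"synthetic-unfold-{spec.seed}")
    return ens, truth


def gen_committor(spec: GeneratorSpec) -> TimeSeries:
    """Boltzmann-sigmoid transition-probability series with clipped noise."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, spec.t_max, spec.n_frames)
    p = 1.0 / (1.0 + np.exp((t - spec.tau_ts) / spec.tau_trans))
    if spec.committor_noise > 0:
        p = np.clip(p + rng.normal(0.0, spec.committor_noise, size=p.shape),
                    0.0, 1.0)
    return TimeSeries(t, p, label="P")


def gen_phi_ensembles(spec: GeneratorSpec, native_set: NativeContactSet,
                      reference: StructureEnsemble | None = None,
                      chains: str = "PDR"):
    """Folded / transition-state / unfolded ensembles with planted Φ*.

    Residue-level realization: in each TS frame residue s is independently
    "in place" with probability q_s, so a contact (i, j) survives with
    probability q_i q_j and the implied ground truth is
    Φ*_i = Σ_{c∋i} q_i q_j / n_i (computed exactly and returned).  The
    folded ensemble keeps every contact; the unfolded ensemble displaces
    every residue every frame.  ``spec.phi_star`` sets the per-base targets
    that the q_s are derived from (sqrt interpolation); missing bases
    default to 0.5.
    """
    spec.validate()
    if reference is None:
        atoms, base = _ideal_complex()
        keep = [i for i, a in enumerate(atoms) if a.chain_id in set(chains)]
        atoms = [atoms[i] for i in keep]
        base = base[keep]
    else:
        atoms = reference.atoms
        base = reference.coords[0]
    sites = []
    for a in atoms:
        if a.site not in sites:
            sites.append(a.site)
    site_atoms = {s: [i for i, a in enumerate(atoms) if a.site == s]
                  for s in sites}

    targets = dict(spec.phi_star or {})
    q = {s: float(np.sqrt(targets.get(s, 0.5))) for s in sites}

    rng = np.random.default_rng(spec.seed)

    def make(kind):
        coords = np.empty((spec.n_frames, len(atoms), 3))
        for f in range(spec.n_frames):
            frame = base.copy()
            for s in sites:
                if kind == "folded":
                    out = False
                elif kind == "unfolded":
                    out = True
                else:
                    out = rng.random() >= q[s]
                if out:
                    v = rng.normal(size=3)
                    v /= np.linalg.norm(v)
                    frame[site_atoms[s]] += v * (17.0 + rng.uniform(0.0, 8.0))
            coords[f] = frame
        coords += rng.normal(0.0, spec.noise_sigma, size=coords.shape)
        return StructureEnsemble(atoms=list(atoms), coords=coords,
                                 name=f"synthetic-phi-{kind}-{spec.seed}")

    folded, ts, unfolded = make("folded"), make("ts"), make("unfolded")

    phi_truth = {}
    for s in sites:
        pairs = native_set.pairs_of(s)
        if not pairs:
            continue
        surv = [q[p.site_a] * q[p.site_b] for p in pairs]
        phi_truth[s] = float(np.sum(surv) / len(pairs))
    return folded, ts, unfolded, {"phi_star": phi_truth, "q": q}


def gen_mechanism_pair(spec: GeneratorSpec
                       ) -> tuple[StructureEnsemble, StructureEnsemble,
                                  StructureEnsemble, dict]:
    """(bound, apo, partner) ensembles for one mechanism scenario.

    IF: the apo ligand is the bound conformation deformed by
    ``deformation = (radius, magnitude)`` -- only residues whose backbone
    site lies within ``radius`` of the partner mass center are displaced,
    each along a fixed random direction of length ``magnitude``.
    CS: the apo pool cycles ``n_conformers`` global conformers, exactly one
    of which matches the bound conformation up to jitter; the others are
    globally displaced by ``cs_spread`` per residue.
    """
    spec.validate()
    if spec.scenario not in ("IF", "CS"):
        raise ConfigError(f"scenario must be IF or CS, got {spec.scenario!r}")
    atoms, base = _ideal_complex()
    lig_idx = [i for i, a in enumerate(atoms)
               if a.chain_id in (DNA_CHAIN, RNA_CHAIN)]
    prot_idx = [i for i, a in enumerate(atoms)
                if a.chain_id == PROTEIN_CHAIN]
    lig_atoms = [atoms[i] for i in lig_idx]
    prot_atoms = [atoms[i] for i in prot_idx]
    lig_base, prot_base = base[lig_idx], base[prot_idx]

    masses = np.array([a.mass for a in prot_atoms])
    partner_center = (prot_base * masses[:, None]).sum(axis=0) / masses.sum()

    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    sigma = spec.noise_sigma

    bound = lig_base[None] + rng.normal(0, sigma, (n, len(lig_atoms), 3))
    partner = prot_base[None] + rng.normal(0, sigma, (n, len(prot_atoms), 3))

    lig_sites = []
    for a in lig_atoms:
        if a.site not in lig_sites:
            lig_sites.append(a.site)
    site_atoms = {s: [i for i, a in enumerate(lig_atoms) if a.site == s]
                  for s in lig_sites}
    # backbone (C5') position per site on the ideal geometry
    bb_pos = {}
    for s in lig_sites:
        cand = [i for i in site_atoms[s] if lig_atoms[i].atom_name == "C5'"]
        bb_pos[s] = lig_base[cand[0]]

    truth = {"scenario": spec.scenario, "partner_center": partner_center}
    if spec.scenario == "IF":
        radius, magnitude = spec.deformation
        apo_base = lig_base.copy()
        deformed = []
        for s in lig_sites:
            if np.linalg.norm(bb_pos[s] - partner_center) <= radius:
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                apo_base[site_atoms[s]] += magnitude * v
                deformed.append(s)
        apo = apo_base[None] + rng.normal(0, sigma, (n, len(lig_atoms), 3))
        truth["deformed_sites"] = deformed
        truth["magnitude"] = magnitude
    else:
        conformers = [lig_base.copy()]
        for _ in range(spec.n_conformers - 1):
            conf = lig_base.copy()
            for s in lig_sites:
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                conf[site_atoms[s]] += spec.cs_spread * v
            conformers.append(conf)
        order = rng.permutation(
            np.resize(np.arange(spec.n_conformers), n))
        apo = np.stack([conformers[k] for k in order]) \
            + rng.normal(0, sigma, (n, len(lig_atoms), 3))
        truth["conformer_of_frame"] = order
        truth["bound_like_conformer"] = 0

    mk = lambda at, c, name: StructureEnsemble(atoms=list(at), coords=c,
                                               name=name)
    return (mk(lig_atoms, bound, f"bound-{spec.seed}"),
            mk(lig_atoms, apo, f"apo-{spec.scenario}-{spec.seed}"),
            mk(prot_atoms, partner, f"partner-{spec.seed}"),
            truth)
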