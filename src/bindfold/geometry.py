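"""Geometric kernels: mass centers, Kabsch superposition, RMSD, Rg, RMSF,
and base-pair-to-partner distance series.

All routines work on plain (N, 3) coordinate arrays in Å so they can be
applied to whole frames or to selections.  The Kabsch solver enforces a
proper rotation (the reflection branch is removed by sign-correcting the
smallest singular value), so ``kabsch_rmsd`` is the minimum RMSD over rigid
motions only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, InsufficientDataError, LookupError_
from .ensemble_io import Selection, StructureEnsemble, select

__all__ = [
    "mass_center",
    "kabsch_transform",
    "kabsch_rmsd",
    "apply_transform",
    "radius_of_gyration",
    "rmsf",
    "FluctuationProfile",
    "pair_to_partner_distance",
]


def mass_center(ensemble: StructureEnsemble, selection: Selection,
                frame_index: int) -> np.ndarray:
    """Mass-weighted mean of the selected coordinates in one frame (Å)."""
    return mass_center_coords(
        ensemble.coords[frame_index, selection.atom_indices],
        ensemble.masses[selection.atom_indices])


def mass_center_coords(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if coords.shape[-2] == 0:
        raise GeometryError("mass center of an empty selection")
    if total <= 0:
        raise GeometryError("zero total mass")
    if np.all(masses == masses[0]):
        # equal-mass selections use the plain mean: exact for single-atom
        # sites, which keeps strict-inequality distance criteria sharp
        return coords.mean(axis=-2)
    return (coords * masses[..., :, None]).sum(axis=-2) / total


@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ (x - centroid_b) + centroid_a maps frame b onto frame a."""

    rotation: np.ndarray
    centroid_a: np.ndarray
    centroid_b: np.ndarray


def apply_transform(transform: RigidTransform, coords: np.ndarray) -> np.ndarray:
    return (coords - transform.centroid_b) @ transform.rotation.T \
        + transform.centroid_a


def kabsch_transform(coords_a: np.ndarray, coords_b: np.ndarray,
                     weights: np.ndarray | None = None
                     ) -> tuple[RigidTransform, float]:
    """Optimal proper-rigid superposition of ``coords_b`` onto ``coords_a``.

    Returns the transform and the minimal (weighted) RMSD in Å.  Requires
    N >= 3 non-collinear points in each set.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise GeometryError("coordinate sets must share shape (N, 3)")
    n = a.shape[0]
    if n < 3:
        raise GeometryError(f"superposition needs N >= 3 points, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.sum() <= 0:
            raise GeometryError("non-positive total weight")
        w = w / w.sum()

    ca = (w[:, None] * a).sum(axis=0)
    cb = (w[:, None] * b).sum(axis=0)
    a0, b0 = a - ca, b - cb
    # collinearity check on both sets
    for pts, label in ((a0, "a"), (b0, "b")):
        s = np.linalg.svd(pts * np.sqrt(w)[:, None], compute_uv=False)
        if s[1] <= 1e-10 * max(s[0], 1.0):
            raise GeometryError(f"degenerate (collinear) point set {label}")

    h = (b0 * w[:, None]).T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T

    e0 = float((w[:, None] * (a0 ** 2 + b0 ** 2)).sum())
    msd = max(e0 - 2.0 * float(s[0] + s[1] + d * s[2]), 0.0)
    return RigidTransform(rot, ca, cb), float(np.sqrt(msd))


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
                weights: np.ndarray | None = None) -> float:
    """Minimum RMSD (Å) over all proper rigid superpositions."""
    return kabsch_transform(coords_a, coords_b, weights)[1]


def radius_of_gyration(ensemble: StructureEnsemble, selection: Selection,
                       frame_index: int) -> float:
    """Mass-weighted radius of gyration (Å) of a selection in one frame."""
    coords = ensemble.coords[frame_index, selection.atom_indices]
    masses = ensemble.masses[selection.atom_indices]
    return rg_coords(coords, masses)


def rg_coords(coords: np.ndarray, masses: np.ndarray) -> float:
    center = mass_center_coords(coords, masses)
    dev2 = ((coords - center) ** 2).sum(axis=1)
    return float(np.sqrt((masses * dev2).sum() / masses.sum()))


@dataclass
class FluctuationProfile:
    """Per-site RMSF in Å; optionally the SD across replica trajectories."""

    site_labels: list[str]
    rmsf: np.ndarray
    sd_across_trajectories: np.ndarray | None = None

    def to_records(self):
        rec = {"site": self.site_labels, "rmsf_A": self.rmsf}
        if self.sd_across_trajectories is not None:
            rec["sd_A"] = self.sd_across_trajectories
        return rec


def _superpose_to_mean(frames: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Iteratively superpose frames onto their mean structure.

    Two iterations are enough for convergence in practice; tests assert the
    profile is stable under a third.
    """
    out = frames.copy()
    for _ in range(iterations):
        mean = out.mean(axis=0)
        for f in range(out.shape[0]):
            tr, _ = kabsch_transform(mean, out[f])
            out[f] = apply_transform(tr, out[f])
    return out


def rmsf(ensemble: StructureEnsemble, selection: Selection,
         iterations: int = 2) -> FluctuationProfile:
    """Per-site root-mean-square fluctuation about the mean structure.

    Frames are first superposed onto the (iterated) mean so rigid-body
    motion does not inflate the fluctuations.
    """
    if ensemble.n_frames < 2:
        raise InsufficientDataError("RMSF needs at least two frames")
    frames = ensemble.coords[:, selection.atom_indices, :]
    aligned = _superpose_to_mean(frames, iterations=iterations)
    mean = aligned.mean(axis=0)
    per_site = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))
    labels = [f"{a.chain_id}:{a.residue_index}"
              for a in (ensemble.atoms[i] for i in selection.atom_indices)]
    return FluctuationProfile(labels, per_site)


def rmsf_replicas(ensembles: list[StructureEnsemble], selection: Selection
                  ) -> FluctuationProfile:
    """RMSF per replica trajectory, then mean +/- SD across replicas."""
    profiles = [rmsf(e, selection) for e in ensembles]
    stack = np.stack([p.rmsf for p in profiles])
    return FluctuationProfile(profiles[0].site_labels, stack.mean(axis=0),
                              stack.std(axis=0, ddof=1) if len(profiles) > 1
                              else None)


def pair_to_partner_distance(ensemble: StructureEnsemble,
                             base_pair: tuple[tuple[str, int], tuple[str, int]],
                             partner_selection: Selection):
    """Distances from a partner's mass center to each base of a base pair.

    Returns per-frame distances ``(d_first, d_second)`` plus the difference
    series ``d_first - d_second`` -- with the RNA base first this is the
    "RNA closer than DNA when negative" convention of the distance analyses.
    """
    from .kinetics import TimeSeries  # local import to avoid a cycle

    masses = ensemble.masses
    sels = []
    for site in base_pair:
        try:
            sels.append(select(ensemble, "sidechain", residue=site))
        except LookupError_:
            raise
    part_idx = partner_selection.atom_indices
    t = (ensemble.times if ensemble.times is not None
         else np.arange(ensemble.n_frames, dtype=float))
    d = []
    for sel in sels:
        idx = sel.atom_indices
        centers = mass_center_coords(ensemble.coords[:, idx, :], masses[idx])
        partner_centers = mass_center_coords(
            ensemble.coords[:, part_idx, :], masses[part_idx])
        d.append(np.linalg.norm(centers - partner_centers, axis=1))
    return (
        TimeSeries(t, d[0], label="d_first"),
        TimeSeries(t, d[1], label="d_second"),
        TimeSeries(t, d[0] - d[1], label="d_first_minus_second"),
    )
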