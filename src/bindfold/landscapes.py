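"""Free-energy surfaces and apo-minus-bound distance-difference maps.

The free-energy surface is the negative log of a normalised 2-D histogram
of two order parameters (Qf/Qb, Qf/Rg, RMSD/Rg ...), in kT units and
shifted so the most populated bin sits at zero.  The distance-difference
map compares mean internal site-site distances between an apo and a bound
ensemble over all frames: positive entries mean the pair contracts upon
binding, negative entries mean it extends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .ensemble_io import Selection, StructureEnsemble
from .errors import CorrespondenceError, EmptyInputError

__all__ = ["Landscape2D", "DistanceDifferenceMap",
           "free_energy_surface", "distance_difference_map"]


@dataclass
class Landscape2D:
    """Normalised 2-D histogram and its -ln(p/p_max) free-energy surface.

    Empty bins carry +inf free energy in memory; exports replace them with
    (max finite + 1) kT so plots stay scaled.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray
    free_energy: np.ndarray
    x_label: str = "x"
    y_label: str = "y"

    def export_free_energy(self) -> np.ndarray:
        fe = self.free_energy.copy()
        finite = np.isfinite(fe)
        if finite.any():
            fe[~finite] = fe[finite].max() + 1.0
        else:
            fe[:] = 0.0
        return fe

    def plot(self, path):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 4))
        m = ax.pcolormesh(self.x_edges, self.y_edges,
                          self.export_free_energy().T, shading="auto",
                          cmap="viridis")
        fig.colorbar(m, ax=ax, label="free energy (kT)")
        ax.set_xlabel(self.x_label)
        ax.set_ylabel(self.y_label)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def free_energy_surface(x: np.ndarray, y: np.ndarray,
                        bins: tuple[int, int] = (50, 50),
                        pad_fraction: float = 0.02,
                        x_label: str = "x", y_label: str = "y") -> Landscape2D:
    """-ln(p) landscape from a normalised 2-D histogram of two observables.

    The grid spans the observed range padded by ``pad_fraction`` on each
    side (degenerate ranges get a unit pad so single-well data are valid).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EmptyInputError("observable vectors must be equal-length 1-D")
    if x.size == 0:
        raise EmptyInputError("no samples")

    def edges(v, n):
        lo, hi = float(v.min()), float(v.max())
        pad = (hi - lo) * pad_fraction
        if hi == lo:  # degenerate range: single-well data stay valid
            pad = max(abs(lo), 1.0) * 0.01
        return np.linspace(lo - pad, hi + pad, n + 1)

    xe, ye = edges(x, bins[0]), edges(y, bins[1])
    h, _, _ = np.histogram2d(x, y, bins=(xe, ye))
    p = h / h.sum()
    with np.errstate(divide="ignore"):
        fe = -np.log(p / p.max())
    fe[p == 0] = np.inf
    return Landscape2D(xe, ye, p, fe, x_label=x_label, y_label=y_label)


@dataclass
class DistanceDifferenceMap:
    """delta[i, j] = <d_apo(i, j)> - <d_bound(i, j)> over all frames, Å."""

    site_labels: list[str]
    delta: np.ndarray

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        n = len(self.site_labels)
        if self.delta.shape != (n, n):
            raise CorrespondenceError("delta matrix must be n_sites x n_sites")

    def plot(self, path):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 4))
        lim = max(abs(self.delta).max(), 1e-9)
        m = ax.imshow(self.delta, cmap="RdBu_r", vmin=-lim, vmax=lim,
                      origin="lower")
        fig.colorbar(m, ax=ax, label="apo - bound distance (Å)")
        ax.set_xlabel("site index")
        ax.set_ylabel("site index")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _mean_distance_matrix(ensemble: StructureEnsemble, selection: Selection
                          ) -> np.ndarray:
    idx = selection.atom_indices
    n = idx.size
    acc = np.zeros(n * (n - 1) // 2)
    for f in range(ensemble.n_frames):
        acc += pdist(ensemble.coords[f, idx, :])
    return squareform(acc / ensemble.n_frames)


def distance_difference_map(apo: StructureEnsemble, bound: StructureEnsemble,
                            apo_sites: Selection, bound_sites: Selection
                            ) -> DistanceDifferenceMap:
    """Mean apo site-site distances minus mean bound distances.

    The two selections must address the same residues (chain + author
    residue index); a mismatch raises listing the offending sites.  Being a
    function of internal distances only, the map is invariant to any rigid
    motion applied per frame to either ensemble.
    """
    key_apo = [apo.atoms[i].site for i in apo_sites.atom_indices]
    key_bound = [bound.atoms[i].site for i in bound_sites.atom_indices]
    if key_apo != key_bound:
        only_a = sorted(set(key_apo) - set(key_bound))
        only_b = sorted(set(key_bound) - set(key_apo))
        raise CorrespondenceError(
            f"site lists differ (apo-only: {only_a[:5]}, "
            f"bound-only: {only_b[:5]}, or ordering mismatch)")
    d_apo = _mean_distance_matrix(apo, apo_sites)
    d_bound = _mean_distance_matrix(bound, bound_sites)
    labels = [f"{c}:{r}" for c, r in key_apo]
    return DistanceDifferenceMap(labels, d_apo - d_bound)
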