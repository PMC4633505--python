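"""Transition-state ensemble extraction and Φ-value prediction.

For a two-state unfolding process the per-snapshot transition probability
P(t) (probability that the snapshot folds rather than unfolds; supplied by
an external committor estimator) follows the Boltzmann sigmoid

    P(t) = 1 / (1 + exp((t - tau_TS) / tau_trans))

so P(tau_TS) = 1/2 by construction and the fitted curve lies in the
transition band P in [0.4, 0.6] over a window of width 2*ln(1.5)*tau_trans
centred on tau_TS.  Snapshots inside that window form the transition-state
ensemble (TSE).

Per-base Φ-values measure how native-like each base is at the transition
state:  Φ_i = (N_TS,i - N_U,i) / (N_F,i - N_U,i), with N the mean number of
satisfied native contacts of base i over the folded, TSE and unfolded
ensembles.  Φ ≈ 1 means the base's native contacts are already formed at
the transition state; Φ ≈ 0 means they form only after it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .contacts import NATIVE_CUTOFF, NativeContactSet, sidechain_centers
from .ensemble_io import StructureEnsemble, is_nucleotide
from .errors import (
    CorrespondenceError,
    EmptyInputError,
    FitError,
    InsufficientDataError,
    NoTransitionError,
)
from .geometry import apply_transform, kabsch_transform
from .kinetics import TimeSeries

__all__ = [
    "BoltzmannFitResult",
    "TSEWindow",
    "PhiRecord",
    "fit_boltzmann",
    "transition_window",
    "extract_tse",
    "per_base_contact_counts",
    "phi_values",
]

TSE_BAND = (0.4, 0.6)


def _sigmoid(t, tau_ts, tau_trans):
    return 1.0 / (1.0 + np.exp((t - tau_ts) / tau_trans))


@dataclass
class BoltzmannFitResult:
    """Fitted P(t) = 1 / (1 + exp((t - tau_ts)/tau_trans))."""

    tau_ts: float
    tau_trans: float
    r_squared: float
    covariance: np.ndarray

    def __post_init__(self):
        if self.tau_trans <= 0:
            raise FitError(f"non-positive tau_trans {self.tau_trans}")

    def predict(self, t) -> np.ndarray:
        return _sigmoid(np.asarray(t, dtype=float), self.tau_ts, self.tau_trans)

    def band_window(self, band: tuple[float, float] = TSE_BAND
                    ) -> tuple[float, float]:
        """Times where the fitted P lies in ``band`` (P decreases with t)."""
        lo_p, hi_p = band
        t_at = lambda p: self.tau_ts + self.tau_trans * np.log((1 - p) / p)
        return (float(t_at(hi_p)), float(t_at(lo_p)))

    def summary(self) -> str:
        se = np.sqrt(np.diag(self.covariance))
        t_lo, t_hi = self.band_window()
        return "\n".join([
            "Boltzmann transition-probability fit",
            "  P(t) = 1 / (1 + exp((t - tau_TS)/tau_trans))",
            f"  tau_TS (ns)     {self.tau_ts:10.4f}  (SE {se[0]:.4f})",
            f"  tau_trans (ns)  {self.tau_trans:10.4f}  (SE {se[1]:.4f})",
            f"  R^2             {self.r_squared:10.4f}",
            f"  P(tau_TS)       {float(self.predict(self.tau_ts)):10.4f}",
            f"  band 0.4-0.6    [{t_lo:.4f}, {t_hi:.4f}] ns",
        ])


def fit_boltzmann(p_series: TimeSeries) -> BoltzmannFitResult:
    """Least-squares Boltzmann-sigmoid fit of a transition-probability series.

    The series must straddle P = 0.5 (otherwise no transition is observed
    and :class:`NoTransitionError` is raised).
    """
    if len(p_series) < 8:
        raise InsufficientDataError(
            f"need >= 8 points to fit, got {len(p_series)}")
    t, p = p_series.t, p_series.y
    if p.min() >= 0.5 or p.max() <= 0.5:
        raise NoTransitionError(
            "series never crosses P = 0.5; no transition to locate")
    below = np.nonzero(p <= 0.5)[0]
    tau_ts0 = float(t[below[0]]) if below.size else float(t[len(t) // 2])
    span = float(t[-1] - t[0])
    p0 = [tau_ts0, max(span / 20.0, 1e-3)]
    try:
        popt, pcov = curve_fit(_sigmoid, t, p, p0=p0,
                               bounds=([t[0] - span, 1e-9],
                                       [t[-1] + span, 10 * span]),
                               maxfev=20000)
    except (RuntimeError, ValueError) as err:
        raise FitError(f"Boltzmann fit failed: {err}") from err
    resid = p - _sigmoid(t, *popt)
    sstot = float(((p - p.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / sstot if sstot > 0 else 0.0
    return BoltzmannFitResult(tau_ts=float(popt[0]), tau_trans=float(popt[1]),
                              r_squared=float(min(max(r2, 0.0), 1.0)),
                              covariance=np.asarray(pcov))


def transition_window(fit: BoltzmannFitResult,
                      band: tuple[float, float] = TSE_BAND
                      ) -> tuple[float, float]:
    """Closed-form [t_lo, t_hi] where the fitted P lies inside the band."""
    return fit.band_window(band)


@dataclass
class TSEWindow:
    """Transition-state ensemble: frames whose fitted P is in the band."""

    t_lo: float
    t_hi: float
    snapshot_indices: np.ndarray
    average_structure: np.ndarray
    n_snapshots: int

    def summary(self) -> str:
        return (f"TSE window [{self.t_lo:.4f}, {self.t_hi:.4f}] ns, "
                f"{self.n_snapshots} snapshots")


def extract_tse(trajectory: StructureEnsemble, fit: BoltzmannFitResult,
                band: tuple[float, float] = TSE_BAND) -> TSEWindow:
    """Snapshots whose time maps to fitted P inside the band.

    The average structure is the coordinate mean after Kabsch superposition
    of every window frame onto the frame nearest tau_TS.  A degenerate band
    (lo == hi) returns the single snapshot nearest tau_TS.
    """
    if trajectory.times is None:
        raise EmptyInputError("trajectory needs frame times for TSE extraction")
    times = trajectory.times
    if times[-1] < fit.tau_ts:
        raise EmptyInputError(
            f"trajectory ends at {times[-1]:.3f} ns, before tau_TS = "
            f"{fit.tau_ts:.3f} ns")
    if band[0] == band[1]:
        idx = np.array([int(np.argmin(np.abs(times - fit.tau_ts)))])
        t_lo = t_hi = fit.tau_ts
    else:
        t_lo, t_hi = fit.band_window(band)
        idx = np.nonzero((times >= t_lo) & (times <= t_hi))[0]
        if idx.size == 0:
            raise EmptyInputError(
                f"no snapshots in [{t_lo:.4f}, {t_hi:.4f}] ns: sampling too "
                "coarse, use a finer stride")
    ref_i = idx[int(np.argmin(np.abs(times[idx] - fit.tau_ts)))]
    ref = trajectory.coords[ref_i]
    aligned = []
    for i in idx:
        tr, _ = kabsch_transform(ref, trajectory.coords[i])
        aligned.append(apply_transform(tr, trajectory.coords[i]))
    return TSEWindow(t_lo=float(t_lo), t_hi=float(t_hi),
                     snapshot_indices=idx,
                     average_structure=np.mean(aligned, axis=0),
                     n_snapshots=int(idx.size))


def per_base_contact_counts(ensemble: StructureEnsemble,
                            native_set: NativeContactSet,
                            bases: list[tuple[str, int]] | None = None,
                            cutoff: float = NATIVE_CUTOFF
                            ) -> dict[tuple[str, int], float]:
    """Mean number of satisfied native contacts per base over the frames.

    For each base the native-set pairs involving it are counted as
    satisfied in a frame when their side-chain center distance is strictly
    below the native cutoff; the mean over frames is real-valued.
    """
    if ensemble.n_frames == 0:
        raise EmptyInputError("empty ensemble")
    if bases is None:
        bases = [(c, r) for c, r, n in ensemble.residues()
                 if is_nucleotide(n)]
    centers = sidechain_centers(ensemble)
    counts: dict[tuple[str, int], float] = {}
    for base in bases:
        pairs = native_set.pairs_of(base)
        if not pairs:
            counts[base] = 0.0
            continue
        a = np.stack([centers[p.site_a] for p in pairs])
        b = np.stack([centers[p.site_b] for p in pairs])
        d = np.linalg.norm(a - b, axis=2)
        counts[base] = float((d < cutoff).sum(axis=0).mean())
    return counts


@dataclass
class PhiRecord:
    base_id: tuple[str, int]
    n_folded: float
    n_ts: float
    n_unfolded: float
    phi: float | None  # None when N_F == N_U (undefined)

    @property
    def defined(self) -> bool:
        return self.phi is not None


def phi_values(folded_counts: dict, tse_counts: dict, unfolded_counts: dict
               ) -> list[PhiRecord]:
    """Φ_i = (N_TS,i - N_U,i) / (N_F,i - N_U,i) per base.

    The three count mappings must cover the same bases; bases whose folded
    and unfolded counts coincide have undefined Φ and are flagged rather
    than ranked.
    """
    if set(folded_counts) != set(tse_counts) or set(folded_counts) != set(unfolded_counts):
        raise CorrespondenceError("count vectors cover different base lists")
    out = []
    for base in folded_counts:
        nf, nts, nu = folded_counts[base], tse_counts[base], unfolded_counts[base]
        phi = None if nf == nu else (nts - nu) / (nf - nu)
        out.append(PhiRecord(base, float(nf), float(nts), float(nu),
                             None if phi is None else float(phi)))
    out.sort(key=lambda r: r.base_id)
    return out


def phi_records_to_frame(records: list[PhiRecord]):
    import pandas as pd
    return pd.DataFrame([{
        "chain": r.base_id[0], "residue": r.base_id[1],
        "n_folded": r.n_folded, "n_ts": r.n_ts, "n_unfolded": r.n_unfolded,
        "phi": np.nan if r.phi is None else r.phi,
        "defined": r.defined,
    } for r in records])
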