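"""Unfolding/unbinding kinetics: Q and Rg time series and first-order fits.

Qf (intra-group tertiary contacts) and Qb (inter-group binding contacts)
are the surviving fractions of stable folded-state native contacts along a
high-temperature trajectory.  Both -- and the radius of gyration -- relax
as single exponentials when unfolding is first-order, so each series is
fitted to

    y(t) = A * exp(-t / tau) + B

by bounded nonlinear least squares with jittered restarts.  tau is reported
as the process half-time (the convention of the source analyses); a
conventional ln2*tau column is also emitted, clearly labelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .contacts import NATIVE_CUTOFF, NativeContactSet, sidechain_centers
from .ensemble_io import Selection, StructureEnsemble
from .errors import (
    EmptyInputError,
    FitError,
    InsufficientDataError,
    UnidentifiableModelError,
)
from .geometry import rg_coords

__all__ = [
    "TimeSeries",
    "ExpFitResult",
    "q_series",
    "rg_series",
    "fit_exponential",
    "aggregate_fits",
]


@dataclass
class TimeSeries:
    """(t, y) pairs; t in ns, strictly increasing."""

    t: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise EmptyInputError("t and y must be equal-length 1-D arrays")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise EmptyInputError("times must be strictly increasing")

    def __len__(self):
        return self.t.size


def _exp_model(t, a, tau, b):
    return a * np.exp(-t / tau) + b


@dataclass
class ExpFitResult:
    """Fitted y(t) = A exp(-t/tau) + B.

    ``tau`` is the half-time in the convention used throughout this package
    (the fitted exponential time constant); ``half_time_ln2`` is the
    conventional ln2*tau, provided for comparison only.
    """

    tau: float
    amplitude: float
    offset: float
    r_squared: float
    covariance: np.ndarray
    label: str = ""

    def __post_init__(self):
        if self.tau <= 0:
            raise FitError(f"non-positive tau {self.tau}")

    @property
    def half_time_ln2(self) -> float:
        return float(np.log(2.0) * self.tau)

    def predict(self, t: np.ndarray) -> np.ndarray:
        return _exp_model(np.asarray(t, dtype=float),
                          self.amplitude, self.tau, self.offset)

    def summary(self) -> str:
        se = np.sqrt(np.diag(self.covariance))
        lines = [
            f"First-order decay fit {self.label}".rstrip(),
            f"  y(t) = A exp(-t/tau) + B",
            f"  tau (ns)      {self.tau:10.4f}  (SE {se[1]:.4f})",
            f"  A             {self.amplitude:10.4f}  (SE {se[0]:.4f})",
            f"  B             {self.offset:10.4f}  (SE {se[2]:.4f})",
            f"  R^2           {self.r_squared:10.4f}",
            f"  ln2*tau (ns)  {self.half_time_ln2:10.4f}  [not the reported half-time]",
        ]
        return "\n".join(lines)


def q_series(trajectory: StructureEnsemble, native_set: NativeContactSet,
             scope: str = "intra", cutoff: float = NATIVE_CUTOFF) -> TimeSeries:
    """Per-frame surviving fraction of scoped native contacts.

    A contact survives in a frame when its side-chain mass-center distance
    is strictly below the native cutoff in that frame.
    """
    pairs = sorted(native_set.scoped(scope))
    if not pairs:
        raise EmptyInputError(f"native set has no {scope!r} contacts")
    centers = sidechain_centers(trajectory)
    a = np.stack([centers[p.site_a] for p in pairs])  # (n_pairs, n_frames, 3)
    b = np.stack([centers[p.site_b] for p in pairs])
    d = np.linalg.norm(a - b, axis=2)
    q = (d < cutoff).mean(axis=0)
    t = (trajectory.times if trajectory.times is not None
         else np.arange(trajectory.n_frames, dtype=float))
    return TimeSeries(t, q, label=f"Q{'f' if scope == 'intra' else 'b'}")


def rg_series(trajectory: StructureEnsemble, selection: Selection) -> TimeSeries:
    """Radius of gyration of a selection along the trajectory."""
    masses = trajectory.masses[selection.atom_indices]
    rg = np.array([
        rg_coords(trajectory.coords[f, selection.atom_indices, :], masses)
        for f in range(trajectory.n_frames)])
    t = (trajectory.times if trajectory.times is not None
         else np.arange(trajectory.n_frames, dtype=float))
    return TimeSeries(t, rg, label="Rg")


def fit_exponential(series: TimeSeries, n_restarts: int = 5,
                    seed: int = 0) -> ExpFitResult:
    """Bounded least-squares fit of A exp(-t/tau) + B.

    Time is internally re-zeroed (t -> t - t[0]) so a uniform time shift of
    the input changes only the amplitude bookkeeping, never tau.  Initial
    guesses: B = min(y), A = y(0) - B, tau = first crossing of B + A/e;
    restarts jitter the guesses multiplicatively.
    """
    if len(series) < 8:
        raise InsufficientDataError(
            f"need >= 8 points to fit, got {len(series)}")
    y = series.y
    if np.ptp(y) < 1e-12:
        raise UnidentifiableModelError(
            "constant series cannot constrain an exponential decay")
    t = series.t - series.t[0]
    t_max = float(t[-1])

    b0 = float(y.min()) if y[0] >= y[-1] else float(y.max())
    a0 = float(y[0] - b0)
    target = b0 + a0 / np.e
    if a0 >= 0:
        crossing = np.nonzero(y <= target)[0]
    else:
        crossing = np.nonzero(y >= target)[0]
    tau0 = float(t[crossing[0]]) if crossing.size and t[crossing[0]] > 0 \
        else t_max / 3.0
    tau0 = min(max(tau0, 1e-6), 10.0 * t_max)

    rng = np.random.default_rng(seed)
    lo = [-np.inf, 1e-9, -np.inf]
    hi = [np.inf, 10.0 * t_max, np.inf]
    best, best_cov, best_sse = None, None, np.inf
    last_err = None
    for k in range(n_restarts):
        jit = rng.uniform(0.5, 1.5, size=3) if k else np.ones(3)
        p0 = [a0 * jit[0] if a0 != 0 else 0.1 * jit[0],
              float(np.clip(tau0 * jit[1], 1e-9, 10 * t_max)),
              b0 * jit[2]]
        try:
            popt, pcov = curve_fit(_exp_model, t, y, p0=p0,
                                   bounds=(lo, hi), maxfev=20000)
        except (RuntimeError, ValueError) as err:
            last_err = err
            continue
        sse = float(((y - _exp_model(t, *popt)) ** 2).sum())
        if sse < best_sse:
            best, best_cov, best_sse = popt, pcov, sse
    if best is None:
        raise FitError(f"exponential fit failed after {n_restarts} restarts: "
                       f"{last_err}")
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - best_sse / sstot if sstot > 0 else 0.0
    return ExpFitResult(tau=float(best[1]), amplitude=float(best[0]),
                        offset=float(best[2]),
                        r_squared=float(min(max(r2, 0.0), 1.0)),
                        covariance=np.asarray(best_cov),
                        label=series.label)


@dataclass
class AggregateFit:
    """Mean +/- sample SD of (tau, A, B) across replica trajectories."""

    tau_mean: float
    tau_sd: float | None
    amplitude_mean: float
    amplitude_sd: float | None
    offset_mean: float
    offset_sd: float | None
    n: int
    label: str = ""

    def summary(self) -> str:
        def fmt(m, s):
            return f"{m:.3f}" + (f" +/- {s:.3f}" if s is not None else " (single fit)")
        return (f"{self.label or 'aggregate'} over {self.n} trajectories: "
                f"tau {fmt(self.tau_mean, self.tau_sd)} ns, "
                f"A {fmt(self.amplitude_mean, self.amplitude_sd)}, "
                f"B {fmt(self.offset_mean, self.offset_sd)}")


def aggregate_fits(fits: list[ExpFitResult]) -> AggregateFit:
    """Across-replica mean and sample SD of each fitted parameter."""
    if not fits:
        raise EmptyInputError("no fits to aggregate")
    taus = np.array([f.tau for f in fits])
    amps = np.array([f.amplitude for f in fits])
    offs = np.array([f.offset for f in fits])
    sd = (lambda v: float(v.std(ddof=1))) if len(fits) > 1 else (lambda v: None)
    return AggregateFit(
        tau_mean=float(taus.mean()), tau_sd=sd(taus),
        amplitude_mean=float(amps.mean()), amplitude_sd=sd(amps),
        offset_mean=float(offs.mean()), offset_sd=sd(offs),
        n=len(fits), label=fits[0].label)
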