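"""Boltzmann transition-probability fits, TSE extraction and Φ-values."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bindfold import (
    GeneratorSpec,
    TimeSeries,
    extract_tse,
    fit_boltzmann,
    gen_committor,
    gen_phi_ensembles,
    gen_unfolding,
    per_base_contact_counts,
    phi_values,
)
from bindfold.errors import (
    CorrespondenceError,
    EmptyInputError,
    NoTransitionError,
)


def _sigmoid_series(tau_ts=5.0, tau_trans=0.4, n=200, t_max=10.0):
    t = np.linspace(0, t_max, n)
    return TimeSeries(t, 1.0 / (1.0 + np.exp((t - tau_ts) / tau_trans)))


def test_fitted_curve_is_half_at_tau_ts():
    """P(tau_TS) = 0.5: the 50% transition criterion holds by construction."""
    fit = fit_boltzmann(gen_committor(GeneratorSpec(seed=3, n_frames=200)))
    assert float(fit.predict(fit.tau_ts)) == pytest.approx(0.5, abs=1e-12)


def test_noiseless_regeneration():
    fit = fit_boltzmann(_sigmoid_series())
    assert fit.tau_ts == pytest.approx(5.0, abs=1e-6)
    assert fit.tau_trans == pytest.approx(0.4, abs=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


def test_band_width_closed_form():
    """Width of {t : 0.4 <= P(t) <= 0.6} equals 2 ln(1.5) tau_trans."""
    fit = fit_boltzmann(_sigmoid_series(tau_trans=0.4))
    lo, hi = fit.band_window((0.4, 0.6))
    assert hi - lo == pytest.approx(2 * np.log(1.5) * fit.tau_trans, rel=1e-9)
    assert lo < fit.tau_ts < hi


def test_no_transition_rejected():
    t = np.linspace(0, 10, 50)
    with pytest.raises(NoTransitionError):
        fit_boltzmann(TimeSeries(t, np.full(50, 0.8)))
    with pytest.raises(NoTransitionError):
        fit_boltzmann(TimeSeries(t, np.full(50, 0.2)))


def test_noisy_recovery_median_error():
    """Median |tau_ts error| < 5% of tau_ts over 50 noisy series."""
    errs = []
    for s in range(50):
        series = gen_committor(GeneratorSpec(seed=s, n_frames=200,
                                             committor_noise=0.05))
        errs.append(abs(fit_boltzmann(series).tau_ts - 5.0))
    assert np.median(errs) < 0.05 * 5.0


def test_extract_tse_window(native_set):
    traj, _ = gen_unfolding(GeneratorSpec(seed=5, n_frames=500,
                                          scenario="unfold"), native_set)
    fit = fit_boltzmann(_sigmoid_series(tau_ts=5.0, tau_trans=0.4))
    window = extract_tse(traj, fit)
    expected_width = 2 * np.log(1.5) * 0.4
    assert window.t_hi - window.t_lo == pytest.approx(expected_width, rel=1e-9)
    dt = traj.times[1] - traj.times[0]
    assert window.n_snapshots == pytest.approx(expected_width / dt, abs=1.5)
    assert window.average_structure.shape == (traj.n_atoms, 3)
    in_band = (traj.times >= window.t_lo) & (traj.times <= window.t_hi)
    assert np.array_equal(np.nonzero(in_band)[0], window.snapshot_indices)


def test_extract_tse_degenerate_band(native_set):
    traj, _ = gen_unfolding(GeneratorSpec(seed=5, n_frames=100,
                                          scenario="unfold"), native_set)
    fit = fit_boltzmann(_sigmoid_series())
    window = extract_tse(traj, fit, band=(0.5, 0.5))
    assert window.n_snapshots == 1
    nearest = int(np.argmin(np.abs(traj.times - fit.tau_ts)))
    assert window.snapshot_indices[0] == nearest


def test_extract_tse_trajectory_too_short(native_set):
    traj, _ = gen_unfolding(GeneratorSpec(seed=5, n_frames=100, t_max=3.0,
                                          scenario="unfold"), native_set)
    fit = fit_boltzmann(_sigmoid_series(tau_ts=5.0))
    with pytest.raises(EmptyInputError):
        extract_tse(traj, fit)


@pytest.mark.parametrize("triple,phi", [
    ((14, 14, 1), 1.0),            # fully native transition state
    ((14, 1, 1), 0.0),             # fully denatured transition state
    ((14, 5, 1), 4.0 / 13.0),      # worked count triple
])
def test_phi_arithmetic(triple, phi):
    nf, nts, nu = triple
    recs = phi_values({("D", 1): nf}, {("D", 1): nts}, {("D", 1): nu})
    assert recs[0].phi == pytest.approx(phi)


def test_phi_undefined_when_folded_equals_unfolded():
    recs = phi_values({("D", 1): 3.0}, {("D", 1): 2.0}, {("D", 1): 3.0})
    assert recs[0].phi is None and not recs[0].defined


def test_phi_misaligned_bases_rejected():
    with pytest.raises(CorrespondenceError):
        phi_values({("D", 1): 1.0}, {("D", 2): 1.0}, {("D", 1): 0.0})


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.floats(min_value=0.1, max_value=10.0))
def test_phi_invariant_under_count_rescaling(scale):
    base = {("D", 1): 14.0, ("R", 2): 8.0}
    ts = {("D", 1): 5.0, ("R", 2): 4.0}
    un = {("D", 1): 1.0, ("R", 2): 0.0}
    r1 = phi_values(base, ts, un)
    r2 = phi_values({k: v * scale for k, v in base.items()},
                    {k: v * scale for k, v in ts.items()},
                    {k: v * scale for k, v in un.items()})
    for a, b in zip(r1, r2):
        assert a.phi == pytest.approx(b.phi, rel=1e-9)


def test_per_base_counts_match_brute_force(folded_complex, native_set):
    """Mean per-base counts equal an independent per-frame recount."""
    ens, _ = folded_complex
    bases = [(c, r) for c, r, n in ens.residues() if c in ("D", "R")][:6]
    counts = per_base_contact_counts(ens, native_set, bases)
    from bindfold.contacts import sidechain_centers
    centers = sidechain_centers(ens)
    for base in bases:
        pairs = native_set.pairs_of(base)
        total = 0
        for f in range(ens.n_frames):
            total += sum(
                np.linalg.norm(centers[p.site_a][f] - centers[p.site_b][f])
                < 7.5 for p in pairs)
        assert counts[base] == pytest.approx(total / ens.n_frames, abs=1e-12)


def test_base_without_native_pairs_gives_undefined_phi(native_set):
    counts = {("X", 99): 0.0}
    recs = phi_values(counts, counts, counts)
    assert recs[0].phi is None


def test_planted_phi_recovery(native_set):
    """The pipeline recovers the generator's planted per-base Φ* within
    ±0.1 on 500-frame ensembles."""
    rng = np.random.default_rng(2)
    from bindfold.synthetic import _ideal_complex
    ens_atoms, _ = _ideal_complex()
    bases = sorted({a.site for a in ens_atoms if a.chain_id in "DR"})
    targets = {b: float(rng.uniform(0.1, 0.9)) for b in bases}
    spec = GeneratorSpec(seed=7, n_frames=500, phi_star=targets)
    folded, ts, unfolded, truth = gen_phi_ensembles(spec, native_set)
    cf = per_base_contact_counts(folded, native_set, bases)
    ct = per_base_contact_counts(ts, native_set, bases)
    cu = per_base_contact_counts(unfolded, native_set, bases)
    recs = phi_values(cf, ct, cu)
    checked = 0
    for r in recs:
        if r.defined and r.base_id in truth["phi_star"]:
            assert r.phi == pytest.approx(truth["phi_star"][r.base_id],
                                          abs=0.1)
            checked += 1
    assert checked >= 15
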