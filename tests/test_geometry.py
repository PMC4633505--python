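"""Geometric kernels against independent oracles.

The Kabsch solver is cross-checked against a quaternion (Horn) superposition
oracle implemented here from scratch; mass centers and Rg against direct
summation.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bindfold import (
    GeneratorSpec,
    Selection,
    gen_complex,
    kabsch_rmsd,
    mass_center,
    radius_of_gyration,
    rmsf,
    select,
)
from bindfold.errors import GeometryError, InsufficientDataError
from bindfold.geometry import pair_to_partner_distance

from conftest import make_ensemble


# --- independent quaternion superposition oracle (Horn 1987) -------------

def quaternion_rmsd(a, b):
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = b.T @ a
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = (a ** 2).sum() + (b ** 2).sum()
    msd = max(e0 - 2.0 * lam, 0.0) / a.shape[0]
    return float(np.sqrt(msd))


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


def _toy(masses, coords):
    rows = [("A", i + 1, "ALA", "CB", "C") for i in range(len(coords))]
    ens = make_ensemble(rows, [coords])
    for a, m in zip(ens.atoms, masses):
        object.__setattr__(a, "mass", float(m))
    return ens, Selection("all", np.arange(len(coords)))


def test_mass_center_examples():
    ens, sel = _toy([1, 1], np.array([[0., 0, 0], [2, 0, 0]]))
    assert mass_center(ens, sel, 0) == pytest.approx([1, 0, 0])
    ens, sel = _toy([12, 1], np.array([[0., 0, 0], [13, 0, 0]]))
    assert mass_center(ens, sel, 0) == pytest.approx([1, 0, 0])


def test_mass_center_matches_direct_summation():
    rng = np.random.default_rng(3)
    coords = rng.normal(size=(10, 3))
    masses = rng.uniform(1, 20, 10)
    ens, sel = _toy(masses, coords)
    oracle = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    assert np.abs(mass_center(ens, sel, 0) - oracle).max() < 1e-12


def test_kabsch_identical_and_rigid():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(6, 3))
    assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)
    rz = np.array([[0., -1, 0], [1, 0, 0], [0, 0, 1]])  # 90° about z
    b = a @ rz.T + np.array([5.0, 5.0, 5.0])
    assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)


def test_kabsch_matches_quaternion_oracle():
    rng = np.random.default_rng(1)
    for _ in range(20):
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        assert kabsch_rmsd(a, b) == pytest.approx(quaternion_rmsd(a, b),
                                                  abs=1e-9)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_kabsch_symmetric_and_rigid_invariant(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(7, 3))
    b = rng.normal(size=(7, 3))
    r = kabsch_rmsd(a, b)
    assert kabsch_rmsd(b, a) == pytest.approx(r, abs=1e-9)
    rot = random_rotation(rng)
    moved = b @ rot.T + rng.normal(size=3) * 10
    assert kabsch_rmsd(a, moved) == pytest.approx(r, abs=1e-9)


def test_kabsch_degenerate_rejected():
    line = np.outer(np.arange(4.0), np.array([1.0, 0, 0]))
    cloud = np.random.default_rng(0).normal(size=(4, 3))
    with pytest.raises(GeometryError):
        kabsch_rmsd(line, cloud)
    with pytest.raises(GeometryError):
        kabsch_rmsd(cloud[:2], cloud[:2])


def test_rg_examples_and_oracle():
    ens, sel = _toy([1, 1], np.zeros((2, 3)))
    assert radius_of_gyration(ens, sel, 0) == 0.0
    ens, sel = _toy([1, 1], np.array([[0., 0, 0], [2, 0, 0]]))
    assert radius_of_gyration(ens, sel, 0) == pytest.approx(1.0)
    rng = np.random.default_rng(5)
    coords = rng.normal(size=(20, 3)) * 4
    masses = rng.uniform(1, 16, 20)
    ens, sel = _toy(masses, coords)
    center = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    oracle = np.sqrt((masses * ((coords - center) ** 2).sum(axis=1)).sum()
                     / masses.sum())
    assert radius_of_gyration(ens, sel, 0) == pytest.approx(oracle, abs=1e-12)


def test_rg_scales_linearly():
    rng = np.random.default_rng(6)
    coords = rng.normal(size=(8, 3))
    ens, sel = _toy(np.ones(8), coords)
    ens2, sel2 = _toy(np.ones(8), coords * 2.5)
    assert radius_of_gyration(ens2, sel2, 0) == pytest.approx(
        2.5 * radius_of_gyration(ens, sel, 0))


def test_rmsf_static_is_zero():
    coords = np.random.default_rng(0).normal(size=(5, 3))
    ens = make_ensemble([("A", i + 1, "ALA", "CA", "C") for i in range(5)],
                        [coords, coords, coords])
    prof = rmsf(ens, Selection("s", np.arange(5)))
    assert np.abs(prof.rmsf).max() < 1e-12


def test_rmsf_single_frame_rejected():
    coords = np.random.default_rng(0).normal(size=(5, 3))
    ens = make_ensemble([("A", i + 1, "ALA", "CA", "C") for i in range(5)],
                        [coords])
    with pytest.raises(InsufficientDataError):
        rmsf(ens, Selection("s", np.arange(5)))


def test_rmsf_isotropic_jitter_closed_form():
    """Isotropic per-coordinate jitter sigma gives RMSF ~ sigma*sqrt(3)."""
    sigma = 0.5
    ens, _ = gen_complex(GeneratorSpec(seed=9, n_frames=4000,
                                       noise_sigma=sigma))
    prof = rmsf(ens, select(ens, "backbone_sites"))
    # superposition to the mean absorbs ~6/(3N) of the variance
    assert prof.rmsf.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.03)


def test_rmsf_superposition_converged_after_two_iterations():
    """A third mean-structure superposition iteration changes nothing
    measurable: two iterations suffice."""
    ens, _ = gen_complex(GeneratorSpec(seed=3, n_frames=100, noise_sigma=0.4))
    sel = select(ens, "backbone_sites")
    p2 = rmsf(ens, sel, iterations=2)
    p3 = rmsf(ens, sel, iterations=3)
    assert np.abs(p2.rmsf - p3.rmsf).max() < 1e-6


def test_rmsf_time_order_independent():
    ens, _ = gen_complex(GeneratorSpec(seed=2, n_frames=40, noise_sigma=0.4))
    sel = select(ens, "backbone_sites")
    prof = rmsf(ens, sel)
    rng = np.random.default_rng(0)
    shuffled = make_shuffled(ens, rng)
    prof2 = rmsf(shuffled, sel)
    assert np.allclose(prof.rmsf, prof2.rmsf)


def make_shuffled(ens, rng):
    from bindfold import StructureEnsemble
    order = rng.permutation(ens.n_frames)
    return StructureEnsemble(atoms=list(ens.atoms),
                             coords=ens.coords[order])


def test_rmsf_single_mobile_site():
    base = np.random.default_rng(1).normal(size=(4, 3)) * 20
    frames = [base.copy() for _ in range(60)]
    rng = np.random.default_rng(2)
    for f in frames:
        f[2] += rng.normal(0, 1.0, 3)
    ens = make_ensemble([("A", i + 1, "ALA", "CA", "C") for i in range(4)],
                        frames)
    prof = rmsf(ens, Selection("s", np.arange(4)), iterations=0)
    assert prof.rmsf[2] > 1.0
    assert max(prof.rmsf[i] for i in (0, 1, 3)) < 1e-9


def test_pair_to_partner_distance_symmetry_and_drift(folded_complex):
    ens, _ = folded_complex
    # symmetric placement: distance difference of a base to itself is zero
    partner = select(ens, "calpha")
    d_r, d_d, diff = pair_to_partner_distance(
        ens, (("R", 11), ("R", 11)), partner)
    assert np.abs(diff.y).max() < 1e-12
    d_r, d_d, diff = pair_to_partner_distance(
        ens, (("R", 11), ("D", 12)), partner)
    assert diff.y.shape == (ens.n_frames,)
    assert np.allclose(diff.y, d_r.y - d_d.y)


def test_pair_to_partner_distance_monotone_drift():
    """A partner approaching the RNA base linearly gives a decreasing
    RNA-minus-DNA difference series."""
    n = 20
    rows = [("R", 1, "A", "N1", "N"), ("D", 1, "DC", "N1", "N"),
            ("P", 1, "ALA", "CA", "C")]
    frames = []
    for f in range(n):
        partner_y = 30.0 - f  # approaches the RNA base from above
        frames.append(np.array([[0.0, 0, 0], [10.0, 0, 0],
                                [0.0, partner_y, 0.0]]))
    ens = make_ensemble(rows, frames)
    partner = Selection("partner", np.array([2]))
    _, _, diff = pair_to_partner_distance(ens, (("R", 1), ("D", 1)), partner)
    assert np.all(np.diff(diff.y) < 0)
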