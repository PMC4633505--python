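"""Interaction classifiers, populations and native-contact sets."""

import numpy as np
import pytest

from bindfold import (
    GeneratorSpec,
    SitePair,
    StructureEnsemble,
    classify_electrostatic,
    classify_hbond,
    classify_hydrophobic,
    contact_population,
    gen_complex,
    native_contact_set,
)
from bindfold.contacts import scan_contacts
from bindfold.errors import BindfoldError

from conftest import BINDING_GROUPS, make_ensemble


def _two_sidechains(distance):
    """Two ALA residues on different chains with CB centers ``distance`` apart."""
    rows = [("A", 1, "ALA", "CB", "C"), ("B", 1, "ALA", "CB", "C")]
    return make_ensemble(rows, [np.array([[0., 0, 0], [distance, 0, 0]])])


@pytest.mark.parametrize("distance,expected", [
    (6.4, True),   # inside the 6.5 Å cutoff
    (6.6, False),  # outside
    (6.5, False),  # boundary excluded: strictly "closer than"
])
def test_hydrophobic_boundary(distance, expected):
    ens = _two_sidechains(distance)
    assert classify_hydrophobic(ens, ("A", 1), ("B", 1), 0) is expected


def _charged_vs_phosphate(distance, resname="ARG"):
    rows = [("A", 1, resname, "CB", "C"),
            ("D", 2, "DC", "P", "P")]
    return make_ensemble(rows, [np.array([[0., 0, 0], [distance, 0, 0]])])


@pytest.mark.parametrize("distance,expected", [(10.9, True), (11.1, False)])
def test_electrostatic_boundary(distance, expected):
    ens = _charged_vs_phosphate(distance)
    assert classify_electrostatic(ens, ("A", 1), ("D", 2), 0) is expected


def test_electrostatic_requires_positive_residue():
    ens = _charged_vs_phosphate(5.0, resname="ASP")
    with pytest.raises(BindfoldError):
        classify_electrostatic(ens, ("A", 1), ("D", 2), 0)


def test_electrostatic_charged_group_atoms():
    """When the Arg guanidinium atoms are present, the charge center uses
    them, not the whole side chain."""
    rows = [("A", 1, "ARG", "CB", "C"), ("A", 1, "ARG", "NH1", "N"),
            ("A", 1, "ARG", "NH2", "N"),
            ("D", 2, "DC", "P", "P")]
    coords = np.array([[50., 0, 0],   # CB far away: must not matter
                       [10.5, 0, 0], [10.5, 0, 0],
                       [0., 0, 0]])
    ens = make_ensemble(rows, [coords])
    assert classify_electrostatic(ens, ("A", 1), ("D", 2), 0) is True


def test_electrostatic_missing_phosphate_warns_false():
    rows = [("A", 1, "LYS", "CB", "C"), ("D", 1, "DC", "C5'", "C")]
    ens = make_ensemble(rows, [np.zeros((2, 3))])
    with pytest.warns(UserWarning, match="phosphate"):
        assert classify_electrostatic(ens, ("A", 1), ("D", 1), 0) is False


def _hbond_pair(distance):
    """Arg NH1 (donor) against cytosine O2 (acceptor)."""
    rows = [("A", 1, "ARG", "NH1", "N"), ("D", 2, "DC", "O2", "O")]
    return make_ensemble(rows, [np.array([[0., 0, 0], [distance, 0, 0]])])


def test_hbond_detection_and_boundary():
    found = classify_hbond(_hbond_pair(3.1), 0)
    assert len(found) == 1
    assert found[0]["distance_A"] == pytest.approx(3.1)
    assert classify_hbond(_hbond_pair(3.6), 0) == []


def test_hbond_requires_polar_atoms():
    rows = [("A", 1, "ALA", "CB", "C"), ("B", 1, "ALA", "CB", "C")]
    ens = make_ensemble(rows, [np.array([[0., 0, 0], [2.9, 0, 0]])])
    assert classify_hbond(ens, 0) == []


def test_hbond_intra_residue_excluded():
    rows = [("A", 1, "SER", "OG", "O"), ("A", 1, "SER", "N", "N")]
    ens = make_ensemble(rows, [np.array([[0., 0, 0], [2.8, 0, 0]])])
    assert classify_hbond(ens, 0) == []


def _pair_ensemble(distances_per_frame):
    """Two-chain, two-residue ensemble with controlled CB-CB distances."""
    rows = [("A", 1, "ALA", "CB", "C"), ("B", 5, "ALA", "CB", "C")]
    frames = [np.array([[0., 0, 0], [d, 0, 0]]) for d in distances_per_frame]
    return make_ensemble(rows, frames)


def test_native_set_counting_threshold():
    """Pair within 7.5 Å in 6/10 frames is native at threshold 0.5."""
    ens = _pair_ensemble([5.0] * 6 + [9.0] * 4)
    nset = native_contact_set(ens, stability_threshold=0.5)
    assert SitePair(("A", 1), ("B", 5)) in nset.contacts
    with pytest.warns(UserWarning, match="empty"):
        nset_strict = native_contact_set(ens, stability_threshold=0.7)
    assert not nset_strict.contacts


def test_native_set_adjacent_excluded():
    rows = [("A", 1, "ALA", "CB", "C"), ("A", 2, "ALA", "CB", "C"),
            ("A", 3, "ALA", "CB", "C")]
    frames = [np.array([[0., 0, 0], [4.0, 0, 0], [0.0, 4.0, 0]])] * 4
    ens = make_ensemble(rows, frames)
    nset = native_contact_set(ens)
    # i,i+1 pairs excluded; i,i+2 at 5.66 Å included
    assert nset.contacts == frozenset({SitePair(("A", 1), ("A", 3))})


def test_native_set_interchain_never_sequence_excluded():
    ens = _pair_ensemble([7.4] * 5)
    nset = native_contact_set(ens)
    assert SitePair(("A", 1), ("B", 5)) in nset.inter_chain_subset


def test_native_set_nestedness(folded_complex):
    ens, _ = folded_complex
    loose = native_contact_set(ens, stability_threshold=0.5)
    tight = native_contact_set(ens, stability_threshold=1.0)
    assert tight.contacts <= loose.contacts


def test_native_set_groups_partition(native_set):
    union = (native_set.intra_chain_subset | native_set.inter_chain_subset
             | native_set.receptor_internal)
    assert union == native_set.contacts
    for p in native_set.inter_chain_subset:
        chains = {p.site_a[0], p.site_b[0]}
        assert "P" in chains and (chains & {"D", "R"})


def test_planted_contact_sets_recovered(folded_complex, native_set):
    """Pipeline-recovered stable contacts equal the generator's construction
    census exactly (the planted geometry is the oracle)."""
    _, truth = folded_complex
    recovered = {(p.site_a, p.site_b) for p in native_set.contacts}
    assert recovered == truth["native"]
    inter = {(p.site_a, p.site_b) for p in native_set.inter_chain_subset}
    assert inter == truth["native_inter_group"]


def test_planted_population_scan_matches_census(folded_complex):
    ens, truth = folded_complex
    recs = scan_contacts(ens, kinds=("hydrophobic",), interchain_only=False,
                         min_population=0.5)
    rec_pairs = {(r.pair.site_a, r.pair.site_b) for r in recs}
    assert rec_pairs == truth["hydrophobic"]
    recs = scan_contacts(ens, kinds=("electrostatic",), min_population=0.5)
    rec_pairs = {(r.pair.site_a, r.pair.site_b) for r in recs}
    assert rec_pairs == truth["electrostatic"]


@pytest.mark.parametrize("hits,stable", [(30, False), (31, True), (100, True)])
def test_population_stability_cut(hits, stable):
    """Stability requires population strictly above 30%."""
    ens = _pair_ensemble([5.0] * hits + [9.0] * (100 - hits))
    rec = contact_population(
        ens, lambda e, f: classify_hydrophobic(e, ("A", 1), ("B", 5), f),
        SitePair(("A", 1), ("B", 5)), kind="hydrophobic")
    assert rec.population == pytest.approx(hits / 100)
    assert rec.stable is stable


def test_population_frame_permutation_invariant():
    d = [5.0] * 13 + [9.0] * 7
    rng = np.random.default_rng(0)
    pops = []
    for _ in range(3):
        rng.shuffle(d)
        ens = _pair_ensemble(d)
        pops.append(contact_population(
            ens, lambda e, f: classify_hydrophobic(e, ("A", 1), ("B", 5), f),
            SitePair(("A", 1), ("B", 5))).population)
    assert len(set(pops)) == 1


def test_contact_monotone_under_shrinking(folded_complex):
    """Scaling all coordinates by 0.9 never destroys a distance contact."""
    ens, _ = folded_complex
    small = StructureEnsemble(atoms=list(ens.atoms), coords=ens.coords * 0.9)
    before = {(r.pair.site_a, r.pair.site_b)
              for r in scan_contacts(ens, kinds=("hydrophobic",),
                                     interchain_only=False,
                                     min_population=1.0)}
    after = {(r.pair.site_a, r.pair.site_b)
             for r in scan_contacts(small, kinds=("hydrophobic",),
                                    interchain_only=False,
                                    min_population=1.0)}
    assert before <= after


def test_site_pair_canonical_order():
    p = SitePair(("R", 9), ("D", 2))
    assert p.site_a == ("D", 2) and p.site_b == ("R", 9)
    assert p == SitePair(("D", 2), ("R", 9))
    with pytest.raises(BindfoldError):
        SitePair(("A", 1), ("A", 1))
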