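"""Hydrogen-bond detection geometry and tallies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liface import (
    Frame,
    HBond,
    HBondCriteria,
    Topology,
    detect_hbonds,
    tally_lipid_lipid,
    tally_lipid_water,
)
from liface.geometry import LeafletAssignment
from liface.hbonds import minimum_image
from liface.topology import Moiety, MoleculeKind

from conftest import (
    brute_force_hbonds,
    hbond_triples,
    hydroxyl,
    make_atom,
    random_system,
    water_molecule,
)

BOX = np.array([30.0, 30.0, 30.0])


def donor_acceptor_system(d_pos, h_pos, a_pos):
    """Water donor (O+2H) and a lipid acceptor oxygen."""
    atoms = water_molecule(0, 0) + [
        make_atom(3, "OA", 1, MoleculeKind.LIPID, Moiety.ALPHA_RING, acceptor=True)
    ]
    coords = np.array([d_pos, h_pos, np.asarray(d_pos) + [0.3, 0.9, 0.0], a_pos])
    return Frame(time=0.0, coordinates=coords, box=BOX), Topology(atoms)


def test_criteria_validation():
    with pytest.raises(ValueError, match="d_max_heavy"):
        HBondCriteria(d_max_heavy=0.0)
    with pytest.raises(ValueError, match="d_max_heavy"):
        HBondCriteria(d_max_heavy=7.0)
    with pytest.raises(ValueError, match="angle_min"):
        HBondCriteria(angle_min=190.0)


def test_minimum_image_basic():
    box = np.array([10.0, 10.0, 10.0])
    assert np.allclose(minimum_image(np.array([9.0, 0.0, 0.0]), box), [-1.0, 0.0, 0.0])
    assert np.allclose(minimum_image(np.array([-6.0, 4.0, 0.0]), box), [4.0, 4.0, 0.0])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-100, 100), min_size=3, max_size=3))
def test_minimum_image_bounds(delta):
    box = np.array([7.0, 11.0, 13.0])
    out = minimum_image(np.array(delta), box)
    assert np.all(np.abs(out) <= box / 2 + 1e-9)


def test_collinear_bond_detected():
    f, top = donor_acceptor_system([5, 5, 5], [5.95, 5, 5], [7.8, 5, 5])
    found = detect_hbonds(f, top)
    assert hbond_triples(found) == {(0, 1, 3)}
    b = found[0]
    assert b.pair_class == "lipid_water"
    assert b.donor_mol == 0 and b.acceptor_mol == 1
    assert b.acceptor_moiety is Moiety.ALPHA_RING


def test_distance_cutoff_boundary():
    f, top = donor_acceptor_system([5, 5, 5], [5.95, 5, 5], [5 + 3.26, 5, 5])
    assert detect_hbonds(f, top) == []
    f2, top2 = donor_acceptor_system([5, 5, 5], [5.95, 5, 5], [5 + 3.24, 5, 5])
    assert len(detect_hbonds(f2, top2)) == 1


def test_angle_cutoff():
    # place acceptor so that the D-H...A angle is ~140 deg: rejected
    d = np.array([5.0, 5.0, 5.0])
    h = d + np.array([0.95, 0.0, 0.0])
    ang = np.deg2rad(180.0 - 140.0)
    a = h + 2.0 * np.array([np.cos(ang), np.sin(ang), 0.0])
    f, top = donor_acceptor_system(d, h, a)
    assert detect_hbonds(f, top) == []
    # at ~160 deg: accepted
    ang = np.deg2rad(180.0 - 160.0)
    a = h + 2.0 * np.array([np.cos(ang), np.sin(ang), 0.0])
    f, top = donor_acceptor_system(d, h, a)
    assert len(detect_hbonds(f, top)) == 1


def test_pbc_bond_across_boundary():
    # donor near one box face, acceptor just across the periodic boundary
    f, top = donor_acceptor_system([29.5, 5, 5], [29.5 + 0.95, 5, 5], [2.3, 5, 5])
    assert hbond_triples(detect_hbonds(f, top)) == {(0, 1, 3)}


def test_intramolecular_exclusion():
    atoms = hydroxyl(0, 0, Moiety.ALPHA_RING) + [
        make_atom(2, "OG", 0, MoleculeKind.LIPID, Moiety.GLYCEROL, acceptor=True)
    ]
    coords = np.array([[5, 5, 5], [5.95, 5, 5], [7.8, 5, 5]])
    f = Frame(time=0.0, coordinates=coords, box=BOX)
    top = Topology(atoms)
    assert detect_hbonds(f, top, HBondCriteria()) == []
    crit = HBondCriteria(exclude_intramolecular=False)
    assert hbond_triples(detect_hbonds(f, top, crit)) == {(0, 1, 2)}


def test_no_donors_warns():
    atoms = [make_atom(0, "OA", 0, MoleculeKind.LIPID, Moiety.ALPHA_RING, acceptor=True)]
    f = Frame(time=0.0, coordinates=np.zeros((1, 3)) + 5, box=BOX)
    with pytest.warns(UserWarning, match="no donors"):
        assert detect_hbonds(f, Topology(atoms)) == []


def test_detection_matches_bruteforce_small(rng):
    for _ in range(5):
        frame, top = random_system(rng, max_atoms=120)
        got = hbond_triples(detect_hbonds(frame, top))
        assert got == brute_force_hbonds(frame, top, HBondCriteria())


def test_translation_invariance(rng):
    frame, top = random_system(rng, max_atoms=100)
    ref = hbond_triples(detect_hbonds(frame, top))
    for _ in range(5):
        shift = rng.uniform(-50, 50, size=3)
        f2 = Frame(time=0.0, coordinates=frame.coordinates + shift, box=frame.box)
        assert hbond_triples(detect_hbonds(f2, top)) == ref


def test_output_sorted_and_deterministic(rng):
    frame, top = random_system(rng, max_atoms=200)
    out = detect_hbonds(frame, top)
    keys = [(b.frame_time, b.donor_heavy, b.hydrogen, b.acceptor) for b in out]
    assert keys == sorted(keys)
    assert detect_hbonds(frame, top) == out


# ---------------------------------------------------------------------------
# Tallies
# ---------------------------------------------------------------------------

def lipid_head(first_id: int, mol: int) -> list:
    """Minimal lipid: OA/HA hydroxyl + OG acceptor."""
    atoms = hydroxyl(first_id, mol, Moiety.ALPHA_RING)
    atoms[0].atom_name, atoms[1].atom_name = "OA", "HA"
    og = make_atom(first_id + 2, "OG", mol, MoleculeKind.LIPID, Moiety.GLYCEROL,
                   acceptor=True)
    return atoms + [og]


def lw_bond(t, lipid, water_first, lipid_first, moiety=Moiety.ALPHA_RING,
            lipid_is_donor=False):
    if lipid_is_donor:
        return HBond(t, lipid_first, lipid_first + 1, water_first, lipid,
                     water_mol_of(water_first), "lipid_water", moiety, Moiety.WATER)
    return HBond(t, water_first, water_first + 1, lipid_first, water_mol_of(water_first),
                 lipid, "lipid_water", Moiety.WATER, moiety)


def water_mol_of(first_id):
    # waters laid out after 2 lipids of 3 atoms each in the shared tally topology
    return 2 + (first_id - 6) // 3


@pytest.fixture
def tally_topology():
    atoms = lipid_head(0, 0) + lipid_head(3, 1) + water_molecule(6, 2) + water_molecule(9, 3)
    return Topology(atoms)


def test_tally_three_bonds_two_waters(tally_topology):
    """3 lipid-water bonds to lipid 0 via 2 distinct waters."""
    t = 0.0
    bonds = [
        lw_bond(t, 0, 6, 0),                       # water 2 -> OA (ring via O)
        lw_bond(t, 0, 6, 2, Moiety.GLYCEROL),      # water 2 -> OG
        lw_bond(t, 0, 9, 0, lipid_is_donor=True),  # OA-HA -> water 3 (ring via H)
    ]
    df = tally_lipid_water(bonds, tally_topology, [t])
    m = df["mean"]
    # means are over both lipids (lipid 1 has nothing)
    assert m["hbonds_per_head"] == pytest.approx(1.5)
    assert m["hbonds_rings"] == pytest.approx(1.0)
    assert m["hbonds_rings_via_H"] == pytest.approx(0.5)
    assert m["hbonds_rings_via_O"] == pytest.approx(0.5)
    assert m["hbonds_alpha_ring"] == pytest.approx(1.0)
    assert m["hbonds_beta_ring"] == 0.0
    assert m["hbonds_gly"] == pytest.approx(0.5)
    assert m["hbonded_waters_per_head"] == pytest.approx(1.0)
    # one frame -> population SD is zero everywhere
    assert (df["sd"] == 0.0).all()


def test_tally_lipid_water_multi_frame_sd(tally_topology):
    bonds = [lw_bond(0.0, 0, 6, 0)]  # frame 1.0 has no bonds
    df = tally_lipid_water(bonds, tally_topology, [0.0, 1.0])
    assert df.loc["hbonds_per_head", "mean"] == pytest.approx(0.25)
    assert df.loc["hbonds_per_head", "sd"] == pytest.approx(0.25)


def test_tally_lipid_water_region_restriction(tally_topology):
    bonds = [lw_bond(0.0, 0, 6, 0)]
    df = tally_lipid_water(bonds, tally_topology, [0.0], lipid_ids=[1])
    assert df.loc["hbonds_per_head", "mean"] == 0.0
    with pytest.raises(ValueError, match="no lipids"):
        tally_lipid_water(bonds, tally_topology, [0.0], lipid_ids=[])


def test_tally_lipid_lipid_orientations(tally_topology):
    leaf = LeafletAssignment(labels={0: 0, 1: 1}, n_leaflets=2)
    bond = HBond(0.0, 0, 1, 3, 0, 1, "lipid_lipid", Moiety.ALPHA_RING, Moiety.ALPHA_RING)
    df = tally_lipid_lipid([bond], tally_topology, leaf, [0.0])
    # one bond, two endpoint heads, two lipids -> 1.0 per head
    assert df.loc["hbond_head_head_vertical", "mean"] == pytest.approx(1.0)
    assert df.loc["hbond_head_head_horizontal", "mean"] == 0.0
    assert df.loc["hbond_head_head_total", "mean"] == pytest.approx(1.0)
    assert df.loc["hbond_alpha_alpha", "mean"] == pytest.approx(1.0)

    leaf_h = LeafletAssignment(labels={0: 0, 1: 0}, n_leaflets=2)
    df2 = tally_lipid_lipid([bond], tally_topology, leaf_h, [0.0])
    assert df2.loc["hbond_head_head_horizontal", "mean"] == pytest.approx(1.0)
    assert df2.loc["hbond_head_head_vertical", "mean"] == 0.0
    # total = horizontal + vertical in both cases
    for d in (df, df2):
        assert d.loc["hbond_head_head_total", "mean"] == pytest.approx(
            d.loc["hbond_head_head_horizontal", "mean"]
            + d.loc["hbond_head_head_vertical", "mean"]
        )


def test_tally_lipid_lipid_missing_leaflet_label(tally_topology):
    leaf = LeafletAssignment(labels={0: 0}, n_leaflets=2)
    bond = HBond(0.0, 0, 1, 3, 0, 1, "lipid_lipid", Moiety.ALPHA_RING, Moiety.GLYCEROL)
    with pytest.raises(ValueError, match="leaflet"):
        tally_lipid_lipid([bond], tally_topology, leaf, [0.0])
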