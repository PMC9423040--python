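"""Leaflet assignment and interface geometry."""

import numpy as np
import pytest

from liface import (
    Frame,
    Trajectory,
    area_per_lipid,
    assign_leaflets,
    bilayer_width,
    electron_density_profile,
    head_vector_angles,
    interface_overlap_probability,
    ring_plane_angle,
)
from liface.geometry import (
    DegenerateGeometryError,
    DensityProfile,
    LeafletAssignment,
    _histogram_angles,
    _plane_normal,
)
from liface.synth import FixtureSpec, generate_angle_cloud, generate_fixture


@pytest.fixture(scope="module")
def bilayer():
    return generate_fixture(FixtureSpec(n_lipids_per_leaflet=4, n_leaflets=2, seed=5))


@pytest.fixture(scope="module")
def double_bilayer():
    return generate_fixture(FixtureSpec(n_lipids_per_leaflet=4, n_leaflets=4, seed=5))


def test_assign_leaflets_two(bilayer):
    top, traj, man = bilayer
    leaf = assign_leaflets(traj, top, n_leaflets=2)
    assert leaf.labels == man.leaflet_labels
    assert leaf.n_leaflets == 2
    assert leaf.leaflet_positions is not None
    assert leaf.leaflet_positions[0] < leaf.leaflet_positions[1]


def test_assign_leaflets_four(double_bilayer):
    top, traj, man = double_bilayer
    leaf = assign_leaflets(traj, top, n_leaflets=4)
    assert leaf.labels == man.leaflet_labels
    assert np.all(np.diff(leaf.leaflet_positions) > 0)


def test_outward_signs():
    leaf = LeafletAssignment(labels={0: 0, 1: 1, 2: 2, 3: 3}, n_leaflets=4)
    assert [leaf.outward_sign(k) for k in range(4)] == [-1, 1, -1, 1]


def test_assign_leaflets_errors(bilayer):
    top, traj, _ = bilayer
    with pytest.raises(ValueError, match="n_leaflets"):
        assign_leaflets(traj, top, n_leaflets=3)
    flat = Frame(time=0.0, coordinates=np.zeros_like(traj[0].coordinates) + 5.0,
                 box=traj[0].box)
    with pytest.raises(DegenerateGeometryError):
        assign_leaflets(flat, top, n_leaflets=2)


def test_area_per_lipid(bilayer):
    top, traj, _ = bilayer
    leaf = assign_leaflets(traj, top, n_leaflets=2)
    # 4 lipids per leaflet on a 10 A lattice: 2x2 cells -> 20x20 box
    al = area_per_lipid(traj[0], leaf)
    assert al["mean"] == pytest.approx(100.0)
    assert al["per_leaflet"][0] == pytest.approx(100.0)


def test_bilayer_widths(bilayer):
    top, traj, _ = bilayer
    leaf = assign_leaflets(traj, top, n_leaflets=2)
    # leaflet planes at -20/+20; the electron-weighted COM of the
    # ring-moiety atoms sits ~1.67 A outward of each anchor plane
    d_rr, sd_rr = bilayer_width(traj, top, leaf, mode="D_RR")
    assert d_rr == pytest.approx(43.346, abs=0.05)
    d_cc, sd_cc = bilayer_width(traj, top, leaf, mode="D_CC", atom_name="C2P")
    assert d_cc == pytest.approx(40.0, abs=0.05)
    assert d_rr > d_cc
    with pytest.raises(ValueError, match="unknown width mode"):
        bilayer_width(traj, top, leaf, mode="D_XX")
    with pytest.raises(ValueError, match="not found"):
        bilayer_width(traj, top, leaf, mode="D_CC", atom_name="NOPE")


def test_head_vector_angle_closed_form():
    for angle in (0.0, 45.0, 90.0):
        top, traj, man = generate_angle_cloud(
            FixtureSpec(n_lipids_per_leaflet=9, n_leaflets=2, seed=11,
                        head_vector_angle=angle))
        leaf = man.leaflets()
        dist = head_vector_angles(traj, top, leaf, ("C2P", "O4P"))
        assert np.allclose(dist.samples, angle, atol=1e-6)
        assert abs(dist.mode_deg - angle) <= 2.0  # within one bin width


def test_head_vector_angle_leaflet_symmetric():
    # both leaflets planted at 30 deg from their *outward* normals must
    # yield one 30-deg population, not 30 and 150
    top, traj, man = generate_angle_cloud(
        FixtureSpec(n_lipids_per_leaflet=6, n_leaflets=2, seed=2,
                    head_vector_angle=30.0))
    dist = head_vector_angles(traj, top, man.leaflets(), ("C2P", "O4P"))
    assert np.allclose(dist.samples, 30.0, atol=1e-6)


def test_angle_histogram_normalisation_and_tie():
    dist = _histogram_angles(np.array([10.0, 10.1, 50.0, 50.2]), bin_width=2.0)
    assert np.isclose((dist.probability * 2.0).sum(), 1.0)
    # two bins tie with 2 samples each; the smaller angle wins
    assert dist.mode_deg == 11.0
    with pytest.raises(ValueError, match="no angle samples"):
        _histogram_angles(np.array([]), bin_width=2.0)


def test_plane_normal_and_ring_angle():
    pts = np.array([[1.0, 0, 0], [0, 1.0, 0], [-1.0, 0, 0], [0, -1.0, 0]])
    n = _plane_normal(pts)
    assert np.allclose(n, [0, 0, 1])
    with pytest.raises(DegenerateGeometryError, match="collinear"):
        _plane_normal(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.0, 0, 0]]))


def test_ring_plane_angle_closed_form():
    for dihedral in (0.0, 30.0, 82.0, 162.0):
        top, traj, man = generate_angle_cloud(
            FixtureSpec(n_lipids_per_leaflet=4, n_leaflets=2, seed=4,
                        ring_dihedral=dihedral))
        dist = ring_plane_angle(
            traj, top, ["RA1", "RA2", "RA3", "RA4"], ["RB1", "RB2", "RB3", "RB4"])
        assert np.allclose(dist.samples, dihedral, atol=1e-6)


def test_electron_density_conservation(bilayer):
    top, traj, _ = bilayer
    sel = {
        "lipid": np.nonzero([a.molecule_kind.value == "lipid" for a in top.atoms])[0],
    }
    prof = electron_density_profile(traj, top, sel, bin_width=1.0)
    expected = float(top.electron_counts[sel["lipid"]].sum())
    assert prof.total_electrons("lipid") == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError, match="bin_width"):
        electron_density_profile(traj, top, sel, bin_width=0.0)


def test_interface_overlap_half():
    edges = np.linspace(0.0, 8.0, 9)
    ch3 = DensityProfile(axis=2, bin_edges=edges,
                         densities={"ch3": np.ones(8)}, cross_section=1.0, n_frames=1)
    wat = np.zeros(8)
    wat[[0, 1, 6, 7]] = 5.0  # half of each side is watered
    water = DensityProfile(axis=2, bin_edges=edges,
                           densities={"water": wat}, cross_section=1.0, n_frames=1)
    out = interface_overlap_probability(ch3, water, midplane=4.0)
    assert out["lower"] == 0.5
    assert out["upper"] == 0.5
    assert out["mean"] == 0.5


def test_interface_overlap_binning_mismatch():
    e1 = np.linspace(0, 8, 9)
    e2 = np.linspace(0, 8, 5)
    a = DensityProfile(2, e1, {"ch3": np.ones(8)}, 1.0, 1)
    b = DensityProfile(2, e2, {"water": np.ones(4)}, 1.0, 1)
    with pytest.raises(ValueError, match="binning"):
        interface_overlap_probability(a, b)
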