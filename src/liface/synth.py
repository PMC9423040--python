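"""Synthetic membrane fixtures with planted, manifest-backed interactions.

No trajectories are deposited with galactolipid interface studies, so every
pipeline stage is exercised on generated systems whose ground truth is
known by construction:

* lamellar (2-leaflet) and double-bilayer (4-leaflet) layouts of a
  simplified head-group lipid on a lattice, with waters positioned to
  realise an exact planted set of H-bonds and water bridges (horizontal
  and vertical),
* per-edge on/off schedules realised as graph series for lifetime
  statistics, and
* head-vector / ring-plane / density clouds at prescribed angles and
  distributions.

The simplified lipid (residue ``SLX``) carries only head-group moiety
sites (α-ring and β-ring hydroxyls, an acceptor-only ring oxygen, a
glycerol acceptor), four inert ring atoms per ring for plane fits, and a
terminal-CH₃ proxy — the analysis never needs chemically complete lipids.

Planted geometry uses a donor–acceptor distance of 2.8 Å and collinear
D–H···A arrangements, leaving a wide margin to the default detection
criterion; coordinate noise is bounded so the planted set stays detected
and nothing else comes within range.  After building each fixture the
generator *verifies* it by running the geometric detectors and comparing
against the manifest, raising :class:`GenerationError` on any mismatch.
All randomness flows from a single seeded generator, so identical
(spec, seed) produce identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .bridges import detect_water_bridges
from .geometry import LeafletAssignment
from .hbonds import HBondCriteria, detect_hbonds
from .io import Frame, Trajectory
from .topology import Moiety, Topology, default_annotation_config

__all__ = [
    "GenerationError",
    "PlantedHBond",
    "PlantedBridge",
    "EdgeSchedule",
    "FixtureSpec",
    "FixtureManifest",
    "generate_fixture",
    "generate_edge_schedule_trajectory",
    "generate_angle_cloud",
    "exponential_schedule",
    "component_graph",
]

MAX_NOISE_AMPLITUDE = 0.10  # Å; keeps 2.8 Å / 180° plants inside 3.25 Å / 150°
BOND_LENGTH = 2.8  # planted donor–acceptor distance, Å
OH_LENGTH = 0.95  # O–H bond length, Å

# per-lipid atom template: (name, offsets relative to the anchor, with the
# membrane-normal component scaled by the leaflet's outward sign)
_LIPID_ATOMS = [
    "C2P", "OG", "OA", "HA", "OB", "HB", "O4P",
    "RA1", "RA2", "RA3", "RA4", "RB1", "RB2", "RB3", "RB4", "CM",
]
_WATER_ATOMS = ["OW", "HW1", "HW2"]


class GenerationError(RuntimeError):
    """Fixture spec cannot be realised (packing, roles, or noise margin)."""


@dataclass(frozen=True)
class PlantedHBond:
    """A planted H-bond: lipid↔water or direct lipid↔lipid."""

    lipid: int  # global lipid index
    moiety: str  # alpha_ring | beta_ring | glycerol
    donor: str = "water"  # which side donates: "water" | "lipid" (first lipid for pairs)
    partner_lipid: int | None = None  # set for direct lipid–lipid bonds
    partner_moiety: str | None = None


@dataclass(frozen=True)
class PlantedBridge:
    """A planted water bridge between two lipids."""

    lipid_a: int
    moiety_a: str
    lipid_b: int
    moiety_b: str
    water_role: str = "double_donor"  # double_donor | double_acceptor | mixed


@dataclass(frozen=True)
class EdgeSchedule:
    node_a: int
    node_b: int
    on_frames: tuple[int, ...]
    kind: str = "hbond"  # hbond | wb


@dataclass
class FixtureSpec:
    """Full description of a synthetic fixture."""

    n_lipids_per_leaflet: int = 4
    n_leaflets: int = 2
    lattice_spacing: float = 10.0  # Å
    n_frames: int = 1
    dt: float = 1.0  # ps
    noise_amplitude: float = 0.05  # Å, uniform per coordinate
    seed: int = 0
    planted_hbonds: tuple[PlantedHBond, ...] = ()
    planted_bridges: tuple[PlantedBridge, ...] = ()
    # schedule fixtures
    n_nodes: int = 10
    edge_schedules: tuple[EdgeSchedule, ...] = ()
    # angle/density cloud fixtures
    head_vector_angle: float | None = None  # degrees from the outward normal
    ring_dihedral: float | None = None  # degrees between ring planes
    ch3_sigma: float = 3.0  # Å spread of the CH3 cloud around its leaflet centre
    n_free_waters: int = 0

    @property
    def n_lipids(self) -> int:
        return self.n_lipids_per_leaflet * self.n_leaflets


@dataclass
class FixtureManifest:
    """Ground truth of a generated fixture."""

    spec: FixtureSpec
    # planted H-bond triples as global atom ids (identical in every frame)
    hbond_triples: list[tuple[int, int, int]]
    # bridge records: dicts matching WaterBridge fields (minus frame_time)
    bridge_records: list[dict]
    leaflet_labels: dict[int, int]  # lipid molecule id -> leaflet
    n_lipids: int = 0
    n_waters: int = 0
    resnames: list[str] = field(default_factory=list)
    schedule_runs: list[int] | None = None  # analytic run lengths (frames)

    # -- expected tallies, computed by plain counting -----------------------
    def leaflets(self) -> LeafletAssignment:
        return LeafletAssignment(
            labels=dict(self.leaflet_labels),
            n_leaflets=self.spec.n_leaflets,
            normal_axis=2,
        )

    def expected_lipid_water(self) -> dict[str, float]:
        """Per-head means of the lipid–water summary rows.

        Counts both the directly planted lipid–water bonds and the two
        H-bonds each planted bridge's water makes with its lipids.
        """
        n = self.n_lipids
        acc = dict.fromkeys(
            ["hbonds_per_head", "hbonds_rings", "hbonds_rings_via_H",
             "hbonds_rings_via_O", "hbonds_alpha_ring", "hbonds_beta_ring",
             "hbonds_gly"], 0.0)
        distinct_waters = 0  # every planted water is unique to its bond/bridge

        def add(lipid: int, moiety: str, lipid_donates: bool) -> None:
            acc["hbonds_per_head"] += 1
            if moiety in ("alpha_ring", "beta_ring"):
                acc["hbonds_rings"] += 1
                acc["hbonds_rings_via_H" if lipid_donates else "hbonds_rings_via_O"] += 1
                acc["hbonds_alpha_ring" if moiety == "alpha_ring" else "hbonds_beta_ring"] += 1
            elif moiety == "glycerol":
                acc["hbonds_gly"] += 1

        waters_touching = 0
        for p in self._planted_lw():
            add(p.lipid, p.moiety, p.donor == "lipid")
            waters_touching += 1
        for b in self.spec.planted_bridges:
            a_donates = b.water_role == "double_acceptor"
            b_donates = b.water_role in ("double_acceptor", "mixed")
            add(b.lipid_a, b.moiety_a, a_donates)
            add(b.lipid_b, b.moiety_b, b_donates)
            waters_touching += 2  # one distinct water seen by two lipids
        out = {k: v / n for k, v in acc.items()}
        out["hbonded_waters_per_head"] = waters_touching / n
        return out

    def _planted_lw(self) -> list[PlantedHBond]:
        return [p for p in self.spec.planted_hbonds if p.partner_lipid is None]

    def expected_bridge_counts(self) -> dict[str, float]:
        """Per-head means of the water-bridge summary rows."""
        n = self.n_lipids
        keys = ["wb_per_head", "wb_ring_ring", "wb_alpha_alpha", "wb_alpha_beta",
                "wb_beta_beta", "wb_gly_gly", "wb_gly_ring",
                "wb_horizontal", "wb_vertical", "wb_total"]
        acc = dict.fromkeys(keys, 0.0)
        for r in self.bridge_records:
            acc["wb_per_head"] += 2
            acc["wb_total"] += 2
            acc[f"wb_{r['orientation']}"] += 2
            cat = _pair_category(r["moiety_a"], r["moiety_b"])
            if cat in ("alpha_alpha", "alpha_beta", "beta_beta"):
                acc["wb_ring_ring"] += 2
                acc[f"wb_{cat}"] += 2
            elif cat:
                acc[f"wb_{cat}"] += 2
        return {k: v / n for k, v in acc.items()}

    def expected_lipid_lipid_counts(self) -> dict[str, float]:
        """Per-head means of the direct lipid–lipid H-bond rows."""
        n = self.n_lipids
        acc = {"hbond_head_head_horizontal": 0.0, "hbond_head_head_vertical": 0.0,
               "hbond_head_head_total": 0.0}
        for p in self.spec.planted_hbonds:
            if p.partner_lipid is None:
                continue
            la = self.leaflet_labels[p.lipid]
            lb = self.leaflet_labels[p.partner_lipid]
            orient = "horizontal" if la == lb else "vertical"
            acc[f"hbond_head_head_{orient}"] += 2
            acc["hbond_head_head_total"] += 2
        return {k: v / n for k, v in acc.items()}


def _pair_category(ma: str, mb: str) -> str | None:
    ring = {"alpha_ring", "beta_ring"}
    if ma in ring and mb in ring:
        pair = tuple(sorted([ma, mb]))
        return {("alpha_ring", "alpha_ring"): "alpha_alpha",
                ("alpha_ring", "beta_ring"): "alpha_beta",
                ("beta_ring", "beta_ring"): "beta_beta"}[pair]
    if ma == "glycerol" and mb == "glycerol":
        return "gly_gly"
    if "glycerol" in (ma, mb) and (ma in ring or mb in ring):
        return "gly_ring"
    return None


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GenerationError("degenerate direction in fixture construction")
    return v / n


def _ring_points(center: np.ndarray, e1: np.ndarray, e2: np.ndarray, radius: float = 0.8):
    """Four ring atoms whose oriented plane normal is e1 × e2."""
    pts = []
    for phi in (0.0, 0.5 * np.pi, np.pi, 1.5 * np.pi):
        pts.append(center + radius * (np.cos(phi) * e1 + np.sin(phi) * e2))
    return pts


class _Builder:
    """Accumulates atom positions; enforces one placement per planted site."""

    def __init__(self, spec: FixtureSpec):
        self.spec = spec
        n = spec.n_lipids_per_leaflet
        self.n_cols = int(math.ceil(math.sqrt(n)))
        self.n_rows = int(math.ceil(n / self.n_cols))
        a = spec.lattice_spacing
        self.box_xy = np.array([self.n_cols * a, self.n_rows * a])
        if spec.n_leaflets == 2:
            self.leaflet_z = np.array([-20.0, 20.0])
            self.box_z = 60.0
        elif spec.n_leaflets == 4:
            self.leaflet_z = np.array([-45.0, -15.0, 15.0, 45.0])
            self.box_z = 120.0
        else:
            raise GenerationError("n_leaflets must be 2 or 4")
        self.box = np.array([self.box_xy[0], self.box_xy[1], self.box_z])
        self.overrides: dict[tuple[int, str], np.ndarray] = {}
        self.waters: list[dict] = []  # {"OW":…, "HW1":…, "HW2":…}

    # lattice anchor of a lipid (z at its leaflet plane, centred box frame)
    def anchor(self, lipid: int) -> np.ndarray:
        leaf, k = divmod(lipid, self.spec.n_lipids_per_leaflet)
        i, j = divmod(k, self.n_cols)
        a = self.spec.lattice_spacing
        return np.array([(j + 0.5) * a, (i + 0.5) * a, self.leaflet_z[leaf]])

    def leaflet_of(self, lipid: int) -> int:
        return lipid // self.spec.n_lipids_per_leaflet

    def outward(self, lipid: int) -> float:
        return -1.0 if self.leaflet_of(lipid) % 2 == 0 else 1.0

    def set_atom(self, lipid: int, name: str, pos: np.ndarray) -> None:
        key = (lipid, name)
        if key in self.overrides:
            raise GenerationError(
                f"site atom {name} of lipid {lipid} needed by two planted interactions"
            )
        self.overrides[key] = np.asarray(pos, dtype=float)

    def add_water(self, ow, hw1, hw2) -> int:
        self.waters.append({"OW": np.asarray(ow, float),
                            "HW1": np.asarray(hw1, float),
                            "HW2": np.asarray(hw2, float)})
        return len(self.waters) - 1

    def default_positions(self, lipid: int) -> dict[str, np.ndarray]:
        p = self.anchor(lipid)
        w = self.outward(lipid)

        def off(x, y, z):
            return p + np.array([x, y, z * w])

        d: dict[str, np.ndarray] = {
            "C2P": off(0.0, 0.0, 0.0),
            "OG": off(1.2, 0.0, 0.3),
            "OA": off(-1.2, 0.8, 0.5),
            "OB": off(0.8, -1.0, 0.6),
            "O4P": off(0.0, 0.0, 3.0),
            "CM": off(0.0, 0.0, -12.0),
        }
        d["HA"] = d["OA"] + OH_LENGTH * _unit(np.array([-1.0, 1.0, w]))
        d["HB"] = d["OB"] + OH_LENGTH * _unit(np.array([1.0, -1.0, w]))
        ex, ey, ez = np.eye(3)
        for nm, pt in zip(["RA1", "RA2", "RA3", "RA4"],
                          _ring_points(off(-1.2, 0.8, 1.8), ex, ey)):
            d[nm] = pt
        for nm, pt in zip(["RB1", "RB2", "RB3", "RB4"],
                          _ring_points(off(0.8, -1.0, 1.9), ex, ey)):
            d[nm] = pt
        return d


_SITE_FOR = {
    # (moiety, lipid_donates) -> (heavy atom, hydrogen or None)
    ("alpha_ring", True): ("OA", "HA"),
    ("alpha_ring", False): ("OA", None),
    ("beta_ring", True): ("OB", "HB"),
    ("beta_ring", False): ("O4P", None),
    ("glycerol", False): ("OG", None),
}


def _site(builder: _Builder, lipid: int, moiety: str, lipid_donates: bool):
    key = (moiety, lipid_donates)
    if key not in _SITE_FOR:
        raise GenerationError(
            f"moiety {moiety!r} cannot act as {'donor' if lipid_donates else 'acceptor'}"
            " in the synthetic lipid (glycerol is acceptor-only)"
        )
    return _SITE_FOR[key]


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def _plant_lipid_water(builder: _Builder, p: PlantedHBond, azimuth_counter: dict) -> dict:
    """Place one water realising a lipid–water H-bond; returns manifest info."""
    lipid_donates = p.donor == "lipid"
    heavy, hydro = _site(builder, p.lipid, p.moiety, lipid_donates)
    defaults = builder.default_positions(p.lipid)
    site = defaults[heavy]
    w = builder.outward(p.lipid)
    k = azimuth_counter.get(p.lipid, 0)
    azimuth_counter[p.lipid] = k + 1
    phi = math.radians(180.0 * k + 37.0)  # spread waters of one lipid apart
    theta = math.radians(60.0)  # tilt from the outward normal
    u = np.array([math.sin(theta) * math.cos(phi),
                  math.sin(theta) * math.sin(phi),
                  w * math.cos(theta)])
    ow = site + BOND_LENGTH * u
    zhat = np.array([0.0, 0.0, w])
    if lipid_donates:
        builder.set_atom(p.lipid, hydro, site + OH_LENGTH * u)
        hw1 = ow + OH_LENGTH * zhat
        hw2 = ow + OH_LENGTH * _unit(u + zhat)
        water = builder.add_water(ow, hw1, hw2)
        return {"water": water, "donor_side": "lipid", "heavy": heavy, "hydrogen": hydro}
    else:
        hw1 = ow - OH_LENGTH * u  # collinear with the acceptor
        hw2 = ow + OH_LENGTH * zhat
        water = builder.add_water(ow, hw1, hw2)
        return {"water": water, "donor_side": "water", "heavy": heavy, "hydrogen": "HW1"}


def _bridge_frame(builder: _Builder, la: int, lb: int):
    """Midpoint, separation direction and apex direction for a planted pair."""
    pa, pb = builder.anchor(la), builder.anchor(lb)
    horizontal = builder.leaflet_of(la) == builder.leaflet_of(lb)
    if horizontal:
        lat = np.linalg.norm((pb - pa)[:2])
        if not (0.0 < lat <= builder.spec.lattice_spacing * 1.5):
            raise GenerationError(
                f"lipids {la},{lb}: horizontal plant needs lattice-adjacent lipids"
            )
        wsign = builder.outward(la)
        m = 0.5 * (pa + pb) + np.array([0.0, 0.0, 1.5 * wsign])
        e = _unit(pb - pa)
        apex = np.array([0.0, 0.0, wsign])
    else:
        if np.linalg.norm((pb - pa)[:2]) > 1e-6:
            raise GenerationError(
                f"lipids {la},{lb}: vertical plant needs laterally aligned lipids"
            )
        if abs(pa[2] - pb[2]) > 31.0:
            raise GenerationError(
                f"lipids {la},{lb}: vertical plant needs apposing inner leaflets"
            )
        m = 0.5 * (pa + pb)
        e = _unit(pb - pa)
        apex = np.array([1.0, 0.0, 0.0])
    return m, e, apex, horizontal


def _plant_bridge(builder: _Builder, b: PlantedBridge) -> dict:
    m, e, apex, horizontal = _bridge_frame(builder, b.lipid_a, b.lipid_b)
    half = 2.5
    rise = math.sqrt(BOND_LENGTH**2 - half**2)
    sites = {}
    for lipid, moiety, sgn in ((b.lipid_a, b.moiety_a, -1.0), (b.lipid_b, b.moiety_b, +1.0)):
        donates = (
            b.water_role == "double_acceptor"
            or (b.water_role == "mixed" and sgn > 0)
        )
        heavy, hydro = _site(builder, lipid, moiety, donates)
        pos = m + sgn * half * e
        builder.set_atom(lipid, heavy, pos)
        sites[sgn] = (lipid, heavy, hydro, pos, donates)
    ow = m + rise * apex
    hws = {}
    spare = [_unit(apex + e), _unit(apex - e)]
    for sgn in (-1.0, +1.0):
        lipid, heavy, hydro, pos, donates = sites[sgn]
        if donates:
            builder.set_atom(lipid, hydro, pos + OH_LENGTH * _unit(ow - pos))
        else:
            hws[sgn] = ow + OH_LENGTH * _unit(pos - ow)
        # keep a displaced hydroxyl's hydrogen with its heavy atom
        if not donates and hydro is not None:
            builder.set_atom(lipid, hydro, pos + OH_LENGTH * _unit(apex + sgn * e))
    hw_list = [hws[s] for s in sorted(hws)]
    while len(hw_list) < 2:
        hw_list.append(ow + OH_LENGTH * spare[len(hw_list) % 2])
    water = builder.add_water(ow, hw_list[0], hw_list[1])
    return {
        "water": water,
        "orientation": "horizontal" if horizontal else "vertical",
    }


def _plant_direct(builder: _Builder, p: PlantedHBond) -> dict:
    """Direct lipid–lipid H-bond; p.lipid donates iff p.donor == 'lipid'."""
    if p.donor not in ("lipid", "partner"):
        raise GenerationError("direct lipid–lipid plant needs donor='lipid' or 'partner'")
    donor_lipid, donor_moiety = (p.lipid, p.moiety)
    acc_lipid, acc_moiety = (p.partner_lipid, p.partner_moiety)
    if p.donor == "partner":
        donor_lipid, donor_moiety, acc_lipid, acc_moiety = (
            acc_lipid, acc_moiety, donor_lipid, donor_moiety)
    m, e, apex, horizontal = _bridge_frame(builder, donor_lipid, acc_lipid)
    half = 1.4
    d_heavy, d_hydro = _site(builder, donor_lipid, donor_moiety, True)
    a_heavy, a_hydro = _site(builder, acc_lipid, acc_moiety, False)
    d_pos = m - half * e
    a_pos = m + half * e
    builder.set_atom(donor_lipid, d_heavy, d_pos)
    builder.set_atom(donor_lipid, d_hydro, d_pos + OH_LENGTH * e)
    builder.set_atom(acc_lipid, a_heavy, a_pos)
    if a_hydro is not None:
        builder.set_atom(acc_lipid, a_hydro, a_pos + OH_LENGTH * _unit(e + apex))
    return {"donor_lipid": donor_lipid, "d_heavy": d_heavy, "d_hydro": d_hydro,
            "acc_lipid": acc_lipid, "a_heavy": a_heavy}


def _assemble(builder: _Builder, spec: FixtureSpec, rng: np.random.Generator):
    """Atom tables + coordinates from defaults, overrides and waters."""
    names: list[str] = []
    resnames: list[str] = []
    mol_ids: list[int] = []
    coords: list[np.ndarray] = []
    for lipid in range(spec.n_lipids):
        defaults = builder.default_positions(lipid)
        for nm in _LIPID_ATOMS:
            names.append(nm)
            resnames.append("SLX")
            mol_ids.append(lipid)
            coords.append(builder.overrides.get((lipid, nm), defaults[nm]))
    for wi, wat in enumerate(builder.waters):
        for nm in _WATER_ATOMS:
            names.append(nm)
            resnames.append("SOL")
            mol_ids.append(spec.n_lipids + wi)
            coords.append(wat[nm])
    xyz = np.array(coords)
    # free bulk waters on a coarse lattice in the outer water slabs,
    # alternating between the top and bottom slab (centred frame)
    if spec.n_free_waters:
        z_slab = builder.box_z / 2.0 - 4.0
        a = 7.0
        ncol = max(1, int(builder.box_xy[0] // a))
        nrow = max(1, int(builder.box_xy[1] // a))
        extra = []
        for idx in range(spec.n_free_waters):
            side = 1.0 if idx % 2 == 0 else -1.0
            k = idx // 2
            i, j = divmod(k, ncol)
            if i >= nrow:
                raise GenerationError("too many free waters for the box")
            ow = np.array([(j + 0.5) * a, (i + 0.5) * a, side * z_slab])
            hw1 = ow + OH_LENGTH * np.array([0.0, 0.0, side])
            hw2 = ow + OH_LENGTH * np.array([1.0, 0.0, 0.0])
            for nm, pos in zip(_WATER_ATOMS, (ow, hw1, hw2)):
                names.append(nm)
                resnames.append("SOL")
                mol_ids.append(spec.n_lipids + len(builder.waters) + idx)
                extra.append(pos)
        xyz = np.vstack([xyz, np.array(extra)]) if len(xyz) else np.array(extra)
    # shift to a positive box frame
    xyz = xyz + np.array([0.0, 0.0, builder.box_z / 2.0])
    return names, resnames, mol_ids, xyz


def generate_fixture(spec: FixtureSpec) -> tuple[Topology, Trajectory, FixtureManifest]:
    """Build a fixture realising exactly the planted interactions.

    Deterministic given ``spec.seed``; raises :class:`GenerationError`
    when the spec is infeasible (site conflicts, non-adjacent planted
    pairs, noise beyond the geometric margin) or when the verification
    pass — running the detectors on the generated frames — disagrees with
    the manifest in any frame.
    """
    if spec.noise_amplitude > MAX_NOISE_AMPLITUDE:
        raise GenerationError(
            f"noise_amplitude {spec.noise_amplitude} Å exceeds the planted-"
            f"geometry margin ({MAX_NOISE_AMPLITUDE} Å)"
        )
    rng = np.random.default_rng(spec.seed)
    builder = _Builder(spec)
    azimuths: dict[int, int] = {}

    lw_info = []
    direct_info = []
    for p in spec.planted_hbonds:
        if p.partner_lipid is None:
            lw_info.append((p, _plant_lipid_water(builder, p, azimuths)))
        else:
            direct_info.append((p, _plant_direct(builder, p)))
    bridge_info = [(b, _plant_bridge(builder, b)) for b in spec.planted_bridges]

    names, resnames, mol_ids, xyz = _assemble(builder, spec, rng)
    annotation = default_annotation_config()
    res_by_mol: dict[int, str] = {}
    for m, r in zip(mol_ids, resnames):
        res_by_mol.setdefault(m, r)
    topology = annotation.annotate(resnames, names, mol_ids)

    # --- manifest -----------------------------------------------------------
    def atom_id(mol: int, name: str) -> int:
        return topology.find_atom(mol, name)

    triples: list[tuple[int, int, int]] = []
    for p, info in lw_info:
        wmol = spec.n_lipids + info["water"]
        if info["donor_side"] == "lipid":
            triples.append((atom_id(p.lipid, info["heavy"]),
                            atom_id(p.lipid, info["hydrogen"]),
                            atom_id(wmol, "OW")))
        else:
            triples.append((atom_id(wmol, "OW"), atom_id(wmol, "HW1"),
                            atom_id(p.lipid, info["heavy"])))
    for p, info in direct_info:
        triples.append((atom_id(info["donor_lipid"], info["d_heavy"]),
                        atom_id(info["donor_lipid"], info["d_hydro"]),
                        atom_id(info["acc_lipid"], info["a_heavy"])))
    bridge_records = []
    for b, info in bridge_info:
        wmol = spec.n_lipids + info["water"]
        # the two water H-bonds of the bridge
        for lipid, moiety, sgn in ((b.lipid_a, b.moiety_a, -1), (b.lipid_b, b.moiety_b, +1)):
            donates = (b.water_role == "double_acceptor"
                       or (b.water_role == "mixed" and sgn > 0))
            heavy, hydro = _site(builder, lipid, moiety, donates)
            if donates:
                triples.append((atom_id(lipid, heavy), atom_id(lipid, hydro),
                                atom_id(wmol, "OW")))
            else:
                hw = "HW1" if (sgn < 0 or b.water_role != "double_donor") else "HW2"
                triples.append((atom_id(wmol, "OW"), atom_id(wmol, hw),
                                atom_id(lipid, heavy)))
        la, lb = sorted((b.lipid_a, b.lipid_b))
        ma, mb = (b.moiety_a, b.moiety_b) if la == b.lipid_a else (b.moiety_b, b.moiety_a)
        bridge_records.append({
            "water_mol": wmol, "lipid_a": la, "lipid_b": lb,
            "moiety_a": ma, "moiety_b": mb,
            "orientation": info["orientation"], "water_role": b.water_role,
        })

    leaflet_labels = {lip: builder.leaflet_of(lip) for lip in range(spec.n_lipids)}
    manifest = FixtureManifest(
        spec=spec,
        hbond_triples=sorted(triples),
        bridge_records=bridge_records,
        leaflet_labels=leaflet_labels,
        n_lipids=spec.n_lipids,
        n_waters=len(builder.waters) + spec.n_free_waters,
        resnames=[res_by_mol[m] for m in sorted(res_by_mol)],
    )

    # --- frames with bounded noise ------------------------------------------
    frames = []
    for i in range(spec.n_frames):
        noise = rng.uniform(-spec.noise_amplitude, spec.noise_amplitude, xyz.shape)
        frames.append(Frame(time=i * spec.dt, coordinates=xyz + noise, box=builder.box))
    traj = Trajectory(frames)

    _verify(topology, traj, manifest)
    return topology, traj, manifest


def _verify(topology: Topology, traj: Trajectory, manifest: FixtureManifest) -> None:
    """Detection on every frame must recover the manifest exactly."""
    expected = set(manifest.hbond_triples)
    leaflets = manifest.leaflets()
    exp_bridges = {
        (r["water_mol"], r["lipid_a"], r["lipid_b"], r["orientation"], r["water_role"])
        for r in manifest.bridge_records
    }
    for frame in traj:
        found = detect_hbonds(frame, topology, HBondCriteria())
        got = {(b.donor_heavy, b.hydrogen, b.acceptor) for b in found}
        if got != expected:
            raise GenerationError(
                f"fixture verification failed at t={frame.time}: "
                f"spurious={sorted(got - expected)} missing={sorted(expected - got)}"
            )
        wbs = detect_water_bridges(found, topology, leaflets)
        got_b = {(w.water_mol, w.lipid_a, w.lipid_b, w.orientation, w.water_role)
                 for w in wbs}
        if got_b != exp_bridges:
            raise GenerationError(
                f"fixture bridge verification failed at t={frame.time}"
            )


# ---------------------------------------------------------------------------
# Edge-schedule fixtures
# ---------------------------------------------------------------------------

def exponential_schedule(
    rng: np.random.Generator,
    n_frames: int,
    mean_on: float,
    mean_off: float,
) -> tuple[int, ...]:
    """On-frames of an alternating geometric on/off process.

    Run lengths are geometric with the given means (discrete analogue of
    exponential waiting times at 1-frame resolution), starting in the off
    state.
    """
    frames: list[int] = []
    t = 0
    on = False
    while t < n_frames:
        mean = mean_on if on else mean_off
        length = int(rng.geometric(min(1.0, 1.0 / mean)))
        if on:
            frames.extend(range(t, min(t + length, n_frames)))
        t += length
        on = not on
    return tuple(frames)


def _run_lengths(on_frames: Sequence[int]) -> list[int]:
    runs = []
    on = sorted(on_frames)
    if not on:
        return runs
    start = prev = on[0]
    for f in on[1:]:
        if f == prev + 1:
            prev = f
        else:
            runs.append(prev - start + 1)
            start = prev = f
    runs.append(prev - start + 1)
    return runs


def generate_edge_schedule_trajectory(
    spec: FixtureSpec,
) -> tuple[list[nx.Graph], FixtureManifest]:
    """Per-frame interaction graphs realising the edge schedules exactly.

    All nodes live in one leaflet; frame times are ``i·dt``.  The manifest
    carries the analytic run lengths of every schedule.
    """
    for s in spec.edge_schedules:
        if s.on_frames and max(s.on_frames) >= spec.n_frames:
            raise GenerationError("schedule references a frame beyond n_frames")
    graphs = []
    for i in range(spec.n_frames):
        g = nx.Graph(frame_time=i * spec.dt, leaflet=0)
        g.add_nodes_from(range(spec.n_nodes))
        for s in spec.edge_schedules:
            if i in s.on_frames:
                if not g.has_edge(s.node_a, s.node_b):
                    g.add_edge(s.node_a, s.node_b, n_hbond=0, n_wb=0)
                g.edges[s.node_a, s.node_b]["n_hbond" if s.kind == "hbond" else "n_wb"] += 1
        graphs.append(g)
    runs = [r for s in spec.edge_schedules for r in _run_lengths(s.on_frames)]
    manifest = FixtureManifest(
        spec=spec, hbond_triples=[], bridge_records=[],
        leaflet_labels={}, schedule_runs=runs,
    )
    return graphs, manifest


def component_graph(sizes: Sequence[int], seed: int = 0) -> nx.Graph:
    """A graph whose connected components have exactly the given sizes."""
    rng = np.random.default_rng(seed)
    g = nx.Graph(frame_time=0.0, leaflet=0)
    node = 0
    for size in sizes:
        members = list(range(node, node + size))
        g.add_nodes_from(members)
        shuffled = list(members)
        rng.shuffle(shuffled)
        for a, b in zip(shuffled, shuffled[1:]):  # random spanning path
            g.add_edge(a, b, n_hbond=1, n_wb=0)
        node += size
    return g


# ---------------------------------------------------------------------------
# Angle / density clouds
# ---------------------------------------------------------------------------

def generate_angle_cloud(spec: FixtureSpec) -> tuple[Topology, Trajectory, FixtureManifest]:
    """Lipids with head vectors at a prescribed angle from the outward
    normal (uniform random azimuth), ring planes at a prescribed dihedral,
    a Gaussian CH₃ cloud per leaflet and optional bulk waters.
    """
    theta = math.radians(spec.head_vector_angle or 0.0)
    if not (0.0 <= math.degrees(theta) <= 180.0):
        raise GenerationError("head_vector_angle must be in [0, 180] degrees")
    delta = math.radians(spec.ring_dihedral or 0.0)
    rng = np.random.default_rng(spec.seed)
    builder = _Builder(spec)

    for lipid in range(spec.n_lipids):
        p = builder.anchor(lipid)
        w = builder.outward(lipid)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        v = np.array([math.sin(theta) * math.cos(phi),
                      math.sin(theta) * math.sin(phi),
                      w * math.cos(theta)])
        builder.set_atom(lipid, "O4P", p + 3.0 * v)
        # ring planes: base frame rotated by a random azimuth about z,
        # second ring rotated by the dihedral about the shared e1 axis
        psi = rng.uniform(0.0, 2.0 * np.pi)
        e1 = np.array([math.cos(psi), math.sin(psi), 0.0])
        e2a = np.array([-math.sin(psi), math.cos(psi), 0.0])
        e2b = math.cos(delta) * e2a + math.sin(delta) * np.array([0.0, 0.0, 1.0])
        ca = p + np.array([-1.2, 0.8, 1.8 * w])
        cb = p + np.array([0.8, -1.0, 1.9 * w])
        for nm, pt in zip(["RA1", "RA2", "RA3", "RA4"], _ring_points(ca, e1, e2a)):
            builder.set_atom(lipid, nm, pt)
        for nm, pt in zip(["RB1", "RB2", "RB3", "RB4"], _ring_points(cb, e1, e2b)):
            builder.set_atom(lipid, nm, pt)
        # CH3 proxy: Gaussian along the normal around the bilayer core side
        z_cm = rng.normal(p[2] - 12.0 * w, spec.ch3_sigma)
        builder.set_atom(lipid, "CM", np.array([p[0], p[1], z_cm]))

    names, resnames, mol_ids, xyz = _assemble(builder, spec, rng)
    annotation = default_annotation_config()
    topology = annotation.annotate(resnames, names, mol_ids)
    frames = [Frame(time=i * spec.dt, coordinates=xyz.copy(), box=builder.box)
              for i in range(spec.n_frames)]
    manifest = FixtureManifest(
        spec=spec, hbond_triples=[], bridge_records=[],
        leaflet_labels={lip: builder.leaflet_of(lip) for lip in range(spec.n_lipids)},
        n_lipids=spec.n_lipids, n_waters=spec.n_free_waters,
        resnames=["SLX"] * spec.n_lipids + ["SOL"] * spec.n_free_waters,
    )
    return topology, Trajectory(frames), manifest
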