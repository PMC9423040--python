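"""Geometric hydrogen-bond detection and per-head tallies.

A hydrogen bond is a (donor-heavy, hydrogen, acceptor) triple with the
donor–acceptor distance below a cutoff and the donor–H···acceptor angle
above a lower bound, both evaluated under the minimum-image convention in
an orthorhombic box.  The galactolipid head groups carry hydroxyls that are
both donors and acceptors plus acceptor-only oxygens, so lipid–water,
direct lipid–lipid and water–water bonds all arise from the same criterion.

Default criterion: d(D···A) ≤ 3.25 Å and ∠D–H···A ≥ 150°.  The underlying
trajectories do not come with a canonical convention, so both values are
configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import Frame
from .topology import (
    HEAD_MOIETIES,
    RING_MOIETIES,
    Moiety,
    MoleculeKind,
    Topology,
)

__all__ = [
    "HBondCriteria",
    "HBond",
    "detect_hbonds",
    "hbonds_to_dataframe",
    "tally_lipid_water",
    "tally_lipid_lipid",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond criterion (Å, degrees)."""

    d_max_heavy: float = 3.25
    angle_min: float = 150.0
    exclude_intramolecular: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.d_max_heavy <= 5.0):
            raise ValueError("d_max_heavy must be in (0, 5] Å")
        if not (0.0 <= self.angle_min <= 180.0):
            raise ValueError("angle_min must be in [0, 180] degrees")


@dataclass(frozen=True)
class HBond:
    """One detected hydrogen bond (atom ids are 0-based)."""

    frame_time: float
    donor_heavy: int
    hydrogen: int
    acceptor: int
    donor_mol: int
    acceptor_mol: int
    pair_class: str  # lipid_water | lipid_lipid | water_water | other
    donor_moiety: Moiety
    acceptor_moiety: Moiety


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    return delta - box * np.round(delta / box)


def _pair_class(kind_d: MoleculeKind, kind_a: MoleculeKind) -> str:
    kinds = {kind_d, kind_a}
    if kinds == {MoleculeKind.LIPID, MoleculeKind.WATER}:
        return "lipid_water"
    if kinds == {MoleculeKind.LIPID}:
        return "lipid_lipid"
    if kinds == {MoleculeKind.WATER}:
        return "water_water"
    return "other"


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBond]:
    """Detect all hydrogen bonds in one frame.

    Candidate donor–acceptor pairs come from a periodic KD-tree query at
    the heavy-atom cutoff; the angle test then runs over each donor's
    bonded hydrogens with minimum-image geometry.  The result is exactly
    the set of triples satisfying both criteria.
    """
    donors = np.nonzero(topology.is_donor_heavy)[0]
    acceptors = np.nonzero(topology.is_acceptor)[0]
    if donors.size == 0 or acceptors.size == 0:
        warnings.warn("no donors or no acceptors in topology; returning no H-bonds")
        return []

    box = frame.box
    pos = frame.wrapped()
    # cKDTree with boxsize requires coordinates strictly inside [0, box)
    pos = np.where(pos >= box, pos - box, pos)

    tree_a = cKDTree(pos[acceptors], boxsize=box)
    tree_d = cKDTree(pos[donors], boxsize=box)
    pairs = tree_d.query_ball_tree(tree_a, r=criteria.d_max_heavy)

    cos_min = np.cos(np.deg2rad(criteria.angle_min))
    out: list[HBond] = []
    coords = frame.coordinates
    for di, alist in zip(donors, pairs):
        rec_d = topology.atoms[di]
        for aj_local in alist:
            aj = int(acceptors[aj_local])
            if aj == di:
                continue
            rec_a = topology.atoms[aj]
            if criteria.exclude_intramolecular and rec_d.molecule_id == rec_a.molecule_id:
                continue
            for h in rec_d.bonded_hydrogens:
                if h == aj:
                    continue
                v_d = minimum_image(coords[di] - coords[h], box)
                v_a = minimum_image(coords[aj] - coords[h], box)
                nd = np.linalg.norm(v_d)
                na = np.linalg.norm(v_a)
                if nd == 0.0 or na == 0.0:
                    continue
                # angle >= angle_min  <=>  cos(angle) <= cos(angle_min)
                if float(v_d @ v_a) / (nd * na) <= cos_min + 1e-12:
                    out.append(
                        HBond(
                            frame_time=frame.time,
                            donor_heavy=int(di),
                            hydrogen=int(h),
                            acceptor=aj,
                            donor_mol=rec_d.molecule_id,
                            acceptor_mol=rec_a.molecule_id,
                            pair_class=_pair_class(rec_d.molecule_kind, rec_a.molecule_kind),
                            donor_moiety=rec_d.moiety,
                            acceptor_moiety=rec_a.moiety,
                        )
                    )
    out.sort(key=lambda b: (b.frame_time, b.donor_heavy, b.hydrogen, b.acceptor))
    return out


def hbonds_to_dataframe(hbonds: Iterable[HBond]) -> pd.DataFrame:
    rows = [
        {
            "frame_time": b.frame_time,
            "donor_heavy": b.donor_heavy,
            "hydrogen": b.hydrogen,
            "acceptor": b.acceptor,
            "donor_mol": b.donor_mol,
            "acceptor_mol": b.acceptor_mol,
            "pair_class": b.pair_class,
            "donor_moiety": b.donor_moiety.value,
            "acceptor_moiety": b.acceptor_moiety.value,
        }
        for b in hbonds
    ]
    cols = [
        "frame_time", "donor_heavy", "hydrogen", "acceptor", "donor_mol",
        "acceptor_mol", "pair_class", "donor_moiety", "acceptor_moiety",
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Tallies
# ---------------------------------------------------------------------------

def _mean_sd(per_frame: np.ndarray) -> tuple[float, float]:
    """Time mean ± population SD over per-frame means (SD = 0 for 1 frame)."""
    per_frame = np.asarray(per_frame, dtype=float)
    return float(per_frame.mean()), float(per_frame.std(ddof=0))


def _lipid_side(b: HBond, topology: Topology) -> tuple[int, Moiety, bool]:
    """(lipid molecule, lipid moiety, lipid_is_donor) of a lipid–water bond."""
    if topology.molecule_kind_of(b.donor_mol) is MoleculeKind.LIPID:
        return b.donor_mol, b.donor_moiety, True
    return b.acceptor_mol, b.acceptor_moiety, False


def tally_lipid_water(
    hbonds: Sequence[HBond],
    topology: Topology,
    frame_times: Sequence[float],
    lipid_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-head lipid–water H-bond summary (mean ± SD over frames).

    Rows: total per head, per rings (split into the lipid acting via an H
    of an OH, i.e. as donor, vs via an O acceptor), per α ring, per β ring,
    per glycerol, and the number of *distinct* water molecules H-bonded to
    the head.  Per-frame means over lipids are taken first, then the time
    mean and SD over frames.
    """
    lipids = list(lipid_ids) if lipid_ids is not None else topology.lipid_ids
    if not lipids:
        raise ValueError("no lipids to tally")
    for mol in lipids:
        if topology.head_atom_ids(mol).size == 0:
            raise ValueError(f"lipid {mol} has no annotated head-group atoms")
    lipset = set(lipids)
    frame_times = sorted(set(frame_times))

    keys = [
        "hbonds_per_head",
        "hbonds_rings",
        "hbonds_rings_via_H",
        "hbonds_rings_via_O",
        "hbonds_alpha_ring",
        "hbonds_beta_ring",
        "hbonds_gly",
        "hbonded_waters_per_head",
    ]
    per_frame = {k: [] for k in keys}

    by_frame: dict[float, list[HBond]] = {t: [] for t in frame_times}
    for b in hbonds:
        if b.pair_class == "lipid_water" and b.frame_time in by_frame:
            by_frame[b.frame_time].append(b)

    n = len(lipids)
    for t in frame_times:
        counts = {k: dict.fromkeys(lipids, 0) for k in keys if k != "hbonded_waters_per_head"}
        waters: dict[int, set[int]] = {m: set() for m in lipids}
        for b in by_frame[t]:
            mol, moiety, lipid_is_donor = _lipid_side(b, topology)
            if mol not in lipset:
                continue
            counts["hbonds_per_head"][mol] += 1
            if moiety in RING_MOIETIES:
                counts["hbonds_rings"][mol] += 1
                key = "hbonds_rings_via_H" if lipid_is_donor else "hbonds_rings_via_O"
                counts[key][mol] += 1
                ring_key = (
                    "hbonds_alpha_ring" if moiety is Moiety.ALPHA_RING else "hbonds_beta_ring"
                )
                counts[ring_key][mol] += 1
            elif moiety is Moiety.GLYCEROL:
                counts["hbonds_gly"][mol] += 1
            water = b.acceptor_mol if lipid_is_donor else b.donor_mol
            waters[mol].add(water)
        for k, d in counts.items():
            per_frame[k].append(sum(d.values()) / n)
        per_frame["hbonded_waters_per_head"].append(sum(len(s) for s in waters.values()) / n)

    data = {k: _mean_sd(v) for k, v in per_frame.items()}
    return pd.DataFrame(
        {"mean": {k: v[0] for k, v in data.items()}, "sd": {k: v[1] for k, v in data.items()}}
    ).loc[keys]


def _moiety_pair_category(m1: Moiety, m2: Moiety) -> str | None:
    ring = RING_MOIETIES
    if m1 in ring and m2 in ring:
        a, b = sorted([m1.value, m2.value])
        return {
            ("alpha_ring", "alpha_ring"): "alpha_alpha",
            ("alpha_ring", "beta_ring"): "alpha_beta",
            ("beta_ring", "beta_ring"): "beta_beta",
        }[(a, b)]
    if m1 is Moiety.GLYCEROL and m2 is Moiety.GLYCEROL:
        return "gly_gly"
    if (m1 is Moiety.GLYCEROL and m2 in ring) or (m2 is Moiety.GLYCEROL and m1 in ring):
        return "gly_ring"
    return None


def tally_lipid_lipid(
    hbonds: Sequence[HBond],
    topology: Topology,
    leaflets,
    frame_times: Sequence[float],
    lipid_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-head direct lipid–lipid H-bond summary split by orientation.

    Each bond contributes once to both endpoint heads.  ``horizontal``
    means both lipids sit in the same leaflet, ``vertical`` in different
    (apposing) leaflets; ``total = horizontal + vertical`` holds per lipid
    by construction.  Moiety-pair categories follow the ring/glycerol
    taxonomy.
    """
    lipids = list(lipid_ids) if lipid_ids is not None else topology.lipid_ids
    lipset = set(lipids)
    frame_times = sorted(set(frame_times))
    n = len(lipids)
    if n == 0:
        raise ValueError("no lipids to tally")

    categories = ["alpha_alpha", "alpha_beta", "beta_beta", "gly_ring", "gly_gly"]
    orients = ["horizontal", "vertical", "total"]
    keys = [f"hbond_head_head_{o}" for o in orients] + [
        f"hbond_{c}" for c in categories
    ]
    per_frame = {k: [] for k in keys}

    by_frame: dict[float, list[HBond]] = {t: [] for t in frame_times}
    for b in hbonds:
        if b.pair_class == "lipid_lipid" and b.frame_time in by_frame:
            by_frame[b.frame_time].append(b)

    for t in frame_times:
        acc = dict.fromkeys(keys, 0)
        for b in by_frame[t]:
            try:
                la = leaflets.label_of(b.donor_mol)
                lb = leaflets.label_of(b.acceptor_mol)
            except KeyError as exc:
                raise ValueError(f"lipid missing from leaflet assignment: {exc}") from exc
            touches = int(b.donor_mol in lipset) + int(b.acceptor_mol in lipset)
            if touches == 0:
                continue
            orient = "horizontal" if la == lb else "vertical"
            acc[f"hbond_head_head_{orient}"] += touches
            acc["hbond_head_head_total"] += touches
            cat = _moiety_pair_category(b.donor_moiety, b.acceptor_moiety)
            if cat is not None:
                acc[f"hbond_{cat}"] += touches
        for k in keys:
            per_frame[k].append(acc[k] / n)

    data = {k: _mean_sd(v) for k, v in per_frame.items()}
    return pd.DataFrame(
        {"mean": {k: v[0] for k, v in data.items()}, "sd": {k: v[1] for k, v in data.items()}}
    ).loc[keys]
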