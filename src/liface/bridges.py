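"""Water-bridge detection and per-head tallies.

A water bridge is a single water molecule simultaneously H-bonded to two
*different* lipid molecules, linking their head groups.  Bridges are
classified by the moiety pair on the lipid side (ring–ring with α/β
splits, glycerol–ring, glycerol–glycerol), by orientation (horizontal =
both lipids in the same leaflet, vertical = apposing leaflets) and by the
water's role (donor of both H-bonds, acceptor of both, or mixed).

A water bound to k ≥ 2 lipids contributes C(k,2) bridges — one per
unordered lipid pair — matching the pairwise-link definition used for the
interaction-network edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .hbonds import HBond, _mean_sd, _moiety_pair_category
from .topology import Moiety, MoleculeKind, RING_MOIETIES, Topology

__all__ = ["WaterBridge", "detect_water_bridges", "tally_bridges", "bridges_to_dataframe"]


@dataclass(frozen=True)
class WaterBridge:
    frame_time: float
    water_mol: int
    lipid_a: int  # unordered pair, stored with lipid_a < lipid_b
    lipid_b: int
    moiety_a: Moiety
    moiety_b: Moiety
    orientation: str  # horizontal | vertical
    water_role: str  # double_donor | double_acceptor | mixed


def _moiety_priority(m: Moiety) -> int:
    # prefer ring moieties over glycerol over anything else when a water
    # makes several H-bonds to the same lipid
    if m in RING_MOIETIES:
        return 0
    if m is Moiety.GLYCEROL:
        return 1
    return 2


def detect_water_bridges(
    hbonds: Sequence[HBond],
    topology: Topology,
    leaflets,
) -> list[WaterBridge]:
    """Enumerate water bridges from a frame-range H-bond list.

    For each (frame, water) the distinct lipid partners are collected from
    the lipid–water bonds; every unordered pair of distinct partners
    yields one bridge.  When a water makes several H-bonds to the same
    lipid, the representative bond for moiety/role classification is the
    ring-moiety bond if present, then glycerol, ties broken by lowest
    lipid atom id.
    """
    # (frame, water) -> lipid -> best (priority, lipid_atom, moiety, water_is_donor)
    partners: dict[tuple[float, int], dict[int, tuple]] = {}
    for b in hbonds:
        if b.pair_class != "lipid_water":
            continue
        if topology.molecule_kind_of(b.donor_mol) is MoleculeKind.WATER:
            water, lipid = b.donor_mol, b.acceptor_mol
            moiety, lipid_atom, water_is_donor = b.acceptor_moiety, b.acceptor, True
        else:
            water, lipid = b.acceptor_mol, b.donor_mol
            moiety, lipid_atom, water_is_donor = b.donor_moiety, b.donor_heavy, False
        key = (b.frame_time, water)
        cand = (_moiety_priority(moiety), lipid_atom, moiety, water_is_donor)
        best = partners.setdefault(key, {}).get(lipid)
        if best is None or cand[:2] < best[:2]:
            partners[key][lipid] = cand

    out: list[WaterBridge] = []
    for (t, water), lip_map in sorted(partners.items()):
        for la, lb in combinations(sorted(lip_map), 2):
            _, _, ma, wa_donor = lip_map[la]
            _, _, mb, wb_donor = lip_map[lb]
            if wa_donor and wb_donor:
                role = "double_donor"
            elif not wa_donor and not wb_donor:
                role = "double_acceptor"
            else:
                role = "mixed"
            orient = "horizontal" if leaflets.label_of(la) == leaflets.label_of(lb) else "vertical"
            out.append(
                WaterBridge(
                    frame_time=t,
                    water_mol=water,
                    lipid_a=la,
                    lipid_b=lb,
                    moiety_a=ma,
                    moiety_b=mb,
                    orientation=orient,
                    water_role=role,
                )
            )
    return out


def bridges_to_dataframe(bridges: Sequence[WaterBridge]) -> pd.DataFrame:
    cols = [
        "frame_time", "water_mol", "lipid_a", "lipid_b",
        "moiety_a", "moiety_b", "orientation", "water_role",
    ]
    rows = [
        {
            "frame_time": b.frame_time,
            "water_mol": b.water_mol,
            "lipid_a": b.lipid_a,
            "lipid_b": b.lipid_b,
            "moiety_a": b.moiety_a.value,
            "moiety_b": b.moiety_b.value,
            "orientation": b.orientation,
            "water_role": b.water_role,
        }
        for b in bridges
    ]
    return pd.DataFrame(rows, columns=cols)


def tally_bridges(
    bridges: Sequence[WaterBridge],
    topology: Topology,
    frame_times: Sequence[float],
    lipid_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-head water-bridge summary (mean ± SD over frames).

    Each bridge counts once for each of its two endpoint heads ("bridges
    touching the head").  Rows cover the total, ring–ring with α/β
    splits, glycerol–glycerol and glycerol–ring categories, and the
    horizontal/vertical/total orientation split.
    """
    lipids = list(lipid_ids) if lipid_ids is not None else topology.lipid_ids
    n = len(lipids)
    if n == 0:
        raise ValueError("no lipids to tally")
    lipset = set(lipids)
    frame_times = sorted(set(frame_times))

    keys = [
        "wb_per_head",
        "wb_ring_ring",
        "wb_alpha_alpha",
        "wb_alpha_beta",
        "wb_beta_beta",
        "wb_gly_gly",
        "wb_gly_ring",
        "wb_horizontal",
        "wb_vertical",
        "wb_total",
    ]
    per_frame = {k: [] for k in keys}

    by_frame: dict[float, list[WaterBridge]] = {t: [] for t in frame_times}
    for b in bridges:
        if b.frame_time in by_frame:
            by_frame[b.frame_time].append(b)

    for t in frame_times:
        acc = dict.fromkeys(keys, 0)
        for b in by_frame[t]:
            touches = int(b.lipid_a in lipset) + int(b.lipid_b in lipset)
            if touches == 0:
                continue
            acc["wb_per_head"] += touches
            acc["wb_total"] += touches
            acc[f"wb_{b.orientation}"] += touches
            cat = _moiety_pair_category(b.moiety_a, b.moiety_b)
            if cat in ("alpha_alpha", "alpha_beta", "beta_beta"):
                acc["wb_ring_ring"] += touches
                acc[f"wb_{cat}"] += touches
            elif cat is not None:
                acc[f"wb_{cat}"] += touches
        for k in keys:
            per_frame[k].append(acc[k] / n)

    data = {k: _mean_sd(v) for k, v in per_frame.items()}
    return pd.DataFrame(
        {"mean": {k: v[0] for k, v in data.items()}, "sd": {k: v[1] for k, v in data.items()}}
    ).loc[keys]
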