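"""Shared test fixtures and independent oracles.

The brute-force H-bond oracle enumerates *all* donor/acceptor pairs in
O(N^2 * H) with explicit minimum-image geometry, independently of the
KD-tree candidate search used by the library.
"""

from __future__ import annotations

import numpy as np
import pytest

from liface import Frame, HBond, HBondCriteria, Topology
from liface.topology import AtomRecord, Moiety, MoleculeKind


# ---------------------------------------------------------------------------
# Small hand-built topologies
# ---------------------------------------------------------------------------

def make_atom(
    atom_id: int,
    name: str,
    mol: int,
    kind: MoleculeKind = MoleculeKind.OTHER,
    moiety: Moiety = Moiety.OTHER,
    electrons: int = 8,
    acceptor: bool = False,
    hydrogens: list[int] | None = None,
) -> AtomRecord:
    hydrogens = hydrogens or []
    return AtomRecord(
        atom_id=atom_id,
        atom_name=name,
        molecule_id=mol,
        molecule_kind=kind,
        moiety=moiety,
        element=name[:1],
        electron_count=electrons,
        is_donor_heavy=bool(hydrogens),
        is_acceptor=acceptor,
        bonded_hydrogens=hydrogens,
    )


def water_molecule(first_id: int, mol: int) -> list[AtomRecord]:
    """O (donor via 2 H, acceptor) + 2 H records."""
    o = make_atom(first_id, "OW", mol, MoleculeKind.WATER, Moiety.WATER,
                  electrons=8, acceptor=True,
                  hydrogens=[first_id + 1, first_id + 2])
    h1 = make_atom(first_id + 1, "HW1", mol, MoleculeKind.WATER, Moiety.WATER, electrons=1)
    h2 = make_atom(first_id + 2, "HW2", mol, MoleculeKind.WATER, Moiety.WATER, electrons=1)
    return [o, h1, h2]


def hydroxyl(first_id: int, mol: int, moiety: Moiety,
             kind: MoleculeKind = MoleculeKind.LIPID) -> list[AtomRecord]:
    """O-H pair: the oxygen is both donor and acceptor."""
    o = make_atom(first_id, "O", mol, kind, moiety, electrons=8, acceptor=True,
                  hydrogens=[first_id + 1])
    h = make_atom(first_id + 1, "H", mol, kind, moiety, electrons=1)
    return [o, h]


# ---------------------------------------------------------------------------
# Brute-force H-bond oracle
# ---------------------------------------------------------------------------

def min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def brute_force_hbonds(
    frame: Frame, topology: Topology, criteria: HBondCriteria
) -> set[tuple[int, int, int]]:
    """All (donor_heavy, hydrogen, acceptor) triples, enumerated pairwise."""
    box = frame.box
    coords = frame.coordinates
    cos_min = np.cos(np.deg2rad(criteria.angle_min))
    out: set[tuple[int, int, int]] = set()
    donors = [a for a in topology.atoms if a.is_donor_heavy]
    acceptors = [a for a in topology.atoms if a.is_acceptor]
    for d in donors:
        for a in acceptors:
            if a.atom_id == d.atom_id:
                continue
            if criteria.exclude_intramolecular and d.molecule_id == a.molecule_id:
                continue
            dv = min_image(coords[d.atom_id] - coords[a.atom_id], box)
            if np.linalg.norm(dv) > criteria.d_max_heavy:
                continue
            for h in d.bonded_hydrogens:
                if h == a.atom_id:
                    continue
                v_d = min_image(coords[d.atom_id] - coords[h], box)
                v_a = min_image(coords[a.atom_id] - coords[h], box)
                nd, na = np.linalg.norm(v_d), np.linalg.norm(v_a)
                if nd == 0.0 or na == 0.0:
                    continue
                if float(v_d @ v_a) / (nd * na) <= cos_min + 1e-12:
                    out.add((d.atom_id, h, a.atom_id))
    return out


def hbond_triples(hbonds: list[HBond]) -> set[tuple[int, int, int]]:
    return {(b.donor_heavy, b.hydrogen, b.acceptor) for b in hbonds}


# ---------------------------------------------------------------------------
# Random systems for oracle-equivalence tests
# ---------------------------------------------------------------------------

def random_system(rng: np.random.Generator, max_atoms: int = 500):
    """A random mixed lipid/water system with arbitrary positions.

    Positions are drawn in [-box, 2*box] so wrapping and periodic images
    are exercised; molecules are one heavy atom plus 0-2 hydrogens with
    random donor/acceptor roles.
    """
    box = rng.uniform(12.0, 28.0, size=3)
    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    mol = 0
    while len(records) < max_atoms - 3:
        n_h = int(rng.integers(0, 3))
        acceptor = bool(rng.random() < 0.7) or n_h == 0
        is_water = bool(rng.random() < 0.5)
        kind = MoleculeKind.WATER if is_water else MoleculeKind.LIPID
        moiety = (
            Moiety.WATER
            if is_water
            else [Moiety.ALPHA_RING, Moiety.BETA_RING, Moiety.GLYCEROL, Moiety.OTHER][
                int(rng.integers(0, 4))
            ]
        )
        i0 = len(records)
        heavy_pos = rng.uniform(-box, 2 * box)
        hyd_ids = list(range(i0 + 1, i0 + 1 + n_h))
        records.append(
            make_atom(i0, "O", mol, kind, moiety, electrons=8,
                      acceptor=acceptor, hydrogens=hyd_ids)
        )
        coords.append(heavy_pos)
        for k in range(n_h):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            records.append(make_atom(i0 + 1 + k, f"H{k}", mol, kind, moiety, electrons=1))
            coords.append(heavy_pos + rng.uniform(0.8, 1.2) * direction)
        mol += 1
        if rng.random() < 0.02:
            break
    topology = Topology(records)
    frame = Frame(time=0.0, coordinates=np.array(coords), box=box)
    return frame, topology


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
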