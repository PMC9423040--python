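"""Annotated topologies for membrane interface analysis.

A :class:`Topology` carries the static per-atom metadata the analysis needs:
which molecule each atom belongs to, whether that molecule is a lipid or a
water, which head-group *moiety* the atom is part of (galactose rings,
glycerol backbone, acyl chain, water), hydrogen-bond donor/acceptor roles,
and electron counts for density profiles.

Annotations come from a user-editable YAML config keyed by residue name and
atom name, so arbitrary lipids can be supported without code changes.  A
preset config for MGDG/DGDG head-group numbering, TIP3P water and the
synthetic test lipid ships with the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Moiety",
    "MoleculeKind",
    "AtomRecord",
    "Topology",
    "AnnotationConfig",
    "ConfigError",
    "load_annotation_config",
    "default_annotation_config",
]


class Moiety(str, Enum):
    """Head-group moiety an atom belongs to.

    The glycerol backbone conventionally includes the glycosidic O1'
    oxygen; this is expressed in the annotation config, not in code.
    """

    ALPHA_RING = "alpha_ring"
    BETA_RING = "beta_ring"
    GLYCEROL = "glycerol"
    CHAIN = "chain"
    WATER = "water"
    OTHER = "other"


class MoleculeKind(str, Enum):
    LIPID = "lipid"
    WATER = "water"
    OTHER = "other"


RING_MOIETIES = frozenset({Moiety.ALPHA_RING, Moiety.BETA_RING})
HEAD_MOIETIES = frozenset({Moiety.ALPHA_RING, Moiety.BETA_RING, Moiety.GLYCEROL})


class ConfigError(ValueError):
    """Raised when an annotation config is malformed or does not match."""


@dataclass
class AtomRecord:
    """Static annotation of a single atom (0-based internal indices)."""

    atom_id: int
    atom_name: str
    molecule_id: int
    molecule_kind: MoleculeKind
    moiety: Moiety
    element: str
    electron_count: int
    is_donor_heavy: bool = False
    is_acceptor: bool = False
    bonded_hydrogens: list[int] = field(default_factory=list)

    def validate(self) -> None:
        if self.is_donor_heavy and not self.bonded_hydrogens:
            raise ConfigError(
                f"atom {self.atom_name} (id {self.atom_id}) flagged as donor "
                "heavy atom but has no bonded hydrogens"
            )
        if (self.moiety is Moiety.WATER) != (self.molecule_kind is MoleculeKind.WATER):
            raise ConfigError(
                f"atom {self.atom_name}: moiety 'water' must coincide with "
                "molecule kind 'water'"
            )
        if self.electron_count <= 0:
            raise ConfigError(
                f"atom {self.atom_name}: electron count must be positive"
            )


class Topology:
    """Column-oriented view over a list of :class:`AtomRecord`.

    Provides the vectorised masks and per-molecule groupings that the
    detection and geometry modules operate on.
    """

    def __init__(self, atoms: Iterable[AtomRecord]):
        self.atoms: list[AtomRecord] = list(atoms)
        for a in self.atoms:
            a.validate()
        n = len(self.atoms)
        self.n_atoms = n
        self.atom_names = np.array([a.atom_name for a in self.atoms], dtype=object)
        self.molecule_ids = np.array([a.molecule_id for a in self.atoms], dtype=np.int64)
        self.moieties = np.array([a.moiety for a in self.atoms], dtype=object)
        self.molecule_kinds = np.array([a.molecule_kind for a in self.atoms], dtype=object)
        self.electron_counts = np.array([a.electron_count for a in self.atoms], dtype=np.int64)
        self.is_donor_heavy = np.array([a.is_donor_heavy for a in self.atoms], dtype=bool)
        self.is_acceptor = np.array([a.is_acceptor for a in self.atoms], dtype=bool)
        # molecule-level bookkeeping
        self._mol_kind: dict[int, MoleculeKind] = {}
        self._mol_atoms: dict[int, list[int]] = {}
        for a in self.atoms:
            self._mol_atoms.setdefault(a.molecule_id, []).append(a.atom_id)
            self._mol_kind.setdefault(a.molecule_id, a.molecule_kind)

    # -- molecule accessors -------------------------------------------------
    @property
    def molecule_id_list(self) -> list[int]:
        return sorted(self._mol_atoms)

    @property
    def lipid_ids(self) -> list[int]:
        return [m for m in self.molecule_id_list if self._mol_kind[m] is MoleculeKind.LIPID]

    @property
    def water_ids(self) -> list[int]:
        return [m for m in self.molecule_id_list if self._mol_kind[m] is MoleculeKind.WATER]

    def molecule_kind_of(self, molecule_id: int) -> MoleculeKind:
        return self._mol_kind[molecule_id]

    def atoms_of(self, molecule_id: int) -> np.ndarray:
        return np.asarray(self._mol_atoms[molecule_id], dtype=np.int64)

    # -- masks --------------------------------------------------------------
    def moiety_mask(self, moieties: Iterable[Moiety]) -> np.ndarray:
        wanted = set(moieties)
        return np.array([m in wanted for m in self.moieties], dtype=bool)

    def head_atom_ids(self, molecule_id: int) -> np.ndarray:
        ids = self.atoms_of(molecule_id)
        return ids[[self.atoms[i].moiety in HEAD_MOIETIES for i in ids]]

    def find_atom(self, molecule_id: int, atom_name: str) -> int:
        for i in self.atoms_of(molecule_id):
            if self.atoms[i].atom_name == atom_name:
                return int(i)
        raise KeyError(f"atom {atom_name!r} not found in molecule {molecule_id}")

    def select_by_name(self, atom_name: str) -> np.ndarray:
        return np.nonzero(self.atom_names == atom_name)[0]

    def __len__(self) -> int:
        return self.n_atoms


# ---------------------------------------------------------------------------
# Annotation config
# ---------------------------------------------------------------------------

_ELEMENT_ELECTRONS = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}


@dataclass
class _AtomRule:
    moiety: Moiety
    element: str
    electrons: int
    acceptor: bool = False
    hydrogens: tuple[str, ...] = ()


@dataclass
class AnnotationConfig:
    """Residue-name → atom-name → annotation rules."""

    residues: dict[str, tuple[MoleculeKind, dict[str, _AtomRule]]]

    @classmethod
    def from_mapping(cls, data: Mapping) -> "AnnotationConfig":
        residues: dict[str, tuple[MoleculeKind, dict[str, _AtomRule]]] = {}
        mols = data.get("molecules", data)
        for resname, resdef in mols.items():
            try:
                kind = MoleculeKind(resdef.get("kind", "other"))
            except ValueError as exc:
                raise ConfigError(f"residue {resname}: bad kind {resdef.get('kind')!r}") from exc
            rules: dict[str, _AtomRule] = {}
            for aname, adef in (resdef.get("atoms") or {}).items():
                adef = adef or {}
                element = str(adef.get("element", aname[0]))
                electrons = int(adef.get("electrons", _ELEMENT_ELECTRONS.get(element, 0)))
                try:
                    moiety = Moiety(adef.get("moiety", "other"))
                except ValueError as exc:
                    raise ConfigError(
                        f"residue {resname} atom {aname}: bad moiety {adef.get('moiety')!r}"
                    ) from exc
                rules[str(aname)] = _AtomRule(
                    moiety=moiety,
                    element=element,
                    electrons=electrons,
                    acceptor=bool(adef.get("acceptor", False)),
                    hydrogens=tuple(adef.get("hydrogens", ()) or ()),
                )
            residues[str(resname)] = (kind, rules)
        return cls(residues=residues)

    def annotate(
        self,
        resnames: Iterable[str],
        atom_names: Iterable[str],
        molecule_ids: Iterable[int],
    ) -> Topology:
        """Build a :class:`Topology` for atoms grouped into molecules.

        Atom names with no matching rule are mapped to moiety ``other``
        with a logged warning.  A rule's ``hydrogens`` entry naming an atom
        absent from that molecule is a config error.
        """
        resnames = list(resnames)
        atom_names = list(atom_names)
        molecule_ids = [int(m) for m in molecule_ids]
        n = len(atom_names)
        if not (len(resnames) == len(molecule_ids) == n):
            raise ValueError("resnames, atom_names, molecule_ids must have equal length")

        # index atoms of each molecule by name for hydrogen resolution
        mol_name_to_id: dict[int, dict[str, int]] = {}
        for i, (mol, aname) in enumerate(zip(molecule_ids, atom_names)):
            mol_name_to_id.setdefault(mol, {})[aname] = i

        records: list[AtomRecord] = []
        warned: set[tuple[str, str]] = set()
        for i in range(n):
            resname, aname, mol = resnames[i], atom_names[i], molecule_ids[i]
            entry = self.residues.get(resname)
            if entry is None:
                if (resname, "") not in warned:
                    warnings.warn(f"residue {resname!r} not in annotation config; atoms mapped to 'other'")
                    warned.add((resname, ""))
                kind, rules = MoleculeKind.OTHER, {}
            else:
                kind, rules = entry
            rule = rules.get(aname)
            if rule is None:
                if entry is not None and (resname, aname) not in warned:
                    warnings.warn(
                        f"atom {aname!r} of residue {resname!r} not in annotation config; mapped to 'other'"
                    )
                    warned.add((resname, aname))
                moiety = Moiety.WATER if kind is MoleculeKind.WATER else Moiety.OTHER
                element = aname[:1] or "X"
                electrons = _ELEMENT_ELECTRONS.get(element, 1)
                acceptor = False
                hydrogens: list[int] = []
            else:
                moiety = rule.moiety
                element = rule.element
                electrons = rule.electrons
                acceptor = rule.acceptor
                hydrogens = []
                for hname in rule.hydrogens:
                    h = mol_name_to_id[mol].get(hname)
                    if h is None:
                        raise ConfigError(
                            f"residue {resname} atom {aname}: bonded hydrogen "
                            f"{hname!r} absent from molecule {mol}"
                        )
                    hydrogens.append(h)
            records.append(
                AtomRecord(
                    atom_id=i,
                    atom_name=aname,
                    molecule_id=mol,
                    molecule_kind=kind,
                    moiety=moiety,
                    element=element,
                    electron_count=electrons,
                    is_donor_heavy=bool(hydrogens),
                    is_acceptor=acceptor,
                    bonded_hydrogens=hydrogens,
                )
            )
        return Topology(records)


def load_annotation_config(path: str | Path) -> AnnotationConfig:
    """Load an annotation config from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"annotation config {path} is not a mapping")
    return AnnotationConfig.from_mapping(data)


def default_annotation_config() -> AnnotationConfig:
    """The shipped presets: MGDG, DGDG, TIP3P water and the synthetic lipid."""
    ref = resources.files("liface.data").joinpath("annotations.yaml")
    data = yaml.safe_load(ref.read_text())
    return AnnotationConfig.from_mapping(data)
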