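"""Structure/trajectory I/O and result-table writing.

Reading goes through MDAnalysis, which handles PDB/GRO structures and
XTC/multi-model trajectories and performs the nm→Å conversion for GRO
exactly once.  Internally everything is Å and ps.  Only orthorhombic boxes
are supported; triclinic input raises :class:`FormatError`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .topology import AnnotationConfig, Moiety, Topology, default_annotation_config

__all__ = [
    "Frame",
    "Trajectory",
    "RegionMask",
    "FormatError",
    "TopologyError",
    "load_structure",
    "load_trajectory",
    "write_structure",
    "write_trajectory",
    "write_table",
]


class FormatError(ValueError):
    """Unreadable or unsupported structure/trajectory file."""


class TopologyError(ValueError):
    """Trajectory inconsistent with the supplied topology."""


@dataclass
class Frame:
    """One time point: coordinates (Å) and an orthorhombic box (Å)."""

    time: float  # ps
    coordinates: np.ndarray  # (n_atoms, 3), Å
    box: np.ndarray  # (3,), Å

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be strictly positive")

    def wrapped(self) -> np.ndarray:
        """Coordinates wrapped into [0, box) on each axis."""
        return np.mod(self.coordinates, self.box)


class Trajectory:
    """An ordered sequence of frames sharing one topology."""

    def __init__(self, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory must contain at least one frame")
        times = np.array([f.time for f in frames])
        if np.any(np.diff(times) <= 0):
            raise FormatError("frame times must be strictly increasing")
        n = frames[0].coordinates.shape[0]
        if any(f.coordinates.shape[0] != n for f in frames):
            raise TopologyError("all frames must have the same atom count")
        self.frames = frames

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def n_atoms(self) -> int:
        return self.frames[0].coordinates.shape[0]

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]


@dataclass
class RegionMask:
    """Select lipids by head-group centre-of-mass bounds and/or explicit ids.

    Used to restrict tallies to sub-regions of a system (e.g. the locally
    connected regions of a double bilayer); the boundaries themselves are
    user input.
    """

    name: str
    axis_bounds: dict[int, tuple[float, float]] | None = None  # axis -> (lo, hi), Å
    molecule_ids: list[int] | None = None

    def __post_init__(self) -> None:
        if self.axis_bounds is None and self.molecule_ids is None:
            raise ValueError("RegionMask needs axis_bounds and/or molecule_ids")

    def select(self, frame: Frame, topology: Topology) -> list[int]:
        """Lipid molecule ids belonging to the region in this frame."""
        out = []
        explicit = set(self.molecule_ids) if self.molecule_ids is not None else None
        for mol in topology.lipid_ids:
            if explicit is not None and mol in explicit:
                out.append(mol)
                continue
            if self.axis_bounds is None:
                continue
            head = topology.head_atom_ids(mol)
            if head.size == 0:
                continue
            w = topology.electron_counts[head].astype(float)
            com = np.average(frame.coordinates[head], axis=0, weights=w)
            ok = all(lo <= com[ax] <= hi for ax, (lo, hi) in self.axis_bounds.items())
            if ok:
                out.append(mol)
        return out


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _check_box(dimensions) -> np.ndarray:
    if dimensions is None or not np.all(np.asarray(dimensions)[:3] > 0):
        raise FormatError("structure has no valid box dimensions")
    dims = np.asarray(dimensions, dtype=float)
    if not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise FormatError("only orthorhombic boxes are supported (triclinic input)")
    return dims[:3].copy()


def _universe(path: str | Path, *extra):
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise FormatError(f"empty file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mda.Universe(str(path), *[str(e) for e in extra])
    except FormatError:
        raise
    except Exception as exc:  # MDAnalysis raises a zoo of parse errors
        raise FormatError(f"could not parse {path}: {exc}") from exc


def load_structure(
    path: str | Path,
    annotation: AnnotationConfig | None = None,
) -> tuple[Topology, Frame]:
    """Read a PDB/GRO structure and annotate it.

    Returns the annotated topology and the first frame (coordinates in Å;
    MDAnalysis converts GRO nm input on read).
    """
    annotation = annotation or default_annotation_config()
    u = _universe(path)
    box = _check_box(u.dimensions)
    resnames = [a.resname for a in u.atoms]
    names = [a.name for a in u.atoms]
    # molecule id = 0-based running index over residues
    mol_ids = [int(a.resindex) for a in u.atoms]
    topology = annotation.annotate(resnames, names, mol_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        time = float(getattr(u.trajectory.ts, "time", 0.0) or 0.0)
        frame = Frame(time=time, coordinates=u.atoms.positions.astype(np.float64), box=box)
    return topology, frame


def _cryst1_box(path: Path):
    """Box from a PDB CRYST1 record, or None (fallback when the trajectory
    reader does not propagate per-frame dimensions)."""
    if path.suffix.lower() not in {".pdb", ".ent"}:
        return None
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                try:
                    vals = [float(line[6:15]), float(line[15:24]), float(line[24:33]),
                            float(line[33:40]), float(line[40:47]), float(line[47:54])]
                except ValueError:
                    return None
                return vals
    return None


def load_trajectory(
    path: str | Path,
    topology: Topology,
    structure_path: str | Path | None = None,
    dt: float = 1.0,
) -> Trajectory:
    """Read a trajectory (XTC needs ``structure_path``; multi-model PDB/GRO
    stands alone).

    Frames lacking time stamps get ``index * dt`` (ps).
    """
    if structure_path is not None:
        u = _universe(structure_path, path)
    else:
        u = _universe(path)
    if len(u.atoms) != topology.n_atoms:
        raise TopologyError(
            f"trajectory has {len(u.atoms)} atoms, topology has {topology.n_atoms}"
        )
    fallback_dims = u.dimensions
    if fallback_dims is None:
        fallback_dims = _cryst1_box(Path(path))
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, ts in enumerate(u.trajectory):
            dims = ts.dimensions if ts.dimensions is not None else fallback_dims
            box = _check_box(dims)
            t = float(getattr(ts, "time", 0.0) or 0.0)
            if t == 0.0 and i > 0:
                t = i * dt
            frames.append(
                Frame(time=t, coordinates=u.atoms.positions.astype(np.float64), box=box))
    times = [f.time for f in frames]
    if len(frames) > 1 and all(t == 0.0 for t in times):
        for i, f in enumerate(frames):
            f.time = i * dt
    return Trajectory(frames)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _mda_universe_from(topology: Topology, frame: Frame, resnames: Sequence[str]):
    import MDAnalysis as mda

    n_res = len(topology.molecule_id_list)
    u = mda.Universe.empty(
        n_atoms=topology.n_atoms,
        n_residues=n_res,
        atom_resindex=[topology.molecule_id_list.index(a.molecule_id) for a in topology.atoms]
        if topology.molecule_id_list != list(range(n_res))
        else topology.molecule_ids,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.atom_name for a in topology.atoms])
    u.add_TopologyAttr("resnames", list(resnames))
    u.add_TopologyAttr("resids", [m + 1 for m in topology.molecule_id_list])
    u.atoms.positions = frame.coordinates
    u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
    return u


def write_structure(path: str | Path, topology: Topology, frame: Frame, resnames: Sequence[str]) -> None:
    """Write a single frame as GRO or PDB (per-molecule residue names)."""
    u = _mda_universe_from(topology, frame, resnames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(
    path: str | Path, topology: Topology, trajectory: Trajectory, resnames: Sequence[str]
) -> None:
    """Write a multi-frame trajectory (XTC, or multi-model PDB by suffix)."""
    import MDAnalysis as mda

    u = _mda_universe_from(topology, trajectory[0], resnames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_atoms, multiframe=True) as w:
            for frame in trajectory:
                u.atoms.positions = frame.coordinates
                u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
                u.trajectory.ts.time = frame.time
                w.write(u.atoms)


def write_table(records: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write a result table as CSV or JSON; round-trips at full precision."""
    if records is None:
        raise ValueError("records must not be None")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        records.to_csv(path, index=True)
    elif format == "json":
        payload = json.loads(records.to_json(orient="split", double_precision=15))
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown table format {format!r}")
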