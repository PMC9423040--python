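"""Leaflet assignment and interface geometry.

Covers the structural observables of a lamellar galactolipid system:

* leaflet partition of the lipids along the membrane normal,
* area per lipid A_L = box surface area / lipids per leaflet,
* bilayer widths D_RR (between mean ring centre-of-mass positions of the
  two leaflets) and D_CC (between mean positions of the glycerol C2″
  atoms),
* head-group vector angle ω against the bilayer normal, with the tilt
  reported as the mode of the ω distribution,
* the angle between the least-squares planes of the α and β rings,
* electron-density profiles along the normal, and
* the probability of finding terminal-CH₃ density inside the watered part
  of the interface (overlap of the CH₃ profile with non-zero water
  density).

All positions are Å; electron counts come from the topology annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .hbonds import minimum_image
from .io import Frame, Trajectory
from .topology import Moiety, RING_MOIETIES, Topology

logger = logging.getLogger(__name__)

__all__ = [
    "LeafletAssignment",
    "AngleDistribution",
    "DensityProfile",
    "assign_leaflets",
    "area_per_lipid",
    "bilayer_width",
    "head_vector_angles",
    "ring_plane_angle",
    "electron_density_profile",
    "interface_overlap_probability",
]


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class LeafletAssignment:
    """Frame-stable partition of lipids into leaflets along the normal.

    Labels run 0..n_leaflets−1 ordered by mean head-group position; in a
    double-bilayer (4-leaflet) stack, leaflets (0,1) and (2,3) form the
    two bilayers.  Even labels face the −normal direction (their heads
    point outward toward smaller coordinates), odd labels face +normal.
    """

    labels: dict[int, int]
    n_leaflets: int
    normal_axis: int = 2
    leaflet_positions: np.ndarray | None = None  # mean head position per label, Å

    def label_of(self, molecule_id: int) -> int:
        return self.labels[molecule_id]

    def members(self, label: int) -> list[int]:
        return sorted(m for m, l in self.labels.items() if l == label)

    def outward_sign(self, label: int) -> int:
        """+1 if the leaflet's heads face +normal, −1 otherwise."""
        return -1 if label % 2 == 0 else 1


@dataclass
class AngleDistribution:
    """Histogrammed angle distribution in degrees, normalised to unit area."""

    bin_edges: np.ndarray
    probability: np.ndarray  # density per degree; sum(prob * width) == 1
    mode_deg: float
    samples: np.ndarray | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class DensityProfile:
    """Electron-density profiles along the normal (e⁻/Å³ per selection)."""

    axis: int
    bin_edges: np.ndarray
    densities: dict[str, np.ndarray]
    cross_section: float  # box area perpendicular to the axis, Å²
    n_frames: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def total_electrons(self, selection: str) -> float:
        """Integral of the profile (per frame) in electrons."""
        return float(self.densities[selection].sum() * self.cross_section * self.bin_width)


# ---------------------------------------------------------------------------
# Leaflets
# ---------------------------------------------------------------------------

def _head_com_positions(
    frames: Trajectory | Frame, topology: Topology, axis: int
) -> tuple[list[int], np.ndarray]:
    """Time-averaged head-group centre position along the normal per lipid."""
    frame_list = frames.frames if isinstance(frames, Trajectory) else [frames]
    lipids = topology.lipid_ids
    pos = np.zeros(len(lipids))
    for f in frame_list:
        for k, mol in enumerate(lipids):
            head = topology.head_atom_ids(mol)
            if head.size == 0:
                raise ValueError(f"lipid {mol} has no annotated head atoms")
            w = topology.electron_counts[head].astype(float)
            pos[k] += np.average(f.coordinates[head, axis], weights=w)
    pos /= len(frame_list)
    return lipids, pos


def _kmeans_1d(values: np.ndarray, k: int, n_iter: int = 200) -> np.ndarray:
    """Deterministic 1-D k-means: quantile init + Lloyd iterations."""
    centers = np.quantile(values, (np.arange(k) + 0.5) / k)
    labels = np.zeros(len(values), dtype=int)
    for _ in range(n_iter):
        labels = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [values[labels == j].mean() if np.any(labels == j) else centers[j] for j in range(k)]
        )
        if np.allclose(new, centers):
            break
        centers = new
    return labels


def assign_leaflets(
    frames: Trajectory | Frame,
    topology: Topology,
    n_leaflets: int = 2,
    normal_axis: int = 2,
) -> LeafletAssignment:
    """Partition lipids into leaflets from time-averaged head positions.

    Two leaflets: split at the midplane (mean head position).  Four
    leaflets (double bilayer): 1-D k-means with k=4.  The assignment is
    computed once and reused for every frame.
    """
    if n_leaflets not in (2, 4):
        raise ValueError("n_leaflets must be 2 or 4")
    lipids, pos = _head_com_positions(frames, topology, normal_axis)
    if len(lipids) < n_leaflets:
        raise ValueError(f"{len(lipids)} lipids cannot fill {n_leaflets} leaflets")
    if np.ptp(pos) < 1e-9:
        raise DegenerateGeometryError("all head positions coincide along the normal")

    if n_leaflets == 2:
        mid = pos.mean()
        raw = (pos > mid).astype(int)
    else:
        raw = _kmeans_1d(pos, 4)

    # order labels by mean position along the normal
    means = []
    for j in sorted(set(raw)):
        means.append((np.mean(pos[raw == j]), j))
    if len(means) != n_leaflets:
        raise DegenerateGeometryError("leaflet clustering produced an empty leaflet")
    means.sort()
    remap = {old: new for new, (_, old) in enumerate(means)}
    labels = {mol: remap[raw[k]] for k, mol in enumerate(lipids)}
    leaflet_pos = np.array([m for m, _ in means])
    if np.any(np.diff(leaflet_pos) <= 0):
        raise DegenerateGeometryError("leaflet positions are not strictly ordered")
    return LeafletAssignment(
        labels=labels,
        n_leaflets=n_leaflets,
        normal_axis=normal_axis,
        leaflet_positions=leaflet_pos,
    )


# ---------------------------------------------------------------------------
# Structural parameters
# ---------------------------------------------------------------------------

def area_per_lipid(frame: Frame, leaflets: LeafletAssignment) -> dict:
    """A_L = in-plane box area / lipids per leaflet, per leaflet and mean."""
    axes = [a for a in range(3) if a != leaflets.normal_axis]
    area = float(frame.box[axes[0]] * frame.box[axes[1]])
    if area <= 0:
        raise ValueError("box has zero in-plane area")
    per_leaflet = {}
    for label in range(leaflets.n_leaflets):
        n = len(leaflets.members(label))
        if n == 0:
            raise ValueError(f"leaflet {label} is empty")
        per_leaflet[label] = area / n
    return {"per_leaflet": per_leaflet, "mean": float(np.mean(list(per_leaflet.values())))}


def bilayer_width(
    frames: Trajectory,
    topology: Topology,
    leaflets: LeafletAssignment,
    mode: str = "D_RR",
    atom_name: str = "C2''",
    leaflet_pair: tuple[int, int] = (0, 1),
) -> tuple[float, float]:
    """Bilayer width (mean ± SD over frames, Å).

    ``D_RR``: distance between the mean normal positions of the per-lipid
    ring centres-of-mass in the two leaflets.  ``D_CC``: same for the
    glycerol C2″ atom (name configurable; the synthetic lipid uses
    ``C2P``).
    """
    axis = leaflets.normal_axis
    lo, hi = leaflet_pair
    widths = []
    for f in frames:
        means = {}
        for label in (lo, hi):
            vals = []
            for mol in leaflets.members(label):
                ids = topology.atoms_of(mol)
                if mode == "D_RR":
                    sel = ids[[topology.atoms[i].moiety in RING_MOIETIES for i in ids]]
                    if sel.size == 0:
                        raise ValueError(f"lipid {mol}: no ring atoms annotated")
                    w = topology.electron_counts[sel].astype(float)
                    vals.append(np.average(f.coordinates[sel, axis], weights=w))
                elif mode == "D_CC":
                    sel = [i for i in ids if topology.atoms[i].atom_name == atom_name]
                    if not sel:
                        raise ValueError(f"lipid {mol}: atom {atom_name!r} not found")
                    vals.append(float(np.mean(f.coordinates[sel, axis])))
                else:
                    raise ValueError(f"unknown width mode {mode!r}")
            means[label] = float(np.mean(vals))
        widths.append(abs(means[hi] - means[lo]))
    widths = np.asarray(widths)
    return float(widths.mean()), float(widths.std(ddof=0))


# ---------------------------------------------------------------------------
# Angles
# ---------------------------------------------------------------------------

def _histogram_angles(samples: np.ndarray, bin_width: float, amax: float = 180.0) -> AngleDistribution:
    n_bins = int(round(amax / bin_width))
    edges = np.linspace(0.0, amax, n_bins + 1)
    counts, _ = np.histogram(samples, bins=edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("no angle samples")
    prob = counts / (total * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = counts.max()
    # ties broken toward the smaller angle
    mode = float(centers[np.nonzero(counts == peak)[0][0]])
    if np.count_nonzero(counts == peak) > 1:
        logger.info("angle-distribution mode tie; reporting the smallest-angle bin")
    return AngleDistribution(bin_edges=edges, probability=prob, mode_deg=mode, samples=samples)


def head_vector_angles(
    frames: Trajectory,
    topology: Topology,
    leaflets: LeafletAssignment,
    vector_spec: tuple[str, str],
    bin_width: float = 2.0,
) -> AngleDistribution:
    """Distribution of the head-group vector angle ω against the normal.

    For each lipid and frame, ω = arccos(v̂ · n̂) with v the vector from
    ``vector_spec[0]`` to ``vector_spec[1]`` (e.g. C2″ → O4′) and n̂ the
    *outward* leaflet normal, so lower-leaflet vectors are reflected and
    ω is leaflet-symmetric.  The mode of the distribution is the tilt.
    """
    from_name, to_name = vector_spec
    axis = leaflets.normal_axis
    samples = []
    for f in frames:
        for mol, label in leaflets.labels.items():
            i = topology.find_atom(mol, from_name)
            j = topology.find_atom(mol, to_name)
            v = minimum_image(f.coordinates[j] - f.coordinates[i], f.box)
            norm = np.linalg.norm(v)
            if norm < 1e-9:
                raise DegenerateGeometryError(
                    f"zero-length head vector for lipid {mol} at t={f.time}"
                )
            cosw = leaflets.outward_sign(label) * v[axis] / norm
            samples.append(np.degrees(np.arccos(np.clip(cosw, -1.0, 1.0))))
    return _histogram_angles(np.asarray(samples), bin_width)


def _plane_normal(points: np.ndarray) -> np.ndarray:
    """Oriented least-squares plane normal of ≥3 points.

    The unsigned normal is the singular vector of the smallest singular
    value; its sign is fixed by the cross product of the first two
    centred points, so the result is deterministic in the atom order.
    """
    c = points.mean(axis=0)
    x = points - c
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    if s[1] < 1e-9:  # rank < 2: collinear
        raise DegenerateGeometryError("ring atoms are collinear")
    n = vt[-1]
    ref = np.cross(x[0], x[1])
    if np.linalg.norm(ref) > 1e-12 and np.dot(n, ref) < 0:
        n = -n
    return n / np.linalg.norm(n)


def ring_plane_angle(
    frames: Trajectory,
    topology: Topology,
    ring_a_atoms: Sequence[str],
    ring_b_atoms: Sequence[str],
    bin_width: float = 2.0,
) -> AngleDistribution:
    """Distribution of the angle between the α- and β-ring planes.

    Plane normals are oriented by each ring's atom ordering (cross product
    of the first two centred atoms), so the angle lives in [0°, 180°] and
    coplanar rings with consistently ordered atoms give 0°.
    """
    samples = []
    for f in frames:
        for mol in topology.lipid_ids:
            pa = np.array([f.coordinates[topology.find_atom(mol, n)] for n in ring_a_atoms])
            pb = np.array([f.coordinates[topology.find_atom(mol, n)] for n in ring_b_atoms])
            na, nb = _plane_normal(pa), _plane_normal(pb)
            ang = np.degrees(np.arccos(np.clip(float(na @ nb), -1.0, 1.0)))
            samples.append(ang)
    return _histogram_angles(np.asarray(samples), bin_width)


# ---------------------------------------------------------------------------
# Density profiles and interface overlap
# ---------------------------------------------------------------------------

def electron_density_profile(
    frames: Trajectory,
    topology: Topology,
    selections: Mapping[str, np.ndarray],
    bin_width: float = 1.0,
    axis: int = 2,
) -> DensityProfile:
    """Time-averaged electron-density profiles along the normal.

    Atoms are point-assigned to bins (no smoothing kernel); for each
    selection the integral over the box reproduces the selection's total
    electron count per frame.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    box = frames[0].box
    n_bins = max(1, int(round(box[axis] / bin_width)))
    edges = np.linspace(0.0, box[axis], n_bins + 1)
    width = edges[1] - edges[0]
    axes = [a for a in range(3) if a != axis]
    area = float(box[axes[0]] * box[axes[1]])

    densities = {name: np.zeros(n_bins) for name in selections}
    for f in frames:
        z = np.mod(f.coordinates[:, axis], box[axis])
        for name, sel in selections.items():
            sel = np.asarray(sel, dtype=np.int64)
            w = topology.electron_counts[sel].astype(float)
            hist, _ = np.histogram(z[sel], bins=edges, weights=w)
            densities[name] += hist
    for name in densities:
        densities[name] /= len(frames) * area * width
    return DensityProfile(
        axis=axis, bin_edges=edges, densities=densities, cross_section=area, n_frames=len(frames)
    )


def interface_overlap_probability(
    ch3_profile: DensityProfile,
    water_profile: DensityProfile,
    ch3_name: str = "ch3",
    water_name: str = "water",
    midplane: float | None = None,
    water_threshold_frac: float = 1e-3,
) -> dict:
    """Probability of finding CH₃ density where water density is non-zero.

    Per leaflet (bins below/above the bilayer midplane), the probability
    is the CH₃ density summed over bins whose water density exceeds
    ``water_threshold_frac`` of the bulk (maximum) water density, divided
    by the total CH₃ density on that side.  The midplane defaults to the
    CH₃-density-weighted centre.
    """
    if ch3_profile.bin_edges.shape != water_profile.bin_edges.shape or not np.allclose(
        ch3_profile.bin_edges, water_profile.bin_edges
    ):
        raise ValueError("profiles must share the same binning")
    ch3 = ch3_profile.densities[ch3_name]
    wat = water_profile.densities[water_name]
    centers = ch3_profile.bin_centers
    if ch3.sum() <= 0:
        raise ValueError("empty CH3 profile")
    if midplane is None:
        midplane = float(np.average(centers, weights=ch3))
    watered = wat > water_threshold_frac * wat.max()
    out = {}
    for name, side in (("lower", centers <= midplane), ("upper", centers > midplane)):
        tot = ch3[side].sum()
        out[name] = float(ch3[side & watered].sum() / tot) if tot > 0 else 0.0
    out["mean"] = 0.5 * (out["lower"] + out["upper"])
    out["midplane"] = midplane
    return out
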