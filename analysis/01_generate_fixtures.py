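#!/usr/bin/env python
"""Step 1: generate the synthetic membrane systems used by steps 2-5.

Writes, under results/fixtures/:
  bilayer/        2-leaflet lamellar system with planted H-bonds and bridges
  double_bilayer/ 4-leaflet stack with a vertical (inter-bilayer) bridge
  angle_cloud/    orientation/density fixture with planted head tilt 32 deg
                  and ring dihedral 82 deg
Each directory holds fixture.gro, fixture_traj.pdb and manifest.json.
"""

import json
from pathlib import Path

from liface import FixtureSpec, PlantedBridge, PlantedHBond
from liface.io import write_structure, write_trajectory
from liface.synth import generate_angle_cloud, generate_fixture

RESULTS = Path(__file__).resolve().parent.parent / "results" / "fixtures"

BILAYER = FixtureSpec(
    n_lipids_per_leaflet=4, n_leaflets=2, n_frames=5, seed=2024,
    planted_hbonds=(
        PlantedHBond(0, "alpha_ring", "water"),
        PlantedHBond(1, "beta_ring", "lipid"),
        PlantedHBond(4, "glycerol", "water"),
        PlantedHBond(6, "alpha_ring", "lipid",
                     partner_lipid=7, partner_moiety="beta_ring"),
    ),
    planted_bridges=(
        PlantedBridge(2, "alpha_ring", 3, "beta_ring", "double_donor"),
    ),
    n_free_waters=6,
)

DOUBLE_BILAYER = FixtureSpec(
    n_lipids_per_leaflet=4, n_leaflets=4, n_frames=5, seed=2025,
    planted_hbonds=(
        PlantedHBond(1, "beta_ring", "water"),
        PlantedHBond(13, "alpha_ring", "lipid"),
    ),
    planted_bridges=(
        PlantedBridge(4, "alpha_ring", 8, "beta_ring", "mixed"),   # vertical
        PlantedBridge(14, "glycerol", 15, "alpha_ring", "double_donor"),
    ),
    n_free_waters=6,
)

ANGLE_CLOUD = FixtureSpec(
    n_lipids_per_leaflet=16, n_leaflets=2, n_frames=10, seed=2026,
    head_vector_angle=32.0, ring_dihedral=82.0, ch3_sigma=3.0,
    n_free_waters=12,
)


def emit(name: str, generator, spec: FixtureSpec) -> None:
    out = RESULTS / name
    out.mkdir(parents=True, exist_ok=True)
    topology, traj, manifest = generator(spec)
    write_structure(out / "fixture.gro", topology, traj[0], manifest.resnames)
    write_trajectory(out / "fixture_traj.pdb", topology, traj, manifest.resnames)
    (out / "manifest.json").write_text(json.dumps({
        "hbond_triples": manifest.hbond_triples,
        "bridges": manifest.bridge_records,
        "leaflet_labels": manifest.leaflet_labels,
        "n_lipids": manifest.n_lipids,
        "n_waters": manifest.n_waters,
        "n_leaflets": spec.n_leaflets,
        "head_vector_angle": spec.head_vector_angle,
        "ring_dihedral": spec.ring_dihedral,
    }, indent=1))
    print(f"{name}: {manifest.n_lipids} lipids, {manifest.n_waters} waters, "
          f"{len(manifest.hbond_triples)} planted H-bonds, "
          f"{len(manifest.bridge_records)} planted bridges -> {out}")


def main() -> None:
    emit("bilayer", generate_fixture, BILAYER)
    emit("double_bilayer", generate_fixture, DOUBLE_BILAYER)
    emit("angle_cloud", generate_angle_cloud, ANGLE_CLOUD)


if __name__ == "__main__":
    main()
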