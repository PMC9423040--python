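#!/usr/bin/env python
"""Step 2: hydrogen-bond detection and per-head tallies.

Reads the fixtures from step 1, detects all H-bonds with the geometric
criterion (d <= 3.25 A, angle >= 150 deg), and writes per-head lipid-water
and lipid-lipid summary tables under results/hbonds/.
"""

from pathlib import Path

from liface import (
    HBondCriteria,
    assign_leaflets,
    detect_hbonds,
    load_structure,
    load_trajectory,
    tally_lipid_lipid,
    tally_lipid_water,
    write_table,
)
from liface.hbonds import hbonds_to_dataframe

ROOT = Path(__file__).resolve().parent.parent / "results"


def analyse(name: str, n_leaflets: int) -> None:
    fix = ROOT / "fixtures" / name
    out = ROOT / "hbonds" / name
    out.mkdir(parents=True, exist_ok=True)
    topology, _ = load_structure(fix / "fixture.gro")
    traj = load_trajectory(fix / "fixture_traj.pdb", topology)
    criteria = HBondCriteria()
    leaflets = assign_leaflets(traj, topology, n_leaflets=n_leaflets)
    hbonds = [b for f in traj for b in detect_hbonds(f, topology, criteria)]
    write_table(hbonds_to_dataframe(hbonds), out / "hbonds.csv")
    lw = tally_lipid_water(hbonds, topology, traj.times)
    write_table(lw, out / "lipid_water_summary.csv")
    ll = tally_lipid_lipid(hbonds, topology, leaflets, traj.times)
    write_table(ll, out / "lipid_lipid_summary.csv")
    print(f"{name}: {len(hbonds)} H-bonds over {len(traj)} frames")
    print(lw.round(4))


def main() -> None:
    analyse("bilayer", 2)
    analyse("double_bilayer", 4)


if __name__ == "__main__":
    main()
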