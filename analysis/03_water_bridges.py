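#!/usr/bin/env python
"""Step 3: water-bridge detection and per-head tallies.

Reads the fixtures from step 1, enumerates single-water bridges between
lipid pairs, and writes moiety-pair / orientation summaries under
results/bridges/.
"""

from pathlib import Path

from liface import (
    HBondCriteria,
    assign_leaflets,
    detect_hbonds,
    detect_water_bridges,
    load_structure,
    load_trajectory,
    tally_bridges,
    write_table,
)
from liface.bridges import bridges_to_dataframe

ROOT = Path(__file__).resolve().parent.parent / "results"


def analyse(name: str, n_leaflets: int) -> None:
    fix = ROOT / "fixtures" / name
    out = ROOT / "bridges" / name
    out.mkdir(parents=True, exist_ok=True)
    topology, _ = load_structure(fix / "fixture.gro")
    traj = load_trajectory(fix / "fixture_traj.pdb", topology)
    leaflets = assign_leaflets(traj, topology, n_leaflets=n_leaflets)
    hbonds = [b for f in traj for b in detect_hbonds(f, topology, HBondCriteria())]
    bridges = detect_water_bridges(hbonds, topology, leaflets)
    write_table(bridges_to_dataframe(bridges), out / "bridges.csv")
    summary = tally_bridges(bridges, topology, traj.times)
    write_table(summary, out / "bridge_summary.csv")
    vertical = sum(1 for b in bridges if b.orientation == "vertical")
    print(f"{name}: {len(bridges)} bridges ({vertical} vertical) "
          f"over {len(traj)} frames")
    print(summary.round(4))


def main() -> None:
    analyse("bilayer", 2)
    analyse("double_bilayer", 4)


if __name__ == "__main__":
    main()
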