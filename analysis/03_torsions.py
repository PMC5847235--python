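#!/usr/bin/env python
"""Glycosidic torsion statistics: rotamer occupancies and energy maps.

Writes per-linkage phi/psi/omega occupancies for both conditions and
the Boltzmann energy grid of the flexible 5-4 (1-6) linkage's psi-omega
plane, the plane where flow-induced state changes are expected first.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from glycoflow.io import read_trajectory
from glycoflow.topology import build_man6glcnac2_topology
from glycoflow.torsions import (assign_rotamer_states, boltzmann_energy_map,
                                population_map2d, torsion_series)

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "torsions"
BURN = 0.25


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    topology = build_man6glcnac2_topology()
    rows = []
    for label in ("diffusion", "flow"):
        traj = read_trajectory(ROOT / "trajectories" / f"{label}.extxyz")
        skip = int(round(BURN * traj.n_frames))
        for lid, linkage in topology.linkages.items():
            for angle, _ in linkage.dihedrals:
                s = torsion_series(traj, topology, lid, angle)
                _, occ = assign_rotamer_states(s.values[skip:])
                rows.append({"condition": label, "linkage": lid,
                             "angle": angle,
                             **{f"p({k})": round(v, 3) for k, v in occ.items()}})
        psi = torsion_series(traj, topology, "5-4", "psi")
        omega = torsion_series(traj, topology, "5-4", "omega")
        emap = boltzmann_energy_map(population_map2d(psi, omega, 15.0), 300.0)
        pd.DataFrame(emap.energies.filled(np.nan)).to_csv(
            OUT / f"energy_5-4_psi_omega_{label}.tsv", sep="\t", index=False)
        from glycoflow.plots import plot_energy_map
        plot_energy_map(emap, OUT / f"energy_5-4_psi_omega_{label}.png",
                        title=f"5-4 psi/omega ({label})")
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "occupancies.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"\ntables written to {OUT}")


if __name__ == "__main__":
    main()
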