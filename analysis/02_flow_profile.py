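#!/usr/bin/env python
"""Bulk velocity and slab velocity profile for both conditions.

Expected picture: the zero-force run hovers near 0; the flow run
reaches a steady bulk velocity, and its profile along y dips inside
the tethered glycan's range of movement and recovers toward the far
field above it.
"""

from pathlib import Path

import numpy as np

from glycoflow.flow import bulk_velocity, slab_velocity_profile
from glycoflow.io import read_trajectory
from glycoflow.units import velocity_to_si

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "flow"
BURN = 0.25


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    profiles = {}
    for label in ("diffusion", "flow"):
        traj = read_trajectory(ROOT / "trajectories" / f"{label}.extxyz")
        mean, sd = bulk_velocity(traj, "solvent", "x", BURN)
        print(f"{label}: bulk v_x = {mean:+.3f} ± {sd:.3f} Å/ps "
              f"({velocity_to_si(mean):+.1f} ± {velocity_to_si(sd):.1f} m/s)")
        prof = slab_velocity_profile(traj, "solvent", "y", "x", 7.0,
                                     burn_in=BURN)
        profiles[label] = prof
        prof.to_frame().to_csv(OUT / f"profile_{label}.tsv", sep="\t",
                               index=False)
        if label == "flow":
            sol = np.flatnonzero(traj.atoms.kind == "solute")
            ymax = traj.positions_array(sol)[:, :, 1].max()
            occ = prof.counts > 0
            dip = prof.means[occ & (prof.centers < ymax)].min()
            print(f"  solute reaches y = {ymax:.1f} Å; slowest slab below it "
                  f"{dip:.3f} Å/ps vs bulk {prof.bulk_mean:.3f} Å/ps")
    from glycoflow.plots import plot_velocity_profile
    plot_velocity_profile(profiles, OUT / "profiles.png")
    print(f"profiles written to {OUT}")


if __name__ == "__main__":
    main()
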