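#!/usr/bin/env python
"""Run the matched diffusion/flow pair of desk-scale simulations.

Two runs from the same seed and initial state, differing only in the
body force on the solvent beads, are the raw material for every later
comparison.  Trajectories (extended XYZ with velocities) land in
results/trajectories/.
"""

import argparse
import time
from pathlib import Path

from glycoflow.io import write_trajectory
from glycoflow.simulate import desk_config, run_simulation
from glycoflow.topology import build_man6glcnac2_topology

OUT = Path(__file__).resolve().parent.parent / "results" / "trajectories"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--duration", type=float, default=40.0, help="ps")
    args = ap.parse_args()

    OUT.mkdir(parents=True, exist_ok=True)
    topology = build_man6glcnac2_topology()
    for label, mult in (("diffusion", 0.0), ("flow", 1.0)):
        cfg = desk_config(duration=args.duration, seed=args.seed).with_flow(mult)
        t0 = time.perf_counter()
        traj = run_simulation(cfg, topology)
        path = OUT / f"{label}.extxyz"
        write_trajectory(traj, path)
        cfg.to_yaml(OUT / f"{label}.yaml")
        print(f"{label}: {traj.n_frames} frames ({cfg.duration} ps, "
              f"{traj.n_atoms} atoms) in {time.perf_counter() - t0:.1f} s "
              f"-> {path}")


if __name__ == "__main__":
    main()
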