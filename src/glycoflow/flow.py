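"""Bulk flow velocity and slab velocity profiles.

The bulk velocity along an axis is the mean over frames of the
per-frame mean over selected atoms,

    v_bulk = (1/m) sum_j (1/n) sum_i v_ij,

with the spread reported as the standard deviation of the per-frame
means.  The slab profile averages the instantaneous flow-axis
velocities of atoms whose (wrapped) profile-axis coordinate falls in
overlapping slabs of fixed width, covering the whole box periodically.
Analysis entry points discard an initial burn-in window (default the
first 10% of frames).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Trajectory, select
from .units import velocity_to_si

__all__ = ["VelocityProfile", "bulk_velocity", "slab_velocity_profile",
           "velocity_to_si"]

_AXIS = {"x": 0, "y": 1, "z": 2}


def _axis_index(axis) -> int:
    if isinstance(axis, str):
        try:
            return _AXIS[axis]
        except KeyError:
            raise ValueError(f"axis must be x, y or z, got {axis!r}") from None
    return int(axis)


def _burn_slice(n_frames: int, burn_in) -> slice:
    """First-``burn_in`` discard window: fraction if < 1, else frame count."""
    if burn_in is None:
        return slice(0, n_frames)
    skip = int(round(burn_in * n_frames)) if 0 <= burn_in < 1 else int(burn_in)
    if skip >= n_frames:
        raise ValueError(f"burn-in {burn_in} discards all {n_frames} frames")
    return slice(skip, n_frames)


@dataclass
class VelocityProfile:
    centers: np.ndarray  # Å along the profile axis
    means: np.ndarray  # per-slab mean velocity; NaN where count == 0
    counts: np.ndarray  # samples per slab (atom-frames)
    slab_width: float  # Å
    bulk_mean: float
    bulk_sd: float
    unit: str = "A/ps"

    def to_si(self) -> "VelocityProfile":
        if self.unit == "m/s":
            return self
        return VelocityProfile(
            self.centers, velocity_to_si(self.means, self.unit), self.counts,
            self.slab_width, velocity_to_si(self.bulk_mean, self.unit),
            velocity_to_si(self.bulk_sd, self.unit), "m/s")

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"center": self.centers, "mean": self.means,
                             "count": self.counts})


def bulk_velocity(trajectory: Trajectory, selection="solvent", axis="x",
                  burn_in: float = 0.1) -> tuple[float, float]:
    """Bulk velocity (Å/ps): inner mean over atoms, outer over frames.

    Returns (mean, sd) where sd is taken over the per-frame means.
    """
    ax = _axis_index(axis)
    idx = select(trajectory.atoms, selection)
    sl = _burn_slice(trajectory.n_frames, burn_in)
    v = trajectory.velocities_array(idx)[sl, :, ax]
    frame_means = v.mean(axis=1)
    return float(frame_means.mean()), float(frame_means.std(ddof=0))


def slab_velocity_profile(trajectory: Trajectory, selection="solvent",
                          profile_axis="y", flow_axis="x",
                          slab_width: float = 7.0, slab_stride: float = 1.0,
                          burn_in: float = 0.1) -> VelocityProfile:
    """Mean flow-axis velocity in overlapping slabs along the profile axis.

    Slab centers run across the full box at ``slab_stride`` spacing;
    membership is periodic (coordinates wrapped into the box, slabs
    wrap around the boundary), so the profile repeats above and below
    the box.  Empty slabs get count 0 and mean NaN rather than a
    silent 0.
    """
    if slab_width <= 0 or slab_stride <= 0:
        raise ValueError("slab_width and slab_stride must be positive")
    pax = _axis_index(profile_axis)
    fax = _axis_index(flow_axis)
    idx = select(trajectory.atoms, selection)
    sl = _burn_slice(trajectory.n_frames, burn_in)
    box_l = float(trajectory.box[pax])
    coords = np.mod(trajectory.positions_array(idx)[sl, :, pax], box_l).ravel()
    vels = trajectory.velocities_array(idx)[sl, :, fax].ravel()

    centers = np.arange(0.0, box_l, slab_stride)
    means = np.full(len(centers), np.nan)
    counts = np.zeros(len(centers), dtype=int)
    half = slab_width / 2.0
    for k, c in enumerate(centers):
        # periodic membership in [c - w/2, c + w/2)
        mask = np.mod(coords - (c - half), box_l) < slab_width
        counts[k] = int(mask.sum())
        if counts[k]:
            means[k] = vels[mask].mean()

    frame_means = trajectory.velocities_array(idx)[sl, :, fax].mean(axis=1)
    return VelocityProfile(
        centers=centers, means=means, counts=counts, slab_width=slab_width,
        bulk_mean=float(frame_means.mean()),
        bulk_sd=float(frame_means.std(ddof=0)),
    )
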