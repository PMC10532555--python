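"""Per-frame distance series between residue selections and contact statistics.

A "contact" follows the hydrogen-bond-scale criterion: two heavy atoms within
a closed cutoff, default 3.0 Å. The per-frame quantity is the minimum
min-image distance over all cross pairs of the two selections, so the
reported "minimum observed distance" for a pair of residues is the minimum
over frames of that per-frame minimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .errors import DomainError
from .trajio import Selection, Trajectory

DEFAULT_HBOND_CUTOFF = 3.0  # Å, heavy-atom hydrogen-bond length scale


@dataclass
class ContactSeries:
    """Per-frame minimum heavy-atom distance between two labelled selections."""

    label_a: str
    label_b: str
    distances: np.ndarray  # Å, one per analyzed frame
    timestep: float  # ps per analyzed frame
    frames: np.ndarray = field(default=None)

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        if self.frames is None:
            self.frames = np.arange(len(self.distances))

    @property
    def n_frames(self) -> int:
        return len(self.distances)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "time_ps": self.frames * self.timestep,
                "distance_A": self.distances,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label_a="A", label_b="B", timestep=None) -> "ContactSeries":
        df = pd.read_csv(path)
        if timestep is None:
            t = df["time_ps"].to_numpy()
            f = df["frame"].to_numpy()
            timestep = float((t[1] - t[0]) / (f[1] - f[0])) if len(df) > 1 else 1.0
        return cls(label_a, label_b, df["distance_A"].to_numpy(),
                   timestep, frames=df["frame"].to_numpy())


@dataclass(frozen=True)
class ContactStats:
    """Occupancy fraction plus min/mean/max of a distance series."""

    fraction_in_contact: float
    min_distance: float
    mean_distance: float
    max_distance: float
    cutoff: float
    n_frames: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def min_distance_series(traj: Trajectory, sel_a: Selection, sel_b: Selection,
                        stride: int = 1) -> ContactSeries:
    """Per-frame minimum min-image distance over all cross pairs A × B."""
    for sel, side in ((sel_a, "A"), (sel_b, "B")):
        if len(sel) == 0:
            raise DomainError(f"selection {side} ({sel.label!r}) is empty")
    if np.intersect1d(sel_a.indices, sel_b.indices).size:
        raise DomainError(
            f"selections {sel_a.label!r} and {sel_b.label!r} overlap"
        )
    dists, frames = [], []
    for i, coords, box in traj.iter_frames(stride):
        dists.append(
            geometry.min_cross_distance(coords, box, sel_a.indices, sel_b.indices)
        )
        frames.append(i)
    return ContactSeries(
        label_a=sel_a.label, label_b=sel_b.label,
        distances=np.array(dists), timestep=traj.timestep * stride,
        frames=np.array(frames),
    )


def contact_stats(series: ContactSeries,
                  cutoff: float = DEFAULT_HBOND_CUTOFF) -> ContactStats:
    """Occupancy (fraction of frames with distance ≤ cutoff, closed interval)
    and distance statistics of a series."""
    if series.n_frames == 0:
        raise DomainError("empty contact series")
    d = series.distances
    return ContactStats(
        fraction_in_contact=float(np.mean(d <= cutoff)),
        min_distance=float(np.min(d)),
        mean_distance=float(np.mean(d)),
        max_distance=float(np.max(d)),
        cutoff=float(cutoff),
        n_frames=series.n_frames,
    )


def hbond_candidate_pairs(traj: Trajectory, frame_index: int,
                          polar_sel: Selection, water_sel: Selection,
                          cutoff: float = DEFAULT_HBOND_CUTOFF):
    """Hydrogen-bond candidate pairs at one frame.

    Returns all polar–polar, polar–water and water–water heavy-atom pairs
    within the closed cutoff, as sorted (i, j, distance) with i < j.
    """
    union = np.union1d(polar_sel.indices, water_sel.indices)
    coords, box = traj.frame(frame_index)
    return geometry.pairs_within_cutoff(coords, box, union, union, cutoff)
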