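"""Side-chain fluctuation (RMSF) and stable-spatial-position (SP) analysis.

A polar side chain that swings between a few preferred orientations shows up
in the time series of χ — the angle between the Cα→terminal-polar-atom vector
and the host helix axis — as a small number of narrow bands. A *stable
spatial position* is a band whose fluctuation amplitude is on par with
thermal fluctuations: operationally, an angular mode whose RMS width is at
most ``sp_amplitude_ratio`` times a thermal baseline, holding at least
``min_occupancy`` of the frames.

χ is defined through an arccos, so angles live on [0°, 180°] and are treated
as a plain (non-circular) 1-D variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import argrelmax

from . import geometry
from .errors import DomainError
from .trajio import Selection, Trajectory

#: Default terminal polar heavy atom used for the side-chain vector.
SIDECHAIN_TIP_ATOMS = {
    "ASN": "ND2", "GLN": "NE2", "ASP": "OD1", "GLU": "OE1",
    "HIS": "NE2", "SER": "OG", "THR": "OG1", "TYR": "OH",
    "ARG": "NH1", "LYS": "NZ", "TRP": "NE1",
}


@dataclass
class RmsfResult:
    """Per-atom RMSF (Å) about each atom's time-mean position."""

    atom_indices: np.ndarray
    rmsf: np.ndarray

    def __post_init__(self):
        self.rmsf = np.asarray(self.rmsf, dtype=float)


def rmsf_from_coords(coords: np.ndarray) -> np.ndarray:
    """RMSF of each atom from a ``(n_frames, n_atoms, 3)`` coordinate stack."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise DomainError("RMSF needs at least 2 frames of (n_atoms, 3) coords")
    mean = coords.mean(axis=0)
    disp2 = np.sum((coords - mean) ** 2, axis=2)
    return np.sqrt(disp2.mean(axis=0))


def rmsf(traj: Trajectory, sel: Selection,
         superpose_on: Selection | None = None, stride: int = 1) -> RmsfResult:
    """Per-atom RMSF of a selection, optionally after superposing each frame
    onto frame 0 by a reference selection (e.g. backbone Cα)."""
    stack = []
    ref = None
    for i, coords, box in traj.iter_frames(stride):
        if superpose_on is not None:
            sub = coords[superpose_on.indices]
            if ref is None:
                ref = sub
            rot, trans = geometry.superpose_transform(ref, sub)
            coords = coords @ rot.T + trans
        stack.append(coords[sel.indices])
    return RmsfResult(atom_indices=sel.indices,
                      rmsf=rmsf_from_coords(np.array(stack)))


# ---------------------------------------------------------------------------
# chi-angle series and SP classification


@dataclass
class AngleSeries:
    """Per-frame χ angle (degrees, [0, 180]) of one residue's side chain."""

    label: str
    chi_deg: np.ndarray
    timestep: float = 1.0

    def __post_init__(self):
        self.chi_deg = np.asarray(self.chi_deg, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.chi_deg)


def chi_angle_series(traj: Trajectory, ca_sel: Selection, tip_sel: Selection,
                     helix_ca_sel: Selection, label: str = "",
                     stride: int = 1) -> AngleSeries:
    """χ(t) for one residue: angle between the Cα→tip vector and the axis of
    the host helix (axis re-fit each frame from the helix Cα trace)."""
    if len(ca_sel) != 1 or len(tip_sel) != 1:
        raise DomainError("ca_sel and tip_sel must each resolve to one atom")
    angles = []
    for _, coords, box in traj.iter_frames(stride):
        axis = geometry.helix_axis(coords[helix_ca_sel.indices])
        vec = coords[tip_sel.indices[0]] - coords[ca_sel.indices[0]]
        angles.append(geometry.chi_angle(vec, axis))
    return AngleSeries(label=label or ca_sel.label, chi_deg=np.array(angles),
                       timestep=traj.timestep * stride)


@dataclass
class StablePosition:
    center_deg: float
    amplitude_deg: float  # RMS deviation of member frames about the center
    occupancy: float
    label: str = ""


@dataclass
class SPModel:
    """Stable spatial positions of one χ series.

    SPs are labelled SP1, SP2, ... by descending occupancy. Frames not within
    2×amplitude of any SP center are "transient". ``n_transitions`` counts
    changes of SP between consecutive *assigned* frames.
    """

    residue: str
    sps: list[StablePosition]
    baseline_deg: float
    assignments: np.ndarray  # per-frame SP index, -1 for transient
    n_transitions: int
    params: dict = field(default_factory=dict)

    @property
    def occupancies(self) -> np.ndarray:
        return np.array([sp.occupancy for sp in self.sps])

    @property
    def transient_fraction(self) -> float:
        return float(np.mean(self.assignments < 0))

    def to_dict(self) -> dict:
        return {
            "residue": self.residue,
            "baseline_deg": self.baseline_deg,
            "n_transitions": self.n_transitions,
            "transient_fraction": self.transient_fraction,
            "sps": [
                {"label": sp.label, "center_deg": sp.center_deg,
                 "amplitude_deg": sp.amplitude_deg, "occupancy": sp.occupancy}
                for sp in self.sps
            ],
            "params": self.params,
        }

    def assignments_frame(self, series: AngleSeries) -> pd.DataFrame:
        labels = np.array(["transient"] + [sp.label for sp in self.sps])
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.assignments)),
                "chi_deg": series.chi_deg,
                "sp_label": labels[self.assignments + 1],
            }
        )


_BIN_DEG = 2.0
_SMOOTH_SIGMA_BINS = 1.5


def _candidate_modes(chi: np.ndarray) -> np.ndarray:
    """Local maxima (degrees) of the smoothed 2° histogram of the series."""
    edges = np.arange(0.0, 180.0 + _BIN_DEG, _BIN_DEG)
    hist, _ = np.histogram(chi, bins=edges)
    smooth = gaussian_filter1d(hist.astype(float), _SMOOTH_SIGMA_BINS,
                               mode="nearest")
    peaks = argrelmax(smooth, order=2)[0]
    # plateaus/edges: include the global max if argrelmax found nothing
    if len(peaks) == 0 and np.any(smooth > 0):
        peaks = np.array([int(np.argmax(smooth))])
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers[peaks]


def classify_sps(series: AngleSeries, baseline_deg: float,
                 min_occupancy: float = 0.05,
                 sp_amplitude_ratio: float = 1.5,
                 merge_separation_deg: float = 15.0) -> SPModel:
    """Classify a χ series into stable spatial positions.

    Candidate states are modes of the smoothed angle histogram. For each
    candidate the member set is the frames within the widest window a
    qualifying SP could claim (± 2 × sp_amplitude_ratio × baseline of the
    mode); the candidate's center is the member mean and its amplitude the
    member RMS deviation. Candidates closer than ``merge_separation_deg``
    merge into the more occupied one. A candidate is an SP iff its amplitude
    is ≤ sp_amplitude_ratio × baseline and its occupancy ≥ min_occupancy.
    Frames within 2×amplitude of an SP center are assigned to it (nearest
    center wins); all other frames are transient.
    """
    if baseline_deg <= 0:
        raise DomainError(f"baseline_deg must be > 0, got {baseline_deg}")
    chi = series.chi_deg
    if len(chi) < 100:
        raise DomainError("SP classification needs at least 100 frames")

    window = 2.0 * sp_amplitude_ratio * baseline_deg
    cands = []
    for mode in _candidate_modes(chi):
        members = chi[np.abs(chi - mode) <= window]
        if len(members) == 0:
            continue
        center = float(members.mean())
        amp = float(np.sqrt(np.mean((members - center) ** 2)))
        cands.append({"center": center, "amplitude": max(amp, 1e-9),
                      "occupancy": len(members) / len(chi)})

    # merge candidates closer than the separation threshold
    cands.sort(key=lambda c: -c["occupancy"])
    kept: list[dict] = []
    for c in cands:
        if any(abs(c["center"] - k["center"]) <= merge_separation_deg
               for k in kept):
            continue
        kept.append(c)

    sps = [c for c in kept
           if c["amplitude"] <= sp_amplitude_ratio * baseline_deg
           and c["occupancy"] >= min_occupancy]

    # final frame assignment: nearest SP center within 2×amplitude
    assignments = np.full(len(chi), -1, dtype=int)
    if sps:
        centers = np.array([c["center"] for c in sps])
        amps = np.array([c["amplitude"] for c in sps])
        dev = np.abs(chi[:, None] - centers[None, :])
        nearest = np.argmin(dev, axis=1)
        within = dev[np.arange(len(chi)), nearest] <= 2.0 * amps[nearest]
        assignments[within] = nearest[within]

    # occupancies from the final assignment; order SPs by descending occupancy
    order = np.argsort(
        [-(np.mean(assignments == k)) for k in range(len(sps))], kind="stable"
    )
    remap = {int(old): new for new, old in enumerate(order)}
    final_sps = []
    new_assign = np.full_like(assignments, -1)
    for old, new in remap.items():
        mask = assignments == old
        new_assign[mask] = new
        member = chi[mask]
        center = float(member.mean()) if len(member) else sps[old]["center"]
        amp = (float(np.sqrt(np.mean((member - center) ** 2)))
               if len(member) else sps[old]["amplitude"])
        final_sps.append(
            StablePosition(center_deg=center, amplitude_deg=amp,
                           occupancy=float(np.mean(mask)))
        )
    # final_sps is already in descending-occupancy order via `order`
    for i, sp in enumerate(final_sps):
        sp.label = f"SP{i + 1}"

    assigned = new_assign[new_assign >= 0]
    n_trans = int(np.sum(assigned[1:] != assigned[:-1])) if len(assigned) else 0

    return SPModel(
        residue=series.label, sps=final_sps, baseline_deg=baseline_deg,
        assignments=new_assign, n_transitions=n_trans,
        params={"min_occupancy": min_occupancy,
                "sp_amplitude_ratio": sp_amplitude_ratio,
                "merge_separation_deg": merge_separation_deg},
    )


def atom_position_probability(traj: Trajectory, atom_sel: Selection,
                              grid_spacing: float = 1.0, stride: int = 1):
    """Residence-probability grid of a single atom's position (the ND2/NE2
    probability-map analysis). Delegates to :func:`hydration.density_map`."""
    if len(atom_sel) != 1:
        raise DomainError("atom_position_probability needs a single-atom selection")
    from .hydration import density_map

    return density_map(traj, atom_sel, grid_spacing=grid_spacing, stride=stride)
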