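"""Lipid (cardiolipin) binding-site detection and residence-time statistics.

A binding site is a patch of protein surface residues whose atoms come
within a cutoff (default 3 Å) of the lipid headgroup — for cardiolipin the
phosphatidic-acid moiety, selected by atom name. Contacts are evaluated per
(protein residue, lipid molecule) pair, so one lipid touching two residues
yields two event streams. Residence events are maximal contact intervals per
pair, with interruptions of at most ``gap_tolerance_frames`` merged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .errors import DomainError
from .trajio import Selection, Trajectory

DEFAULT_LIPID_CUTOFF = 3.0  # Å, headgroup–residue contact criterion


@dataclass
class LipidContacts:
    """Per-frame contact record between protein residues and lipid molecules.

    ``flags`` maps (residue_key, lipid_id) → boolean array over analyzed
    frames, kept only for pairs that are ever in contact. ``residue_key`` is
    the universe residue index; ``residues`` maps it to (chain, resid, name).
    """

    flags: dict[tuple[int, int], np.ndarray]
    residues: dict[int, tuple[str, int, str]]
    lipid_ids: np.ndarray
    n_frames: int
    timestep: float
    cutoff: float

    def residue_label(self, key: int) -> str:
        ch, rid, name = self.residues[key]
        return f"{ch}{name}{rid}"

    def residue_contact_any(self, key: int) -> np.ndarray:
        """Frames in which the residue touches any lipid."""
        out = np.zeros(self.n_frames, dtype=bool)
        for (rk, _), series in self.flags.items():
            if rk == key:
                out |= series
        return out


def lipid_residue_contacts(traj: Trajectory, protein_sel: Selection,
                           lipid_head_sel: Selection,
                           cutoff: float = DEFAULT_LIPID_CUTOFF,
                           stride: int = 1) -> LipidContacts:
    """Scan the trajectory once, recording per-frame residue↔lipid contacts."""
    if len(lipid_head_sel) == 0:
        raise DomainError("lipid headgroup selection is empty")
    if len(protein_sel) == 0:
        raise DomainError("protein selection is empty")
    atoms = traj.topology.atoms
    residx = traj.topology.universe.atoms.resindices
    prot_res = residx[protein_sel.indices]
    lip_mol = residx[lipid_head_sel.indices]
    residues = {}
    for i in protein_sel.indices:
        residues[int(residx[i])] = (
            atoms["chain_id"].iat[i], int(atoms["residue_id"].iat[i]),
            atoms["residue_name"].iat[i],
        )
    raw: dict[tuple[int, int], list[int]] = {}
    n_frames = 0
    for _, coords, box in traj.iter_frames(stride):
        frame_no = n_frames
        n_frames += 1
        pairs = geometry.pairs_within_cutoff(
            coords, box, protein_sel.indices, lipid_head_sel.indices, cutoff
        )
        seen = set()
        for i, j, _ in pairs:
            # pairs_within_cutoff canonicalizes (i < j); recover the sides
            if i in protein_sel.indices and j in lipid_head_sel.indices:
                key = (int(residx[i]), int(residx[j]))
            else:
                key = (int(residx[j]), int(residx[i]))
            if key in seen:
                continue
            seen.add(key)
            raw.setdefault(key, []).append(frame_no)
    flags = {}
    for key, hit_frames in raw.items():
        arr = np.zeros(n_frames, dtype=bool)
        arr[hit_frames] = True
        flags[key] = arr
    return LipidContacts(
        flags=flags, residues=residues, lipid_ids=np.unique(lip_mol),
        n_frames=n_frames, timestep=traj.timestep * stride, cutoff=cutoff,
    )


def lipid_contact_occupancy(traj: Trajectory, protein_sel: Selection,
                            lipid_head_sel: Selection,
                            cutoff: float = DEFAULT_LIPID_CUTOFF,
                            stride: int = 1,
                            contacts: LipidContacts | None = None
                            ) -> pd.DataFrame:
    """Per-residue lipid-contact occupancy table.

    Occupancy of a residue is the fraction of frames in which any of its
    atoms is within the cutoff of any lipid headgroup atom. Returns a
    DataFrame (chain, resid, resname, occupancy) including zero rows for
    never-contacted residues of the protein selection, with the contact
    record attached as ``df.attrs["contacts"]``.
    """
    if contacts is None:
        contacts = lipid_residue_contacts(traj, protein_sel, lipid_head_sel,
                                          cutoff, stride)
    rows = []
    for key, (ch, rid, name) in sorted(contacts.residues.items()):
        occ = float(np.mean(contacts.residue_contact_any(key)))
        rows.append({"residue_key": key, "chain": ch, "resid": rid,
                     "resname": name, "occupancy": occ})
    df = pd.DataFrame(rows)
    df.attrs["contacts"] = contacts
    return df


# ---------------------------------------------------------------------------
# residence events


@dataclass(frozen=True)
class ResidenceEvent:
    lipid_id: int
    residue_label: str
    start_frame: int
    end_frame: int  # inclusive
    duration_ps: float


def _intervals(flags: np.ndarray, gap_tolerance: int) -> list[tuple[int, int]]:
    """Maximal True intervals, merging gaps of ≤ gap_tolerance False frames."""
    idx = np.flatnonzero(flags)
    if len(idx) == 0:
        return []
    out = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= gap_tolerance:
            prev = i
        else:
            out.append((int(start), int(prev)))
            start = prev = i
    out.append((int(start), int(prev)))
    return out


def residence_events(contacts: LipidContacts, residue_key: int | None = None,
                     gap_tolerance_frames: int = 2
                     ) -> tuple[list[ResidenceEvent], float]:
    """Residence events (and their mean duration, ps) for one residue or,
    when ``residue_key`` is None, all residues of the contact record."""
    events = []
    for (rk, lip), flags in sorted(contacts.flags.items()):
        if residue_key is not None and rk != residue_key:
            continue
        for start, end in _intervals(flags, gap_tolerance_frames):
            events.append(
                ResidenceEvent(
                    lipid_id=int(lip), residue_label=contacts.residue_label(rk),
                    start_frame=start, end_frame=end,
                    duration_ps=(end - start + 1) * contacts.timestep,
                )
            )
    mean = (float(np.mean([e.duration_ps for e in events]))
            if events else 0.0)
    return events, mean


def events_table(events: list[ResidenceEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [e.__dict__ for e in events],
        columns=["lipid_id", "residue_label", "start_frame", "end_frame",
                 "duration_ps"],
    )


# ---------------------------------------------------------------------------
# binding-site clustering


@dataclass
class BindingSite:
    site_id: int
    residues: list[tuple[str, int, str]]  # (chain, resid, resname)
    occupancy: float  # fraction of frames any member touches any lipid
    mean_retention_ps: float
    n_events: int

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "residues": [f"{c}{n}{r}" for c, r, n in self.residues],
            "occupancy": self.occupancy,
            "mean_retention_ps": self.mean_retention_ps,
            "n_events": self.n_events,
        }


def cluster_binding_sites(occupancy: pd.DataFrame, traj: Trajectory,
                          min_occupancy: float = 0.1,
                          adjacency: float = 8.0,
                          gap_tolerance_frames: int = 2) -> list[BindingSite]:
    """Group qualifying residues into surface binding sites.

    Residues with occupancy ≥ ``min_occupancy`` are single-linkage clustered
    on the min-image distance between their Cα atoms (first atom of the
    residue when no Cα exists) in the first frame, threshold ``adjacency``.
    Site occupancy is the fraction of frames in which any member residue
    touches any lipid; retention statistics pool the members' residence
    events.
    """
    contacts: LipidContacts = occupancy.attrs["contacts"]
    qual = occupancy[occupancy["occupancy"] >= min_occupancy]
    if len(qual) == 0:
        return []
    coords0, box0 = traj.frame(0)
    residx = traj.topology.universe.atoms.resindices
    names = traj.topology.atoms["name"].to_numpy()
    anchors = []
    for key in qual["residue_key"]:
        members = np.flatnonzero(residx == key)
        ca = [i for i in members if names[i] == "CA"]
        anchors.append(coords0[ca[0] if ca else members[0]])
    anchors = np.array(anchors)
    # single-linkage at a distance threshold == connected components
    n = len(anchors)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(n):
        d = geometry.min_image_distance(anchors[a], anchors, box0)
        for b in np.flatnonzero(d <= adjacency):
            ra, rb = find(a), find(int(b))
            if ra != rb:
                parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for a in range(n):
        groups.setdefault(find(a), []).append(a)

    keys = qual["residue_key"].to_numpy()
    sites = []
    for gi, members in enumerate(sorted(groups.values(), key=lambda m: m[0])):
        member_keys = [int(keys[m]) for m in members]
        any_contact = np.zeros(contacts.n_frames, dtype=bool)
        events = []
        for mk in member_keys:
            any_contact |= contacts.residue_contact_any(mk)
            ev, _ = residence_events(contacts, mk, gap_tolerance_frames)
            events.extend(ev)
        durations = [e.duration_ps for e in events]
        sites.append(
            BindingSite(
                site_id=gi + 1,
                residues=[contacts.residues[mk] for mk in member_keys],
                occupancy=float(np.mean(any_contact)),
                mean_retention_ps=float(np.mean(durations)) if durations else 0.0,
                n_events=len(events),
            )
        )
    sites.sort(key=lambda s: -s.occupancy)
    for i, s in enumerate(sites):
        s.site_id = i + 1
    return sites


def sites_json(sites: list[BindingSite], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in sites], fh, indent=1)
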