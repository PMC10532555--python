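"""Synthetic channel systems with planted, machine-readable ground truth.

The generator emulates the statistical structure of a solvated proton
half-channel at desk scale: a water wire from an entrance region to a target
carboxylate with a controllable per-frame continuity, side chains hopping
between angular states with set occupancies, a structural-water cluster
maintained by 2–3 exchanging waters, a hydration shell with a set mean
count, entrance lacunae that can be bridged into one cavity, and lipid
headgroup beads making contacts over exponentially distributed dwell times.

Waters are one-site (oxygen-only) pseudo-molecules: every in-scope analysis
uses heavy-atom distances, so hydrogens would be dead weight. Nothing here
is a physical water model or a real protein geometry — residues carry
standard names (ASN/ASP/HIS/GLN/GLU/ARG/LYS, TIP3 waters, CDL headgroup
beads) purely so that selection expressions work unchanged.

Every planted quantity is recorded per frame in a :class:`GroundTruth`
manifest written alongside the PDB/DCD pair, so recovery tests compare
measurements against what was actually realized, not just nominal rates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import DomainError
from .trajio import Topology, Trajectory, write_dcd, write_pdb

_DEF_BOX = (40.0, 40.0, 60.0)


@dataclass
class SidechainPlan:
    """Angular-state plan for one side chain: χ state centers (deg), their
    occupancies, Gaussian noise about the center, and geometric dwell."""

    centers_deg: tuple = (60.0, 120.0)
    occupancies: tuple = (0.6, 0.4)
    noise_deg: float = 3.0
    dwell_mean_frames: int = 200


@dataclass
class SyntheticSpec:
    """Parameters of a generated channel system.

    Defaults are the study conditions the analyses are validated against:
    wire continuity 0.75, a 0.90 contact fraction for the Asp119–His245
    analogue pair, a two-state Asn214 analogue at 0.6/0.4, a W1-like cluster
    of 2–3 exchanging waters, ten lipid binding sites with exponential
    dwells of mean 150 ps, and frames recorded every 2 ps.
    """

    seed: int = 0
    n_frames: int = 5000
    timestep: float = 2.0  # ps per frame
    box: tuple = _DEF_BOX
    jitter_sigma: float = 0.05  # Å thermal jitter, truncated at 3 sigma
    include_waters: bool = True

    wire_continuity: float = 0.75
    contact_fraction: float = 0.90

    asn214: SidechainPlan = field(default_factory=SidechainPlan)
    gln252: SidechainPlan = field(
        default_factory=lambda: SidechainPlan(
            centers_deg=(90.0,), occupancies=(1.0,), noise_deg=4.0,
            dwell_mean_frames=200)
    )

    w1_third_occupancy: float = 0.5  # P(third cluster slot occupied)
    w1_exchange_dwell_frames: int = 50
    w1_pool: int = 5

    shell_pool: int = 30
    shell_mean_count: float = 15.0

    n_bulk_waters: int = 40

    #: "on" | "off" | int frame at which the entrance lacunae become bridged
    bridge_schedule: object = "on"

    n_lipid_sites: int = 10
    lipid_occupancies: tuple | None = None  # default: spread over [0.25, 0.9]
    lipid_dwell_mean_ps: float = 150.0

    def validate(self) -> None:
        def bad(fieldname, msg):
            raise DomainError(f"invalid spec field {fieldname!r}: {msg}")

        if self.n_frames < 1:
            bad("n_frames", "must be >= 1")
        if self.timestep <= 0:
            bad("timestep", "must be > 0")
        if any(b <= 0 for b in self.box):
            bad("box", "edges must be > 0")
        if not 0.0 <= self.wire_continuity <= 1.0:
            bad("wire_continuity", "must be in [0, 1]")
        if not 0.0 <= self.contact_fraction <= 1.0:
            bad("contact_fraction", "must be in [0, 1]")
        for name, plan in (("asn214", self.asn214), ("gln252", self.gln252)):
            occ = np.asarray(plan.occupancies, dtype=float)
            if len(occ) != len(plan.centers_deg):
                bad(name, "centers and occupancies differ in length")
            if np.any(occ < 0) or abs(occ.sum() - 1.0) > 1e-9:
                bad(name, "occupancies must be >= 0 and sum to 1")
            if not all(0.0 <= c <= 180.0 for c in plan.centers_deg):
                bad(name, "state centers must be in [0, 180] degrees")
        if not 0.0 <= self.w1_third_occupancy <= 1.0:
            bad("w1_third_occupancy", "must be in [0, 1]")
        if self.w1_pool < 3:
            bad("w1_pool", "needs at least 3 waters for a 2-3 water cluster")
        if self.shell_pool < 0 or self.n_bulk_waters < 0:
            bad("shell_pool/n_bulk_waters", "must be >= 0")
        if self.shell_pool and not 0 < self.shell_mean_count <= self.shell_pool:
            bad("shell_mean_count", "must be in (0, shell_pool]")
        if self.bridge_schedule not in ("on", "off") and not isinstance(
                self.bridge_schedule, int):
            bad("bridge_schedule", "must be 'on', 'off' or a frame index")
        if self.n_lipid_sites < 0:
            bad("n_lipid_sites", "must be >= 0")
        if self.lipid_occupancies is not None and len(
                self.lipid_occupancies) != self.n_lipid_sites:
            bad("lipid_occupancies", "length must equal n_lipid_sites")

    @classmethod
    def paper_like(cls, seed: int = 0, n_frames: int = 5000,
                   hydration: str = "default", **overrides) -> "SyntheticSpec":
        """The default study conditions, with low/high hydration variants for
        the lipid-composition contrast (low ≈ plain-PC membrane, high ≈
        cardiolipin-rich membrane)."""
        kw = {}
        if hydration == "low":
            kw.update(shell_mean_count=8.0, wire_continuity=0.60,
                      bridge_schedule="off")
        elif hydration == "high":
            kw.update(shell_mean_count=18.0, wire_continuity=0.90,
                      bridge_schedule="on")
        elif hydration != "default":
            raise DomainError(f"unknown hydration condition {hydration!r}")
        kw.update(overrides)
        return cls(seed=seed, n_frames=n_frames, **kw)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Realized values of every planted quantity, per frame where relevant."""

    spec: dict
    wire: dict      # exists[], continuity, break_residue
    contact: dict   # in_contact[], fraction, labels
    sidechains: dict  # residue -> {centers, state[], occupancies_realized, ...}
    w1: dict        # k[], mean_count, centroid, exchange stats
    hydration: dict  # counts[], mean
    cavity: dict    # bridged[], components_bridged, components_unbridged
    lipids: dict    # sites: [{residue, occupancy_nominal, occupancy_realized,
                    #          events: [[start, end], ...]}], dwell_mean_ps

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump(asdict(self), fh, default=default)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)

    def check_consistency(self) -> None:
        """Planted summaries must match recounts of planted per-frame data."""
        n = len(self.wire["exists"])
        assert abs(np.mean(self.wire["exists"]) -
                   self.wire["continuity_realized"]) < 1e-12
        assert abs(np.mean(self.contact["in_contact"]) -
                   self.contact["fraction_realized"]) < 1e-12
        for res in self.sidechains.values():
            states = np.asarray(res["state"])
            occ = np.asarray(res["occupancies_realized"])
            recount = np.array([np.mean(states == k) for k in range(len(occ))])
            assert np.allclose(occ, recount)
        for site in self.lipids["sites"]:
            dur = sum(e - s + 1 for s, e in site["events"])
            assert abs(dur / n - site["occupancy_realized"]) < 1e-12


# ---------------------------------------------------------------------------
# schedules


def _state_schedule(rng, n, occupancies, dwell_mean):
    occ = np.asarray(occupancies, dtype=float)
    out = np.empty(n, dtype=int)
    t = 0
    while t < n:
        s = rng.choice(len(occ), p=occ)
        d = int(rng.geometric(1.0 / dwell_mean))
        out[t:t + d] = s
        t += d
    return out


def _onoff_schedule(rng, n, occupancy, on_mean_frames):
    """Alternating exponential on/off intervals; returns (flags, on_intervals)."""
    flags = np.zeros(n, dtype=bool)
    intervals = []
    if occupancy <= 0:
        return flags, intervals
    if occupancy >= 1:
        flags[:] = True
        return flags, [(0, n - 1)]
    off_mean = on_mean_frames * (1.0 - occupancy) / occupancy
    t = 0
    on = rng.random() < occupancy
    while t < n:
        mean = on_mean_frames if on else off_mean
        d = max(1, int(round(rng.exponential(mean))))
        end = min(n, t + d)
        if on:
            flags[t:end] = True
            intervals.append((t, end - 1))
        t = end
        on = not on
    return flags, intervals


# ---------------------------------------------------------------------------
# geometry of the synthetic channel (all positions Å, box 40 x 40 x 60)

_CHANNEL_XY = np.array([20.0, 20.0])
_WIRE_Z0, _WIRE_SPACING, _N_WIRE = 12.0, 2.65, 12  # nodes 0..11 plus a cap node
_BREAK_NODE = 7
_HELIX_RESIDS = range(204, 219)
_HELIX_ORIGIN = (27.0, 20.0, 17.0)
_SIDECHAIN_LEN = 3.0


def _wire_nodes() -> np.ndarray:
    z = _WIRE_Z0 + _WIRE_SPACING * np.arange(_N_WIRE)
    nodes = np.column_stack(
        [np.full(_N_WIRE, 20.0), np.full(_N_WIRE, 20.0), z]
    )
    # cap water reaching the target carboxylate; off voxel boundaries
    cap = np.array([[20.5, 20.5, 43.4]])
    return np.vstack([nodes, cap])


_W1_SLOTS = np.array(
    [[18.5, 20.5, 44.5], [17.5, 20.5, 44.5], [18.5, 21.5, 44.5]]
)

_BLOB_A = np.array([12.0, 20.0, 10.0]) + np.array(
    [[0, 0, 0], [-2.4, 0, 0], [0, 2.4, 0], [0, -2.4, 0], [-1.2, 0, 2.2]]
)
_BLOB_B = np.array([28.0, 20.0, 10.0]) + np.array(
    [[0, 0, 0], [2.4, 0, 0], [0, 2.4, 0], [0, -2.4, 0], [1.2, 0, 2.2]]
)
_BRIDGE = np.array(
    [[14.8, 20, 10], [17.6, 20, 10], [20.4, 20, 10], [23.2, 20, 10],
     [26.0, 20, 10]], dtype=float
)

_LIPID_RING_RADIUS = 14.0


def _residue_table():
    """Static residues: (chain, resid, resname, [(atom, xyz or None)]).

    None coordinates are dynamic and filled per frame.
    """
    from .geometry import ideal_helix

    helix = ideal_helix(len(_HELIX_RESIDS), origin=_HELIX_ORIGIN)
    rows = []
    for k, rid in enumerate(_HELIX_RESIDS):
        if rid == 214:
            rows.append(("A", rid, "ASN",
                         [("CA", helix[k]), ("ND2", None)]))
        else:
            rows.append(("A", rid, "ALA", [("CA", helix[k])]))
    rows += [
        ("A", 219, "GLU", [("CA", np.array([26.0, 20, 16.0])),
                           ("OE1", np.array([25.0, 20, 16.0]))]),
        ("A", 119, "ASP", [("CA", np.array([27.0, 20, 21.9])),
                           ("OD1", None)]),
        ("A", 245, "HIS", [("CA", np.array([27.0, 20, 27.0])),
                           ("NE2", np.array([26.0, 20, 26.0]))]),
        ("A", 252, "GLN", [("CA", np.array([26.5, 20, 40.0])),
                           ("NE2", None)]),
        ("A", 116, "ASN", [("CA", np.array([31.0, 26, 24.0])),
                           ("ND2", np.array([30.0, 25, 24.0]))]),
        ("A", 144, "SER", [("CA", np.array([31.0, 14, 24.0])),
                           ("OG", np.array([30.0, 15, 24.0]))]),
        ("A", 24, "ARG", [("CA", np.array([20.0, 25, 10.0])),
                          ("NH1", np.array([20.0, 23, 10.8]))]),
        ("A", 132, "HIS", [("CA", np.array([20.0, 15, 10.0])),
                           ("NE2", np.array([20.0, 17, 10.8]))]),
        ("C", 61, "ASP", [("CA", np.array([20.0, 22.5, 45.5])),
                          ("OD1", np.array([20.0, 20.5, 44.5]))]),
    ]
    return rows, helix


def _lipid_sites(n_sites):
    """(lys_ca, lys_nz, cl_on) positions for each binding site."""
    out = []
    for s in range(n_sites):
        theta = 2 * np.pi * s / max(n_sites, 1)
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        z = 12.0 if s % 2 == 0 else 44.0
        ca = np.array([20.0, 20.0, z]) + _LIPID_RING_RADIUS * u
        nz = ca + 1.3 * u
        cl = nz + 2.5 * u
        out.append((ca, nz, cl))
    return out


@dataclass
class GeneratedSystem:
    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    box: np.ndarray
    truth: GroundTruth
    pdb_path: Path | None = None
    dcd_path: Path | None = None
    truth_path: Path | None = None

    def trajectory(self) -> Trajectory:
        return Trajectory.from_arrays(
            self.topology, self.coords, self.box,
            timestep=self.truth.spec["timestep"],
        )


def _sample_shell_positions(rng, n, centers, box, forbidden, min_forbidden,
                            entrance_atoms):
    """Fixed in-shell water positions subject to placement constraints."""
    out = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 20000:
            raise DomainError("could not place shell waters; relax the spec")
        c = centers[rng.integers(len(centers))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = c + rng.uniform(3.2, 4.5) * direction
        if np.any(pos < 1.5) or np.any(pos > np.asarray(box) - 1.5):
            continue
        if np.min(np.linalg.norm(forbidden - pos, axis=1)) < min_forbidden:
            continue
        if np.min(np.linalg.norm(entrance_atoms - pos, axis=1)) < 10.5:
            continue
        if out and np.min(np.linalg.norm(np.array(out) - pos, axis=1)) < 2.0:
            continue
        out.append(pos)
    return np.array(out) if out else np.zeros((0, 3))


def _sample_bulk_positions(rng, n, box, forbidden, entrance_atoms):
    out = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 20000:
            raise DomainError("could not place bulk waters; relax the spec")
        pos = np.array([rng.uniform(32.0, 38.0), rng.uniform(2.0, 38.0),
                        rng.uniform(4.0, 56.0)])
        if np.min(np.linalg.norm(forbidden - pos, axis=1)) < 3.6:
            continue
        if np.min(np.linalg.norm(entrance_atoms - pos, axis=1)) < 10.5:
            continue
        if out and np.min(np.linalg.norm(np.array(out) - pos, axis=1)) < 2.4:
            continue
        out.append(pos)
    return np.array(out) if out else np.zeros((0, 3))


def _parking_slots():
    """Far-corner lattice for off-duty waters and lipid beads."""
    xs = np.arange(8.0, 32.1, 3.6)
    zs = np.arange(16.0, 42.1, 3.6)
    ys = np.array([2.2, 5.4])
    slots = np.array([(x, y, z) for z in zs for y in ys for x in xs])
    return slots


def _static_connectivity_ok(water_pos, source_mask, target, margin_cutoff=3.3):
    """True when no H-bond-distance path links a source water to the target
    with the break node removed (worst-case: every water simultaneously at
    its active position). Returns (ok, offending_path_indices)."""
    from scipy.spatial import cKDTree

    pts = np.vstack([water_pos, target[None, :]])
    tgt = len(pts) - 1
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=margin_cutoff)
    adj: dict[int, list[int]] = {i: [] for i in range(len(pts))}
    for i, j in pairs:
        adj[i].append(j)
        adj[j].append(i)
    from collections import deque

    parent = {i: None for i in np.flatnonzero(source_mask)}
    queue = deque(sorted(parent))
    while queue:
        u = queue.popleft()
        if u == tgt:
            path = [u]
            while parent[path[-1]] is not None:
                path.append(parent[path[-1]])
            return False, path[::-1]
        for v in adj[u]:
            if v not in parent:
                parent[v] = u
                queue.append(v)
    return True, None


def generate_arrays(spec: SyntheticSpec) -> GeneratedSystem:
    """Generate the system in memory; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    box = np.asarray(spec.box, dtype=float)

    residues, helix = _residue_table()
    wire = _wire_nodes()
    lipid_geo = _lipid_sites(spec.n_lipid_sites)

    # ---------------- schedules -------------------------------------------
    break_flags = rng.random(n) < (1.0 - spec.wire_continuity)
    wire_exists = ~break_flags

    k_contact = int(round(spec.contact_fraction * n))
    contact_flags = np.zeros(n, dtype=bool)
    contact_flags[rng.permutation(n)[:k_contact]] = True

    sc_states = {}
    for label, plan in (("aAsn214", spec.asn214), ("aGln252", spec.gln252)):
        if len(plan.centers_deg) == 1:
            sc_states[label] = np.zeros(n, dtype=int)
        else:
            sc_states[label] = _state_schedule(
                rng, n, plan.occupancies, plan.dwell_mean_frames)

    w1_third = rng.random(n) < spec.w1_third_occupancy
    # exchange: which pool waters hold the three cluster slots per segment
    w1_assign = np.full((n, spec.w1_pool), -1, dtype=int)  # water -> slot
    t = 0
    while t < n:
        d = int(rng.geometric(1.0 / spec.w1_exchange_dwell_frames))
        holders = rng.permutation(spec.w1_pool)[:3]
        for slot, w in enumerate(holders):
            w1_assign[t:t + d, w] = slot
        t += d
    w1_k = 2 + w1_third.astype(int)

    shell_prob = (spec.shell_mean_count / spec.shell_pool
                  if spec.shell_pool else 0.0)
    shell_flags = rng.random((n, spec.shell_pool)) < shell_prob

    if spec.bridge_schedule == "on":
        bridged = np.ones(n, dtype=bool)
    elif spec.bridge_schedule == "off":
        bridged = np.zeros(n, dtype=bool)
    else:
        bridged = np.arange(n) >= int(spec.bridge_schedule)

    if spec.lipid_occupancies is None:
        lipid_occ = (np.linspace(0.25, 0.9, spec.n_lipid_sites)
                     if spec.n_lipid_sites else np.array([]))
    else:
        lipid_occ = np.asarray(spec.lipid_occupancies, dtype=float)
    dwell_frames = spec.lipid_dwell_mean_ps / spec.timestep
    lipid_flags, lipid_events = [], []
    for occ in lipid_occ:
        flags, ev = _onoff_schedule(rng, n, float(occ), dwell_frames)
        lipid_flags.append(flags)
        lipid_events.append(ev)

    # ---------------- static water placement ------------------------------
    entrance_atoms = np.array([[20.0, 23, 10.8], [20.0, 17, 10.8],
                               [20.0, 25, 10.0], [20.0, 15, 10.0]])
    shell_centers = np.array(
        [xyz for ch, rid, rn, atoms in residues if rid in
         (116, 119, 144, 214, 245, 252)
         for _, xyz in atoms if xyz is not None]
    )
    forbidden = np.vstack([wire, _W1_SLOTS])
    if spec.include_waters:
        shell_pos = _sample_shell_positions(
            rng, spec.shell_pool, shell_centers, box, forbidden, 3.6,
            entrance_atoms)
        bulk_pos = _sample_bulk_positions(rng, spec.n_bulk_waters, box,
                                          forbidden, entrance_atoms)
        # reject placements that could bridge the broken wire
        target = np.array([20.0, 20.5, 44.5])
        for _ in range(200):
            active = [np.delete(wire, _BREAK_NODE, axis=0), _W1_SLOTS,
                      _BLOB_A, _BLOB_B, _BRIDGE]
            offsets = {}
            base_count = 0
            for arr in active:
                base_count += len(arr)
            if len(shell_pos):
                offsets["shell"] = base_count
                active.append(shell_pos)
                base_count += len(shell_pos)
            if len(bulk_pos):
                offsets["bulk"] = base_count
                active.append(bulk_pos)
                base_count += len(bulk_pos)
            pos = np.vstack(active)
            src = np.zeros(len(pos), dtype=bool)
            for ea in entrance_atoms:
                src |= np.linalg.norm(pos - ea, axis=1) <= 6.3
            ok, path = _static_connectivity_ok(pos, src, target)
            if ok:
                break
            # resample the first replaceable water on the offending path
            fixed = None
            for node in path:
                if "shell" in offsets and offsets["shell"] <= node < (
                        offsets["shell"] + len(shell_pos)):
                    k = node - offsets["shell"]
                    shell_pos[k] = _sample_shell_positions(
                        rng, 1, shell_centers, box, forbidden, 3.6,
                        entrance_atoms)[0]
                    fixed = True
                    break
                if "bulk" in offsets and offsets["bulk"] <= node < (
                        offsets["bulk"] + len(bulk_pos)):
                    k = node - offsets["bulk"]
                    bulk_pos[k] = _sample_bulk_positions(
                        rng, 1, box, forbidden, entrance_atoms)[0]
                    fixed = True
                    break
            if not fixed:
                raise DomainError(
                    "structural waters alone bridge the broken wire; "
                    "the channel geometry is inconsistent")
        else:
            raise DomainError("could not decorrelate shell/bulk waters from "
                              "the wire break after 200 attempts")
    else:
        shell_pos = np.zeros((0, 3))
        bulk_pos = np.zeros((0, 3))

    # ---------------- topology assembly -----------------------------------
    names, resnames, resids, chains, elements = [], [], [], [], []
    base = []

    def add_atom(name, ch, rid, rn, xyz, element=None):
        names.append(name)
        chains.append(ch)
        resids.append(rid)
        resnames.append(rn)
        elements.append(element or name[0])
        base.append(np.zeros(3) if xyz is None else np.asarray(xyz, float))
        return len(names) - 1

    dynamic = {}
    for ch, rid, rn, atoms in residues:
        for aname, xyz in atoms:
            idx = add_atom(aname, ch, rid, rn, xyz)
            if xyz is None:
                dynamic[(ch, rid, aname)] = idx

    lipid_idx = []
    for s, (ca, nz, cl) in enumerate(lipid_geo):
        add_atom("CA", "A", 301 + s, "LYS", ca)
        add_atom("NZ", "A", 301 + s, "LYS", nz)
        lipid_idx.append(add_atom("P1", "L", 401 + s, "CDL", cl, element="P"))

    water_groups = {}
    wat_rid = 0

    def add_waters(key, positions):
        nonlocal wat_rid
        idx = []
        for pos in positions:
            wat_rid += 1
            idx.append(add_atom("OH2", "W", wat_rid, "TIP3", pos, element="O"))
        water_groups[key] = np.array(idx, dtype=int)

    if spec.include_waters:
        add_waters("wire", wire)
        add_waters("w1", np.tile(_W1_SLOTS[0], (spec.w1_pool, 1)))
        add_waters("shell", shell_pos)
        add_waters("blob_a", _BLOB_A)
        add_waters("blob_b", _BLOB_B)
        add_waters("bridge", _BRIDGE)
        add_waters("bulk", bulk_pos)
    else:
        for key in ("wire", "w1", "shell", "blob_a", "blob_b", "bridge",
                    "bulk"):
            water_groups[key] = np.array([], dtype=int)

    topology = Topology.from_arrays(names, resnames, resids, chains, elements)
    n_atoms = topology.n_atoms
    base = np.array(base)

    # parking slots for everything that ever leaves its active position
    slots = _parking_slots()
    slot_cursor = 0

    def take_slots(count):
        nonlocal slot_cursor
        if slot_cursor + count > len(slots):
            raise DomainError("parking lattice exhausted; shrink the spec")
        out = slots[slot_cursor:slot_cursor + count]
        slot_cursor += count
        return out

    lipid_park = take_slots(spec.n_lipid_sites)
    if spec.include_waters:
        wire_park = take_slots(1)[0]
        w1_park = take_slots(spec.w1_pool)
        shell_park = take_slots(spec.shell_pool)
        bridge_park = take_slots(len(_BRIDGE))

    # ---------------- per-frame coordinates -------------------------------
    coords = np.broadcast_to(base, (n, n_atoms, 3)).copy()

    def chi_positions(plan, states, ca_xyz, toward_xy):
        u = np.zeros(3)
        u[:2] = toward_xy - ca_xyz[:2]
        u /= np.linalg.norm(u)
        chi = np.array(plan.centers_deg, dtype=float)[states]
        chi = chi + np.clip(rng.normal(0, plan.noise_deg, n),
                            -3 * plan.noise_deg, 3 * plan.noise_deg)
        chi_r = np.radians(np.clip(chi, 0.0, 180.0))
        axis = np.array([0.0, 0.0, 1.0])
        return (ca_xyz + _SIDECHAIN_LEN *
                (np.cos(chi_r)[:, None] * axis + np.sin(chi_r)[:, None] * u),
                chi)

    ca214 = helix[list(_HELIX_RESIDS).index(214)]
    nd2_pos, chi214 = chi_positions(spec.asn214, sc_states["aAsn214"], ca214,
                                    _CHANNEL_XY)
    coords[:, dynamic[("A", 214, "ND2")]] = nd2_pos
    ca252 = np.array([26.5, 20, 40.0])
    ne2_pos, chi252 = chi_positions(spec.gln252, sc_states["aGln252"], ca252,
                                    _CHANNEL_XY)
    coords[:, dynamic[("A", 252, "NE2")]] = ne2_pos

    od1_contact = np.array([26.0, 20, 23.4])   # 2.6 Å below His245 NE2
    od1_far = np.array([26.0, 20, 20.5])       # 5.5 Å below
    od1 = dynamic[("A", 119, "OD1")]
    coords[:, od1] = np.where(contact_flags[:, None], od1_contact, od1_far)

    for s, idx in enumerate(lipid_idx):
        on = lipid_flags[s][:, None]
        coords[:, idx] = np.where(on, base[idx], lipid_park[s])

    w1_centroid = _W1_SLOTS.mean(axis=0)
    if spec.include_waters:
        bn = water_groups["wire"][_BREAK_NODE]
        coords[break_flags, bn] = wire_park

        for w in range(spec.w1_pool):
            widx = water_groups["w1"][w]
            slot = w1_assign[:, w]
            active = (slot >= 0) & ((slot < 2) | w1_third)
            pos = np.where(active[:, None],
                           _W1_SLOTS[np.clip(slot, 0, 2)], w1_park[w])
            coords[:, widx] = pos

        for w in range(spec.shell_pool):
            widx = water_groups["shell"][w]
            coords[:, widx] = np.where(shell_flags[:, w][:, None],
                                       shell_pos[w], shell_park[w])

        for k, widx in enumerate(water_groups["bridge"]):
            coords[:, widx] = np.where(bridged[:, None], _BRIDGE[k],
                                       bridge_park[k])

    jit = np.clip(rng.normal(0.0, spec.jitter_sigma, coords.shape),
                  -3 * spec.jitter_sigma, 3 * spec.jitter_sigma)
    coords = (coords + jit).astype(np.float32)

    # ---------------- ground truth ----------------------------------------
    if not spec.include_waters:
        wire_exists = np.zeros(n, dtype=bool)
    # realized W1 site-membership runs, for residence-time recovery
    w1_runs = []
    if spec.include_waters:
        for w in range(spec.w1_pool):
            slot = w1_assign[:, w]
            inside = (slot >= 0) & ((slot < 2) | w1_third)
            padded = np.concatenate([[0], inside.astype(int), [0]])
            diff = np.diff(padded)
            starts = np.flatnonzero(diff == 1)
            ends = np.flatnonzero(diff == -1)
            w1_runs.extend((ends - starts).tolist())

    sc_truth = {}
    for label, plan, chi in (("aAsn214", spec.asn214, chi214),
                             ("aGln252", spec.gln252, chi252)):
        states = sc_states[label]
        sc_truth[label] = {
            "centers_deg": list(plan.centers_deg),
            "occupancies_nominal": list(plan.occupancies),
            "occupancies_realized": [float(np.mean(states == k))
                                     for k in range(len(plan.centers_deg))],
            "state": states,
            "chi_deg": chi,
            "noise_deg": plan.noise_deg,
            "dwell_mean_frames": plan.dwell_mean_frames,
            "n_transitions": int(np.sum(states[1:] != states[:-1])),
        }

    truth = GroundTruth(
        spec={**asdict(spec), "box": list(spec.box)},
        wire={
            "exists": wire_exists,
            "continuity_nominal": spec.wire_continuity,
            "continuity_realized": float(np.mean(wire_exists)),
            "break_residue": "AASN214",
        },
        contact={
            "labels": ["aAsp119", "aHis245"],
            "in_contact": contact_flags,
            "fraction_nominal": spec.contact_fraction,
            "fraction_realized": float(np.mean(contact_flags)),
            "distance_contact": 2.6,
            "distance_far": 5.5,
        },
        sidechains=sc_truth,
        w1={
            "k": w1_k if spec.include_waters else np.zeros(n, dtype=int),
            "mean_count_realized": (float(np.mean(w1_k))
                                    if spec.include_waters else 0.0),
            "centroid": w1_centroid,
            "exchange_dwell_frames": spec.w1_exchange_dwell_frames,
            "mean_residence_frames_realized":
                float(np.mean(w1_runs)) if w1_runs else 0.0,
        },
        hydration={
            "counts": shell_flags.sum(axis=1) if spec.include_waters
            else np.zeros(n, dtype=int),
            "mean_nominal": spec.shell_mean_count if spec.include_waters else 0,
            "mean_realized": (float(np.mean(shell_flags.sum(axis=1)))
                              if spec.include_waters else 0.0),
        },
        cavity={
            "bridged": bridged,
            "components_bridged": 1,
            "components_unbridged": 3,
        },
        lipids={
            "dwell_mean_ps": spec.lipid_dwell_mean_ps,
            "sites": [
                {
                    "residue": f"ALYS{301 + s}",
                    "occupancy_nominal": float(lipid_occ[s]),
                    "occupancy_realized": float(np.mean(lipid_flags[s])),
                    "events": [[int(a), int(b)] for a, b in lipid_events[s]],
                    "mean_dwell_ps_realized": float(np.mean(
                        [(b - a + 1) * spec.timestep
                         for a, b in lipid_events[s]]))
                    if lipid_events[s] else 0.0,
                }
                for s in range(spec.n_lipid_sites)
            ],
        },
    )
    return GeneratedSystem(topology=topology, coords=coords, box=box,
                           truth=truth)


def generate_system(spec: SyntheticSpec, outdir) -> GeneratedSystem:
    """Generate and write ``system.pdb``, ``system.dcd`` and
    ``ground_truth.json`` into ``outdir``. Byte-identical on rerun with the
    same spec and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    system = generate_arrays(spec)
    pdb = outdir / "system.pdb"
    dcd = outdir / "system.dcd"
    gt = outdir / "ground_truth.json"
    write_pdb(system.topology, system.coords[0], pdb)
    write_dcd(dcd, system.coords, system.box, timestep=spec.timestep)
    system.truth.to_json(gt)
    system.pdb_path, system.dcd_path, system.truth_path = pdb, dcd, gt
    return system
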