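"""Topology/trajectory input-output and atom selections.

Topologies come from fixed-column PDB files (parsed here, so residue ids and
chain identifiers are kept verbatim and format errors can name the offending
line); coordinate trajectories come from CHARMM/NAMD-dialect DCD files or
in-memory arrays. MDAnalysis provides the underlying trajectory reader/writer
and the selection engine; this module is the only place the rest of the
package touches it.

Conventions
-----------
* Atom indices are 0-based and contiguous; PDB residue ids are kept 1-based
  exactly as printed in the file.
* Only orthorhombic unit cells are supported; triclinic cells are rejected.
* Water is recognised by residue name, default set ``{HOH, TIP3, WAT, SOL}``.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.exceptions import SelectionError

from .errors import (
    ConsistencyError,
    DomainError,
    EmptyInputError,
    SelectionSyntaxError,
    TopologyFormatError,
    TruncatedTrajectoryError,
)

DEFAULT_WATER_RESNAMES = frozenset({"HOH", "TIP3", "WAT", "SOL"})

#: Backbone heavy-atom names excluded from the polar side-chain flag.
_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

_ANGLE_TOL = 1e-3  # deg; box angles must be 90 within this to count as orthorhombic


def _guess_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


@dataclass
class Topology:
    """Ordered atom table plus an MDAnalysis universe used for selections.

    ``atoms`` is a DataFrame with one row per atom, in file order, columns:
    ``index, name, element, residue_name, residue_id, chain_id, is_water,
    is_polar_sidechain_atom``.
    """

    atoms: pd.DataFrame
    universe: mda.Universe
    water_resnames: frozenset = DEFAULT_WATER_RESNAMES
    source: Path | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @classmethod
    def from_arrays(
        cls,
        names,
        resnames,
        resids,
        chains,
        elements=None,
        water_resnames=DEFAULT_WATER_RESNAMES,
        source=None,
    ) -> "Topology":
        """Build a topology from per-atom field arrays (no file involved)."""
        names = list(names)
        n = len(names)
        if n == 0:
            raise EmptyInputError("topology with zero atoms")
        resnames = list(resnames)
        resids = list(int(r) for r in resids)
        chains = list(chains)
        if elements is None:
            elements = [_guess_element(nm) for nm in names]
        else:
            elements = list(elements)

        is_water = np.array([rn in water_resnames for rn in resnames])
        is_polar_sc = np.array(
            [
                (el in ("N", "O")) and (not w) and (nm not in _BACKBONE_NAMES)
                for el, w, nm in zip(elements, is_water, names)
            ]
        )
        atoms = pd.DataFrame(
            {
                "index": np.arange(n),
                "name": names,
                "element": elements,
                "residue_name": resnames,
                "residue_id": resids,
                "chain_id": chains,
                "is_water": is_water,
                "is_polar_sidechain_atom": is_polar_sc,
            }
        )
        universe = _build_universe(atoms)
        return cls(atoms=atoms, universe=universe,
                   water_resnames=frozenset(water_resnames), source=source)


def _build_universe(atoms: pd.DataFrame) -> mda.Universe:
    """Create a topology-only MDAnalysis universe mirroring the atom table."""
    n = len(atoms)
    # group consecutive atoms with identical (chain, resid, resname) into residues
    keys = list(zip(atoms["chain_id"], atoms["residue_id"], atoms["residue_name"]))
    resindex = np.empty(n, dtype=int)
    res_keys: list[tuple] = []
    prev = None
    for i, k in enumerate(keys):
        if k != prev:
            res_keys.append(k)
            prev = k
        resindex[i] = len(res_keys) - 1
    chains = [k[0] for k in res_keys]
    seg_names: list[str] = sorted(set(chains))
    seg_index = np.array([seg_names.index(c) for c in chains])

    u = mda.Universe.empty(
        n,
        n_residues=len(res_keys),
        n_segments=len(seg_names),
        atom_resindex=resindex,
        residue_segindex=seg_index,
        trajectory=False,
    )
    u.add_TopologyAttr("names", list(atoms["name"]))
    u.add_TopologyAttr("elements", list(atoms["element"]))
    u.add_TopologyAttr("chainIDs", list(atoms["chain_id"]))
    u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
    u.add_TopologyAttr("resids", [k[1] for k in res_keys])
    u.add_TopologyAttr("segids", seg_names)
    return u


def read_topology(path, water_resnames=DEFAULT_WATER_RESNAMES) -> Topology:
    """Parse fixed-column PDB ATOM/HETATM records into a :class:`Topology`.

    TER/REMARK and all other record types are ignored. Raises
    :class:`TopologyFormatError` (naming the line) on malformed coordinates
    and :class:`EmptyInputError` if no atoms are found.
    """
    path = Path(path)
    names, resnames, resids, chains, elements = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec not in ("ATOM  ", "HETATM"):
                continue
            try:
                name = line[12:16].strip()
                resname = line[17:21].strip()
                chain = line[21].strip() or " "
                resid = int(line[22:26])
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise TopologyFormatError(
                    f"unparseable ATOM/HETATM record ({exc})", lineno
                ) from exc
            elem = line[76:78].strip() if len(line) >= 78 else ""
            names.append(name)
            resnames.append(resname)
            resids.append(resid)
            chains.append(chain)
            elements.append(elem.upper() if elem else _guess_element(name))
    if not names:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    return Topology.from_arrays(
        names, resnames, resids, chains, elements,
        water_resnames=water_resnames, source=path,
    )


def write_pdb(topology: Topology, coords: np.ndarray, path) -> None:
    """Write one frame as fixed-column PDB v3.3 (deterministic, no headers)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topology.n_atoms, 3):
        raise ConsistencyError(
            f"coords shape {coords.shape} does not match {topology.n_atoms} atoms"
        )
    rows = topology.atoms
    with open(path, "w") as fh:
        for i in range(topology.n_atoms):
            name = rows["name"].iat[i]
            # PDB atom-name column convention: 1/2-char elements start col 14
            nm = name if len(name) >= 4 else f" {name:<3s}"
            fh.write(
                "ATOM  {serial:>5d} {nm:<4s}{alt:1s}{res:<4s}{ch:1s}{rid:>4d}{ic:1s}   "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                    serial=(i + 1) % 100000,
                    nm=nm,
                    alt=" ",
                    res=rows["residue_name"].iat[i],
                    ch=rows["chain_id"].iat[i],
                    rid=int(rows["residue_id"].iat[i]) % 10000,
                    ic=" ",
                    x=coords[i, 0], y=coords[i, 1], z=coords[i, 2],
                    occ=1.0, b=0.0,
                    el=rows["element"].iat[i][:2],
                )
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Per-frame coordinates (Å) plus an orthorhombic box, on a topology.

    Thin wrapper over an MDAnalysis trajectory reader (file-backed DCD or
    in-memory array). ``frame(i)`` returns ``(positions, box)`` where box is
    the (Lx, Ly, Lz) edge lengths in Å.
    """

    topology: Topology
    universe: mda.Universe
    timestep: float  # ps per stored frame

    @property
    def n_frames(self) -> int:
        return len(self.universe.trajectory)

    def _box_of(self, ts) -> np.ndarray:
        dims = ts.dimensions
        if dims is None or np.any(dims[:3] <= 0):
            raise DomainError(f"frame {ts.frame}: missing or non-positive unit cell")
        if np.any(np.abs(dims[3:] - 90.0) > _ANGLE_TOL):
            raise ConsistencyError(
                f"frame {ts.frame}: triclinic unit cell (angles {dims[3:]}) "
                "not supported; only orthorhombic boxes are handled"
            )
        return dims[:3].astype(float).copy()

    def frame(self, i: int):
        ts = self.universe.trajectory[i]
        return ts.positions.astype(float).copy(), self._box_of(ts)

    def iter_frames(self, stride: int = 1):
        """Yield ``(frame_index, positions, box)`` for every stride-th frame."""
        for i in range(0, self.n_frames, stride):
            ts = self.universe.trajectory[i]
            yield i, ts.positions.astype(float).copy(), self._box_of(ts)

    @classmethod
    def from_arrays(cls, topology: Topology, coords, box, timestep: float = 2.0
                    ) -> "Trajectory":
        """In-memory trajectory from ``coords (n_frames, n_atoms, 3)``.

        ``box`` is either one (Lx, Ly, Lz) triple used for all frames or an
        array of per-frame triples.
        """
        coords = np.asarray(coords, dtype=np.float32)
        if coords.ndim != 3 or coords.shape[1] != topology.n_atoms:
            raise ConsistencyError(
                f"coords shape {coords.shape} does not match "
                f"{topology.n_atoms} atoms"
            )
        box = np.asarray(box, dtype=float)
        if box.ndim == 1:
            box = np.tile(box, (coords.shape[0], 1))
        if np.any(box <= 0):
            raise DomainError("box edges must be > 0")
        dims = np.hstack([box, np.full((coords.shape[0], 3), 90.0)])
        u = _build_universe(topology.atoms)
        u.load_new(coords, dimensions=dims, dt=timestep, format="memory")
        return cls(topology=topology, universe=u, timestep=timestep)


def _dcd_header(path: Path) -> tuple[int, int]:
    """Return (n_frames_declared, n_atoms) from a CHARMM/NAMD DCD header."""
    with open(path, "rb") as fh:
        head = fh.read(100)
        if len(head) < 96 or head[4:8] != b"CORD":
            raise ConsistencyError(f"{path}: not a CHARMM/NAMD DCD file")
        nframes = struct.unpack("<i", head[8:12])[0]
        # skip the 84-byte header record, then the title record
        fh.seek(92)
        (tlen,) = struct.unpack("<i", fh.read(4))
        fh.seek(92 + 4 + tlen + 4 + 4)
        (natoms,) = struct.unpack("<i", fh.read(4))
    return nframes, natoms


def read_trajectory(path, topology: Topology, timestep: float | None = None
                    ) -> Trajectory:
    """Attach a DCD trajectory to a topology.

    Validates the header atom count against the topology and the declared
    frame count against what the file actually holds (a truncated file raises
    :class:`TruncatedTrajectoryError` naming the frame reached).
    """
    path = Path(path)
    nframes_decl, natoms = _dcd_header(path)
    if natoms != topology.n_atoms:
        raise ConsistencyError(
            f"{path}: DCD has {natoms} atoms but topology has {topology.n_atoms}"
        )
    u = _build_universe(topology.atoms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.load_new(str(path))
    readable = len(u.trajectory)
    if readable < nframes_decl:
        raise TruncatedTrajectoryError(readable, nframes_decl, str(path))
    if timestep is None:
        timestep = float(u.trajectory.dt)
    return Trajectory(topology=topology, universe=u, timestep=timestep)


def write_dcd(path, coords, box, timestep: float = 2.0) -> None:
    """Write frames to a CHARMM/NAMD DCD with a per-frame orthorhombic cell."""
    coords = np.asarray(coords, dtype=np.float32)
    n_frames, n_atoms, _ = coords.shape
    box = np.asarray(box, dtype=float)
    if box.ndim == 1:
        box = np.tile(box, (n_frames, 1))
    u = mda.Universe.empty(n_atoms, trajectory=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n_atoms, dt=timestep) as w:
            for f in range(n_frames):
                u.atoms.positions = coords[f]
                u.dimensions = [box[f, 0], box[f, 1], box[f, 2], 90.0, 90.0, 90.0]
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# selections

import re as _re


@dataclass(frozen=True)
class Selection:
    """A resolved atom selection: the expression plus sorted unique indices."""

    expression: str
    indices: np.ndarray = field(compare=False)
    label: str = ""

    @property
    def n(self) -> int:
        return len(self.indices)

    def __len__(self) -> int:
        return len(self.indices)


_KNOWN_TOKENS = frozenset(
    {"name", "resname", "resid", "chain", "chainid", "element", "water",
     "and", "or", "not", "(", ")", "to"}
)


def _translate(expression: str, water_resnames) -> str:
    expr = _re.sub(r"\bchain\b(?!ID)", "chainID", expression)
    water_clause = "(resname " + " ".join(sorted(water_resnames)) + ")"
    expr = _re.sub(r"\bwater\b", water_clause, expr)
    return expr


def _first_bad_token(expression: str) -> int:
    """Best-effort character position of the first unrecognised keyword."""
    expect_value = False
    for m in _re.finditer(r"[^\s()]+|[()]", expression):
        tok = m.group(0)
        low = tok.lower()
        if low in ("and", "or", "not", "(", ")"):
            expect_value = False
            continue
        if low in _KNOWN_TOKENS:
            expect_value = low not in ("water",)
            continue
        if expect_value:  # value for a preceding keyword; wildcards/ranges ok
            continue
        return m.start()
    return 0


def select(topology: Topology, expression: str, label: str = "") -> Selection:
    """Resolve a selection expression to a sorted unique 0-based index set.

    Grammar: ``name``, ``resname``, ``resid``, ``chain``, ``element``, the
    ``water`` keyword (expands to the topology's water residue-name set) and
    boolean ``and``/``or``/``not`` with parentheses; ``name`` accepts ``*``
    wildcards. An empty result is valid; a syntax error raises
    :class:`SelectionSyntaxError` with the character position.
    """
    translated = _translate(expression, topology.water_resnames)
    try:
        group = topology.universe.select_atoms(translated)
    except (SelectionError, ValueError, TypeError) as exc:
        raise SelectionSyntaxError(
            expression, str(exc), _first_bad_token(expression)
        ) from exc
    idx = np.unique(group.indices).astype(np.int64)
    return Selection(expression=expression, indices=idx, label=label or expression)
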