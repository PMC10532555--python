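import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", module="MDAnalysis")

from channelhydra.synthetic import SyntheticSpec, generate_arrays
from channelhydra.trajio import Topology, Trajectory


def make_system(names, resnames, resids, chains, coords, box=(50.0, 50.0, 50.0),
                timestep=2.0, elements=None):
    """In-memory topology + trajectory from per-atom fields and a coordinate
    stack of shape (n_frames, n_atoms, 3)."""
    topo = Topology.from_arrays(names, resnames, resids, chains,
                                elements=elements)
    traj = Trajectory.from_arrays(topo, np.asarray(coords, dtype=float), box,
                                  timestep=timestep)
    return topo, traj


def water_system(positions, n_frames=1, box=(50.0, 50.0, 50.0), extra=None):
    """System of oxygen-only waters at fixed positions, optionally with extra
    protein atoms appended as (name, resname, resid, chain, xyz) tuples."""
    positions = np.asarray(positions, dtype=float)
    names = ["OH2"] * len(positions)
    resnames = ["TIP3"] * len(positions)
    resids = list(range(1, len(positions) + 1))
    chains = ["W"] * len(positions)
    coords = [positions]
    if extra:
        for name, rn, rid, ch, xyz in extra:
            names.append(name)
            resnames.append(rn)
            resids.append(rid)
            chains.append(ch)
        coords = [np.vstack([positions] + [np.asarray(e[4], dtype=float)[None]
                                           for e in extra])]
    coords = np.repeat(np.asarray(coords), n_frames, axis=0)
    return make_system(names, resnames, resids, chains, coords, box=box)


@pytest.fixture(scope="session")
def paper_system():
    """One default-condition synthetic channel system (medium length)."""
    return generate_arrays(SyntheticSpec.paper_like(seed=11, n_frames=1500))


@pytest.fixture(scope="session")
def paper_trajectory(paper_system):
    return paper_system.trajectory()
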