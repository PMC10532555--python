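"""Periodic-boundary distance geometry.

All distances use the minimum-image convention in an orthorhombic box.
Neighbor queries go through a periodic k-d tree and are, by contract,
output-identical to a brute-force all-pairs scan (tested against one).
Cutoffs are closed intervals: a pair at exactly the cutoff distance counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConsistencyError, DomainError

# slack factor for tree queries; exact distances are re-checked afterwards
_QUERY_SLACK = 1.0 + 1e-9


def _check_box(box) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise DomainError(f"box must be three positive edge lengths, got {box}")
    return box


def min_image_displacement(p, q, box) -> np.ndarray:
    """Minimum-image displacement vector(s) q - p (broadcasting)."""
    box = _check_box(box)
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(p, q, box) -> float | np.ndarray:
    """Minimum-image Euclidean distance between points (broadcasting)."""
    d = min_image_displacement(p, q, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def _wrap(coords, box):
    return np.mod(np.asarray(coords, dtype=float), box)


def periodic_tree(coords, box) -> cKDTree:
    """k-d tree over coordinates wrapped into a periodic orthorhombic box."""
    box = _check_box(box)
    return cKDTree(_wrap(coords, box), boxsize=box)


def pairs_within_cutoff(coords, box, idx_a, idx_b, cutoff: float):
    """All pairs (i, j, distance) with i from ``idx_a``, j from ``idx_b`` and
    min-image distance ≤ cutoff (closed interval).

    Each unordered pair is reported once even when the index sets overlap;
    self-pairs are never reported. Output is sorted by (i, j).
    """
    if cutoff <= 0:
        raise DomainError(f"cutoff must be > 0, got {cutoff}")
    box = _check_box(box)
    coords = np.asarray(coords, dtype=float)
    idx_a = np.asarray(idx_a, dtype=np.int64)
    idx_b = np.asarray(idx_b, dtype=np.int64)
    if len(idx_a) == 0 or len(idx_b) == 0:
        return []
    tree_a = cKDTree(_wrap(coords[idx_a], box), boxsize=box)
    tree_b = cKDTree(_wrap(coords[idx_b], box), boxsize=box)
    hits = tree_a.query_ball_tree(tree_b, r=cutoff * _QUERY_SLACK)
    seen = set()
    out = []
    for ia_local, neigh in enumerate(hits):
        i = idx_a[ia_local]
        for ib_local in neigh:
            j = idx_b[ib_local]
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            d = float(min_image_distance(coords[i], coords[j], box))
            if d <= cutoff:
                seen.add(key)
                out.append((int(key[0]), int(key[1]), d))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def min_cross_distance(coords, box, idx_a, idx_b) -> float:
    """Minimum min-image distance over all cross pairs A × B."""
    box = _check_box(box)
    coords = np.asarray(coords, dtype=float)
    tree_b = cKDTree(_wrap(coords[idx_b], box), boxsize=box)
    d, _ = tree_b.query(_wrap(coords[idx_a], box), k=1)
    return float(np.min(d))


# ---------------------------------------------------------------------------
# rigid superposition


def superpose_transform(ref, mov):
    """Optimal rotation R and translation t minimizing |R·mov + t - ref|².

    Kabsch algorithm (SVD with determinant correction, so no reflections).
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape:
        raise ConsistencyError(
            f"point counts differ: {ref.shape} vs {mov.shape}"
        )
    if ref.ndim != 2 or ref.shape[0] < 3:
        raise DomainError("superposition needs at least 3 points")
    cref = ref.mean(axis=0)
    cmov = mov.mean(axis=0)
    h = (mov - cmov).T @ (ref - cref)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cref - rot @ cmov
    return rot, trans


def superpose_rmsd(ref, mov) -> float:
    """Least-squares RMSD (Å) after optimal rigid superposition."""
    rot, trans = superpose_transform(ref, mov)
    moved = (np.asarray(mov, dtype=float) @ rot.T) + trans
    diff = moved - np.asarray(ref, dtype=float)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


# ---------------------------------------------------------------------------
# helix axis and the chi angle


@dataclass(frozen=True)
class HelixAxis:
    """Axis of an alpha helix: centroid origin plus a unit direction vector
    oriented from the N-terminal toward the C-terminal end."""

    origin: np.ndarray
    direction: np.ndarray


def helix_axis(calpha_coords) -> HelixAxis:
    """Principal axis of an ordered (N→C) set of Cα positions.

    The direction is the leading principal component of the centered cloud,
    sign-fixed so it points toward the C-terminal end.
    """
    x = np.asarray(calpha_coords, dtype=float)
    if x.ndim != 2 or x.shape[0] < 4:
        raise DomainError("helix axis needs at least 4 Cα positions")
    centroid = x.mean(axis=0)
    centered = x - centroid
    if np.allclose(centered, 0.0):
        raise DomainError("degenerate (zero-variance) Cα cloud")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if np.dot(direction, x[-1] - x[0]) < 0:
        direction = -direction
    direction = direction / np.linalg.norm(direction)
    return HelixAxis(origin=centroid, direction=direction)


def chi_angle(sidechain_vec, axis: HelixAxis) -> float:
    """Angle χ (degrees, in [0, 180]) between a side-chain vector and a helix
    axis. The side-chain vector is conventionally Cα → terminal polar heavy
    atom (Asn: ND2, Gln: NE2, ...)."""
    v = np.asarray(sidechain_vec, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise DomainError("zero-length side-chain vector")
    cosang = np.clip(np.dot(v / norm, axis.direction), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def ideal_helix(n_residues: int, rise: float = 1.5, radius: float = 2.3,
                turn_deg: float = 100.0, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Cα trace of an ideal alpha helix along +z (used for fixtures)."""
    t = np.arange(n_residues)
    ang = np.radians(turn_deg) * t
    pts = np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), rise * t]
    )
    return pts + np.asarray(origin, dtype=float)
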