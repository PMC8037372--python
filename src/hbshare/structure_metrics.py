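"""RMSD time series, pairwise-RMSD clustering, representative-frame selection.

The clustering is the greedy neighbor-count scheme common in conformational
analysis of MD trajectories: on the matrix of pairwise (optionally
superposed) RMSDs, the frame with the most neighbors within the cutoff is
taken as a cluster center, it and its neighbors are removed, and the process
repeats.  Clusters are reported in decreasing size; all ties break toward the
lowest frame index so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import GeometryError, ParameterError
from .trajectory_io import Frame, Trajectory

__all__ = [
    "RmsdSeries",
    "ClusterResult",
    "kabsch_superpose",
    "rmsd_series",
    "cluster_frames",
    "representative_frame",
]


@dataclass
class RmsdSeries:
    times: np.ndarray       # fs
    values: np.ndarray      # Å
    selection: list[int]
    reference: int          # frame identifier of the reference


@dataclass
class ClusterResult:
    """Partition of frames into non-overlapping clusters.

    ``assignment`` maps frame index -> cluster id; cluster ids are ordered by
    decreasing size.  ``centers[k]`` is the center frame of cluster k.
    """

    assignment: dict[int, int]
    sizes: list[int]
    centers: list[int]
    cutoff: float


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the least-squares deviation
    from ``target``; the rotation is proper (det = +1).  For degenerate
    (collinear) point sets the minimizing rotation is not unique but the
    minimum RMSD is, and one minimizer is returned.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("point sets must both be N×3")
    if mobile.shape[0] < 2:
        raise GeometryError("need at least 2 points to superpose")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    p, q = mobile - cm, target - ct
    cov = p.T @ q
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ct - rotation @ cm
    aligned = p @ rotation.T
    rmsd = float(np.sqrt(((aligned - q) ** 2).sum() / mobile.shape[0]))
    return rotation, translation, rmsd


def _frame_rmsd(a: np.ndarray, b: np.ndarray, align: bool) -> float:
    if align:
        return kabsch_superpose(a, b)[2]
    return float(np.sqrt(((a - b) ** 2).sum() / a.shape[0]))


def rmsd_series(
    traj: Trajectory,
    reference: Frame,
    selection: Sequence[int],
    align: bool = True,
) -> RmsdSeries:
    """Per-frame RMSD (Å) of ``selection`` against a reference frame.

    When ``align`` is true each frame is Kabsch-superposed onto the reference
    on the same selection before the deviation is measured (a local RMSD uses
    a local superposition).
    """
    sel = list(selection)
    if not sel:
        raise ParameterError("selection must not be empty")
    ref = reference.coordinates[sel]
    values = np.array(
        [_frame_rmsd(fr.coordinates[sel], ref, align) for fr in traj.frames]
    )
    return RmsdSeries(
        times=traj.times, values=values, selection=sel, reference=reference.frame_index
    )


def pairwise_rmsd_matrix(
    traj: Trajectory, selection: Sequence[int], align: bool = True
) -> np.ndarray:
    """Symmetric matrix of pairwise (aligned) RMSDs over the selection."""
    sel = list(selection)
    if not sel:
        raise ParameterError("selection must not be empty")
    coords = [fr.coordinates[sel] for fr in traj.frames]
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _frame_rmsd(coords[i], coords[j], align)
    return mat


def cluster_frames(
    traj: Trajectory,
    selection: Sequence[int],
    cutoff: float = 0.6,
    align: bool = True,
    rmsd_matrix: Optional[np.ndarray] = None,
) -> ClusterResult:
    """Greedy neighbor-count clustering on the pairwise aligned-RMSD matrix.

    The default 0.6 Å cutoff is a package default for local active-site RMSDs,
    not a literature value; report the cutoff with any clustering result.
    Every member lies within ``cutoff`` of its cluster center (inclusive).
    """
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be > 0, got {cutoff}")
    mat = pairwise_rmsd_matrix(traj, selection, align) if rmsd_matrix is None else rmsd_matrix
    n = mat.shape[0]
    remaining = list(range(n))
    clusters: list[tuple[int, list[int]]] = []  # (center, members)
    while remaining:
        rem = np.array(remaining)
        neigh = mat[np.ix_(rem, rem)] <= cutoff  # includes self
        counts = neigh.sum(axis=1)
        best = int(np.argmax(counts))  # argmax takes the first (lowest index) on ties
        center = int(rem[best])
        members = [int(rem[k]) for k in np.nonzero(neigh[best])[0]]
        clusters.append((center, members))
        remaining = [f for f in remaining if f not in set(members)]
    clusters.sort(key=lambda cm: (-len(cm[1]), cm[0]))
    assignment: dict[int, int] = {}
    sizes, centers = [], []
    for cid, (center, members) in enumerate(clusters):
        sizes.append(len(members))
        centers.append(center)
        for f in members:
            assignment[f] = cid
    return ClusterResult(assignment=assignment, sizes=sizes, centers=centers, cutoff=cutoff)


def representative_frame(result: ClusterResult) -> int:
    """Center frame of the most populated cluster (ties: lowest center index)."""
    if not result.sizes:
        raise ParameterError("empty cluster result")
    best = max(range(len(result.sizes)), key=lambda k: (result.sizes[k], -result.centers[k]))
    return result.centers[best]
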