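"""Per-well network-trajectory embedding.

Each well's per-day pairwise-FC vectors (Fisher z over unordered
electrode pairs, fixed lexicographic order) are stacked into an m × k
feature matrix A (m recordings, k pairs). The rows are mean-centered —
no variance scaling, since every feature already shares Fisher-z units
and scaling would explode near-constant pairs — and projected onto the
first two principal components. Network change is the Euclidean
distance of each day's 2-PC point to the Day-0 point.

The embedding is computed separately for each well: a pair feature is
only comparable to itself across days within one well, so pooling
wells into a single decomposition would mix incommensurable features.

For m = 3 recordings, 3 centered points span at most a plane, so the
2-PC embedding is *exactly* distance-preserving: the plotted distances
equal the full k-dimensional distances. The full-space distances are
reported alongside as a check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import FCMatrix, pair_index
from .stats import StatResult, two_sample_t

__all__ = [
    "WellTrajectory",
    "build_feature_matrix",
    "pca_embed",
    "trajectory_distances",
    "embed_well",
    "compare_group_distances",
]


@dataclass
class WellTrajectory:
    """Feature matrix, 2-PC coordinates and distances for one well."""

    A: np.ndarray  # (m, k)
    pair_ids: np.ndarray  # (k, 2) unordered pairs retained
    dropped_pairs: np.ndarray = None  # (d, 2) pairs invalid on >= 1 day
    pc_coords: np.ndarray = None  # (m, 2)
    explained_variance_ratio: np.ndarray = None
    distances: np.ndarray = None  # (m,) 2-PC distance to day 0
    distances_full: np.ndarray = None  # (m,) full-space distance to day 0
    meta: dict = field(default_factory=dict)

    @property
    def n_days(self) -> int:
        return self.A.shape[0]


def build_feature_matrix(fc_by_day: list[FCMatrix]) -> WellTrajectory:
    """Stack one well's daily FC pair vectors into the feature matrix A.

    A pair that is invalid on *any* day carries no comparable signal
    and is dropped from every row; dropped pairs are recorded.
    """
    if len(fc_by_day) < 2:
        raise ValueError("need FC for at least 2 days")
    n = fc_by_day[0].n_electrodes
    for fc in fc_by_day:
        if fc.n_electrodes != n or not np.array_equal(
            fc.electrode_ids, fc_by_day[0].electrode_ids
        ):
            raise ValueError("all days must share the same electrode set")
    i, j = pair_index(n)
    rows, valids = [], []
    for fc in fc_by_day:
        zv, va = fc.pair_vector()
        rows.append(zv)
        valids.append(va)
    keep = np.logical_and.reduce(valids)
    A = np.stack(rows)[:, keep]
    pairs = np.column_stack([i, j])
    return WellTrajectory(
        A=A,
        pair_ids=pairs[keep],
        dropped_pairs=pairs[~keep],
    )


def pca_embed(traj: WellTrajectory) -> WellTrajectory:
    """Project the rows of A onto the first two principal components.

    Columns are mean-centered (no scaling); scores come from an economy
    SVD of the centered matrix. Sign convention: each component is
    flipped so its largest-magnitude loading is positive, making the
    embedding deterministic.
    """
    if traj.A is None or traj.A.shape[0] < 2:
        raise ValueError("need at least 2 recordings to embed")
    Ac = traj.A - traj.A.mean(axis=0, keepdims=True)
    m = Ac.shape[0]
    U, s, Vt = np.linalg.svd(Ac, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each PC positive
    for c in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[c]))
        if Vt[c, pivot] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    scores = U * s  # (m, r)
    coords = np.zeros((m, 2))
    r = min(2, scores.shape[1])
    coords[:, :r] = scores[:, :r]
    total_var = float(np.sum(s**2))
    if total_var > 0:
        evr = (s[:2] ** 2) / total_var
    else:
        evr = np.zeros(min(2, s.size))
    traj.pc_coords = coords
    traj.explained_variance_ratio = evr
    traj.meta["singular_values"] = s
    return traj


def trajectory_distances(traj: WellTrajectory) -> WellTrajectory:
    """Euclidean distance of each day's point to the Day-0 point.

    Computed in 2-PC space (what gets plotted) and in the full feature
    space; for m = 3 the two coincide up to numerical error.
    """
    if traj.pc_coords is None:
        raise ValueError("run pca_embed first")
    d2 = np.linalg.norm(traj.pc_coords - traj.pc_coords[0], axis=1)
    Ac = traj.A - traj.A.mean(axis=0, keepdims=True)
    dfull = np.linalg.norm(Ac - Ac[0], axis=1)
    traj.distances = d2
    traj.distances_full = dfull
    return traj


def embed_well(fc_by_day: list[FCMatrix]) -> WellTrajectory:
    """Convenience: feature matrix → PCA → distances in one call."""
    return trajectory_distances(pca_embed(build_feature_matrix(fc_by_day)))


def compare_group_distances(
    day_treated: np.ndarray, day_control: np.ndarray
) -> StatResult:
    """Two-sample t-test (with Cohen's d) on per-well trajectory distances."""
    day_treated = np.asarray(day_treated, dtype=float)
    day_control = np.asarray(day_control, dtype=float)
    if day_treated.size < 2 or day_control.size < 2:
        raise ValueError("need at least 2 wells per group")
    return two_sample_t(day_treated, day_control)
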