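"""Burst-excluded functional connectivity from binned spike trains.

Spike trains are vectorized into non-overlapping 50-ms count bins and
functional connectivity (FC) is the Pearson correlation of each
unordered electrode pair's bin-count vectors, Fisher z-transformed
(``z = atanh(rho)``). Correlation between spike trains is positively
biased during epochs of high shared rate, so population-burst bins are
excluded by default; :func:`burst_bias_check` quantifies that bias on a
given recording by computing the mean pairwise z with and without the
burst bins.

Pairs are unordered (k = n(n-1)/2): Pearson correlation is symmetric,
so the ordered-pair duplication adds no information. An ordered-pair
switch exists on :meth:`FCMatrix.pair_vector` for replication attempts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .spikes import BurstMask, SpikeTrainSet

__all__ = [
    "BinnedSpikeMatrix",
    "FCMatrix",
    "NetworkGraph",
    "bin_spike_counts",
    "pairwise_fc",
    "burst_bias_check",
    "threshold_network",
    "pair_index",
]

RHO_CLIP = 1.0 - 1e-7


def pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of unordered pairs (i < j) in fixed lexicographic order."""
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


@dataclass
class BinnedSpikeMatrix:
    """Electrode × bin spike counts at fixed bin width.

    Bin ``b`` covers the half-open interval ``[b·width, (b+1)·width)``;
    a trailing partial bin is discarded.
    """

    counts: np.ndarray
    width: float
    electrode_ids: np.ndarray = None
    burst_mask: Optional[BurstMask] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be electrodes × bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.width <= 0:
            raise ValueError("bin width must be positive")
        if self.electrode_ids is None:
            self.electrode_ids = np.arange(self.counts.shape[0])
        self.electrode_ids = np.asarray(self.electrode_ids)

    @property
    def n_electrodes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass
class FCMatrix:
    """Symmetric Fisher-z functional connectivity over electrode pairs.

    ``z`` is an (n, n) symmetric matrix with zero diagonal (the diagonal
    is excluded from every summary); ``valid`` marks pairs where both
    electrodes had nonzero variance over the bins used. Invalid pairs
    hold z = 0 but are excluded — never counted as zero connectivity.
    """

    z: np.ndarray
    valid: np.ndarray
    n_bins_used: int
    burst_excluded: bool
    electrode_ids: np.ndarray = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.z.shape[0]
        if self.z.shape != (n, n) or self.valid.shape != (n, n):
            raise ValueError("z and valid must be square matrices of equal size")
        if not np.allclose(self.z, self.z.T):
            raise ValueError("z must be symmetric")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z must be finite everywhere")
        if self.electrode_ids is None:
            self.electrode_ids = np.arange(n)
        self.electrode_ids = np.asarray(self.electrode_ids)

    @property
    def n_electrodes(self) -> int:
        return self.z.shape[0]

    def pair_vector(self, ordered: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """(z values, validity) over pairs in fixed lexicographic order.

        ``ordered=True`` duplicates each unordered pair (i, j) and
        (j, i) — provided only for replicating analyses that counted
        k = n² ordered pairs.
        """
        i, j = pair_index(self.n_electrodes)
        zv, va = self.z[i, j], self.valid[i, j]
        if ordered:
            zv = np.concatenate([zv, zv])
            va = np.concatenate([va, va])
        return zv, va

    def mean_z(self) -> float:
        zv, va = self.pair_vector()
        if not va.any():
            return np.nan
        return float(zv[va].mean())


@dataclass
class NetworkGraph:
    """Thresholded FC network: edge list (i < j) with per-node degree."""

    edges: np.ndarray  # (n_edges, 3): i, j, z
    degrees: np.ndarray
    threshold: float
    electrode_ids: np.ndarray = None

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


def bin_spike_counts(trains: SpikeTrainSet, width: float = 0.05) -> BinnedSpikeMatrix:
    """Bin spikes into non-overlapping windows of ``width`` seconds."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    n_bins = int(np.floor(trains.duration / width))
    counts = np.zeros((trains.n_electrodes, n_bins), dtype=np.int64)
    for e, t in enumerate(trains.trains):
        if t.size:
            idx = np.floor(t / width).astype(np.int64)
            idx = idx[idx < n_bins]  # trailing partial bin discarded
            counts[e] = np.bincount(idx, minlength=n_bins)
    return BinnedSpikeMatrix(
        counts=counts, width=width, electrode_ids=trains.electrode_ids
    )


def _fc_from_counts(counts: np.ndarray, electrode_ids, n_bins_used, burst_excluded):
    n = counts.shape[0]
    sd = counts.std(axis=1)
    ok = sd > 0
    z = np.zeros((n, n))
    valid = np.zeros((n, n), dtype=bool)
    idx = np.where(ok)[0]
    if idx.size >= 2:
        rho = np.corrcoef(counts[idx].astype(float))
        rho = np.clip(rho, -RHO_CLIP, RHO_CLIP)
        zsub = np.arctanh(rho)
        np.fill_diagonal(zsub, 0.0)
        z[np.ix_(idx, idx)] = zsub
        vsub = np.ones((idx.size, idx.size), dtype=bool)
        np.fill_diagonal(vsub, False)
        valid[np.ix_(idx, idx)] = vsub
    return FCMatrix(
        z=z,
        valid=valid,
        n_bins_used=int(n_bins_used),
        burst_excluded=burst_excluded,
        electrode_ids=electrode_ids,
    )


def pairwise_fc(binned: BinnedSpikeMatrix, exclude_bursts: bool = True) -> FCMatrix:
    """Fisher-z Pearson FC across all unique electrode pairs.

    With ``exclude_bursts`` (default), correlations run over the
    concatenated non-burst bins given by the matrix's burst mask. The
    correlation coefficient is clipped to ±(1 − 1e-7) before the
    z-transform so perfectly correlated pairs stay finite. Pairs
    involving an electrode with zero variance over the used bins are
    marked invalid.
    """
    counts = binned.counts
    if exclude_bursts and binned.burst_mask is not None:
        keep = ~binned.burst_mask.bin_flags
        if keep.size != binned.n_bins:
            raise ValueError("burst mask length does not match bin count")
        counts = counts[:, keep]
        burst_excluded = True
    else:
        burst_excluded = False
    if counts.shape[1] < 2:
        raise ValueError(
            "fewer than 2 usable bins after burst exclusion; "
            "the burst mask removed (almost) the entire recording"
        )
    return _fc_from_counts(
        counts, binned.electrode_ids, counts.shape[1], burst_excluded
    )


def burst_bias_check(binned: BinnedSpikeMatrix) -> tuple[float, float]:
    """Mean pairwise Fisher z including vs excluding burst bins.

    Returns ``(z_with, z_without)`` computed from the same binned
    matrix. With an empty burst mask the two values are equal by
    construction.
    """
    if binned.burst_mask is None:
        raise ValueError("burst_bias_check requires a burst mask")
    z_with = pairwise_fc(binned, exclude_bursts=False).mean_z()
    if binned.burst_mask.bin_flags.any():
        z_without = pairwise_fc(binned, exclude_bursts=True).mean_z()
    else:
        z_without = z_with
    return z_with, z_without


def threshold_network(fc: FCMatrix, z_min: float = 0.80) -> NetworkGraph:
    """Edges are valid pairs with z above ``z_min``; degree per node."""
    i, j = pair_index(fc.n_electrodes)
    zv = fc.z[i, j]
    keep = (zv > z_min) & fc.valid[i, j]
    edges = np.column_stack([i[keep], j[keep], zv[keep]])
    degrees = np.zeros(fc.n_electrodes, dtype=int)
    for a, b in zip(i[keep], j[keep]):
        degrees[a] += 1
        degrees[b] += 1
    return NetworkGraph(
        edges=edges,
        degrees=degrees,
        threshold=z_min,
        electrode_ids=fc.electrode_ids,
    )
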