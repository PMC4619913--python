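"""Binary anatomical network construction from streamline endpoints.

Two regions u and v are joined by an edge when at least ``threshold`` (default
3) streamlines have one terminal point in u and the other in v.  The fiber
count is used only to decide edge existence; the analysed network is binary,
symmetric, with zero diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .grids import in_bounds, world_to_voxel
from .parcellation import homotopic_pairs
from .tracking import StreamlineSet

__all__ = [
    "LabelVolume",
    "ConnectomeMatrix",
    "assign_endpoints",
    "build_matrix",
    "largest_component_size",
    "component_size_sweep",
]

logger = logging.getLogger(__name__)


@dataclass
class LabelVolume:
    """Integer region labels on the diffusion grid (0 = background).

    Labels 1..N partition into homotopic pairs (2k-1, 2k); odd ids are left
    hemisphere, even ids right.
    """

    labels: np.ndarray  # 3D int
    affine: np.ndarray
    region_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if self.n_regions % 2 != 0:
            raise ValueError(
                f"region count must be even (homotopic pairs), got {self.n_regions}"
            )

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return homotopic_pairs(self.n_regions)


@dataclass
class ConnectomeMatrix:
    """Fiber-count matrix and its binarization at the edge threshold."""

    fiber_counts: np.ndarray  # (N, N) int
    adjacency: np.ndarray  # (N, N) {0, 1}
    threshold: int
    node_ids: np.ndarray  # region labels 1..N

    @property
    def n_nodes(self) -> int:
        return self.fiber_counts.shape[0]


def assign_endpoints(streamlines: StreamlineSet, labels: LabelVolume) -> list[tuple[int, int] | None]:
    """Map each streamline's two terminal points to region labels.

    A streamline contributes a pair only when both terminal voxels carry a
    nonzero label and the labels differ (self-connections are discarded).
    """
    if not np.allclose(streamlines.affine, labels.affine):
        raise ValueError("streamlines and label volume use different affines")
    out: list[tuple[int, int] | None] = []
    n_unassigned = 0
    shape = labels.labels.shape
    for line in streamlines.streamlines:
        ends = np.vstack([line[0], line[-1]])
        vox = world_to_voxel(labels.affine, ends)
        if not in_bounds(vox, shape).all():
            out.append(None)
            n_unassigned += 1
            continue
        u, v = (int(labels.labels[tuple(vox[0])]), int(labels.labels[tuple(vox[1])]))
        if u == 0 or v == 0 or u == v:
            out.append(None)
            n_unassigned += 1
        else:
            out.append((u, v))
    if n_unassigned:
        logger.info(
            "%d of %d streamlines did not connect two distinct regions",
            n_unassigned, len(streamlines),
        )
    return out


def build_matrix(assignments, n_regions: int, threshold: int = 3) -> ConnectomeMatrix:
    """Accumulate fiber counts per unordered region pair and binarize."""
    if threshold < 1:
        raise ValueError("edge threshold must be >= 1")
    counts = np.zeros((n_regions, n_regions), dtype=np.int64)
    for pair in assignments:
        if pair is None:
            continue
        u, v = pair
        if not (1 <= u <= n_regions and 1 <= v <= n_regions):
            raise ValueError(f"region id {max(u, v)} outside 1..{n_regions}")
        counts[u - 1, v - 1] += 1
        counts[v - 1, u - 1] += 1
    np.fill_diagonal(counts, 0)
    adjacency = (counts >= threshold).astype(np.int8)
    return ConnectomeMatrix(
        fiber_counts=counts,
        adjacency=adjacency,
        threshold=threshold,
        node_ids=np.arange(1, n_regions + 1),
    )


def largest_component_size(adjacency: np.ndarray) -> int:
    """Node count of the largest connected component of a binary graph."""
    adjacency = np.asarray(adjacency)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be square")
    n_comp, membership = connected_components(csr_matrix(adjacency), directed=False)
    return int(np.bincount(membership, minlength=n_comp).max())


def component_size_sweep(fiber_count_matrices, thresholds) -> dict[int, float]:
    """Cohort mean of the largest-component size as a function of threshold.

    The diagnostic behind the edge-threshold choice: the threshold is picked so
    that the mean largest component keeps every node.
    """
    out: dict[int, float] = {}
    for t in thresholds:
        sizes = [
            largest_component_size((np.asarray(c) >= t).astype(np.int8))
            for c in fiber_count_matrices
        ]
        out[int(t)] = float(np.mean(sizes))
    return out
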