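"""Deterministic FACT streamline tractography.

Fiber assignment by continuous tracking: every voxel whose FA exceeds the
seed threshold launches one bidirectional streamline.  Propagation follows
the principal diffusion eigenvector of the *current* voxel (nearest-neighbour
orientation lookup), sign-aligned with the incoming direction at every step.
A track terminates when

* the turning angle would exceed ``angle_stop_deg`` (default 50 degrees),
* the next voxel's FA falls below ``fa_stop_threshold`` (default 0.2),
* the next point leaves the volume, or
* ``max_steps`` is reached.

Points are stored in world millimetres; the step size defaults to half the
smallest voxel dimension, an approximation of voxel-face FACT transit that
keeps the path inside the voxels whose orientations it samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import in_bounds, voxel_to_world, world_to_voxel
from .tensor import FAMap, TensorField

__all__ = ["TrackingParams", "StreamlineSet", "track_fact", "count_streamline_voxels"]


@dataclass(frozen=True)
class TrackingParams:
    """FACT seeding and termination rules."""

    fa_seed_threshold: float = 0.2
    fa_stop_threshold: float = 0.2
    angle_stop_deg: float = 50.0
    step_size_mm: float | None = None  # None -> 0.5 * min voxel dimension
    max_steps: int = 300
    seeds_per_voxel: int = 1
    min_steps: int = 3  # discard shorter fragments (seed-only debris)
    seed: int = 0  # used only when seeds_per_voxel > 1 (jittered placement)

    def __post_init__(self) -> None:
        if not (0.0 < self.fa_seed_threshold < 1.0):
            raise ValueError("fa_seed_threshold must lie in (0, 1)")
        if not (0.0 < self.fa_stop_threshold < 1.0):
            raise ValueError("fa_stop_threshold must lie in (0, 1)")
        if not (0.0 < self.angle_stop_deg < 90.0):
            raise ValueError("angle_stop_deg must lie in (0, 90)")
        if self.step_size_mm is not None and self.step_size_mm <= 0:
            raise ValueError("step_size_mm must be positive")
        if self.seeds_per_voxel < 1:
            raise ValueError("seeds_per_voxel must be >= 1")


@dataclass
class StreamlineSet:
    """Ordered world-coordinate polylines with seed and termination metadata."""

    streamlines: list[np.ndarray]  # each (k, 3) world mm, k >= 2
    seed_voxels: np.ndarray  # (n, 3) int
    termination_reasons: list[tuple[str, str]]  # (backward end, forward end)
    affine: np.ndarray

    def __len__(self) -> int:
        return len(self.streamlines)

    def subset(self, indices) -> "StreamlineSet":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return StreamlineSet(
            streamlines=[self.streamlines[i] for i in indices],
            seed_voxels=self.seed_voxels[indices] if len(self.seed_voxels) else self.seed_voxels,
            termination_reasons=[self.termination_reasons[i] for i in indices],
            affine=self.affine,
        )


def _half_tracks(start_points, init_dirs, directions, enterable, fa_shape,
                 affine, step, cos_stop, max_steps):
    """Propagate all seeds simultaneously in one direction.

    Returns (paths, lengths, reasons): ``paths[i, :lengths[i]]`` are the accepted
    points beyond the start point.
    """
    n = start_points.shape[0]
    paths = np.zeros((n, max_steps, 3))
    lengths = np.zeros(n, dtype=np.int64)
    reasons = np.array(["max_steps"] * n, dtype=object)

    p = start_points.copy()
    d_prev = init_dirs.copy()
    active = np.ones(n, dtype=bool)

    for step_i in range(max_steps):
        # the first move is a half step, so with the default half-voxel step
        # subsequent points never sit exactly on a voxel boundary (where the
        # round-half-down lookup would break mirror symmetry)
        this_step = 0.5 * step if step_i == 0 else step
        if not active.any():
            break
        idx = np.flatnonzero(active)
        vox = world_to_voxel(affine, p[idx])
        e = directions[vox[:, 0], vox[:, 1], vox[:, 2]]
        # sign-align the voxel eigenvector with the incoming direction
        dots = np.einsum("ij,ij->i", e, d_prev[idx])
        e = np.where(dots[:, None] < 0, -e, e)
        cos_turn = np.abs(dots)
        angle_bad = cos_turn < cos_stop
        reasons[idx[angle_bad]] = "angle"

        q = p[idx] + this_step * e
        vq = world_to_voxel(affine, q)
        inside = in_bounds(vq, fa_shape)
        reasons[idx[~angle_bad & ~inside]] = "bounds"
        ok = ~angle_bad & inside
        fa_bad = np.zeros_like(ok)
        sub = np.flatnonzero(ok)
        if sub.size:
            vq_ok = vq[sub]
            fa_bad_sub = ~enterable[vq_ok[:, 0], vq_ok[:, 1], vq_ok[:, 2]]
            fa_bad[sub] = fa_bad_sub
            reasons[idx[sub[fa_bad_sub]]] = "fa"
        ok &= ~fa_bad

        accepted = idx[ok]
        p[accepted] = q[ok]
        d_prev[accepted] = e[ok]
        paths[accepted, lengths[accepted]] = q[ok]
        lengths[accepted] += 1
        active[idx[~ok]] = False
    return paths, lengths, reasons


def track_fact(tensors: TensorField, fa: FAMap, params: TrackingParams | None = None) -> StreamlineSet:
    """Run FACT over the whole volume and return the retained streamlines."""
    params = params or TrackingParams()
    if tensors.shape != fa.fa.shape:
        raise ValueError("tensor field and FA map shapes differ")
    if not np.allclose(tensors.affine, fa.affine):
        raise ValueError("tensor field and FA map affines differ")

    affine = tensors.affine
    shape = fa.fa.shape
    voxel_dims = np.linalg.norm(affine[:3, :3], axis=0)
    step = params.step_size_mm if params.step_size_mm is not None else 0.5 * float(voxel_dims.min())
    cos_stop = np.cos(np.deg2rad(params.angle_stop_deg))

    directions = np.ascontiguousarray(tensors.principal_direction)
    finite_dir = np.isfinite(directions).all(axis=-1)
    directions = np.where(finite_dir[..., None], directions, 0.0)
    # voxels a step may enter; a non-finite orientation terminates with reason "fa"
    enterable = (fa.fa >= params.fa_stop_threshold) & finite_dir & tensors.valid_mask

    seed_mask = (fa.fa > params.fa_seed_threshold) & finite_dir & tensors.valid_mask
    seed_vox = np.argwhere(seed_mask)
    if seed_vox.shape[0] == 0:
        return StreamlineSet([], np.empty((0, 3), dtype=np.int64), [], affine)

    if params.seeds_per_voxel == 1:
        seeds_world = voxel_to_world(affine, seed_vox)
        seed_owner = np.arange(seed_vox.shape[0])
    else:
        rng = np.random.default_rng(params.seed)
        reps = params.seeds_per_voxel
        jitter_vox = rng.uniform(-0.5, 0.5, size=(seed_vox.shape[0], reps, 3))
        all_vox = seed_vox[:, None, :] + jitter_vox
        seeds_world = voxel_to_world(affine, all_vox.reshape(-1, 3))
        seed_owner = np.repeat(np.arange(seed_vox.shape[0]), reps)

    init_dirs = directions[
        seed_vox[seed_owner, 0], seed_vox[seed_owner, 1], seed_vox[seed_owner, 2]
    ]

    fwd_paths, fwd_len, fwd_reason = _half_tracks(
        seeds_world, init_dirs, directions, enterable, shape, affine,
        step, cos_stop, params.max_steps,
    )
    bwd_paths, bwd_len, bwd_reason = _half_tracks(
        seeds_world, -init_dirs, directions, enterable, shape, affine,
        step, cos_stop, params.max_steps,
    )

    streamlines: list[np.ndarray] = []
    kept_idx: list[int] = []
    reasons: list[tuple[str, str]] = []
    for i in range(seeds_world.shape[0]):
        total_steps = int(fwd_len[i] + bwd_len[i])
        if total_steps < params.min_steps:
            continue
        back = bwd_paths[i, : bwd_len[i]][::-1]
        fwd = fwd_paths[i, : fwd_len[i]]
        line = np.vstack([back, seeds_world[i][None, :], fwd])
        streamlines.append(line)
        kept_idx.append(i)
        reasons.append((str(bwd_reason[i]), str(fwd_reason[i])))

    kept = np.asarray(kept_idx, dtype=np.int64)
    seed_voxels = seed_vox[seed_owner[kept]] if kept.size else np.empty((0, 3), dtype=np.int64)
    return StreamlineSet(streamlines, seed_voxels, reasons, affine)


def count_streamline_voxels(streamlines: StreamlineSet, fa: FAMap) -> tuple[np.ndarray, float]:
    """Deduplicated voxel set traversed by the streamlines, and its mean FA.

    Every traversed voxel is counted once regardless of how many streamlines
    (or points) visit it; the mean FA is unweighted over that voxel set.
    """
    if len(streamlines) == 0:
        raise ValueError("streamline set is empty")
    points = np.vstack([s for s in streamlines.streamlines])
    vox = world_to_voxel(fa.affine, points)
    vox = vox[in_bounds(vox, fa.fa.shape)]
    vox = np.unique(vox, axis=0)
    mean_fa = float(fa.fa[vox[:, 0], vox[:, 1], vox[:, 2]].mean())
    return vox, mean_fa
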