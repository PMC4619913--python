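"""Multi-ROI reconstruction of named white-matter tracts.

A tract protocol selects streamlines by waypoint logic: a streamline is
retained when it intersects *every* include ROI and *no* exclude ROI.  The
intersection test asks whether any polyline vertex falls inside the ROI's
voxel mask; with a tracking step of at most half a voxel this is an adequate
surrogate for segment-level intersection.

Anatomically meaningful ROI placements (cingulum, optic radiation, inferior
fronto-occipital and longitudinal fasciculi, arcuate, uncinate) are
configuration the user supplies for real data; for the bundled phantom
template, :func:`phantom_protocols` builds matching waypoint protocols.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectome import LabelVolume
from .grids import in_bounds, world_to_voxel
from .phantom import PhantomSpec, default_waypoint_boxes
from .tensor import FAMap
from .tracking import StreamlineSet, count_streamline_voxels

__all__ = [
    "TractProtocol", "TractStats", "select_tract", "tract_stats",
    "phantom_protocols", "load_protocols_yaml", "dump_protocols_yaml",
]


@dataclass
class TractProtocol:
    """Waypoint selection rule for one named tract in one hemisphere."""

    name: str
    hemisphere: str  # left | right
    include_rois: list[np.ndarray]  # boolean voxel masks; intersect ALL
    exclude_rois: list[np.ndarray] = field(default_factory=list)  # intersect NONE

    def __post_init__(self) -> None:
        if not self.include_rois:
            raise ValueError(f"tract {self.name!r}: needs at least one include ROI")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"tract {self.name!r}: hemisphere must be left or right")

    @classmethod
    def from_labels(cls, name: str, hemisphere: str, labels: LabelVolume,
                    include_ids, exclude_ids=()) -> "TractProtocol":
        """Build ROIs from region label ids of a parcellation volume."""
        inc = [np.isin(labels.labels, list(np.atleast_1d(ids))) for ids in include_ids]
        exc = [np.isin(labels.labels, list(np.atleast_1d(ids))) for ids in exclude_ids]
        return cls(name, hemisphere, inc, exc)


@dataclass
class TractStats:
    """Per-tract fiber count and mean FA over the traversed voxel set."""

    name: str
    hemisphere: str
    fiber_number: int
    mean_fa: float  # nan when not trackable
    trackable: bool


def _hits_mask(vox: np.ndarray, mask: np.ndarray) -> bool:
    inside = in_bounds(vox, mask.shape)
    v = vox[inside]
    return bool(mask[v[:, 0], v[:, 1], v[:, 2]].any()) if v.size else False


def select_tract(streamlines: StreamlineSet, protocol: TractProtocol) -> StreamlineSet:
    """Streamlines intersecting every include ROI and no exclude ROI."""
    keep = []
    for i, line in enumerate(streamlines.streamlines):
        vox = world_to_voxel(streamlines.affine, line)
        if all(_hits_mask(vox, m) for m in protocol.include_rois) and \
                not any(_hits_mask(vox, m) for m in protocol.exclude_rois):
            keep.append(i)
    subset = streamlines.subset(np.asarray(keep, dtype=np.int64))
    if len(subset) == 0:
        warnings.warn(
            f"tract {protocol.name!r} ({protocol.hemisphere}): no streamline satisfied "
            f"the protocol; tract not trackable in this subject"
        )
    return subset


def tract_stats(subset: StreamlineSet, fa: FAMap, name: str = "", hemisphere: str = "",
                min_fibers: int = 1) -> TractStats:
    """Fiber count and unweighted mean FA over the deduplicated voxel set."""
    n = len(subset)
    trackable = n >= min_fibers
    if trackable:
        _, mean_fa = count_streamline_voxels(subset, fa)
    else:
        mean_fa = float("nan")
    return TractStats(name=name, hemisphere=hemisphere, fiber_number=n,
                      mean_fa=mean_fa, trackable=trackable)


def load_protocols_yaml(path, grid_shape=None) -> list[TractProtocol]:
    """Read tract protocols from a YAML file.

    Expected layout::

        grid_shape: [16, 18, 14]
        tracts:
          - name: AF
            hemisphere: left
            include:
              - {x: [0, 3], y: [14, 14], z: [2, 4]}
              - {x: [0, 3], y: [16, 16], z: [2, 4]}
            exclude: []

    ROI boxes are inclusive voxel-index ranges on the diffusion grid.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    shape = tuple(grid_shape or doc.get("grid_shape") or ())
    if len(shape) != 3:
        raise ValueError(f"{path}: grid_shape missing (and none supplied)")

    def to_mask(box) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        sl = tuple(slice(box[ax][0], box[ax][1] + 1) for ax in ("x", "y", "z"))
        m[sl] = True
        return m

    protocols = []
    for entry in doc.get("tracts", []):
        protocols.append(
            TractProtocol(
                name=entry["name"],
                hemisphere=entry["hemisphere"],
                include_rois=[to_mask(b) for b in entry.get("include", [])],
                exclude_rois=[to_mask(b) for b in entry.get("exclude", [])],
            )
        )
    return protocols


def dump_protocols_yaml(path, grid_shape=None) -> None:
    """Write the default phantom protocols as an editable starting point."""
    import yaml

    from .phantom import _GRID

    shape = list(grid_shape or _GRID)
    entries = []
    for name, sides in default_waypoint_boxes().items():
        for hemisphere, boxes in sides.items():
            entries.append(
                {
                    "name": name,
                    "hemisphere": hemisphere,
                    "include": [
                        {"x": list(x), "y": list(y), "z": list(z)} for (x, y, z) in boxes
                    ],
                    "exclude": [],
                }
            )
    with open(path, "w") as fh:
        yaml.safe_dump({"grid_shape": shape, "tracts": entries}, fh, sort_keys=False)


def phantom_protocols(spec: PhantomSpec | None = None) -> list[TractProtocol]:
    """Waypoint protocols matching the default phantom template's bundles."""
    from .phantom import _GRID  # template grid

    shape = _GRID if spec is None else tuple(spec.grid_shape)
    protocols = []
    for name, sides in default_waypoint_boxes().items():
        for hemisphere, boxes in sides.items():
            rois = []
            for (x, y, z) in boxes:
                m = np.zeros(shape, dtype=bool)
                m[x[0]: x[1] + 1, y[0]: y[1] + 1, z[0]: z[1] + 1] = True
                rois.append(m)
            protocols.append(TractProtocol(name, hemisphere, rois))
    return protocols
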