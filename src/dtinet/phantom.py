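"""Synthetic labeled diffusion phantoms and multi-subject cohorts.

A phantom is a voxel grid holding isotropic background plus cylindrical fiber
bundles (tubes around polyline centerlines) whose in-tube tensors point along
the local centerline tangent.  Region masks play the role of a parcellation:
labels come in homotopic pairs (odd = left, even = right).  Diffusion-weighted
signals follow the Stejskal-Tanner model S = S0 exp(-b g^T D g), optionally
with Rician noise (|S + complex Gaussian|, the magnitude-MRI convention).

Cohorts are i.i.d. subject draws from a template: per-subject lognormal jitter
on bundle radius and diffusivities plus a small lateral centerline offset give
the within-group variance that the downstream sign tests require, and
configurable left/right effects (radius, axial diffusivity, presence
probability) plant known hemispheric asymmetries whose recovery the analysis
stages are tested against.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .connectome import LabelVolume
from .gradients import GradientTable, default_gradient_table
from .grids import default_affine, voxel_centers, world_to_voxel
from .tensor import DWIVolume, TensorField, fa_from_eigenvalues

__all__ = [
    "BundleSpec",
    "PhantomSpec",
    "BundleAsymmetry",
    "CohortSpec",
    "Subject",
    "GroundTruth",
    "build_phantom",
    "simulate_dwi",
    "generate_cohort",
    "default_phantom_template",
    "default_cohort_spec",
    "default_waypoint_boxes",
]

logger = logging.getLogger(__name__)

TRACKING_FA_THRESHOLD = 0.2


@dataclass(frozen=True)
class BundleSpec:
    """A cylindrical fiber bundle: tube of given radius around a centerline.

    ``axial_diffusivity`` > ``radial_diffusivity`` > 0 (mm^2/s); the implied FA
    of diag(ax, rad, rad) should exceed the tracking threshold for a bundle
    meant to be trackable.  ``presence`` is the per-subject probability that
    the bundle exists at all (1.0 = always), modelling tracts that are not
    reconstructible in every individual.
    """

    name: str
    centerline: np.ndarray  # (k, 3) world mm, k >= 2
    radius_mm: float
    endpoint_regions: tuple[int, int]
    hemisphere: str  # left | right | commissural
    axial_diffusivity: float = 1.7e-3
    radial_diffusivity: float = 0.3e-3
    presence: float = 1.0

    def __post_init__(self) -> None:
        cl = np.asarray(self.centerline, dtype=float)
        if cl.ndim != 2 or cl.shape[0] < 2 or cl.shape[1] != 3:
            raise ValueError(f"bundle {self.name!r}: centerline must be (k>=2, 3)")
        if np.any(np.linalg.norm(np.diff(cl, axis=0), axis=1) == 0):
            raise ValueError(f"bundle {self.name!r}: centerline has duplicate consecutive points")
        object.__setattr__(self, "centerline", cl)
        if self.radius_mm <= 0:
            raise ValueError(f"bundle {self.name!r}: radius must be positive")
        if not (self.axial_diffusivity > self.radial_diffusivity > 0):
            raise ValueError(
                f"bundle {self.name!r}: need axial > radial > 0 diffusivity"
            )
        if self.hemisphere not in ("left", "right", "commissural"):
            raise ValueError(f"bundle {self.name!r}: bad hemisphere {self.hemisphere!r}")
        if not (0.0 <= self.presence <= 1.0):
            raise ValueError(f"bundle {self.name!r}: presence must lie in [0, 1]")

    @property
    def implied_fa(self) -> float:
        ev = np.array([self.axial_diffusivity, self.radial_diffusivity, self.radial_diffusivity])
        return float(fa_from_eigenvalues(ev))

    @property
    def pair_name(self) -> str:
        """Bundle-pair key: the name with a trailing _left/_right stripped."""
        for suffix in ("_left", "_right"):
            if self.name.endswith(suffix):
                return self.name[: -len(suffix)]
        return self.name


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description: grid, parcellation masks, and bundles."""

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    regions: dict[int, np.ndarray]  # label -> boolean mask
    bundles: tuple[BundleSpec, ...]
    background_diffusivity: float = 0.7e-3
    seed: int = 0
    region_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bundles", tuple(self.bundles))
        labels = sorted(self.regions)
        if any(l <= 0 for l in labels):
            raise ValueError("region labels must be positive")
        if len(labels) % 2 != 0 or labels != list(range(1, len(labels) + 1)):
            raise ValueError(
                "region labels must be exactly 1..2R (homotopic pairs (2k-1, 2k))"
            )
        occupancy = np.zeros(self.grid_shape, dtype=np.int64)
        for lab in labels:
            mask = np.asarray(self.regions[lab], dtype=bool)
            if mask.shape != tuple(self.grid_shape):
                raise ValueError(f"region {lab} mask shape mismatch")
            occupancy += mask
        if occupancy.max() > 1:
            raise ValueError("region masks overlap")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.voxel_size)

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def _segment_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Distance of each point to segment a-b, plus the unit segment tangent."""
    ab = b - a
    length2 = float(ab @ ab)
    t = np.clip(((points - a) @ ab) / length2, 0.0, 1.0)
    closest = a + t[:, None] * ab
    dist = np.linalg.norm(points - closest, axis=1)
    return dist, ab / np.sqrt(length2)


def build_phantom(spec: PhantomSpec, bundles: tuple[BundleSpec, ...] | None = None
                  ) -> tuple[LabelVolume, TensorField]:
    """Rasterize a phantom spec into a label volume and a tensor field.

    A voxel belongs to a bundle when its centre lies within the bundle radius
    of the centerline (point-to-segment distance); its tensor's principal axis
    is the tangent of the nearest centerline segment.  Overlaps resolve
    first-wins with a logged warning.  Deterministic: no randomness is used.
    """
    if bundles is None:
        bundles = spec.bundles
    affine = spec.affine
    shape = tuple(spec.grid_shape)
    centers = voxel_centers(shape, affine).reshape(-1, 3)
    n_vox = centers.shape[0]

    labels = np.zeros(shape, dtype=np.int32)
    for lab, mask in spec.regions.items():
        labels[np.asarray(mask, dtype=bool)] = lab

    d_bg = spec.background_diffusivity
    tensors = np.tile(d_bg * np.eye(3), (n_vox, 1, 1))
    owner = np.full(n_vox, -1, dtype=np.int64)

    for bi, bundle in enumerate(bundles):
        cl = bundle.centerline
        best_dist = np.full(n_vox, np.inf)
        best_tan = np.zeros((n_vox, 3))
        for s in range(cl.shape[0] - 1):
            dist, tan = _segment_distances(centers, cl[s], cl[s + 1])
            closer = dist < best_dist
            best_dist[closer] = dist[closer]
            best_tan[closer] = tan
        inside = best_dist <= bundle.radius_mm
        clash = inside & (owner >= 0)
        if clash.any():
            logger.warning(
                "bundle %r overlaps an earlier bundle in %d voxels (first wins)",
                bundle.name, int(clash.sum()),
            )
            inside &= owner < 0
        if not inside.any():
            warnings.warn(
                f"bundle {bundle.name!r} rasterizes to zero voxels "
                f"(radius {bundle.radius_mm} mm too small for this grid)"
            )
        owner[inside] = bi
        t = best_tan[inside]
        ax, rad = bundle.axial_diffusivity, bundle.radial_diffusivity
        tensors[inside] = rad * np.eye(3) + (ax - rad) * np.einsum("ni,nj->nij", t, t)

        for end_point, region in zip((cl[0], cl[-1]), bundle.endpoint_regions):
            vox = world_to_voxel(affine, end_point[None, :])[0]
            if not ((0 <= vox) & (vox < np.array(shape))).all() or \
                    labels[tuple(vox)] != region:
                raise ValueError(
                    f"bundle {bundle.name!r}: endpoint {end_point} does not lie "
                    f"inside its declared region {region}"
                )

    field_ = TensorField.from_tensors(tensors.reshape(*shape, 3, 3), affine)
    return LabelVolume(labels=labels, affine=affine), field_


def simulate_dwi(tensors: TensorField, gtab: GradientTable, s0: float = 1000.0,
                 noise_sigma: float = 0.0, seed: int | np.random.Generator = 0) -> DWIVolume:
    """Forward Stejskal-Tanner simulation, optionally with Rician noise.

    ``noise_sigma`` is expressed relative to S0; noise is added as the
    magnitude of (signal + complex Gaussian), so signals stay positive.
    """
    if s0 <= 0:
        raise ValueError("S0 must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    min_eval = tensors.evals[..., 2]
    bad = min_eval < -1e-12
    if bad.any():
        vox = tuple(int(c) for c in np.argwhere(bad)[0])
        raise ValueError(f"tensor at voxel {vox} is not positive semidefinite")

    shape = tensors.shape
    d6 = np.stack(
        [
            tensors.tensors[..., 0, 0], tensors.tensors[..., 1, 1],
            tensors.tensors[..., 2, 2], tensors.tensors[..., 0, 1],
            tensors.tensors[..., 0, 2], tensors.tensors[..., 1, 2],
        ],
        axis=-1,
    ).reshape(-1, 6)
    b = gtab.bvals
    gx, gy, gz = gtab.bvecs.T
    quad = np.stack([gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz])
    signal = s0 * np.exp(-(d6 @ quad) * b[None, :])

    if noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        sigma = noise_sigma * s0
        real = signal + rng.normal(0.0, sigma, signal.shape)
        imag = rng.normal(0.0, sigma, signal.shape)
        signal = np.hypot(real, imag)

    return DWIVolume(signal.reshape(*shape, len(gtab)), tensors.affine, gtab)


@dataclass(frozen=True)
class BundleAsymmetry:
    """Left/right manipulation of one bundle pair; 1.0 everywhere = none.

    ``radius`` and ``axial_diffusivity`` multiply the *left* bundle's
    parameter; ``presence_left``/``presence_right`` multiply the respective
    presence probabilities (clipped to [0, 1]).
    """

    radius: float = 1.0
    axial_diffusivity: float = 1.0
    presence_left: float = 1.0
    presence_right: float = 1.0

    @property
    def is_null(self) -> bool:
        return all(
            x == 1.0
            for x in (self.radius, self.axial_diffusivity,
                      self.presence_left, self.presence_right)
        )

    @property
    def direction(self) -> str:
        """Sign of the designed asymmetry: 'leftward' or 'rightward'."""
        score = (
            np.log(self.radius) + np.log(self.axial_diffusivity)
            + np.log(max(self.presence_left, 1e-12))
            - np.log(max(self.presence_right, 1e-12))
        )
        return "leftward" if score > 0 else "rightward"


@dataclass(frozen=True)
class CohortSpec:
    """Multi-subject cohort: template phantom + effects + variability model."""

    n_subjects: int
    phantom_template: PhantomSpec
    asymmetry_effects: dict[str, BundleAsymmetry] = field(default_factory=dict)
    gtab: GradientTable = field(default_factory=default_gradient_table)
    s0: float = 1000.0
    noise_sigma: float = 0.02
    radius_jitter_cv: float = 0.05
    diffusivity_jitter_cv: float = 0.03
    offset_jitter_mm: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        pair_names = {b.pair_name for b in self.phantom_template.bundles}
        unknown = set(self.asymmetry_effects) - pair_names
        if unknown:
            raise ValueError(f"asymmetry effects name unknown bundle pairs: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """What was planted: per bundle pair and per affected homotopic region pair.

    A manipulated bundle pair lateralizes *both* of its endpoint region pairs
    (every asymmetric edge has two ends), so both appear here with the
    designed sign.
    """

    bundle_pairs: dict[str, str]  # pair_name -> leftward|rightward
    region_pairs: dict[tuple[int, int], str]  # (left_label, right_label) -> direction


@dataclass
class Subject:
    subject_id: str
    labels: LabelVolume
    dwi: DWIVolume
    gtab: GradientTable
    tensors_true: TensorField


def _jittered_bundles(template: PhantomSpec, effects, rng,
                      radius_cv, diff_cv, offset_mm) -> list[BundleSpec]:
    out = []
    for bundle in template.bundles:
        eff = effects.get(bundle.pair_name, BundleAsymmetry())
        radius = bundle.radius_mm
        axial = bundle.axial_diffusivity
        presence = bundle.presence
        if bundle.hemisphere == "left":
            radius *= eff.radius
            axial *= eff.axial_diffusivity
            presence = min(1.0, presence * eff.presence_left)
        elif bundle.hemisphere == "right":
            presence = min(1.0, presence * eff.presence_right)

        # subject-level biological variability (independent per bundle,
        # including between homotopic twins, so LI has within-group variance)
        radius *= rng.lognormal(0.0, radius_cv) if radius_cv > 0 else 1.0
        diff_scale = rng.lognormal(0.0, diff_cv) if diff_cv > 0 else 1.0
        axial *= diff_scale
        radial = bundle.radial_diffusivity * diff_scale
        offset = np.zeros(3)
        if offset_mm > 0:
            offset[[0, 2]] = rng.normal(0.0, offset_mm, size=2)  # lateral only
        present = rng.random() < presence
        if not present:
            continue
        new = replace(
            bundle,
            centerline=bundle.centerline + offset,
            radius_mm=radius,
            axial_diffusivity=axial,
            radial_diffusivity=radial,
        )
        if new.implied_fa <= TRACKING_FA_THRESHOLD:
            warnings.warn(
                f"bundle {bundle.name!r}: jittered FA {new.implied_fa:.3f} is at or "
                f"below the tracking threshold {TRACKING_FA_THRESHOLD}"
            )
        out.append(new)
    return out


def ground_truth_of(spec: CohortSpec) -> GroundTruth:
    """Designed asymmetries implied by a cohort spec."""
    bundle_pairs: dict[str, str] = {}
    region_pairs: dict[tuple[int, int], str] = {}
    by_pair: dict[str, list[BundleSpec]] = {}
    for b in spec.phantom_template.bundles:
        by_pair.setdefault(b.pair_name, []).append(b)
    for name, eff in spec.asymmetry_effects.items():
        if eff.is_null:
            continue
        direction = eff.direction
        bundle_pairs[name] = direction
        for b in by_pair[name]:
            if b.hemisphere != "left":
                continue
            for region in b.endpoint_regions:
                pair = (region, region + 1) if region % 2 == 1 else (region - 1, region)
                region_pairs[pair] = direction
    return GroundTruth(bundle_pairs=bundle_pairs, region_pairs=region_pairs)


def generate_cohort(spec: CohortSpec):
    """Yield per-subject phantoms with simulated DWI; deterministic per seed.

    Per-subject RNG streams are spawned from the cohort seed, so subject k is
    identical across runs and independent of n_subjects >= k.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_subjects)
    for k in range(spec.n_subjects):
        rng = np.random.default_rng(children[k])
        bundles = _jittered_bundles(
            spec.phantom_template, spec.asymmetry_effects, rng,
            spec.radius_jitter_cv, spec.diffusivity_jitter_cv, spec.offset_jitter_mm,
        )
        labels, tensors = build_phantom(spec.phantom_template, tuple(bundles))
        dwi = simulate_dwi(tensors, spec.gtab, spec.s0, spec.noise_sigma, seed=rng)
        yield Subject(
            subject_id=f"sub-{k + 1:03d}",
            labels=labels,
            dwi=dwi,
            gtab=spec.gtab,
            tensors_true=tensors,
        )


# ---------------------------------------------------------------------------
# Default template: a six-pair (12-region) desk-scale cohort phantom.
#
# Three bundle systems per hemisphere on a 16 x 18 x 14 grid of 2 mm voxels
# (left hemisphere x < midline, mirror-symmetric construction):
#
# * "arcuate"  — bent tube (~35 degree dog-leg) between an inferior-frontal
#   (labels 1/2) and a temporal (3/4) region.  The bend makes completion of
#   FACT tracking caliber-dependent: a thin tube loses its streamlines to
#   corner-cutting at the bend, a thick one completes — the classic
#   hard-to-track arcuate phenomenology.
# * "cingulum" — straight, thick, reliable control between labels 5/6 and 7/8.
# * "uncinate" — straight tube between 9/10 and 11/12 with presence 0.7,
#   giving the null cohorts nonzero laterality variance.
# ---------------------------------------------------------------------------

_GRID = (16, 18, 14)
_VOX = (2.0, 2.0, 2.0)


def _box(shape, x, y, z) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[x[0]: x[1] + 1, y[0]: y[1] + 1, z[0]: z[1] + 1] = True
    return mask


def _mirror_x(mask: np.ndarray) -> np.ndarray:
    return mask[::-1].copy()


def default_phantom_template(arcuate_radius_mm: float = 1.1,
                             uncinate_presence: float = 0.7) -> PhantomSpec:
    """The mirror-symmetric cohort template described in the module docs."""
    shape = _GRID
    nx = shape[0]
    x_mirror = 2.0 * (nx - 1)  # world-mm mirror plane constant: x' = 2(nx-1) - x

    region_names = {
        1: "IFGtriang.L", 2: "IFGtriang.R", 3: "MTG.L", 4: "MTG.R",
        5: "ACG.L", 6: "ACG.R", 7: "PCG.L", 8: "PCG.R",
        9: "ORBinf.L", 10: "ORBinf.R", 11: "TPOsup.L", 12: "TPOsup.R",
    }
    # far boxes span y 15..17 so that end-cap terminal voxels stay labeled
    left_boxes = {
        1: _box(shape, (3, 5), (1, 2), (2, 4)),
        3: _box(shape, (0, 3), (15, 17), (2, 4)),
        5: _box(shape, (3, 5), (1, 2), (6, 8)),
        7: _box(shape, (3, 5), (15, 17), (6, 8)),
        9: _box(shape, (3, 5), (1, 2), (10, 12)),
        11: _box(shape, (3, 5), (15, 17), (10, 12)),
    }
    regions = {}
    for lab, mask in left_boxes.items():
        regions[lab] = mask
        regions[lab + 1] = _mirror_x(mask)

    def mirrored(points):
        pts = np.asarray(points, dtype=float)
        out = pts.copy()
        out[:, 0] = x_mirror - pts[:, 0]
        return out

    # dog-leg: straight frontal limb, ~34 degree diagonal joint, straight
    # temporal limb; FACT corner-cutting at the joint is caliber-sensitive
    arc_left = np.array(
        [[8.0, 4.0, 6.0], [8.0, 22.0, 6.0], [4.0, 28.0, 6.0], [4.0, 32.0, 6.0]]
    )
    cing_left = np.array([[8.0, 4.0, 14.0], [8.0, 32.0, 14.0]])
    unc_left = np.array([[8.0, 4.0, 22.0], [8.0, 32.0, 22.0]])

    bundles = (
        BundleSpec("arcuate_left", arc_left, arcuate_radius_mm, (1, 3), "left"),
        BundleSpec("arcuate_right", mirrored(arc_left), arcuate_radius_mm, (2, 4), "right"),
        BundleSpec("cingulum_left", cing_left, 2.5, (5, 7), "left"),
        BundleSpec("cingulum_right", mirrored(cing_left), 2.5, (6, 8), "right"),
        BundleSpec("uncinate_left", unc_left, 1.3, (9, 11), "left",
                   presence=uncinate_presence),
        BundleSpec("uncinate_right", mirrored(unc_left), 1.3, (10, 12), "right",
                   presence=uncinate_presence),
    )
    return PhantomSpec(
        grid_shape=shape, voxel_size=_VOX, regions=regions, bundles=bundles,
        region_names=region_names,
    )


def default_waypoint_boxes() -> dict[str, dict[str, list[tuple]]]:
    """Waypoint ROI boxes (voxel-index (lo, hi) triples) for the default tracts.

    For the arcuate, both waypoints sit on the post-bend limb, so a subject
    whose tracking fails at the bend still yields a (short) reconstructable
    tract on the far side.
    """
    def mirror(box):
        (x0, x1), y, z = box
        return ((_GRID[0] - 1 - x1, _GRID[0] - 1 - x0), y, z)

    left = {
        "arcuate": [((0, 3), (14, 14), (2, 4)), ((0, 3), (16, 16), (2, 4))],
        "cingulum": [((3, 5), (5, 6), (6, 8)), ((3, 5), (11, 12), (6, 8))],
        "uncinate": [((3, 5), (5, 6), (10, 12)), ((3, 5), (11, 12), (10, 12))],
    }
    out: dict[str, dict[str, list[tuple]]] = {}
    for name, boxes in left.items():
        out[name] = {"left": boxes, "right": [mirror(b) for b in boxes]}
    return out


def default_cohort_spec(n_subjects: int, seed: int = 0,
                        arcuate_radius_effect: float = 1.0,
                        **overrides) -> CohortSpec:
    """Cohort spec over the default template.

    ``arcuate_radius_effect`` > 1 thickens the left arcuate (the designed
    leftward asymmetry); 1.0 gives a null cohort.
    """
    effects = {}
    if arcuate_radius_effect != 1.0:
        effects["arcuate"] = BundleAsymmetry(radius=arcuate_radius_effect)
    return CohortSpec(
        n_subjects=n_subjects,
        phantom_template=default_phantom_template(),
        asymmetry_effects=effects,
        seed=seed,
        **overrides,
    )
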