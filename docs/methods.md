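# Methods

`dtinet` implements a complete desk-scale pipeline for studying hemispheric
asymmetry of binary anatomical brain networks built from diffusion tensor
tractography, together with a synthetic-phantom generator that makes every
stage testable against known ground truth.

## Signal model and tensor estimation

Diffusion-weighted signals follow the Stejskal–Tanner equation
`S = S0 · exp(−b gᵀ D g)` for b-value `b` (s/mm²), unit gradient direction
`g`, and symmetric diffusion tensor `D` (mm²/s). The default encoding is one
b = 0 volume plus 12 directions at b = 1000 s/mm² placed at icosahedron
vertices (six antipodal pairs), a standard well-conditioned low-count scheme.

Fitting is ordinary log-linear least squares on
`ln S = ln S0 − b gᵀ D g`, solved per voxel with a single precomputed
pseudoinverse and followed by eigendecomposition with eigenvalues sorted
λ1 ≥ λ2 ≥ λ3. Weighted and robust (outlier-rejecting) variants were
deliberately left out: the log-linear fit is deterministic, fast, and the
standard choice for 12-direction data. Voxels with any nonpositive signal, or
with b0 signal below a configurable fraction (default 5%) of the robust
(98th-percentile) b0 maximum — a phantom analogue of a brain mask — are
marked invalid rather than raising.

Fractional anisotropy is

    FA = sqrt( ((λ1−λ2)² + (λ1−λ3)² + (λ2−λ3)²) / (2(λ1²+λ2²+λ3²)) ).

Numerical conventions: FA of the zero tensor is 0; since FA is
scale-invariant, "zero" needs a floor, and eigenvalue triples whose largest
value is below 1e-10 mm²/s (seven orders below water diffusivity) are treated
as zero rather than amplifying round-off noise. Negative eigenvalues from
noisy fits are clamped to 0 for FA only; the raw values stay in the tensor
field for diagnostics.

## FACT tractography

Deterministic fiber assignment by continuous tracking: every voxel with
FA > 0.2 seeds one bidirectional streamline; propagation follows the
principal eigenvector of the current voxel (nearest-neighbour orientation
lookup), sign-aligned with the incoming direction at each step. A track
stops when the turning angle would exceed 50°, the next voxel's FA is below
0.2, the point leaves the volume, or the step budget (default 300) runs out.
Streamlines shorter than 3 steps are discarded as seed debris.

Discretization choices, all of which matter for reproducibility:

* step size defaults to half the smallest voxel dimension — an approximation
  of voxel-face FACT transit that keeps consecutive samples inside the voxels
  whose orientations they use;
* voxel lookup rounds half-down on 0-based indices;
* the first move of each half-track is a half step, so with the default step
  no point ever lies exactly on a voxel boundary; this keeps tracking
  mirror-equivariant (a mirrored tensor field yields mirrored streamlines),
  which the laterality analysis relies on;
* the angle test compares the incoming direction with the sign-aligned
  candidate eigenvector at every step, not per voxel transition.

## Network construction and nodal metrics

Streamline terminal points are mapped to an integer parcellation (labels in
homotopic pairs (2k−1, 2k), odd = left). A streamline contributes to the
unordered region pair (u, v) only if both terminals carry nonzero, distinct
labels; no endpoint dilation is applied (an optional 1-voxel dilation exists
but defaults off). Two regions are joined by an edge when at least 3 such
fibers connect them; the fiber count is used only for edge existence, and
the analysed network is binary, symmetric, zero-diagonal. The node count is
taken from the label volume, so small phantoms are first-class; a
full 90-region volume yields the conventional 90×90 matrix. A diagnostic
sweep reports the cohort-mean largest-connected-component size as a function
of the threshold, the criterion by which the threshold of 3 is justified
(the mean component should keep every node).

Nodal metrics on the binary graph with N nodes:

* degree `K_i` (row sum) and network mean `K_p`;
* mean shortest path `L_i` = average BFS hop count to the other nodes, and
  characteristic path length `L_p`; unreachable peers are excluded from the
  average (with the divisor reduced accordingly), and a fully isolated node
  gets `L_i = ∞`, i.e. zero nodal efficiency `1/L_i`. Assigning N or ∞ to
  unreachable pairs was rejected because it distorts laterality ratios; the
  component diagnostic is always reported alongside;
* betweenness `B_i` = Σ over ordered pairs (s,t), s ≠ t ≠ i, of
  σ_st(i)/σ_st with fractional counting over multiple shortest paths,
  computed by Brandes' dependency accumulation; the normalization
  `b_i = B_i/((N−1)(N−2))` maps a star centre to exactly 1. The ordered-pair
  convention is what makes that normalization land in [0, 1].
* hubs: nodes with `b_i` above mean + 1 SD. The literature states no
  universal cutoff; the rule is a configurable default.

## Tract reconstruction

Named tracts are reconstructed by waypoint logic: keep streamlines that
intersect every include ROI and no exclude ROI, with intersection tested at
polyline vertices (adequate because the step is at most half a voxel).
Per tract: fiber number, trackability (≥ 1 fiber by default), and mean FA
taken as the unweighted mean over the deduplicated set of traversed voxels —
each voxel counts once however many streamlines visit it. ROI placements
for real anatomy (cingulum, optic radiation, inferior fronto-occipital and
longitudinal fasciculi, arcuate, uncinate) are user-supplied configuration;
`dtinet tracts --dump-protocols` writes an editable YAML seeded with the
phantom-compatible protocols.

## Laterality statistics

For each homotopic pair and each nodal property, the per-subject laterality
index is `LI = (L − R)/(L + R)`. The path-length property enters as its
reciprocal `1/L_i`, so a positive LI uniformly means better topology on the
left (larger degree and betweenness, shorter paths); computing LI on raw
`L_i` and flipping the sign is the equivalent that was rejected for clarity.
`LI = 0` with L = R = 0 is a degenerate tie.

Group nullity is tested with the exact one-tailed sign test: ties are
dropped; with n nonzero LIs of which k match the tested direction,
`p = P(X ≥ k)`, X ~ Binomial(n, ½). Because no per-region direction is known
a priori, both tails are tested and the smaller is reported with its
direction; the two tails are mutually exclusive at small α, so the Bonferroni
family is the number of homotopic pairs per property (45 for 90 regions,
α = 0.05), applied per property family rather than pooled.

Tract asymmetries in mean FA and fiber number use two-sided paired t-tests
over subjects in whom both hemispheres are trackable, significant at
p < 0.05 uncorrected. All-zero differences give p = 1; nonzero constant
differences (zero variance) are flagged degenerate rather than assigned an
unbounded t.

## The synthetic cohort generator

No imaging data ship with the package; the generator is first-class code that
emulates the study conditions at desk scale. A phantom is a voxel grid
(2 mm isotropic, RAS+) of isotropic background (0.7e-3 mm²/s) plus
cylindrical bundles: tubes of given radius around polyline centerlines, with
in-tube tensors diag(λ∥, λ⊥, λ⊥) = (1.7, 0.3, 0.3)e-3 mm²/s (FA ≈ 0.80)
oriented along the nearest centerline segment. A voxel is in-tube when its
centre is within the radius of the polyline (point-to-segment distance, so
tube ends carry hemispherical caps); overlaps resolve first-wins with a
warning. Rician noise is added as |signal + complex Gaussian| at scale
noise_sigma · S0 (default 0.02, i.e. SNR 50 — coarse voxels at 3 T).

The default cohort template has 12 regions (6 homotopic pairs) and three
mirror-symmetric bundle systems per hemisphere on a 16×18×14 grid:

* **arcuate** (labels 1/2 → 3/4): a dog-leg tube with a ~34° diagonal joint,
  baseline radius 1.1 mm. FACT's nearest-neighbour lookup corner-cuts the
  joint by up to a voxel, so a thin tube sheds its streamlines mid-track
  (terminals in background → no edge) while a 2×-radius tube contains the
  offset path and completes. Bundle caliber therefore causally controls both
  the binary edge and the tract fiber count — the phenomenology of the
  hard-to-track right arcuate fasciculus.
* **cingulum** (5/6 → 7/8): straight, 2.5 mm, reliably tracked control.
* **uncinate** (9/10 → 11/12): straight, 1.3 mm, present in any given
  subject with probability 0.7 per side, so null cohorts have nonzero
  laterality variance (a sign test is degenerate without it).

Subject-level variability: independent lognormal jitter on bundle radius
(CV 0.05) and diffusivities (CV 0.03, applied jointly to λ∥ and λ⊥ so FA is
stable), plus a lateral centerline offset ~ N(0, 0.15 mm) per bundle. The
underlying study used real subjects and reports no within-cohort variability
model, so these magnitudes are the package's own choice of what plausible
biological plus positioning variability looks like at this grid scale; they
were fixed at design time. Per-subject RNG streams are spawned from the
cohort seed, so subject k is reproducible and independent of cohort size.

Designed asymmetries are multiplicative effects per bundle pair on the left
radius, left axial diffusivity, or per-side presence probability; 1.0 means
none. A manipulated bundle pair lateralizes **both** of its endpoint region
pairs — every asymmetric edge has two ends, and the sign test is
magnitude-blind, so this is a structural fact about binary-network laterality,
not an implementation artifact. Ground truth therefore marks both pairs with
the designed sign, and parameter-recovery tests assert that the flagged set
equals exactly that ground-truth set.

What the phantoms do *not* emulate: real cortical geometry, crossing fibers
or multi-compartment signals, acquisition artifacts (EPI distortion, eddy
currents, motion), or partial-volume gradients at tube boundaries. Passing
tests therefore demonstrate correctness of the algorithms and the
recoverability of planted effects under idealized single-fiber conditions,
not performance on real DWI.

## Problem sizes and determinism

The bundled analyses run on the 12-region template with 20-subject cohorts
(end-to-end effect recovery, with 100 replicate null cohorts for the
family-wise error-rate check) and a 200-subject cohort for the null-mean
LI property — sizes chosen so the whole suite exercises every stage on a
single CPU in a few minutes. All randomness flows from explicit integer
seeds; identical configuration and seed reproduce byte-identical reports.

## Known limitations

* FACT here uses fixed-step nearest-neighbour propagation, an approximation
  of exact voxel-face transit; corner-cutting at bends is characteristic of
  this family of algorithms and is exploited by the phantom design, but the
  quantitative completion rates are discretization-dependent.
* The log-linear fit is unweighted; at low SNR its FA estimates are biased
  upward, which matters near the 0.2 seeding threshold.
* Sign tests ignore LI magnitude; strongly and weakly lateralized pairs with
  the same sign pattern are indistinguishable.
* The hub rule (mean + 1 SD of b_i) is a convention, not an inference.
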