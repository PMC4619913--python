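# dtinet

Hemispheric asymmetry of anatomical brain networks from diffusion tensor
tractography — a tested, reusable pipeline from diffusion-weighted volumes to
laterality statistics, exercised end-to-end on synthetic diffusion phantoms
with designed asymmetries.

## What it does

The brain's left and right hemispheres differ not only in the size of
individual regions but in how regions are *wired*. This package quantifies
that wiring asymmetry the way structural-connectome studies do:

1. **Tensor estimation** — per-voxel diffusion tensors by log-linear least
   squares on the Stejskal–Tanner model `S = S0·exp(−b gᵀDg)`, and the
   fractional anisotropy map
   `FA = sqrt(((λ1−λ2)² + (λ1−λ3)² + (λ2−λ3)²) / (2(λ1²+λ2²+λ3²)))`.
2. **Deterministic FACT tractography** — seed every voxel with FA > 0.2,
   follow the principal eigenvector, stop on turns > 50° or FA < 0.2.
3. **Binary connectome** — regions u, v (homotopic label pairs, odd = left)
   are connected when ≥ 3 streamlines terminate in both; a 90-region
   parcellation gives the conventional symmetric 90×90 matrix.
4. **Nodal graph metrics** — degree `K_i`, mean shortest path `L_i`
   (characteristic path length `L_p`), and normalized betweenness
   `b_i = B_i/((N−1)(N−2))` with ordered-pair fractional counting.
5. **Tract reconstruction** — multi-ROI waypoint selection of named tracts
   with per-tract fiber number and mean FA over the traversed voxel set.
6. **Laterality statistics** — per-pair `LI = (L−R)/(L+R)` on `K_i`,
   `1/L_i`, `b_i`; exact one-tailed sign tests with Bonferroni correction
   over the homotopic pairs (45 for 90 regions); paired t-tests on tract FA
   and fiber number.

Because no imaging data ship with the package, a first-class synthetic-data
module generates labeled diffusion phantoms and multi-subject cohorts with
known ground-truth connectivity, configurable hemispheric effects (bundle
radius, diffusivity, presence probability), subject-level jitter, and Rician
noise — so every downstream stage is testable without any download. See
`docs/methods.md` for the models and all numerical conventions.

## Worked example

Simulate a 20-subject cohort in which the left arcuate bundle has twice the
right's radius, run the full pipeline, and test for asymmetry:

```python
from dtinet.phantom import default_cohort_spec
from dtinet.pipeline import analyze_cohort
from dtinet.tracts import phantom_protocols

spec = default_cohort_spec(n_subjects=20, seed=7, arcuate_radius_effect=2.0)
ana = analyze_cohort(spec, protocols=phantom_protocols())

lat = ana.report.laterality
print(lat[lat.significant])
print(ana.report.tracts)
```

Output (abridged):

```
 left_label  right_label   property  median_li  n_nonzero        p direction
          1            2     degree        1.0         19 0.000002  leftward
          3            4     degree        1.0         19 0.000002  leftward
          1            2 efficiency        1.0         19 0.000002  leftward
          3            4 efficiency        1.0         19 0.000002  leftward

   tract  n         t            p  mean_difference  significant
 arcuate 20 14.701252 7.836749e-12            23.75         True
cingulum 20 -0.871006 3.946234e-01            -1.50        False
uncinate 11  0.000000 1.000000e+00             0.00        False
```

Reading this: the thickened left arcuate connects its frontal (labels 1/2)
and temporal (3/4) endpoint pairs only on the left, so in 19 of 20 subjects
the degree laterality index is +1 for exactly those two pairs; the sign test
gives p = 0.5¹⁹ ≈ 2e-6, far below the Bonferroni cutoff 0.05/6, and both
pairs are flagged leftward — precisely the planted ground truth
(`ana.ground_truth.region_pairs`). At the tract level the left arcuate
carries on average 23.75 more streamlines than the right (paired
t(19) = 14.7, p ≈ 8e-12), while the symmetric control (cingulum) and the
variably-present uncinate show no significant asymmetry.

The same chain is available from the shell:

```sh
dtinet simulate-cohort --out cohort/ --seed 7 --subjects 20 --arcuate-radius-effect 2.0
dtinet run-all --cohort cohort/ --out results/ --seed 7
```

which writes per-subject fiber-count/adjacency matrices, nodal metric tables,
TRK streamlines, and the group laterality and tract reports as TSV, plus a
checksummed manifest. Staged subcommands (`fit-tensor`, `track`,
`connectome`, `metrics`, `tracts`, `asymmetry`) expose each intermediate.

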