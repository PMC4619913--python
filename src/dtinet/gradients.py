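"""Diffusion gradient tables (b-values and unit directions).

The same table drives both forward signal simulation and tensor fitting, so
the Stejskal-Tanner model is exercised with a single encoding definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GradientTable", "icosahedral_directions", "default_gradient_table"]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class GradientTable:
    """Diffusion encoding: b-values (s/mm^2) and unit gradient directions.

    b=0 rows carry a zero direction vector.  At least six non-collinear
    diffusion-weighted directions are required for a tensor fit.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) lengths differ"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be nonnegative")
        norms = np.linalg.norm(bvecs, axis=1)
        dwi = bvals > 0
        if np.any(np.abs(norms[dwi] - 1.0) > _UNIT_TOL):
            bad = int(np.argmax(np.abs(norms[dwi] - 1.0) > _UNIT_TOL))
            raise ValueError(
                f"non-b0 gradient directions must be unit vectors (row {bad})"
            )
        if np.any(norms[~dwi] > _UNIT_TOL):
            raise ValueError("b=0 rows must carry a zero direction vector")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0

    def design_matrix(self) -> np.ndarray:
        """Log-linear design for ln S = ln S0 - b g^T D g.

        Columns: [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz],
        matching the unknown vector [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz].
        """
        b = self.bvals
        gx, gy, gz = self.bvecs.T
        return np.column_stack(
            [
                np.ones_like(b),
                -b * gx * gx,
                -b * gy * gy,
                -b * gz * gz,
                -2 * b * gx * gy,
                -2 * b * gx * gz,
                -2 * b * gy * gz,
            ]
        )

    def validate_for_fit(self) -> None:
        """Raise if the table cannot support a tensor fit."""
        if not np.any(self.b0_mask):
            raise ValueError("gradient table has no b=0 entry")
        if int(self.dwi_mask.sum()) < 6:
            raise ValueError(
                f"tensor fit needs >=6 diffusion-weighted directions, "
                f"got {int(self.dwi_mask.sum())}"
            )
        design = self.design_matrix()[self.dwi_mask, 1:]
        if np.linalg.matrix_rank(design) < 6:
            raise ValueError(
                "gradient directions are collinear/degenerate: design matrix is rank-deficient"
            )


def icosahedral_directions() -> np.ndarray:
    """Twelve unit directions at the vertices of a regular icosahedron.

    Six antipodal pairs, well spread over the sphere; a standard low-count
    encoding scheme for 12-direction acquisitions.
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    raw = np.array(
        [
            [0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
            [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
            [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1],
        ],
        dtype=float,
    )
    return raw / np.linalg.norm(raw, axis=1, keepdims=True)


def default_gradient_table(b_value: float = 1000.0) -> GradientTable:
    """One b=0 volume plus 12 diffusion directions at ``b_value`` s/mm^2."""
    dirs = icosahedral_directions()
    bvals = np.concatenate([[0.0], np.full(len(dirs), b_value)])
    bvecs = np.vstack([np.zeros(3), dirs])
    return GradientTable(bvals, bvecs)
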