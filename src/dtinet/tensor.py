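"""Per-voxel diffusion tensor estimation and fractional anisotropy.

The tensor D is fit voxelwise by ordinary log-linear least squares on the
Stejskal-Tanner model ln(S/S0) = -b g^T D g, then diagonalized.  FA is

    FA = sqrt( ((l1-l2)^2 + (l1-l3)^2 + (l2-l3)^2) / (2 (l1^2+l2^2+l3^2)) )

with eigenvalues sorted l1 >= l2 >= l3.  FA of the zero tensor is defined
as 0 (isotropy convention), and eigenvalues are clamped at 0 for the FA
computation only; raw fitted values are preserved for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gradients import GradientTable

__all__ = ["DWIVolume", "TensorField", "FAMap", "fit_tensor", "compute_fa", "fa_from_eigenvalues"]


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal block with its voxel->world affine."""

    data: np.ndarray  # (x, y, z, n_directions)
    affine: np.ndarray  # 4x4
    gtab: GradientTable

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"DWI data must be 4D, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.data.shape[3] != len(self.gtab):
            raise ValueError(
                f"DWI has {self.data.shape[3]} volumes but gradient table has "
                f"{len(self.gtab)} entries"
            )


@dataclass
class TensorField:
    """Voxelwise symmetric diffusion tensors with their spectral decomposition.

    ``evals`` are sorted descending (l1 >= l2 >= l3); ``evecs[..., :, k]`` is the
    unit eigenvector of ``evals[..., k]``.  ``valid_mask`` flags voxels where a
    fit succeeded (positive signals); invalid voxels carry zeros.
    """

    tensors: np.ndarray  # (x, y, z, 3, 3)
    evals: np.ndarray  # (x, y, z, 3) descending
    evecs: np.ndarray  # (x, y, z, 3, 3) columns = eigenvectors
    valid_mask: np.ndarray  # (x, y, z) bool
    affine: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    @property
    def principal_direction(self) -> np.ndarray:
        """Unit eigenvector of the largest eigenvalue, shape (x, y, z, 3)."""
        return self.evecs[..., :, 0]

    @classmethod
    def from_tensors(cls, tensors: np.ndarray, affine: np.ndarray,
                     valid_mask: np.ndarray | None = None) -> "TensorField":
        tensors = np.asarray(tensors, dtype=float)
        if valid_mask is None:
            valid_mask = np.ones(tensors.shape[:3], dtype=bool)
        evals, evecs = _spectral(tensors)
        return cls(tensors, evals, evecs, valid_mask, np.asarray(affine, dtype=float))


@dataclass
class FAMap:
    """Scalar fractional anisotropy per voxel, in [0, 1] on valid voxels."""

    fa: np.ndarray  # (x, y, z)
    valid_mask: np.ndarray
    affine: np.ndarray


def _spectral(tensors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition with eigenvalues sorted descending."""
    evals, evecs = np.linalg.eigh(tensors)  # ascending
    evals = evals[..., ::-1]
    evecs = evecs[..., ::-1]
    return np.ascontiguousarray(evals), np.ascontiguousarray(evecs)


def fa_from_eigenvalues(evals: np.ndarray, zero_tol: float = 1e-10) -> np.ndarray:
    """FA from eigenvalue triples (last axis), zero tensor -> 0.

    Negative eigenvalues (possible in noisy fits) are clamped to 0 here so the
    result stays in [0, 1].  Because FA is scale-invariant, "zero tensor"
    needs a numerical floor: eigenvalues whose largest magnitude falls below
    ``zero_tol`` (default 1e-10 mm^2/s, seven orders below water diffusivity)
    are treated as the zero tensor rather than amplifying round-off noise.
    """
    ev = np.maximum(np.asarray(evals, dtype=float), 0.0)
    l1, l2, l3 = ev[..., 0], ev[..., 1], ev[..., 2]
    num = (l1 - l2) ** 2 + (l1 - l3) ** 2 + (l2 - l3) ** 2
    den = 2.0 * (l1**2 + l2**2 + l3**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(num / den)
    return np.where((den > 0) & (l1 >= zero_tol), fa, 0.0)


def fit_tensor(dwi: DWIVolume, gtab: GradientTable | None = None,
               s0_mask_fraction: float = 0.05) -> TensorField:
    """Voxelwise log-linear least-squares tensor fit.

    Parameters
    ----------
    dwi
        4D signal volume; the 4th axis must match the gradient table.
    gtab
        Encoding; defaults to ``dwi.gtab``.
    s0_mask_fraction
        Voxels whose b0 signal falls below this fraction of the robust
        (98th-percentile) maximum b0 are marked invalid — a phantom analogue
        of a brain mask.

    Voxels with any nonpositive signal are marked invalid rather than raising.
    A rank-deficient gradient scheme raises before any voxel is fit.
    """
    gtab = gtab or dwi.gtab
    if dwi.data.shape[3] != len(gtab):
        raise ValueError("gradient table length does not match DWI 4th axis")
    gtab.validate_for_fit()

    shape = dwi.data.shape[:3]
    signals = dwi.data.reshape(-1, len(gtab))

    s0 = signals[:, gtab.b0_mask].mean(axis=1)
    valid = (signals > 0).all(axis=1) & (s0 > 0)
    if s0_mask_fraction > 0 and np.any(valid):
        robust_max = np.percentile(s0[valid], 98)
        valid &= s0 >= s0_mask_fraction * robust_max

    design = gtab.design_matrix()
    solver = np.linalg.pinv(design)  # (7, n_dirs)

    coeffs = np.zeros((signals.shape[0], 7))
    if np.any(valid):
        log_s = np.log(signals[valid])
        coeffs[valid] = log_s @ solver.T

    dxx, dyy, dzz, dxy, dxz, dyz = coeffs[:, 1:].T
    tensors = np.empty((signals.shape[0], 3, 3))
    tensors[:, 0, 0] = dxx
    tensors[:, 1, 1] = dyy
    tensors[:, 2, 2] = dzz
    tensors[:, 0, 1] = tensors[:, 1, 0] = dxy
    tensors[:, 0, 2] = tensors[:, 2, 0] = dxz
    tensors[:, 1, 2] = tensors[:, 2, 1] = dyz
    tensors[~valid] = 0.0

    tensors = tensors.reshape(*shape, 3, 3)
    evals, evecs = _spectral(tensors)
    return TensorField(tensors, evals, evecs, valid.reshape(shape), dwi.affine)


def compute_fa(tensors: TensorField) -> FAMap:
    """FA map of a tensor field; invalid voxels get FA 0."""
    fa = fa_from_eigenvalues(tensors.evals)
    fa = np.where(tensors.valid_mask, fa, 0.0)
    return FAMap(fa=fa, valid_mask=tensors.valid_mask, affine=tensors.affine)
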