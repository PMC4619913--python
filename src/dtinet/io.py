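"""File I/O: NIfTI volumes, FSL-style bval/bvec, TRK streamlines, TSV reports.

All tabular outputs are plain TSV with region-abbreviation headers so that
pipeline results diff cleanly; streamlines use the TRK interchange format
with world-mm point storage and the voxel-to-world affine in the header.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import Field, Tractogram
from nibabel.streamlines.trk import TrkFile

from .connectome import ConnectomeMatrix, LabelVolume
from .gradients import GradientTable
from .laterality import AsymmetryReport
from .metrics import NodalMetrics
from .phantom import CohortSpec, generate_cohort, ground_truth_of
from .tensor import DWIVolume, FAMap, TensorField
from .tracking import StreamlineSet

__all__ = [
    "read_dwi", "write_dwi", "read_labels", "write_labels",
    "save_streamlines", "load_streamlines",
    "write_tensor_field", "read_tensor_field", "write_fa", "read_fa",
    "write_matrix", "read_matrix", "write_metrics", "write_cohort",
    "write_outputs",
]

_BVEC_TOL = 1e-3


def _region_headers(n: int, names: dict[int, str] | None) -> list[str]:
    names = names or {}
    return [names.get(i, f"R{i:02d}") for i in range(1, n + 1)]


# -- DWI + gradients ---------------------------------------------------------

def read_dwi(nifti_path, bval_path, bvec_path) -> tuple[DWIVolume, GradientTable]:
    """Load a 4D DWI NIfTI plus FSL-style whitespace-separated bval/bvec."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: expected 4D DWI, got {data.ndim}D")
    bvals = np.loadtxt(str(bval_path), ndmin=1).ravel()
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T  # FSL stores 3 rows x N columns
    if bvecs.shape[0] != bvals.shape[0]:
        raise ValueError(
            f"bvec rows ({bvecs.shape[0]}) do not match bval count ({bvals.shape[0]})"
        )
    if data.shape[3] != bvals.shape[0]:
        raise ValueError(
            f"{nifti_path}: {data.shape[3]} volumes but {bvals.shape[0]} b-values"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    dwi_rows = bvals > 0
    if np.any(np.abs(norms[dwi_rows] - 1.0) > _BVEC_TOL):
        raise ValueError(f"{bvec_path}: non-unit gradient direction beyond tolerance")
    bvecs = bvecs.copy()
    bvecs[dwi_rows] /= norms[dwi_rows, None]
    gtab = GradientTable(bvals, bvecs)
    return DWIVolume(data, img.affine, gtab), gtab


def write_dwi(dwi: DWIVolume, nifti_path, bval_path, bvec_path) -> None:
    # float64 so a write -> read round-trip is bit-identical
    nib.save(nib.Nifti1Image(dwi.data.astype(np.float64), dwi.affine), str(nifti_path))
    np.savetxt(str(bval_path), dwi.gtab.bvals[None, :], fmt="%.1f")
    np.savetxt(str(bvec_path), dwi.gtab.bvecs.T, fmt="%.8f")


def read_labels(path, region_names: dict[int, str] | None = None) -> LabelVolume:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    if labels.ndim != 3:
        raise ValueError(f"{path}: expected 3D label volume, got {labels.ndim}D")
    return LabelVolume(labels=labels, affine=img.affine,
                       region_names=region_names or {})


def write_labels(labels: LabelVolume, path) -> None:
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), labels.affine), str(path))


# -- scalar / tensor volumes -------------------------------------------------

_TENSOR_ORDER = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def write_tensor_field(tensors: TensorField, path) -> None:
    """6-component volume (xx, yy, zz, xy, xz, yz) plus a validity channel."""
    comps = [tensors.tensors[..., i, j] for i, j in _TENSOR_ORDER]
    comps.append(tensors.valid_mask.astype(float))
    nib.save(
        nib.Nifti1Image(np.stack(comps, axis=-1).astype(np.float64), tensors.affine),
        str(path),
    )


def read_tensor_field(path) -> TensorField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != 7:
        raise ValueError(f"{path}: not a saved tensor field (need 7 components)")
    shape = data.shape[:3]
    tensors = np.zeros((*shape, 3, 3))
    for c, (i, j) in enumerate(_TENSOR_ORDER):
        tensors[..., i, j] = data[..., c]
        tensors[..., j, i] = data[..., c]
    return TensorField.from_tensors(tensors, img.affine,
                                    valid_mask=data[..., 6] > 0.5)


def write_fa(fa: FAMap, path) -> None:
    nib.save(nib.Nifti1Image(fa.fa.astype(np.float64), fa.affine), str(path))


def read_fa(path) -> FAMap:
    img = nib.load(str(path))
    fa = np.asarray(img.dataobj, dtype=float)
    return FAMap(fa=fa, valid_mask=np.isfinite(fa), affine=img.affine)


# -- streamlines (TRK) -------------------------------------------------------

def save_streamlines(streamlines: StreamlineSet, path,
                     grid_shape: tuple[int, int, int]) -> None:
    """TRK with world-mm points and the voxel-to-world affine in the header."""
    header = {
        Field.VOXEL_TO_RASMM: streamlines.affine.astype(np.float32),
        Field.VOXEL_SIZES: np.linalg.norm(streamlines.affine[:3, :3], axis=0),
        Field.DIMENSIONS: np.asarray(grid_shape, dtype=np.int16),
    }
    tractogram = Tractogram(streamlines.streamlines, affine_to_rasmm=np.eye(4))
    TrkFile(tractogram, header).save(str(path))


def load_streamlines(path) -> StreamlineSet:
    trk = TrkFile.load(str(path))  # points come back in world mm (rasmm)
    lines = [np.asarray(s, dtype=float) for s in trk.tractogram.streamlines]
    return StreamlineSet(
        streamlines=lines,
        seed_voxels=np.empty((0, 3), dtype=np.int64),
        termination_reasons=[("unknown", "unknown")] * len(lines),
        affine=np.asarray(trk.header[Field.VOXEL_TO_RASMM], dtype=float),
    )


# -- tabular reports ---------------------------------------------------------

def write_matrix(matrix: np.ndarray, path, region_names: dict[int, str] | None = None) -> None:
    n = matrix.shape[0]
    headers = _region_headers(n, region_names)
    pd.DataFrame(np.asarray(matrix), index=headers, columns=headers).to_csv(
        path, sep="\t", index_label="region"
    )


def read_matrix(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy()


def write_metrics(metrics: NodalMetrics, path, region_names: dict[int, str] | None = None) -> None:
    headers = _region_headers(metrics.n_nodes, region_names)
    pd.DataFrame(
        {
            "region": headers,
            "degree": metrics.degree,
            "path_length": metrics.path_length,
            "betweenness": metrics.betweenness,
            "norm_betweenness": metrics.norm_betweenness,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _manifest(out_dir: Path, files: list[Path], path_name="manifest.tsv") -> Path:
    rows = [
        {"file": str(f.relative_to(out_dir)), "sha256": _sha256(f)} for f in sorted(files)
    ]
    manifest_path = out_dir / path_name
    pd.DataFrame(rows, columns=["file", "sha256"]).to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


# -- cohort export -----------------------------------------------------------

def write_cohort(spec: CohortSpec, out_dir) -> Path:
    """Write per-subject NIfTI/bval/bvec files plus a cohort manifest TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = ground_truth_of(spec)
    files: list[Path] = []
    rows = []
    region_names = spec.phantom_template.region_names
    for subject in generate_cohort(spec):
        sub_dir = out_dir / subject.subject_id
        sub_dir.mkdir(exist_ok=True)
        dwi_path = sub_dir / "dwi.nii.gz"
        write_dwi(subject.dwi, dwi_path, sub_dir / "dwi.bval", sub_dir / "dwi.bvec")
        write_labels(subject.labels, sub_dir / "labels.nii.gz")
        files += [dwi_path, sub_dir / "dwi.bval", sub_dir / "dwi.bvec",
                  sub_dir / "labels.nii.gz"]
        rows.append(
            {
                "subject_id": subject.subject_id,
                "dwi": f"{subject.subject_id}/dwi.nii.gz",
                "bval": f"{subject.subject_id}/dwi.bval",
                "bvec": f"{subject.subject_id}/dwi.bvec",
                "labels": f"{subject.subject_id}/labels.nii.gz",
                "asymmetric_pairs": ";".join(
                    f"{l}-{r}:{d}" for (l, r), d in sorted(truth.region_pairs.items())
                ),
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "cohort.tsv", sep="\t", index=False)
    if region_names:
        pd.DataFrame(
            sorted(region_names.items()), columns=["label", "region"]
        ).to_csv(out_dir / "regions.tsv", sep="\t", index=False)
        # cohort-level tables are deliberately outside the checksummed list
    return _manifest(out_dir, files)


def write_outputs(out_dir, *, subject_results=None, report: AsymmetryReport | None = None,
                  region_names: dict[int, str] | None = None, grid_shape=None,
                  force: bool = False) -> Path:
    """Write per-subject matrices/metrics/streamlines and the group reports."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def target(path: Path) -> Path:
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists (use force to overwrite)")
        files.append(path)
        return path

    for res in subject_results or []:
        sub_dir = out_dir / res.subject_id
        sub_dir.mkdir(exist_ok=True)
        write_matrix(res.connectome.fiber_counts,
                     target(sub_dir / "fiber_counts.tsv"), region_names)
        write_matrix(res.connectome.adjacency,
                     target(sub_dir / "adjacency.tsv"), region_names)
        write_metrics(res.metrics, target(sub_dir / "nodal_metrics.tsv"), region_names)
        if res.streamlines is not None and grid_shape is not None:
            save_streamlines(res.streamlines, target(sub_dir / "streamlines.trk"),
                             grid_shape)
        if res.tracts:
            pd.DataFrame([vars(t) for t in res.tracts]).to_csv(
                target(sub_dir / "tracts.tsv"), sep="\t", index=False,
                float_format="%.10g",
            )
    if report is not None:
        report.laterality.to_csv(target(out_dir / "laterality.tsv"), sep="\t",
                                 index=False, float_format="%.10g")
        report.tracts.to_csv(target(out_dir / "tract_asymmetry.tsv"), sep="\t",
                             index=False, float_format="%.10g")
    return _manifest(out_dir, files)
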