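"""Reading, writing and shell-partitioning of diffusion-weighted MRI datasets.

On-disk formats are NIfTI-1 for the 4-D image and the FSL text dialect for
the gradient table: ``bvec`` holds 3 rows by V columns of direction
components, ``bval`` one row of V diffusion weightings in s/mm².
Directions are kept in the image coordinate frame exactly as read; no
reorientation by the NIfTI affine is applied, since the QC statistic
depends only on relative angles between directions, which any rigid
reorientation preserves.

The slice axis is fixed as the third array axis (axial slices); datasets
acquired otherwise must be permuted by the caller before use.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GradientTable",
    "DWIDataset",
    "FormatError",
    "ValidationError",
    "read_dwi",
    "write_dwi",
    "split_by_shell",
]


class FormatError(ValueError):
    """File contents do not match the expected on-disk dialect."""


class ValidationError(ValueError):
    """In-memory data violate a container invariant."""


@dataclass(frozen=True)
class GradientTable:
    """Per-volume diffusion encoding: unit direction vectors and b-values.

    Parameters
    ----------
    directions : (V, 3) float array
        Diffusion gradient direction per volume, dimensionless. Unit norm
        for every volume with b > 0; volumes with b = 0 carry (0, 0, 0).
    bvalues : (V,) float array
        Diffusion weighting per volume in s/mm², all ≥ 0.
    """

    directions: np.ndarray
    bvalues: np.ndarray

    def __post_init__(self) -> None:
        directions = np.asarray(self.directions, dtype=float)
        bvalues = np.asarray(self.bvalues, dtype=float)
        if directions.ndim != 2 or directions.shape[1] != 3:
            raise ValidationError(
                f"directions must be (V, 3), got shape {directions.shape}"
            )
        if bvalues.ndim != 1 or bvalues.shape[0] != directions.shape[0]:
            raise ValidationError(
                f"bvalues length {bvalues.shape} does not match "
                f"{directions.shape[0]} directions"
            )
        if bvalues.shape[0] < 1:
            raise ValidationError("gradient table must hold at least one volume")
        if not np.all(np.isfinite(bvalues)):
            raise ValidationError("b-values must be finite")
        if np.any(bvalues < 0):
            raise ValidationError("b-values must be non-negative")
        if not np.all(np.isfinite(directions)):
            raise ValidationError("directions must be finite")
        norms = np.linalg.norm(directions, axis=1)
        weighted = bvalues > 0
        bad = weighted & (np.abs(norms - 1.0) > 1e-3)
        if np.any(bad):
            raise ValidationError(
                f"{int(bad.sum())} diffusion-weighted volumes have non-unit "
                f"directions (norms {norms[bad][:5]}...)"
            )
        object.__setattr__(self, "directions", directions)
        object.__setattr__(self, "bvalues", bvalues)

    def __len__(self) -> int:
        return self.bvalues.shape[0]

    def subset(self, indices: np.ndarray) -> "GradientTable":
        """Return the table restricted to ``indices``, order preserved."""
        idx = np.asarray(indices, dtype=int)
        return GradientTable(self.directions[idx], self.bvalues[idx])


@dataclass
class DWIDataset:
    """A 4-D diffusion-weighted acquisition.

    Parameters
    ----------
    intensities : (X, Y, Z, V) float array
        Non-negative signal intensities; axis 2 is the axial slice axis.
    voxel_size : (3,) float array
        Voxel edge lengths in mm.
    gradients : GradientTable
        One entry per volume along the fourth axis.
    affine : (4, 4) float array, optional
        NIfTI voxel-to-world transform; defaults to a scaled identity.
    original_indices : (V,) int array, optional
        Indices of each volume in the acquisition this dataset was derived
        from; identity for a freshly loaded dataset. Retained through
        shell splitting and QC removal so provenance is never lost.
    """

    intensities: np.ndarray
    voxel_size: np.ndarray
    gradients: GradientTable
    affine: np.ndarray | None = None
    original_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.intensities.ndim != 4:
            raise ValidationError(
                f"intensities must be 4-D (x, y, z, volume), got "
                f"{self.intensities.ndim}-D"
            )
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValidationError("voxel_size must be 3 positive lengths in mm")
        if self.intensities.shape[3] != len(self.gradients):
            raise ValidationError(
                f"image has {self.intensities.shape[3]} volumes but gradient "
                f"table has {len(self.gradients)}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValidationError("intensities must be non-negative")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])
        if self.original_indices is None:
            self.original_indices = np.arange(self.n_volumes)
        else:
            self.original_indices = np.asarray(self.original_indices, dtype=int)
            if self.original_indices.shape != (self.n_volumes,):
                raise ValidationError("original_indices must have one entry per volume")

    @property
    def n_volumes(self) -> int:
        return self.intensities.shape[3]

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]


def _read_gradient_text(bval_path: str | os.PathLike, bvec_path: str | os.PathLike):
    bvals = np.loadtxt(bval_path, ndmin=2)
    if bvals.shape[0] != 1:
        bvals = bvals.T
    if bvals.shape[0] != 1:
        raise FormatError(f"bval file {bval_path} is not a single row of values")
    bvals = bvals[0]
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3 and bvecs.shape[1] == 3:
        logger.warning(
            "bvec file %s is 3-column (transposed) layout; accepting and "
            "transposing to the FSL 3-row convention", bvec_path
        )
        bvecs = bvecs.T
    if bvecs.shape[0] != 3:
        raise FormatError(
            f"bvec file {bvec_path} has shape {bvecs.shape}; expected 3 rows"
        )
    return bvals, bvecs.T  # (V,), (V, 3)


def read_dwi(image_path, bval_path, bvec_path) -> DWIDataset:
    """Load a 4-D NIfTI image plus FSL-style bval/bvec files.

    Directions of diffusion-weighted volumes that are not unit norm are
    renormalized with a logged warning; b = 0 volumes may carry zero
    vectors. Raises :class:`FormatError` when the three files disagree on
    the volume count.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{image_path} is {data.ndim}-D; a 4-D image is required")
    bvals, bvecs = _read_gradient_text(bval_path, bvec_path)
    counts = {"image": data.shape[3], "bval": bvals.shape[0], "bvec": bvecs.shape[0]}
    if len(set(counts.values())) != 1:
        raise FormatError(
            "volume-count mismatch: image has {image}, bval has {bval}, "
            "bvec has {bvec} entries".format(**counts)
        )
    if not np.all(np.isfinite(bvals)) or np.any(bvals < 0):
        raise ValidationError(f"bval file {bval_path} holds negative or non-finite values")

    norms = np.linalg.norm(bvecs, axis=1)
    weighted = bvals > 0
    off = weighted & (np.abs(norms - 1.0) > 1e-3)
    if np.any(off):
        logger.warning(
            "renormalizing %d non-unit gradient directions (max |norm-1| = %.3g)",
            int(off.sum()), float(np.abs(norms[off] - 1.0).max()),
        )
        bvecs = bvecs.copy()
        bvecs[off] /= norms[off, None]
    # negative raw intensities (storage scaling artifacts) are clamped at 0
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DWIDataset(
        intensities=np.clip(data, 0.0, None),
        voxel_size=voxel_size,
        gradients=GradientTable(bvecs, bvals),
        affine=np.asarray(img.affine, dtype=float),
    )


def write_dwi(dataset: DWIDataset, image_path, bval_path, bvec_path) -> None:
    """Write a dataset as NIfTI + FSL bval/bvec, the inverse of :func:`read_dwi`."""
    for p in (image_path, bval_path, bvec_path):
        parent = os.path.dirname(os.fspath(p)) or "."
        if not os.path.isdir(parent):
            raise IOError(f"output directory does not exist: {parent}")
    img = nib.Nifti1Image(dataset.intensities.astype(np.float32), dataset.affine)
    img.header.set_zooms((*dataset.voxel_size, 1.0))
    nib.save(img, str(image_path))
    np.savetxt(bval_path, dataset.gradients.bvalues[None, :], fmt="%.6g")
    np.savetxt(bvec_path, dataset.gradients.directions.T, fmt="%.8f")


def _take_volumes(dataset: DWIDataset, idx: np.ndarray) -> DWIDataset:
    return DWIDataset(
        intensities=dataset.intensities[..., idx],
        voxel_size=dataset.voxel_size,
        gradients=dataset.gradients.subset(idx),
        affine=dataset.affine,
        original_indices=dataset.original_indices[idx],
    )


def split_by_shell(dataset: DWIDataset, b_split: float = 500.0):
    """Partition volumes into a low shell (b ≤ b_split) and a high shell.

    Volume order is preserved inside each partition and the original
    volume indices are carried as metadata, so the split is losslessly
    invertible. One partition may be empty when all volumes fall on one
    side.

    Returns
    -------
    (low, high) : tuple of DWIDataset or None
        ``None`` stands for an empty partition.
    """
    b = dataset.gradients.bvalues
    low_idx = np.flatnonzero(b <= b_split)
    high_idx = np.flatnonzero(b > b_split)
    low = _take_volumes(dataset, low_idx) if low_idx.size else None
    high = _take_volumes(dataset, high_idx) if high_idx.size else None
    return low, high
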