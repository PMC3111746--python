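"""Log-linear diffusion tensor fitting and fractional anisotropy maps.

The single-tensor model predicts the diffusion-weighted signal as
``S = S0 · exp(−b gᵀ D g)`` with D the symmetric 3×3 diffusion tensor in
mm²/s. Taking logs makes the model linear in the six tensor components
and log S0, so an ordinary least-squares fit per voxel recovers both the
tensor and an effective non-diffusion-weighted image (the exponentiated
intercept), even when the acquisition contains no true b = 0 volume —
low-b volumes anchor the intercept through their small but nonzero
weighting.

FA is the normalized dispersion of the tensor eigenvalues λ1, λ2, λ3:

    FA = sqrt(1/2) · sqrt((λ1−λ2)² + (λ2−λ3)² + (λ1−λ3)²)
                   / sqrt(λ1² + λ2² + λ3²)

0 for isotropic diffusion (free water), approaching 1 when a single
direction dominates. Negative fitted eigenvalues (a noise effect) are
clipped to zero before FA, keeping the map in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import DWIDataset, GradientTable, ValidationError

__all__ = [
    "TensorField",
    "FAMap",
    "design_matrix",
    "fit_tensor",
    "fa_from_eigenvalues",
    "compute_fa_map",
    "smooth_map",
    "fa_difference_report",
]

#: value assigned outside the mask in FA maps
FA_SENTINEL = 0.0

#: relative floor applied to intensities before the log transform
LOG_CLAMP_EPS = 1e-4

# order of the six unique tensor components in storage
TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class TensorField:
    """Per-voxel diffusion tensor (6 components) with effective S0.

    ``tensor`` has shape (X, Y, Z, 6) ordered (Dxx, Dyy, Dzz, Dxy, Dxz,
    Dyz) in mm²/s; ``s0`` is the exponentiated fit intercept; ``mask``
    marks foreground voxels where the fit is meaningful.
    """

    tensor: np.ndarray
    s0: np.ndarray
    mask: np.ndarray

    def as_matrices(self) -> np.ndarray:
        """Expand to full symmetric 3×3 matrices, shape (X, Y, Z, 3, 3)."""
        dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(self.tensor, -1, 0)
        out = np.empty(self.tensor.shape[:-1] + (3, 3))
        out[..., 0, 0] = dxx
        out[..., 1, 1] = dyy
        out[..., 2, 2] = dzz
        out[..., 0, 1] = out[..., 1, 0] = dxy
        out[..., 0, 2] = out[..., 2, 0] = dxz
        out[..., 1, 2] = out[..., 2, 1] = dyz
        return out


@dataclass
class FAMap:
    """Scalar FA map in [0, 1] inside ``mask``, sentinel 0 outside."""

    fa: np.ndarray
    mask: np.ndarray


def design_matrix(gradients: GradientTable) -> np.ndarray:
    """Design matrix of the log-linear tensor model, shape (V, 7).

    Row v is (−b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz, 1)
    so that ``log S = row · (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, log S0)``.
    """
    g = gradients.directions
    b = gradients.bvalues
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack([
        -b * gx ** 2,
        -b * gy ** 2,
        -b * gz ** 2,
        -2.0 * b * gx * gy,
        -2.0 * b * gx * gz,
        -2.0 * b * gy * gz,
        np.ones_like(b),
    ])


def _default_mask(s0: np.ndarray) -> np.ndarray:
    robust_max = np.percentile(s0, 99)
    return s0 > 0.10 * robust_max


def fit_tensor(dataset: DWIDataset, mask: np.ndarray | None = None) -> TensorField:
    """Ordinary least squares on log intensities, voxel by voxel.

    Zero or tiny intensities (Rician floor) are clamped to
    ``LOG_CLAMP_EPS`` times a per-voxel S0 estimate before the log.
    When no mask is given, all voxels are fitted and the returned mask
    selects voxels whose effective S0 exceeds 10% of its robust maximum.
    """
    X = design_matrix(dataset.gradients)
    if X.shape[0] < 7 or np.linalg.matrix_rank(X) < 7:
        raise ValidationError(
            "insufficient gradient scheme: the log-linear design matrix must "
            "have rank 7 (≥ 6 non-collinear directions plus intercept information)"
        )
    data = dataset.intensities
    spatial = data.shape[:3]
    flat = data.reshape(-1, data.shape[3])

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != spatial:
            raise ValidationError("mask shape does not match the spatial grid")
        rows = mask.reshape(-1)
    else:
        rows = np.ones(flat.shape[0], dtype=bool)

    signals = flat[rows]
    s0_est = np.max(signals, axis=1, keepdims=True)
    floor = np.maximum(LOG_CLAMP_EPS * np.maximum(s0_est, 1e-300), 1e-300)
    log_s = np.log(np.maximum(signals, floor))

    coef, *_ = np.linalg.lstsq(X, log_s.T, rcond=None)  # (7, n_voxels)
    tensor = np.zeros(spatial + (6,))
    s0 = np.zeros(spatial)
    tensor.reshape(-1, 6)[rows] = coef[:6].T
    s0.reshape(-1)[rows] = np.exp(coef[6])

    out_mask = mask if mask is not None else _default_mask(s0)
    return TensorField(tensor=tensor, s0=s0, mask=out_mask)


def fa_from_eigenvalues(l1, l2, l3):
    """FA of one eigenvalue triple or of broadcastable eigenvalue arrays.

    Negative eigenvalues are clipped to 0 first; an all-zero triple maps
    to FA 0 by convention.
    """
    lam = np.stack(np.broadcast_arrays(
        np.asarray(l1, dtype=float),
        np.asarray(l2, dtype=float),
        np.asarray(l3, dtype=float),
    ), axis=-1)
    if not np.all(np.isfinite(lam)):
        raise ValidationError("eigenvalues must be finite")
    return _fa_from_stacked(lam) if lam.ndim > 1 else float(_fa_from_stacked(lam))


def _fa_from_stacked(lam: np.ndarray) -> np.ndarray:
    lam = np.clip(lam, 0.0, None)
    a, b, c = lam[..., 0], lam[..., 1], lam[..., 2]
    num = (a - b) ** 2 + (b - c) ** 2 + (a - c) ** 2
    den = a ** 2 + b ** 2 + c ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(0.5 * num / den)
    return np.where(den == 0, 0.0, fa)


def compute_fa_map(dataset_or_field, mask: np.ndarray | None = None) -> FAMap:
    """FA map from a dataset (fit first) or directly from a TensorField."""
    if isinstance(dataset_or_field, TensorField):
        field = dataset_or_field
        if mask is not None:
            field = TensorField(field.tensor, field.s0, np.asarray(mask, dtype=bool))
    else:
        field = fit_tensor(dataset_or_field, mask)
    eigvals = np.linalg.eigvalsh(field.as_matrices())  # (X, Y, Z, 3)
    fa = _fa_from_stacked(eigvals)
    fa = np.where(field.mask, fa, FA_SENTINEL)
    return FAMap(fa=fa, mask=field.mask)


def smooth_map(fa_map: FAMap, fwhm_mm, voxel_size) -> FAMap:
    """Masked Gaussian smoothing of an FA map.

    The full width at half maximum per axis is given in mm and converted
    to voxel-space sigmas via σ = FWHM / (2 sqrt(2 ln 2)). Smoothing is
    renormalized over the mask so foreground values never bleed into —
    or get diluted by — background.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,)).copy()
    voxel_size = np.asarray(voxel_size, dtype=float)
    if np.any(fwhm < 0):
        raise ValidationError("FWHM must be non-negative")
    if np.all(fwhm == 0):
        return FAMap(fa=fa_map.fa.copy(), mask=fa_map.mask.copy())
    sigma_vox = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size
    m = fa_map.mask.astype(float)
    num = ndimage.gaussian_filter(fa_map.fa * m, sigma=sigma_vox)
    den = ndimage.gaussian_filter(m, sigma=sigma_vox)
    with np.errstate(divide="ignore", invalid="ignore"):
        smoothed = num / den
    smoothed = np.where(fa_map.mask, smoothed, FA_SENTINEL)
    return FAMap(fa=smoothed, mask=fa_map.mask.copy())


def fa_difference_report(fa_without_qc: FAMap, fa_with_qc: FAMap) -> dict:
    """Summaries of per-voxel |ΔFA| between two maps on a shared grid.

    Returns median, mean, 95th/99th percentile, maximum, and the
    fraction of foreground voxels with |ΔFA| ≥ 0.1 — the scale on which
    artifact removal typically moves single-subject FA.
    """
    if fa_without_qc.fa.shape != fa_with_qc.fa.shape:
        raise ValidationError("FA maps live on different grids")
    if not np.array_equal(fa_without_qc.mask, fa_with_qc.mask):
        raise ValidationError("FA maps carry different masks")
    diff = np.abs(fa_without_qc.fa - fa_with_qc.fa)[fa_without_qc.mask]
    if diff.size == 0:
        raise ValidationError("empty mask: nothing to compare")
    return {
        "median_abs_dfa": float(np.median(diff)),
        "mean_abs_dfa": float(np.mean(diff)),
        "p95_abs_dfa": float(np.percentile(diff, 95)),
        "p99_abs_dfa": float(np.percentile(diff, 99)),
        "max_abs_dfa": float(np.max(diff)),
        "frac_ge_0.1": float(np.mean(diff >= 0.1)),
        "n_voxels": int(diff.size),
    }
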