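"""Slicewise, gradient-direction-weighted signal-dropout detection.

The detector targets motion-induced slice dropouts in diffusion-weighted
volumes: a subject movement during one diffusion-encoded acquisition
wipes out signal in one or a few axial slices of that single volume.
Because different gradient directions produce genuinely different image
contrast, a slice cannot simply be compared with the same slice in every
other volume on equal terms. Instead each comparison is weighted by the
similarity of the two diffusion directions, measured by the dot product
of their unit gradient vectors.

For volume j and a fixed slice position, with ā_j the mean intensity of
that slice and ā_i the same slice in comparison volume i, the pairwise
relative deviation is

    ΔI_ji = |ā_i − ā_j| / (ā_i + ā_j)            (bounded in [0, 1])

and the per-slice statistic is its direction-weighted average over the
N = V − 1 comparison volumes,

    ΔI_j = (1/N) Σ_{i≠j} (g_i · g_j) ΔI_ji.

A volume is eliminated in full as soon as one of its slices exceeds the
detection threshold (default 0.2). The statistic is computed separately
per b-shell, since intensities across shells are not comparable.

Diffusion weighting is invariant under g → −g, so the default weight is
|g_i · g_j| (``antipodal_weights=True``); the signed dot product clipped
below at zero is available for literal fidelity to the formula above.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import DWIDataset, GradientTable, ValidationError, split_by_shell, _take_volumes

__all__ = [
    "QCConfig",
    "SliceIntensityMatrix",
    "DeviationMatrix",
    "QCReport",
    "slice_means",
    "pair_deviation",
    "direction_weight",
    "deviation_matrix",
    "flag_volumes",
    "voxel_outlier_counts",
    "apply_qc",
    "run_qc",
]

#: sentinel for slices excluded from evaluation (background)
NOT_EVALUATED = np.nan


@dataclass(frozen=True)
class QCConfig:
    """Detector configuration.

    Parameters
    ----------
    threshold : float
        Detection threshold on ΔI_j, dimensionless, in (0, 1). Default
        0.2; detection is robust to choices in 0.2–0.3.
    background_floor : float or None
        Minimum slice mean (signal units) for a slice to be evaluated;
        slices below it in any volume are treated as background and
        excluded from flagging. ``None`` (default) resolves to 5% of the
        dataset's robust maximum (99th percentile of slice means).
    antipodal_weights : bool
        Use |g_i·g_j| (default) rather than the signed dot product
        clipped at zero.
    normalize_weights : bool
        Divide by the sum of similarity weights (default), making ΔI_j a
        true weighted average whose scale is independent of the gradient
        scheme — the reading under which a fixed 0.2 threshold is
        portable across acquisitions. ``False`` divides by the fixed
        N = V − 1 instead; that variant's ceiling is the mean pairwise
        weight (≈ 0.5 for a dense uniform scheme), so the same threshold
        detects only far stronger dropouts.
    b_split : float
        Shell boundary in s/mm² used by :func:`run_qc` (default 500).
    """

    threshold: float = 0.2
    background_floor: float | None = None
    antipodal_weights: bool = True
    normalize_weights: bool = True
    b_split: float = 500.0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValidationError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.background_floor is not None and self.background_floor < 0:
            raise ValidationError("background_floor must be >= 0")


@dataclass(frozen=True)
class SliceIntensityMatrix:
    """Per-(volume, slice) mean intensities, shape (V, Z)."""

    means: np.ndarray

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        if means.ndim != 2:
            raise ValidationError("slice-mean matrix must be 2-D (volume, slice)")
        if not np.all(np.isfinite(means) | np.isnan(means)):
            raise ValidationError("slice means must be finite (NaN marks empty slices)")
        with np.errstate(invalid="ignore"):
            if np.any(means < 0):
                raise ValidationError("slice means must be non-negative")
        object.__setattr__(self, "means", means)


@dataclass(frozen=True)
class DeviationMatrix:
    """Weighted deviation ΔI_j per (volume, slice).

    ``delta`` holds NaN at background slices (not evaluated);
    ``n_comparisons`` is the N of the averaging; ``shell_label`` names
    the b-shell the matrix was computed on.
    """

    delta: np.ndarray
    n_comparisons: int
    shell_label: str = ""

    def __post_init__(self) -> None:
        delta = np.asarray(self.delta, dtype=float)
        evaluated = ~np.isnan(delta)
        if np.any((delta[evaluated] < 0) | (delta[evaluated] > 1)):
            raise ValidationError("evaluated deviations must lie in [0, 1]")
        object.__setattr__(self, "delta", delta)

    @property
    def evaluated(self) -> np.ndarray:
        return ~np.isnan(self.delta)


@dataclass
class QCReport:
    """Outcome of a QC run: what was flagged and the evidence behind it."""

    flagged_volumes: set[int]
    deviation: dict[str, DeviationMatrix]
    worst_slice_per_volume: dict[int, tuple[int, float]]
    outlier_counts: np.ndarray | None
    config: QCConfig
    volume_shells: dict[int, str] = field(default_factory=dict)


def slice_means(dataset: DWIDataset, foreground_mask: np.ndarray | None = None) -> SliceIntensityMatrix:
    """Mean intensity of every axial slice of every volume, shape (V, Z).

    With a mask, means are restricted to mask voxels; a slice whose mask
    is empty gets NaN and is excluded downstream.
    """
    data = dataset.intensities
    if foreground_mask is None:
        means = data.mean(axis=(0, 1)).T  # (V, Z)
    else:
        foreground_mask = np.asarray(foreground_mask, dtype=bool)
        if foreground_mask.shape != dataset.spatial_shape:
            raise ValidationError(
                f"mask shape {foreground_mask.shape} does not match spatial "
                f"grid {dataset.spatial_shape}"
            )
        m = foreground_mask[..., None].astype(float)
        counts = foreground_mask.sum(axis=(0, 1)).astype(float)  # (Z,)
        sums = (data * m).sum(axis=(0, 1))  # (Z, V)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = (sums / counts[:, None]).T
        means[:, counts == 0] = np.nan
    return SliceIntensityMatrix(means)


def pair_deviation(abar_i, abar_j):
    """Relative deviation |ā_i − ā_j| / (ā_i + ā_j); 0 when both are 0.

    Symmetric, bounded in [0, 1], and invariant to a common positive
    scaling of both means. Accepts scalars or arrays.
    """
    a = np.asarray(abar_i, dtype=float)
    b = np.asarray(abar_j, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(a < 0) or np.any(b < 0):
            raise ValidationError("slice means must be non-negative")
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.abs(a - b) / denom
    out = np.where(denom == 0, 0.0, out)
    if np.isscalar(abar_i) and np.isscalar(abar_j):
        return float(out)
    return out


def direction_weight(g_i: np.ndarray, g_j: np.ndarray, antipodal: bool = True) -> float:
    """Similarity weight between two unit gradient directions in [0, 1].

    ``antipodal=True`` returns |g_i·g_j| (g and −g encode identical
    diffusion contrast); ``antipodal=False`` returns the dot product
    clipped below at zero.
    """
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    for g in (g_i, g_j):
        if abs(np.linalg.norm(g) - 1.0) > 1e-3:
            raise ValidationError(f"direction {g} is not unit norm")
    dot = float(np.dot(g_i, g_j))
    return abs(dot) if antipodal else max(dot, 0.0)


def _weight_matrix(gradients: GradientTable, config: QCConfig) -> np.ndarray:
    """Pairwise direction-similarity weights with zeroed diagonal.

    Low-b shells whose directions are all zero or all identical carry no
    direction contrast; weights degrade to uniform 1 there.
    """
    dirs = gradients.directions
    norms = np.linalg.norm(dirs, axis=1)
    if np.all(norms < 1e-12) or (
        dirs.shape[0] > 1 and np.allclose(dirs, dirs[0], atol=1e-6)
    ):
        W = np.ones((dirs.shape[0], dirs.shape[0]))
    else:
        # zero-direction volumes inside a directional shell also weight 1
        unit = np.where(norms[:, None] > 1e-12, dirs / np.maximum(norms, 1e-12)[:, None], 0.0)
        dots = unit @ unit.T
        dots[norms < 1e-12, :] = 1.0
        dots[:, norms < 1e-12] = 1.0
        W = np.abs(dots) if config.antipodal_weights else np.clip(dots, 0.0, None)
    np.fill_diagonal(W, 0.0)
    return W


def _resolve_background_floor(means: np.ndarray, config: QCConfig) -> float:
    if config.background_floor is not None:
        return config.background_floor
    finite = means[~np.isnan(means)]
    robust_max = float(np.percentile(finite, 99)) if finite.size else 0.0
    return 0.05 * robust_max


def deviation_matrix(
    slice_mat: SliceIntensityMatrix,
    gradients: GradientTable,
    config: QCConfig | None = None,
    shell_label: str = "",
) -> DeviationMatrix:
    """Direction-weighted slicewise deviation ΔI_j for one b-shell.

    Entry (j, z) averages the pairwise deviations of slice z in volume j
    against the same slice in every other volume, weighted by gradient
    similarity. Background slices — mean below the background floor in
    any volume, or empty under the mask — get NaN and are never flagged.
    """
    config = config or QCConfig()
    means = slice_mat.means
    V, Z = means.shape
    if V != len(gradients):
        raise ValidationError(
            f"slice-mean matrix has {V} volumes but gradient table {len(gradients)}"
        )
    if V < 2:
        raise ValidationError("at least 2 volumes are required per shell")

    W = _weight_matrix(gradients, config)  # (V, V), zero diagonal
    floor = _resolve_background_floor(means, config)
    with np.errstate(invalid="ignore"):
        background = np.any(np.isnan(means) | (means < floor), axis=0)  # (Z,)

    # pairwise ΔI_ji for all volume pairs at once: (V, V, Z)
    a_i = means[:, None, :]
    a_j = means[None, :, :]
    denom = a_i + a_j
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.abs(a_i - a_j) / denom
    dev = np.where(denom == 0, 0.0, dev)
    weighted = np.einsum("ij,ijz->jz", W, np.nan_to_num(dev))
    if config.normalize_weights:
        wsum = W.sum(axis=0)  # per index volume j
        delta = weighted / np.maximum(wsum, 1e-300)[:, None]
    else:
        delta = weighted / (V - 1)
    delta[:, background] = NOT_EVALUATED
    return DeviationMatrix(delta=delta, n_comparisons=V - 1, shell_label=shell_label)


def flag_volumes(deviation: DeviationMatrix, config: QCConfig | None = None) -> set[int]:
    """Volumes whose worst evaluated slice exceeds the threshold.

    One bad slice condemns the whole volume: partial-volume exclusion
    would bias the tensor fit along that gradient direction.
    """
    config = config or QCConfig()
    with np.errstate(invalid="ignore"):
        exceeded = np.nan_to_num(deviation.delta, nan=-1.0) > config.threshold
    return set(np.flatnonzero(exceeded.any(axis=1)).tolist())


def voxel_outlier_counts(dataset: DWIDataset, gradients: GradientTable | None = None,
                         config: QCConfig | None = None) -> np.ndarray:
    """Per-(volume, slice) count of voxels beyond 2 weighted SDs.

    For each voxel and index volume j, the direction-weighted mean and
    weighted standard deviation of the signal across the other volumes
    are computed with the same similarity weights as the deviation
    statistic; the entry (j, z) counts voxels in slice z of volume j
    whose signal deviates from that weighted mean by strictly more than
    two weighted SDs. This is the review-panel statistic, complementary
    to the slice-mean detector.
    """
    gradients = gradients if gradients is not None else dataset.gradients
    config = config or QCConfig()
    V = dataset.n_volumes
    if V < 3:
        raise ValidationError("at least 3 volumes are required for outlier counts")
    if len(gradients) != V:
        raise ValidationError("gradient table does not match volume count")

    W = _weight_matrix(gradients, config)  # (V, V), zero diagonal
    Wn = W / W.sum(axis=0, keepdims=True)  # column j: weights over comparisons i
    S = dataset.intensities  # (X, Y, Z, V)
    m1 = S @ Wn  # weighted mean per index volume, (X, Y, Z, V)
    m2 = (S ** 2) @ Wn
    var = np.clip(m2 - m1 ** 2, 0.0, None)
    sd = np.sqrt(var)
    # strict comparison: with zero spread only a genuine mismatch counts;
    # the relative term absorbs floating-point jitter of the moments
    out = np.abs(S - m1) > 2.0 * sd + 1e-9 * np.abs(m1)
    return out.sum(axis=(0, 1)).T.astype(int)  # (V, Z)


def apply_qc(dataset: DWIDataset, flagged: set[int]) -> DWIDataset:
    """Remove flagged volumes from image and gradient table together.

    Raises when the remainder cannot support a tensor fit: fewer than 7
    volumes, fewer than 6 distinct (antipodal-collapsed) diffusion
    directions, no low-b anchor volume, or a rank-deficient design.
    """
    flagged = set(int(v) for v in flagged)
    if not flagged <= set(range(dataset.n_volumes)):
        raise ValidationError("flagged indices outside the dataset's volume range")
    keep = np.array([v for v in range(dataset.n_volumes) if v not in flagged], dtype=int)
    remaining = _take_volumes(dataset, keep)
    _check_fit_feasible(remaining.gradients)
    return remaining


def _check_fit_feasible(gradients: GradientTable) -> None:
    from .tensor import design_matrix  # local import to avoid a cycle

    b = gradients.bvalues
    msg = None
    if len(gradients) < 7:
        msg = f"only {len(gradients)} volumes remain; at least 7 are required"
    else:
        high = gradients.directions[b > 0]
        # collapse antipodal pairs before counting distinct directions
        canon = high * np.where(high[:, [2]] < 0, -1.0, 1.0)
        distinct = np.unique(np.round(canon, 4), axis=0)
        if distinct.shape[0] < 6:
            msg = f"only {distinct.shape[0]} distinct diffusion directions remain"
        elif not np.any(b <= b.max() * 0.5):
            msg = "no low-b anchor volume remains"
        elif np.linalg.matrix_rank(design_matrix(gradients)) < 7:
            msg = "design matrix is rank deficient"
    if msg is not None:
        raise ValidationError(f"insufficient data for tensor fit: {msg}")


def run_qc(dataset: DWIDataset, config: QCConfig | None = None,
           foreground_mask: np.ndarray | None = None) -> QCReport:
    """Full QC pass: split by shell, detect per shell, union the flags.

    The deviation statistic is computed independently on the low-b and
    high-b shells (intensities across shells are not comparable), volume
    flags are mapped back to original indices and unioned, and the voxel
    outlier-count panel is computed on the high-b shell. Deterministic
    for fixed input.
    """
    config = config or QCConfig()
    low, high = split_by_shell(dataset, config.b_split)
    deviations: dict[str, DeviationMatrix] = {}
    flagged: set[int] = set()
    worst: dict[int, tuple[int, float]] = {}
    volume_shells: dict[int, str] = {}

    for label, shell in (("low_b", low), ("high_b", high)):
        if shell is None or shell.n_volumes < 2:
            continue
        sm = slice_means(shell, foreground_mask)
        dev = deviation_matrix(sm, shell.gradients, config, shell_label=label)
        deviations[label] = dev
        shell_flags = flag_volumes(dev, config)
        flagged |= {int(shell.original_indices[v]) for v in shell_flags}
        masked = np.nan_to_num(dev.delta, nan=-1.0)
        for row, orig in enumerate(shell.original_indices):
            z = int(np.argmax(masked[row]))
            val = dev.delta[row, z]
            worst[int(orig)] = (z, float(val) if np.isfinite(val) else float("nan"))
            volume_shells[int(orig)] = label

    counts = None
    if high is not None and high.n_volumes >= 3:
        counts = voxel_outlier_counts(high, high.gradients, config)

    return QCReport(
        flagged_volumes=flagged,
        deviation=deviations,
        worst_slice_per_volume=worst,
        outlier_counts=counts,
        config=config,
        volume_shells=volume_shells,
    )
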