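"""Synthetic multi-direction DWI phantoms with Rician noise and
ground-truth-labeled slice-dropout artifacts.

The simulator emulates a single-shell clinical diffusion acquisition —
by default 64 unique directions at b = 1000 s/mm² plus 8 low-b
(b = 100 s/mm²) volumes, 2.3 mm isotropic voxels, 40 axial slices — over
a geometric tensor phantom: an isotropic compartment (FA 0), a coherent
anisotropic slab with eigenvalues (1.7, 0.3, 0.3)·10⁻³ mm²/s (FA ≈ 0.8),
and signal-free background. Noise is Rician, the magnitude-MRI
statistic: two independent Gaussian channels of width σ = mean
foreground S0 / SNR, combined as a magnitude. Dropout artifacts
multiply whole slices of chosen volumes by an attenuation factor < 1,
with the injected (volume, slice) set returned as ground truth.

All randomness flows from a single user-supplied seed through one
`numpy.random.Generator`; no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DWIDataset, GradientTable, ValidationError
from .tensor import TensorField, _fa_from_stacked

__all__ = [
    "Region",
    "PhantomSpec",
    "ArtifactEvent",
    "ArtifactSpec",
    "default_gradient_scheme",
    "default_phantom_spec",
    "build_phantom",
    "simulate_signal",
    "inject_artifacts",
    "simulate_study_dataset",
]


@dataclass(frozen=True)
class Region:
    """Axis-aligned box of uniform diffusion properties.

    ``bounds`` is ((x0, x1), (y0, y1), (z0, z1)) in voxel indices,
    half-open; ``eigenvalues`` in mm²/s; ``principal_axis`` is the unit
    direction of the largest eigenvalue (any vector; normalized).
    """

    name: str
    bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    eigenvalues: tuple[float, float, float]
    principal_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def indicator(self, shape: tuple[int, int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = self.bounds
        mask[x0:x1, y0:y1, z0:z1] = True
        return mask


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue model of a synthetic tensor phantom."""

    grid_shape: tuple[int, int, int] = (32, 32, 40)
    voxel_size: tuple[float, float, float] = (2.3, 2.3, 2.3)
    regions: tuple[Region, ...] = ()
    s0: float = 1000.0

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValidationError("phantom needs at least one foreground region")
        if any(e < 0 for r in self.regions for e in r.eigenvalues):
            raise ValidationError("eigenvalues must be non-negative")
        occupancy = np.zeros(self.grid_shape, dtype=int)
        for r in self.regions:
            occupancy += r.indicator(self.grid_shape)
        if np.any(occupancy > 1):
            raise ValidationError("phantom regions overlap")


@dataclass(frozen=True)
class ArtifactEvent:
    """One slice-dropout event: slices [slice_lo, slice_hi] of one volume
    multiplied by ``attenuation`` (must be < 1 to change the signal)."""

    volume: int
    slice_lo: int
    slice_hi: int
    attenuation: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.attenuation < 1.0:
            raise ValidationError(
                f"attenuation must be in [0, 1), got {self.attenuation}"
            )
        if self.slice_hi < self.slice_lo:
            raise ValidationError("slice range is empty")


@dataclass
class ArtifactSpec:
    """A list of dropout events plus the derived ground-truth labels."""

    events: list[ArtifactEvent] = field(default_factory=list)

    @property
    def corrupted_volumes(self) -> set[int]:
        return {e.volume for e in self.events}

    def corruption_mask(self, n_volumes: int, n_slices: int) -> np.ndarray:
        mask = np.zeros((n_volumes, n_slices), dtype=bool)
        for e in self.events:
            mask[e.volume, e.slice_lo:e.slice_hi + 1] = True
        return mask


def default_gradient_scheme(n_high: int = 64, n_low: int = 8,
                            b_high: float = 1000.0, b_low: float = 100.0) -> GradientTable:
    """Deterministic gradient table: Fibonacci hemisphere + low-b anchors.

    The ``n_high`` diffusion directions are placed on a spherical
    Fibonacci lattice restricted to the upper hemisphere, which spreads
    them near-uniformly (antipodal symmetry makes the lower hemisphere
    redundant). The ``n_low`` low-b volumes share direction (0, 0, 1),
    or the zero vector when ``b_low`` is 0.
    """
    if n_high < 6:
        raise ValidationError("at least 6 diffusion directions are required")
    i = np.arange(n_high)
    z = (i + 0.5) / n_high  # uniform in (0, 1]: upper hemisphere
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(1.0 - z ** 2)
    high = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    low_dir = (0.0, 0.0, 1.0) if b_low > 0 else (0.0, 0.0, 0.0)
    low = np.tile(low_dir, (n_low, 1))
    directions = np.vstack([high, low]) if n_low else high
    bvalues = np.concatenate([np.full(n_high, b_high), np.full(n_low, b_low)])
    return GradientTable(directions, bvalues)


def default_phantom_spec(grid_shape=(32, 32, 40), voxel_size=(2.3, 2.3, 2.3),
                         s0: float = 1000.0) -> PhantomSpec:
    """Default phantom: isotropic block + anisotropic slab + background.

    The isotropic region diffuses at 0.7·10⁻³ mm²/s in every direction
    (FA 0); the slab carries eigenvalues (1.7, 0.3, 0.3)·10⁻³ mm²/s with
    the principal axis along x (FA ≈ 0.80). Both span the full slice
    range so every axial slice contains foreground, and a background rim
    is left around them. The slab occupies about a quarter of the
    foreground: in a real axial brain slice no single fiber orientation
    dominates the slice mean, so the direction-dependent swing of
    whole-slice intensities is kept correspondingly modest.
    """
    nx, ny, nz = grid_shape
    x0, x1 = nx // 8, nx - nx // 8
    y0, y1 = ny // 8, ny - ny // 8
    z0, z1 = 1, nz - 1
    y_slab = y0 + (y1 - y0) * 3 // 4
    iso = Region(
        name="isotropic",
        bounds=((x0, x1), (y0, y_slab), (z0, z1)),
        eigenvalues=(0.7e-3, 0.7e-3, 0.7e-3),
    )
    slab = Region(
        name="anisotropic_slab",
        bounds=((x0, x1), (y_slab, y1), (z0, z1)),
        eigenvalues=(1.7e-3, 0.3e-3, 0.3e-3),
        principal_axis=(1.0, 0.0, 0.0),
    )
    return PhantomSpec(grid_shape=grid_shape, voxel_size=voxel_size,
                       regions=(iso, slab), s0=s0)


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking e_x onto ``axis`` (unit)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    ex = np.array([1.0, 0.0, 0.0])
    v = np.cross(ex, a)
    c = float(np.dot(ex, a))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def build_phantom(spec: PhantomSpec) -> TensorField:
    """Assemble the ground-truth tensor field from the region list."""
    shape = spec.grid_shape
    tensor = np.zeros(shape + (6,))
    s0 = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    for region in spec.regions:
        ind = region.indicator(shape)
        R = _rotation_to(np.asarray(region.principal_axis))
        D = R @ np.diag(region.eigenvalues) @ R.T
        comps = np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]])
        tensor[ind] = comps
        s0[ind] = spec.s0
        mask |= ind
    return TensorField(tensor=tensor, s0=s0, mask=mask)


def ground_truth_fa(truth: TensorField) -> np.ndarray:
    """Analytic FA of the ground-truth field (sentinel 0 off-mask)."""
    eigvals = np.linalg.eigvalsh(truth.as_matrices())
    return np.where(truth.mask, _fa_from_stacked(eigvals), 0.0)


def simulate_signal(truth: TensorField, gradients: GradientTable,
                    snr: float | None = None, seed: int = 0,
                    voxel_size=(2.3, 2.3, 2.3)) -> DWIDataset:
    """Forward-simulate the monoexponential tensor signal, optionally
    corrupted by Rician noise.

    Per voxel and volume, S = S0 · exp(−b gᵀ D g). With ``snr`` given,
    two independent Gaussian channels of width σ = (mean foreground S0)
    / snr are added and the magnitude taken — the Rician model of
    magnitude MRI. ``snr=None`` means noise-free. Reproducible for a
    fixed ``seed``.
    """
    if snr is not None and snr <= 0:
        raise ValidationError("snr must be positive")
    g = gradients.directions
    b = gradients.bvalues
    D = truth.as_matrices()  # (X, Y, Z, 3, 3)
    # quadratic form gᵀ D g for every voxel and volume: (X, Y, Z, V)
    quad = np.einsum("vi,...ij,vj->...v", g, D, g)
    signal = truth.s0[..., None] * np.exp(-b * quad)
    if snr is not None:
        rng = np.random.default_rng(seed)
        sigma = float(truth.s0[truth.mask].mean()) / snr if truth.mask.any() else 0.0
        real = signal + rng.normal(0.0, sigma, signal.shape)
        imag = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt(real ** 2 + imag ** 2)
    return DWIDataset(
        intensities=signal,
        voxel_size=np.asarray(voxel_size, dtype=float),
        gradients=gradients,
    )


def inject_artifacts(dataset: DWIDataset, spec: ArtifactSpec):
    """Apply slice-dropout events; return (corrupted dataset, labels).

    Each event multiplies the intensities of its slice range in its
    volume by the attenuation factor. The returned labels are the
    corrupted-volume set and the per-(volume, slice) corruption mask.
    """
    V, Z = dataset.n_volumes, dataset.n_slices
    for e in spec.events:
        if not (0 <= e.volume < V and 0 <= e.slice_lo and e.slice_hi < Z):
            raise ValidationError(
                f"artifact event out of range: volume {e.volume}, "
                f"slices {e.slice_lo}-{e.slice_hi} for a ({V}, {Z}) dataset"
            )
    data = dataset.intensities.copy()
    for e in spec.events:
        data[:, :, e.slice_lo:e.slice_hi + 1, e.volume] *= e.attenuation
    corrupted = DWIDataset(
        intensities=data,
        voxel_size=dataset.voxel_size,
        gradients=dataset.gradients,
        affine=dataset.affine,
        original_indices=dataset.original_indices,
    )
    labels = {
        "corrupted_volumes": spec.corrupted_volumes,
        "corruption_mask": spec.corruption_mask(V, Z),
    }
    return corrupted, labels


def simulate_study_dataset(seed: int = 0, snr: float | None = 20.0,
                           artifact_spec: ArtifactSpec | None = None,
                           n_high: int = 64, n_low: int = 8,
                           b_high: float = 1000.0, b_low: float = 100.0,
                           grid_shape=(32, 32, 40)):
    """One-call study condition: default phantom, default scheme, noise,
    optional artifacts.

    Returns (dataset, truth TensorField, labels dict); labels hold empty
    sets when no artifacts were requested.
    """
    spec = default_phantom_spec(grid_shape=grid_shape)
    truth = build_phantom(spec)
    scheme = default_gradient_scheme(n_high, n_low, b_high, b_low)
    clean = simulate_signal(truth, scheme, snr=snr, seed=seed,
                            voxel_size=spec.voxel_size)
    if artifact_spec is None:
        artifact_spec = ArtifactSpec()
    corrupted, labels = inject_artifacts(clean, artifact_spec)
    return corrupted, truth, labels
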