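# Methods

## Detection model

The detector targets motion-induced slice dropouts: a subject movement
during one diffusion-encoded acquisition attenuates the signal in one
or a few axial slices of that single volume. Detection operates on
whole-slice mean intensities. For slice *z* of volume *j* in a b-shell
of V volumes, the pairwise relative deviation against volume *i* is

    ΔI_ji(z) = |ā_i(z) − ā_j(z)| / (ā_i(z) + ā_j(z)),

a symmetric, scale-invariant quantity in [0, 1]. The per-slice
statistic averages these over the N = V − 1 comparison volumes with
direction-similarity weights:

    ΔI_j(z) = Σ_{i≠j} w_ij ΔI_ji(z) / Σ_{i≠j} w_ij,
    w_ij = |g_i · g_j|.

A volume is removed in full when any evaluated slice exceeds the
threshold. Removing only the slice would leave a partially sampled
gradient direction in the tensor fit; whole-volume elimination keeps
the fit design clean.

Assumptions: dropouts are restricted to a minority of volumes per shell
(the weighted reference is a robust mean only when most companions are
clean); slice means carry enough signal that a ratio statistic is
stable (background slices are excluded, see below); and the acquisition
is single-shell per partition, so intensity differences within a
partition reflect direction contrast and artifact, not b-value.

### Normalization of the weighted average

The statistic divides by Σw rather than by the fixed N. The
unnormalized variant (available as `normalize_weights=False`) has an
upper ceiling of mean(w) · ΔI_ji ≈ 0.5 · ΔI_ji for a dense uniform
direction set, which makes a fixed threshold mean different things on
different gradient schemes — and puts a dropout of attenuation 0.5
(pairwise deviation (1−0.5)/(1+0.5) = 1/3) permanently below a 0.2
threshold. Normalizing by Σw makes ΔI_j a true weighted average of
quantities in [0, 1]: scheme-independent, bounded, and directly
comparable to the 0.2 default threshold. This is the package default.

### Antipodal weighting

Diffusion encoding is invariant under g → −g, so antipodal directions
produce identical contrast and should be maximally similar. The default
weight is |g_i·g_j| (`antipodal_weights=True`); a signed variant
clipped below at zero exists for literal fidelity to the dot-product
formulation. On hemisphere-only schemes (such as the built-in one) the
two rarely differ materially; on whole-sphere schemes the signed
variant discards half the comparisons.

### Thresholds and their robustness

Default threshold 0.2, exposed as `--threshold`. A clean slice's ΔI_j
reflects residual direction contrast and noise; on the default phantom
at SNR 20 it stays below ≈ 0.06, leaving a wide margin to 0.2. A
dropout of attenuation α drives the statistic to ≈ (1−α)/(1+α): 1/3 at
α = 0.5, 0.43 at α = 0.4, 0.54 at α = 0.3. Consequently thresholds 0.2
and 0.3 flag identical volume sets for artifacts with α ≤ 0.4, while at
α = 0.5 the artifact's own value (1/3, minus a small concavity bias
from direction contrast) sits so close to 0.3 that threshold agreement
cannot be guaranteed there — a 0.3 threshold probes the exact deviation
such an artifact produces. Detection itself at the 0.2 default remains
exact at α = 0.5 (verified over 20 seeds in the test suite).

### Background slices

Slices whose mean falls below the background floor in any volume of the
shell are excluded from evaluation (NaN in the deviation matrix, never
flagged). The floor defaults to 5% of the robust maximum (99th
percentile) of the shell's slice means; the ratio statistic is
otherwise unstable at the brain apex/base where means approach the
noise floor. A caller-supplied brain mask restricts the means instead,
with the floor still applied.

### Small shells

Each clean volume's statistic includes ~ΔI/N from every corrupted
companion. With very small shells this back-reaction can flag clean
volumes: at N = 2 (three low-b volumes), a companion dropout of
attenuation 0.4 contributes 0.43/2 ≈ 0.21 > 0.2 to each clean volume.
Acquisitions in the emulated protocols carry 7–8 low-b volumes, where
the effect is diluted below threshold; users with fewer low-b volumes
should review low-b flags manually.

### Voxel-level review statistic

The review panel complements the slice-mean detector with a per-voxel
count: for each index volume, every voxel's signal is compared with its
direction-weighted mean across the other volumes, and the panel counts
voxels deviating by more than two direction-weighted standard
deviations per (volume, slice) cell. The weighted moments use the same
similarity weights normalized to sum 1; the weighted SD is the square
root of the weighted second central moment. With zero spread, only an
exact mismatch counts (a tiny relative tolerance absorbs floating-point
jitter).

## Tensor fit and FA

The single-tensor signal model S = S0 exp(−b gᵀ D g) is fitted per
voxel by ordinary least squares on log intensities, with design rows
(−b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz, 1). The
exponentiated intercept is the effective b = 0 image; low-b volumes
enter as ordinary rows with their true b-value and anchor the
intercept. No weighting or iterative reweighting is applied. Zero or
tiny intensities are clamped to 1e−4 of a per-voxel S0 estimate before
the log (the Rician floor can produce zeros). Rank-deficient designs
(fewer than 6 non-collinear directions plus intercept information) are
rejected.

FA = sqrt(1/2 · [(λ1−λ2)² + (λ2−λ3)² + (λ1−λ3)²] / (λ1² + λ2² + λ3²)),
with negative eigenvalues clipped to 0 first (keeps FA in [0, 1];
standard practice) and FA = 0 for an all-zero triple. The default
foreground mask keeps voxels whose effective S0 exceeds 10% of its
99th-percentile robust maximum.

Gaussian smoothing of FA maps (σ = FWHM / (2√(2 ln 2)) per axis, mm
converted to voxels) is provided for pipeline parity with 8×8×8 mm
kernels; it is masked-renormalized so constants are preserved and
background never bleeds in, and it is off by default.

After QC removal, a tensor fit is refused when fewer than 7 volumes,
fewer than 6 distinct (antipodal-collapsed) b > 0 directions, no low-b
anchor, or a rank-deficient design would remain.

## Synthetic phantom

The simulator emulates a single-shell clinical acquisition: by default
64 unique directions at b = 1000 s/mm² on a deterministic spherical
Fibonacci hemisphere lattice plus 8 low-b (b = 100 s/mm²) volumes
sharing direction (0, 0, 1), a 32×32×40 grid at 2.3 mm isotropic
(40 axial slices), and baseline S0 = 1000.

The default phantom holds an isotropic region (λ = 0.7·10⁻³ mm²/s,
FA 0) and a coherent anisotropic slab (λ = (1.7, 0.3, 0.3)·10⁻³ mm²/s,
principal axis x, FA ≈ 0.80) inside a signal-free background rim; both
regions span the slice range so every slice contains foreground. The
slab occupies about a quarter of the foreground: in a real axial brain
slice no single fiber orientation dominates the slice mean, and this
proportion keeps the direction-dependent swing of whole-slice means
realistically modest. A half-foreground coherent slab would swing slice
means by ±30% across directions, which whole-slice averages of real
brains do not show.

Noise is Rician: two independent Gaussian channels of width
σ = mean(foreground S0)/SNR, combined as a magnitude. The default
SNR 20 refers to the b ≈ 0 signal; diffusion-weighted volumes
consequently sit at lower effective SNR (≈ 10 at b = 1000 in the
isotropic region). One consequence worth knowing: noise induces a
positive FA floor in isotropic tissue — with the default 64-direction
scheme at SNR 30 the median isotropic-region FA measures ≈ 0.05, and
more with sparser schemes. This is a property of eigenvalue dispersion
under noise, not an implementation artifact.

Dropout artifacts are modeled as multiplicative attenuation of whole
slices of chosen volumes (uniform within slice), applied to the
already-noisy magnitude data, with the injected (volume, slice) set
returned as ground-truth labels. Real dropouts are richer —
partial-slice, interleave-striped, spin-history effects — so passing
detection tests here demonstrates sensitivity to the dominant
whole-slice dropout mode, not to every artifact morphology. Eddy
currents, susceptibility distortion and cardiac pulsation are not
simulated, and the phantom has no realistic anatomy; results on it
bound what the statistic can do under its stated model only.

All randomness flows from one user-supplied seed through a single
`numpy.random.Generator`.

## Problem sizes and determinism

The validation suite runs the full 72-volume, 32×32×40 study condition
for end-to-end checks (a single simulate + QC + two tensor fits takes
~2 s), 20-seed suites for detection recovery, and small grids
(16×16×12 and below) for unit-level properties; the whole suite
completes in well under a minute. `scripts/acceptance.py` recomputes
the clean-data deviation maximum and the QC-vs-no-QC median |ΔFA| at
the full default condition from a single seed. Identical inputs give
byte-identical outputs throughout; Hypothesis runs derandomized.

## Design choices where the design was open

- Directions are kept in the image frame as read; no affine
  reorientation (only relative angles matter to the statistic).
- Eq.-style summation over comparisons excludes the index volume
  (the self term has weight 1 and deviation 0 and would only dilute).
- The b-split between shells defaults to 500 s/mm², midway between the
  emulated low-b (100) and high-b (1000) values.
- Shell partitions retain original volume indices as metadata, so
  flags, reports and removals always refer to acquisition indices.
- The low-b shell uses uniform weights when its volumes share one
  direction (or carry zero vectors): there is no direction contrast to
  weight by at b = 100.
- The weighted-SD definition behind the review panel (normalized
  weighted central moments) is a stated choice; other defensible
  definitions (frequency weights, unbiased corrections) differ only at
  small V.

## Known limitations

- Exclusion-only repair: corrupted volumes are dropped, never
  interpolated or imputed; with aggressive thresholds on sparse schemes
  the remaining design can become insufficient (the fit then refuses).
- No motion or eddy-current registration; the statistic assumes slices
  stay spatially aligned across volumes apart from the dropout itself.
- Whole-volume elimination is deliberately conservative for
  multi-slice partial artifacts.
- Detection guarantees are characterized for attenuation ≤ 0.5 at
  SNR ≥ 20 with ≥ 30 well-spread directions; weaker artifacts
  (attenuation closer to 1) approach the clean-data deviation floor
  and are not reliably separable by any fixed threshold on this
  statistic.
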