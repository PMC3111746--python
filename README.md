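# sliceqc

Slicewise quality control for diffusion-weighted MRI (DWI).

Subject motion during a diffusion-weighted acquisition can wipe out the
signal in one or more axial slices of a single diffusion-encoded volume.
Left in the data, such slice dropouts bias the diffusion tensor fit and
the fractional anisotropy (FA) maps derived from it — a particular
concern in clinical cohorts (movement disorders, pediatrics) where
motion is both more common and correlated with the group of interest.
`sliceqc` detects these corrupted volumes automatically, removes them,
and quantifies the effect of the cleanup on the resulting FA maps. A
built-in tensor-phantom simulator with ground-truth artifact labels
makes the whole pipeline testable end to end.

## The detection statistic

Different gradient directions produce genuinely different image
contrast, so a slice cannot be compared with the same slice in other
volumes on equal terms. Each comparison is instead weighted by the
similarity of the two diffusion directions — the dot product of their
unit gradient vectors. For slice position *z* of volume *j*, with ā
denoting within-slice mean intensity, the pairwise relative deviation is

    ΔI_ji = |ā_i − ā_j| / (ā_i + ā_j)        ∈ [0, 1]

and the per-slice statistic is the direction-weighted average over the
comparison volumes *i* ≠ *j*:

    ΔI_j = Σ_i w_ij ΔI_ji / Σ_i w_ij,   w_ij = |g_i · g_j|

A volume is eliminated in full as soon as any of its slices exceeds the
detection threshold (default 0.2; detection is robust for choices in
0.2–0.3). The statistic is computed separately per b-shell, since
intensities are not comparable across diffusion weightings. The
absolute value in the weight reflects the g → −g symmetry of diffusion
encoding; a signed variant and an unnormalized (divide by N = V − 1)
variant are available as configuration switches.

After cleanup the diffusion tensor is fitted per voxel by ordinary
least squares on log signals (`log S = log S0 − b gᵀ D g`), which also
yields an effective b = 0 image from the intercept, and FA is computed
from the tensor eigenvalues.

## Worked example

Simulate a 20-direction phantom with one injected dropout (volume 4,
slices 5–6, attenuation 0.4), run QC, and score it against the ground
truth:

```
$ sliceqc simulate --shape 16 16 12 --n-directions 20 --n-lowb 2 \
      --seed 3 --artifact "4:5-6:0.4" --out demo
wrote demo.nii.gz (22 volumes, 1 corrupted)

$ sliceqc qc --in demo.nii.gz --report qc.tsv --panel panel.png --out cleaned
flagged 1 of 22 volumes: [4]
wrote cleaned dataset (21 volumes) to cleaned.nii.gz

$ sliceqc evaluate --qc-report qc.tsv --truth demo_truth.json
{"tp": 1, "fp": 0, "fn": 0, "tn": 21,
 "sensitivity": 1.0, "specificity": 1.0, "jaccard": 1.0, "n_volumes": 22}
```

The QC run flagged exactly the injected volume: sensitivity and
specificity are both 1. `qc.tsv` lists, per volume, the worst slice and
its ΔI_j (clean volumes here sit at 0.02–0.05, far below the 0.2
threshold), and `panel.png` shows the volume × slice review heatmaps.
Fitting FA with and without the flagged volume and comparing:

```
$ sliceqc fa --in demo.nii.gz --out fa_all.nii
wrote FA map to fa_all.nii (foreground mean FA 0.3339, n=1511)
$ sliceqc fa --in demo.nii.gz --qc-report qc.tsv --out fa_qc.nii
wrote FA map to fa_qc.nii (foreground mean FA 0.3147, n=1511)
$ sliceqc compare-fa fa_all.nii fa_qc.nii
{"median_abs_dfa": 0.0123, ..., "frac_ge_0.1": 0.118, "n_voxels": 1511}
```

The median per-voxel |ΔFA| from removing the corrupted volume is about
0.01 — small for most voxels — while 12% of voxels (those under the
dropout slices of this deliberately small acquisition) move by 0.1 or
more, which is exactly the kind of localized bias the QC step exists to
remove.

The same functions are available as a library: `run_qc`, `apply_qc`,
`fit_tensor`, `compute_fa_map`, `simulate_study_dataset`, etc. — see
the module docstrings in `src/sliceqc/`.

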