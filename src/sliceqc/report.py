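"""Detection evaluation against ground truth and the QC review panel."""

from __future__ import annotations

import numpy as np

from .io import ValidationError
from .qc import DeviationMatrix, QCReport

__all__ = ["evaluate_detection", "render_review_panel", "report_to_rows"]


def evaluate_detection(qc_report: QCReport, truth_labels: dict,
                       n_volumes: int | None = None) -> dict:
    """Volume-level confusion counts of flagged vs truly corrupted volumes.

    ``truth_labels`` is the labels dict the simulator returns (or any
    mapping with a ``corrupted_volumes`` set). Returns sensitivity,
    specificity, the Jaccard index of the two sets, and the raw counts.
    Conventions for empty classes: sensitivity is 1.0 when nothing was
    corrupted, specificity 1.0 when everything was.
    """
    flagged = set(int(v) for v in qc_report.flagged_volumes)
    truth = set(int(v) for v in truth_labels["corrupted_volumes"])
    if n_volumes is None:
        mask = truth_labels.get("corruption_mask")
        if mask is not None:
            n_volumes = np.asarray(mask).shape[0]
        else:
            n_volumes = max(flagged | truth, default=-1) + 1
    universe = set(range(n_volumes))
    if not (flagged <= universe and truth <= universe):
        raise ValidationError("flagged or truth volumes outside the dataset range")

    tp = len(flagged & truth)
    fp = len(flagged - truth)
    fn = len(truth - flagged)
    tn = len(universe - flagged - truth)
    union = len(flagged | truth)
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / len(truth) if truth else 1.0,
        "specificity": tn / (tn + fp) if (tn + fp) else 1.0,
        "jaccard": tp / union if union else 1.0,
        "n_volumes": n_volumes,
    }


def render_review_panel(deviation: DeviationMatrix, outlier_counts: np.ndarray,
                        out_path) -> None:
    """Write the two-panel QC review figure (volume × slice heatmaps).

    Left: the weighted slice deviation ΔI_j; right: the count of voxels
    deviating by more than 2 weighted standard deviations from their
    direction-weighted average. Volumes run along x, slices along y.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    counts = np.asarray(outlier_counts)
    if counts.shape != deviation.delta.shape:
        raise ValidationError("deviation and outlier counts come from different datasets")

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.2))
    im0 = axes[0].imshow(deviation.delta.T, origin="lower", aspect="auto",
                         cmap="viridis", interpolation="nearest")
    axes[0].set_title(r"slice deviation $\Delta I_j$")
    fig.colorbar(im0, ax=axes[0])
    im1 = axes[1].imshow(counts.T, origin="lower", aspect="auto",
                         cmap="magma", interpolation="nearest")
    axes[1].set_title("voxels > 2 weighted SD from average")
    fig.colorbar(im1, ax=axes[1])
    for ax in axes:
        ax.set_xlabel("volume (gradient direction)")
        ax.set_ylabel("slice")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def report_to_rows(qc_report: QCReport) -> list[dict]:
    """Flatten a QCReport into TSV-ready rows, one per volume."""
    rows = []
    for vol in sorted(qc_report.worst_slice_per_volume):
        z, dval = qc_report.worst_slice_per_volume[vol]
        rows.append({
            "volume_index": vol,
            "shell": qc_report.volume_shells.get(vol, ""),
            "worst_slice": z,
            "delta_I": f"{dval:.6f}" if np.isfinite(dval) else "nan",
            "flagged": int(vol in qc_report.flagged_volumes),
        })
    return rows
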