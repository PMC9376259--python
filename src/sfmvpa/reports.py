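"""Small reporting helpers shared by the CLI and examples."""

from __future__ import annotations

import numpy as np

__all__ = ["average_condition_accuracy", "cluster_report"]


def average_condition_accuracy(accuracies) -> float:
    """Equal-weighted mean of per-condition behavioral accuracies (%).

    E.g. the four memory-load conditions' accuracies averaged into one
    summary percentage.
    """
    accuracies = np.asarray(accuracies, float)
    if accuracies.size == 0:
        raise ValueError("need at least one accuracy")
    return float(accuracies.mean())


def cluster_report(cluster_set, stat, centers=None, names=None):
    """Cluster table: -log10(p) at the peak label, size in mm^2, peak coordinates."""
    import pandas as pd

    rows = []
    for i, c in enumerate(cluster_set):
        p_peak = float(np.asarray(stat.p).ravel()[c.peak])
        row = {"cluster": i,
               "neg_log10_p": float(-np.log10(max(p_peak, 1e-300))),
               "size_labels": c.size,
               "size_mm2": c.area_mm2,
               "peak_label": c.peak,
               "region": names[i] if names else ""}
        if centers is not None:
            row.update(zip(("peak_x", "peak_y", "peak_z"), np.asarray(centers)[c.peak]))
        rows.append(row)
    return pd.DataFrame(rows)
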