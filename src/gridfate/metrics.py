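"""Evaluation metrics for lineage intensity and clustering quality.

MAS (manifold alignment score) and PAAC (principal axis alignment
coefficient) measure how strongly a lineage intensity vector aligns with a
2-D embedding's axes or with the first two principal components: each is
the mean absolute Pearson correlation with the two axes.  The standard
external/internal clustering metrics (ARI, NMI, silhouette, Calinski-
Harabasz, Davies-Bouldin) are delegated to scikit-learn; the min-max
comprehensive score combines them across methods with the
Davies-Bouldin column inverted (lower is better).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    normalized_mutual_info_score,
    silhouette_score,
)

__all__ = [
    "mas",
    "paac",
    "clustering_metrics",
    "comprehensive_score",
    "percentile_mask",
]


def _mean_abs_pearson(lineage: np.ndarray, axes: np.ndarray, what: str) -> float:
    L = np.asarray(lineage, dtype=float)
    A = np.asarray(axes, dtype=float)
    if A.ndim != 2 or A.shape[1] != 2:
        raise ValueError(f"{what} must be a (cells, 2) matrix")
    if L.shape[0] != A.shape[0] or L.shape[0] < 2:
        raise ValueError("lineage vector and axes must share >= 2 cells")
    if np.std(L) == 0:
        raise ValueError("lineage intensity is constant; Pearson undefined")
    total = 0.0
    for col in range(2):
        u = A[:, col]
        if np.std(u) == 0:
            raise ValueError(f"{what} column {col} is constant; Pearson undefined")
        total += abs(np.corrcoef(L, u)[0, 1])
    return total / 2.0


def mas(lineage: np.ndarray, umap: np.ndarray) -> float:
    """Manifold alignment score: mean |Pearson| with the two embedding axes."""
    return _mean_abs_pearson(lineage, umap, "embedding")


def paac(lineage: np.ndarray, pcs: np.ndarray) -> float:
    """Principal axis alignment coefficient: mean |Pearson| with PC1/PC2."""
    return _mean_abs_pearson(lineage, pcs, "principal components")


def clustering_metrics(
    labels_true, labels_pred, features: np.ndarray
) -> dict:
    """ARI, NMI, ASW (silhouette), CH and DB for a predicted clustering.

    The internal metrics (ASW, CH, DB) require at least two predicted
    clusters.
    """
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    features = np.asarray(features, dtype=float)
    if np.unique(labels_pred).size < 2:
        raise ValueError("internal metrics require at least 2 predicted clusters")
    return {
        "ARI": float(adjusted_rand_score(labels_true, labels_pred)),
        "NMI": float(normalized_mutual_info_score(labels_true, labels_pred)),
        "ASW": float(silhouette_score(features, labels_pred)),
        "CH": float(calinski_harabasz_score(features, labels_pred)),
        "DB": float(davies_bouldin_score(features, labels_pred)),
    }


def comprehensive_score(
    metric_table: pd.DataFrame, minimize: tuple = ("DB",)
) -> pd.Series:
    """Overall score per method: mean of min-max scaled metric columns.

    Columns named in ``minimize`` (Davies-Bouldin by default) are inverted
    so that 1 is always best.  A constant column carries no ranking
    information and is scaled to 0 with a warning.
    """
    if metric_table.shape[0] < 2:
        raise ValueError("need at least 2 methods to compare")
    scaled = pd.DataFrame(index=metric_table.index, dtype=float)
    for col in metric_table.columns:
        x = metric_table[col].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            warnings.warn(f"metric column {col!r} is constant; scaled to 0",
                          stacklevel=2)
            scaled[col] = 0.0
            continue
        s = (x - lo) / (hi - lo)
        scaled[col] = 1.0 - s if col in minimize else s
    return scaled.mean(axis=1)


def percentile_mask(intensity: np.ndarray, q: float) -> np.ndarray:
    """Binary labels: 1 at or above the q-th percentile of intensity.

    The baseline decision-region labelling used when comparing percentile
    cuts of lineage intensities (e.g. q of 95, 90, 85, 80); the percentile
    is computed with linear interpolation and threshold ties label 1.
    """
    if not 0 < q < 100:
        raise ValueError("q must be in (0, 100)")
    x = np.asarray(intensity, dtype=float)
    thr = np.percentile(x, q)
    return (x >= thr).astype(int)
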