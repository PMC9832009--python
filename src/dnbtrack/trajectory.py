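"""PCA trajectory of samples over time and per-timepoint dispersion.

The temporal expression matrix is reduced to its first two principal
components for trajectory visualization; per-timepoint dispersion (mean
Euclidean distance of replicates to their timepoint centroid in the
embedding) quantifies the elevated sample-to-sample variability expected
just before a critical transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import AnalysisError
from .io import ExpressionMatrix, TimeCourseDesign

__all__ = ["Embedding", "pca_embed", "marker_overlay", "timepoint_dispersion"]


@dataclass
class Embedding:
    """Sample coordinates on the first two principal components."""

    sample_ids: list[str]
    coordinates: np.ndarray  # n_samples x 2
    variance_explained: np.ndarray  # fractions, non-increasing

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)
        if self.coordinates.shape != (len(self.sample_ids), 2):
            raise AnalysisError("embedding must be n_samples x 2")
        ve = self.variance_explained
        if np.any(ve < -1e-12) or np.any(ve > 1 + 1e-12) or ve.sum() > 1 + 1e-9:
            raise AnalysisError("variance_explained fractions must lie in [0,1], sum <= 1")
        if len(ve) == 2 and ve[0] < ve[1] - 1e-12:
            raise AnalysisError("variance_explained must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "pc1": self.coordinates[:, 0], "pc2": self.coordinates[:, 1]}
        )


def pca_embed(e: ExpressionMatrix, scale: bool = False) -> Embedding:
    """Embed samples on the first two principal components.

    Genes are centered (and optionally scaled to unit variance) before the
    decomposition.  Sign convention: each component's loading vector is
    flipped so that its largest-magnitude loading is positive, making the
    embedding deterministic across runs and sample orders.
    """
    n = len(e.sample_ids)
    if n < 3:
        raise AnalysisError(f"PCA trajectory needs >= 3 samples, got {n}")
    x = e.values.T.copy()  # samples x genes
    x -= x.mean(axis=0)
    if scale:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x /= sd
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(x)
    for j in range(coords.shape[1]):
        load = pca.components_[j]
        top = int(np.argmax(np.abs(load)))
        if load[top] < 0:
            coords[:, j] *= -1
    return Embedding(
        sample_ids=list(e.sample_ids),
        coordinates=coords,
        variance_explained=pca.explained_variance_ratio_,
    )


def marker_overlay(emb: Embedding, e: ExpressionMatrix, gene: str) -> pd.DataFrame:
    """Min-max scaled expression of one gene aligned to embedding coordinates.

    A constant gene maps to 0 everywhere by convention.
    """
    idx = e.gene_index([gene])[0]
    sub = e.subset_samples(emb.sample_ids)
    vals = sub.values[idx]
    span = vals.max() - vals.min()
    rel = np.zeros_like(vals) if span == 0 else (vals - vals.min()) / span
    out = emb.to_frame()
    out["relative_expression"] = rel
    return out


def timepoint_dispersion(emb: Embedding, d: TimeCourseDesign) -> pd.DataFrame:
    """Mean Euclidean distance of each time point's samples to their centroid.

    Singleton time points have undefined dispersion and are reported as
    missing.  Returns a table with a ``is_max`` column marking the argmax
    time point (earliest on ties).
    """
    pos = {s: i for i, s in enumerate(emb.sample_ids)}
    rows = []
    for t in d.time_points:
        samples = [s for s in d.samples_at(t) if s in pos]
        if len(samples) < 1:
            continue
        if len(samples) == 1:
            rows.append({"time_weeks": t, "n_samples": 1, "dispersion": np.nan})
            continue
        pts = emb.coordinates[[pos[s] for s in samples]]
        centroid = pts.mean(axis=0)
        disp = float(np.linalg.norm(pts - centroid, axis=1).mean())
        rows.append({"time_weeks": t, "n_samples": len(samples), "dispersion": disp})
    out = pd.DataFrame(rows)
    disp = out["dispersion"].to_numpy()
    out["is_max"] = False
    if np.any(np.isfinite(disp)):
        out.loc[int(np.nanargmax(disp)), "is_max"] = True
    return out
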