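"""Per-salinity PCA of compositional profiles and temperature trajectories.

Within one salinity stratum, relative fatty-acid proportions (% of TFA) of
all samples are ordinated by PCA on the correlation matrix (centred,
unit-variance columns; covariance PCA is selectable).  For each host the
temperature-ordered centroids of the scores trace a *lipid trajectory* in
the PC1–PC2 plane; the angle between the two hosts' net displacement
vectors quantifies whether their compositional responses to warming are
aligned, orthogonal or opposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .fame import DlPolicy, ProfileSet

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryResult",
    "build_trajectory",
    "pca_profiles",
    "trajectory_divergence",
]


@dataclass
class TrajectoryResult:
    """PCA ordination of one salinity stratum plus per-host centroid paths."""

    salinity: float
    scores: pd.DataFrame  # samples × PCs
    loadings: pd.DataFrame  # fatty acids × PCs
    inertia_pct: np.ndarray  # % of total variance per axis, sums to 100
    meta: pd.DataFrame  # sample metadata aligned with scores
    paths: dict[str, pd.DataFrame]  # host -> temperature-ordered centroids
    dropped: list[str]  # fatty acids excluded (constant or unobserved)


def pca_profiles(
    profiles: ProfileSet,
    salinity: float,
    scaling: str = "correlation",
    policy: DlPolicy | None = None,
) -> TrajectoryResult:
    """Centred (and by default unit-variance) PCA of proportions at one salinity.

    Constant fatty acids, and fatty acids not observed in every sample of
    the stratum, are dropped with a logged notice.  Axis signs follow a
    deterministic convention — the largest-magnitude loading of each axis
    is made positive — so results do not mirror-flip between runs.
    """
    if scaling not in ("correlation", "covariance"):
        raise ValueError(f"unknown scaling {scaling!r}")
    stratum = profiles.subset(salinity=salinity)
    if len(stratum) < 3:
        raise ValueError(f"need >= 3 samples at salinity {salinity}, got {len(stratum)}")

    X = stratum.to_wide(policy=policy, proportions=True)
    meta = stratum.meta_frame()

    dropped = [c for c in X.columns if X[c].isna().any()]
    if dropped:
        logger.info("salinity %g: dropping unobserved fatty acids %s", salinity, dropped)
    X = X.drop(columns=dropped)
    const = [c for c in X.columns if float(X[c].std(ddof=0)) < 1e-12]
    if const:
        logger.info("salinity %g: dropping constant fatty acids %s", salinity, const)
        dropped += const
        X = X.drop(columns=const)
    if X.shape[1] == 0:
        raise ValueError("all fatty acids constant; PCA undefined")

    Z = X - X.mean()
    if scaling == "correlation":
        Z = Z / X.std(ddof=0)

    n_axes = min(Z.shape[0] - 1, Z.shape[1])
    pca = PCA(n_components=n_axes)
    scores = pca.fit_transform(Z.to_numpy())
    load = pca.components_.T  # fatty acids × axes

    # sign convention: largest-|loading| entry of each axis made positive
    for j in range(n_axes):
        k = int(np.argmax(np.abs(load[:, j])))
        if load[k, j] < 0:
            load[:, j] *= -1
            scores[:, j] *= -1

    cols = [f"PC{j + 1}" for j in range(n_axes)]
    scores_df = pd.DataFrame(scores, index=X.index, columns=cols)
    loadings_df = pd.DataFrame(load, index=X.columns, columns=cols)
    inertia = 100.0 * pca.explained_variance_ratio_

    paths = build_trajectory(scores_df, meta)
    return TrajectoryResult(
        salinity=salinity,
        scores=scores_df,
        loadings=loadings_df,
        inertia_pct=inertia,
        meta=meta,
        paths=paths,
        dropped=dropped,
    )


def build_trajectory(scores: pd.DataFrame, meta: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Temperature-ordered per-host centroid paths in the PC1–PC2 plane."""
    axes = [c for c in ("PC1", "PC2") if c in scores.columns]
    joined = scores[axes].join(meta[["host", "temperature_C"]])
    paths: dict[str, pd.DataFrame] = {}
    for host, sub in joined.groupby("host"):
        cent = (
            sub.groupby("temperature_C")[axes]
            .mean()
            .sort_index()
            .reset_index()
        )
        paths[str(host)] = cent
    return paths


def path_length(path: pd.DataFrame) -> float:
    """Total polyline length of a centroid path in the PC1–PC2 plane."""
    pts = path[[c for c in path.columns if c.startswith("PC")]].to_numpy(float)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def trajectory_divergence(
    path_a: pd.DataFrame, path_b: pd.DataFrame
) -> tuple[float, str]:
    """Angle between two paths' net displacement vectors, with a label.

    The net displacement runs from the first to the last centroid of each
    path; angles below 60° are *aligned*, 60–120° *orthogonal*, above 120°
    *opposed*.
    """
    vecs = []
    for path in (path_a, path_b):
        if len(path) < 2:
            raise ValueError("path needs >= 2 points")
        pts = path[[c for c in path.columns if c.startswith("PC")]].to_numpy(float)
        v = pts[-1] - pts[0]
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("degenerate path: zero net displacement")
        vecs.append(v / norm)
    cosang = float(np.clip(np.dot(vecs[0], vecs[1]), -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    if angle < 60.0:
        label = "aligned"
    elif angle <= 120.0:
        label = "orthogonal"
    else:
        label = "opposed"
    return angle, label
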