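"""PCA reduction of well profiles and Mahalanobis distances from a reference
centroid.

Distances use the squared-form convention ``D = d' pinv(Sigma) d`` where
``Sigma`` is the covariance of retained principal-component scores over all
wells of the batch and the center is the mean score of the reference wells
(vehicle wells by default).  The generalized (Moore-Penrose) inverse keeps
distances finite when ``Sigma`` is singular.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import NormalizedWellProfile
from .plate_model import FeatureCatalog

logger = logging.getLogger(__name__)


class DistanceError(ValueError):
    pass


@dataclass
class PCSpace:
    """Fitted principal-component space over a well x feature profile."""

    feature_names: list[str]
    center: np.ndarray            # per-feature mean over wells
    scale: np.ndarray             # per-feature SD over wells (ddof=1)
    loadings: np.ndarray          # features x components
    component_variance: np.ndarray
    n_components: int             # retained count k
    variance_threshold: float

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.component_variance / self.component_variance.sum()

    def transform(self, profile: pd.DataFrame) -> np.ndarray:
        """Scores of wells in the retained k-dimensional space."""
        X = profile[self.feature_names].to_numpy(float)
        Xs = (X - self.center) / self.scale
        return Xs @ self.loadings[:, : self.n_components]


@dataclass
class DistanceResult:
    """Per-well squared Mahalanobis distances for one scope."""

    distances: pd.Series          # index (plate_id, well)
    scope: str                    # "global" or "category:<name>"
    reference_wells: list[tuple[str, str]]

    def sqrt(self) -> pd.Series:
        return np.sqrt(self.distances)


def fit_pca(
    profile: NormalizedWellProfile | pd.DataFrame,
    variance_threshold: float = 0.95,
) -> PCSpace:
    """Center+scale the well x feature matrix and decompose it.

    Retains the smallest k whose cumulative explained-variance fraction is
    >= ``variance_threshold``.  Features with zero variance across wells are
    dropped (their scaling is undefined) with a log entry.
    """
    mat = profile.profile if isinstance(profile, NormalizedWellProfile) else profile
    if len(mat) < 2:
        raise DistanceError("need at least 2 wells for PCA")
    X = mat.to_numpy(float)
    names = list(mat.columns)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        logger.info("PCA dropped %d constant feature(s): %s", len(dropped), dropped[:5])
        X, sd = X[:, keep], sd[keep]
        names = [n for n, k in zip(names, keep) if k]
    if X.shape[1] == 0:
        raise DistanceError("no features with nonzero variance")
    center = X.mean(axis=0)
    Xs = (X - center) / sd
    # SVD of the scaled matrix == eigendecomposition of the correlation matrix
    _, s, vt = np.linalg.svd(Xs, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    loadings = vt.T
    # fix component signs: largest-magnitude loading positive
    flip = loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])] < 0
    loadings[:, flip] *= -1.0
    total = var.sum()
    cum = np.cumsum(var) / total
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, len(var))
    return PCSpace(
        feature_names=names,
        center=center,
        scale=sd,
        loadings=loadings,
        component_variance=var,
        n_components=k,
        variance_threshold=variance_threshold,
    )


def mahalanobis_distances(
    space: PCSpace,
    profile: NormalizedWellProfile | pd.DataFrame,
    reference_wells: set[tuple[str, str]] | None = None,
    scope: str = "global",
) -> DistanceResult:
    """Squared Mahalanobis distance of every well from the reference centroid.

    ``reference_wells`` defaults to the vehicle wells of the profile.
    """
    if isinstance(profile, NormalizedWellProfile):
        mat = profile.profile
        if reference_wells is None:
            reference_wells = set(profile.vehicle_index())
    else:
        mat = profile
    if reference_wells is None or not reference_wells:
        raise DistanceError("empty reference well set")
    ref = [k for k in mat.index if k in reference_wells]
    if not ref:
        raise DistanceError("no reference wells present in profile")
    scores = space.transform(mat)
    sigma = np.atleast_2d(np.cov(scores, rowvar=False, ddof=1))
    sigma_pinv = np.linalg.pinv(sigma)
    ref_pos = [i for i, k in enumerate(mat.index) if k in reference_wells]
    mu = scores[ref_pos].mean(axis=0)
    d = scores - mu
    dist = np.einsum("ij,jk,ik->i", d, sigma_pinv, d)
    dist = np.maximum(dist, 0.0)
    return DistanceResult(
        distances=pd.Series(dist, index=mat.index, name="distance"),
        scope=scope,
        reference_wells=ref,
    )


def categorical_distances(
    profile: NormalizedWellProfile,
    catalog: FeatureCatalog,
    variance_threshold: float = 0.95,
) -> dict[str, DistanceResult]:
    """Independent PCA + distances per feature category."""
    catalog.validate_covers(profile.feature_names)
    out: dict[str, DistanceResult] = {}
    for category in catalog.categories():
        feats = [f for f in profile.feature_names if catalog.mapping[f] == category]
        if not feats:
            logger.info("category %s has no surviving features; skipped", category)
            continue
        sub = profile.profile[feats]
        try:
            space = fit_pca(sub, variance_threshold)
        except DistanceError:
            logger.info("category %s degenerate; skipped", category)
            continue
        out[category] = mahalanobis_distances(
            space, sub,
            reference_wells=set(profile.vehicle_index()),
            scope=f"category:{category}",
        )
    return out


def write_distances_csv(
    results: list[DistanceResult],
    meta: pd.DataFrame,
    path,
) -> None:
    """Serialize distance results as plate_id, well, chemical, concentration,
    scope, distance rows."""
    frames = []
    for res in results:
        df = pd.DataFrame(
            {
                "plate_id": [p for p, _ in res.distances.index],
                "well": [w for _, w in res.distances.index],
                "scope": res.scope,
                "distance": res.distances.to_numpy(),
            }
        )
        df["chemical"] = meta["chemical"].to_numpy()
        df["concentration"] = meta["concentration"].to_numpy()
        frames.append(df[["plate_id", "well", "chemical", "concentration", "scope", "distance"]])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
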