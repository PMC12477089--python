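"""DMSO-only plate study: reference-placement iterations and the regression
of Mahalanobis distance on per-well cell count.

Twenty-one normalizations of one vehicle-only plate are produced: each of the
8 rows and 12 columns is designated the solvent-control reference in turn
(20 localized iterations), plus a whole-plate iteration whose center is the
mean of all wells.  Each iteration recomputes normalization statistics from
its reference wells only, refits the PCA, and recomputes the distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .multivariate_distance import DistanceResult, fit_pca, mahalanobis_distances
from .normalization import (
    NormalizationError,
    NormalizationParams,
    filter_wells,
    scale_by_dmso_sd,
)
from .plate_model import Batch, COLUMNS, ROWS

logger = logging.getLogger(__name__)


@dataclass
class ReferenceIteration:
    """One re-normalization with a designated reference well set."""

    label: str  # "whole_plate", "row:A".."row:H", "column:1".."column:12"
    reference_wells: list[tuple[str, str]]
    distances: DistanceResult


@dataclass(frozen=True)
class RegressionSummary:
    """OLS of distance (response) on cell count (predictor)."""

    slope: float
    intercept: float
    t_value: float
    p_value: float
    adjusted_r2: float
    r2: float
    n: int


class _PlateCache:
    """Raw per-well cell arrays and raw well medians, computed once per plate.

    The well median commutes with the per-feature affine map used in
    cell-level normalization, so each reference iteration only needs the
    reference cells' median/MAD plus the cached raw well medians.
    """

    def __init__(self, batch: Batch):
        df = batch.cells.data
        self.feats = batch.feature_names
        X = df[self.feats].to_numpy(float)
        keys = pd.MultiIndex.from_arrays([df["plate_id"], df["well"]])
        codes, uniques = pd.factorize(keys, sort=False)
        order = np.argsort(codes, kind="stable")
        splits = np.nonzero(np.diff(codes[order]))[0] + 1
        self.well_cells = dict(zip(list(uniques), np.split(X[order], splits)))
        self.raw_medians = pd.DataFrame(
            np.vstack([np.median(v, axis=0) for v in self.well_cells.values()]),
            index=pd.MultiIndex.from_tuples(
                list(self.well_cells), names=["plate_id", "well"]
            ),
            columns=self.feats,
        )


def _normalize_with_reference(
    batch: Batch,
    reference_keys: set[tuple[str, str]],
    params: NormalizationParams,
    cache: _PlateCache | None = None,
) -> pd.DataFrame:
    """Cell-level robust z against reference cells, well medians, SD scaling
    by the reference wells.  Returns the normalized well x feature matrix."""
    cache = cache or _PlateCache(batch)
    ref_cells = [cache.well_cells[k] for k in cache.well_cells if k in reference_keys]
    if not ref_cells:
        raise NormalizationError("reference set has no cells")
    V = np.vstack(ref_cells)
    med = np.median(V, axis=0)
    scale = params.mad_scale_constant * np.median(np.abs(V - med), axis=0)
    keep = scale > 0
    kept = [f for f, k in zip(cache.feats, keep) if k]
    if not kept:
        raise NormalizationError("all features have zero reference MAD")
    medians = (cache.raw_medians.loc[:, kept] - med[keep]) / scale[keep]
    profile, _ = scale_by_dmso_sd(
        medians, batch.platemap, params, reference_keys=reference_keys
    )
    return profile


def iterate_reference_normalizations(
    plate: Batch,
    params: NormalizationParams = NormalizationParams(),
    variance_threshold: float = 0.95,
) -> list[ReferenceIteration]:
    """All 21 reference iterations (whole plate + 8 rows + 12 columns).

    QC filters are applied once with the standard thresholds before iterating.
    An iteration whose reference set is emptied (or reduced below two wells)
    by QC is skipped with a log entry.
    """
    roles = {w.role for w in plate.platemap}
    if roles != {"vehicle"}:
        raise NormalizationError(
            f"background analysis expects a vehicle-only plate, found roles {sorted(roles)}"
        )
    filtered, _ = filter_wells(plate, params)
    all_keys = [(w.plate_id, w.well) for w in filtered.platemap]

    labels: list[tuple[str, set[tuple[str, str]]]] = [("whole_plate", set(all_keys))]
    for r in ROWS:
        labels.append(
            (f"row:{r}", {(p, w) for p, w in all_keys if w[0] == r})
        )
    for c in COLUMNS:
        labels.append(
            (f"column:{c}", {(p, w) for p, w in all_keys if int(w[1:]) == c})
        )

    iterations: list[ReferenceIteration] = []
    cache = _PlateCache(filtered)
    for label, ref in labels:
        if len(ref) < 2:
            logger.info("iteration %s skipped: reference reduced to %d well(s)",
                        label, len(ref))
            continue
        try:
            profile = _normalize_with_reference(filtered, ref, params, cache)
            space = fit_pca(profile, variance_threshold)
            dist = mahalanobis_distances(space, profile, reference_wells=ref,
                                         scope=f"reference:{label}")
        except (NormalizationError, np.linalg.LinAlgError) as exc:
            logger.info("iteration %s skipped: %s", label, exc)
            continue
        iterations.append(
            ReferenceIteration(label=label,
                               reference_wells=sorted(ref),
                               distances=dist)
        )
    return iterations


def regress_distance_on_count(
    distances: DistanceResult | pd.Series,
    counts: dict[tuple[str, str], int],
) -> RegressionSummary:
    """OLS of per-well distance on per-well cell count."""
    d = distances.distances if isinstance(distances, DistanceResult) else distances
    y = d.to_numpy(float)
    x = np.array([counts[k] for k in d.index], float)
    if len(y) < 3:
        raise ValueError("need at least 3 wells for regression")
    if np.ptp(x) == 0:
        raise ValueError("cell counts have zero variance")
    if np.ptp(y) == 0:
        # constant response: slope exactly 0, R^2 = 0, adjusted R^2 < 0
        n = len(y)
        return RegressionSummary(
            slope=0.0, intercept=float(y[0]), t_value=0.0, p_value=1.0,
            adjusted_r2=1.0 - (n - 1) / (n - 2), r2=0.0, n=n,
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionSummary(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        t_value=float(model.tvalues[1]),
        p_value=float(model.pvalues[1]),
        adjusted_r2=float(model.rsquared_adj),
        r2=float(model.rsquared),
        n=int(model.nobs),
    )


def combined_regression(
    iterations: list[ReferenceIteration],
    counts: dict[tuple[str, str], int],
) -> RegressionSummary:
    """One OLS over the pooled (distance, count) pairs of the localized
    (non-whole-plate) iterations."""
    localized = [it for it in iterations if it.label != "whole_plate"]
    if len(localized) < 2:
        raise ValueError("need at least 2 localized iterations to pool")
    pooled = pd.concat([it.distances.distances for it in localized])
    return regress_distance_on_count(pooled, counts)


def plate_heatmap_table(values: dict[tuple[str, str], float] | dict[str, float]) -> pd.DataFrame:
    """8x12 grid (rows A-H x columns 1-12) of per-well values; missing blank.

    Keys may be well labels ("A1") or (plate_id, well) tuples for a single
    plate.
    """
    flat: dict[str, float] = {}
    for k, v in values.items():
        well = k[1] if isinstance(k, tuple) else k
        flat[well] = v
    grid = pd.DataFrame(np.nan, index=list(ROWS), columns=list(COLUMNS))
    for well, v in flat.items():
        grid.loc[well[0], int(well[1:])] = v
    return grid


def heatmap_to_values(grid: pd.DataFrame) -> dict[str, float]:
    """Inverse of :func:`plate_heatmap_table` (NaN cells omitted)."""
    out: dict[str, float] = {}
    for r in grid.index:
        for c in grid.columns:
            v = grid.loc[r, c]
            if pd.notna(v):
                out[f"{r}{int(c)}"] = float(v)
    return out


def regression_table(
    iterations: list[ReferenceIteration],
    counts: dict[tuple[str, str], int],
) -> pd.DataFrame:
    """Per-iteration regression summaries plus the pooled row."""
    rows = []
    for it in iterations:
        s = regress_distance_on_count(it.distances, counts)
        rows.append({"iteration": it.label, **s.__dict__})
    if len(iterations) > 2:
        s = combined_regression(iterations, counts)
        rows.append({"iteration": "pooled_localized", **s.__dict__})
    return pd.DataFrame(rows)
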