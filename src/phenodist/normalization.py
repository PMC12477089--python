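"""Well-level QC and the three-step vehicle-referenced normalization.

Steps, applied to a QC-filtered batch:

1. cell-level robust z: subtract the vehicle-cell median of each feature and
   divide by its (scaled) MAD, both computed over all cells of all retained
   vehicle wells in the batch;
2. aggregate cells to wells by the per-feature median;
3. divide every well median by the standard deviation of the vehicle-well
   medians, so vehicle wells have unit spread per feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .plate_model import Batch, PlateMap

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizationParams:
    """Thresholds and conventions for QC and normalization.

    ``mad_scale_constant`` defaults to 1.4826 (normal-consistency factor).
    ``zero_mad_policy`` controls degenerate features: ``drop_feature`` removes
    them with a log entry, ``fallback_sd`` substitutes the vehicle cell-level
    standard deviation for the scaled MAD.
    """

    min_cells: int = 100
    max_count_reduction: float = 0.5
    mad_scale_constant: float = 1.4826
    zero_mad_policy: str = "drop_feature"

    def __post_init__(self) -> None:
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")
        if not 0 < self.max_count_reduction <= 1:
            raise ValueError("max_count_reduction must be in (0, 1]")
        if self.mad_scale_constant <= 0:
            raise ValueError("mad_scale_constant must be positive")
        if self.zero_mad_policy not in ("drop_feature", "fallback_sd"):
            raise ValueError("zero_mad_policy must be drop_feature or fallback_sd")


@dataclass
class NormalizedWellProfile:
    """Well x feature matrix of normalized medians plus provenance.

    ``profile`` is indexed by (plate_id, well) with one column per surviving
    feature; ``meta`` carries chemical/concentration/role per well in the same
    order; ``cell_counts`` maps (plate_id, well) -> analyzable cell count;
    ``exclusions`` lists QC-dropped wells; ``dropped_features`` lists features
    removed for zero spread at either normalization stage.
    """

    profile: pd.DataFrame
    meta: pd.DataFrame
    cell_counts: dict[tuple[str, str], int]
    exclusions: pd.DataFrame
    dropped_features: list[str] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return list(self.profile.columns)

    def vehicle_index(self) -> pd.Index:
        return self.profile.index[(self.meta["role"] == "vehicle").to_numpy()]

    def write_csv(self, path: str | Path) -> None:
        out = pd.concat([self.meta.reset_index(drop=True),
                         self.profile.reset_index(drop=True)], axis=1)
        out.insert(0, "well", [w for _, w in self.profile.index])
        out.insert(0, "plate_id", [p for p, _ in self.profile.index])
        out.to_csv(path, index=False)

    def write_exclusion_log(self, path: str | Path) -> None:
        self.exclusions.to_csv(path, index=False)


def well_cell_counts(batch: Batch) -> dict[tuple[str, str], int]:
    """Analyzable cell count per mapped well; wells with no cells count 0."""
    counts = batch.cells.data.groupby(["plate_id", "well"], sort=False).size()
    out = {(w.plate_id, w.well): 0 for w in batch.platemap}
    for key, n in counts.items():
        out[key] = int(n)
    return out


def filter_wells(
    batch: Batch, params: NormalizationParams = NormalizationParams()
) -> tuple[Batch, pd.DataFrame]:
    """Drop wells failing the cell-count QC rules.

    A well is excluded when its count is strictly below ``min_cells``
    (reason ``low_count``) or its reduction relative to the median vehicle-well
    count strictly exceeds ``max_count_reduction`` (reason ``high_reduction``).
    Vehicle wells are subject to the same rules.
    """
    counts = well_cell_counts(batch)
    vehicle = batch.platemap.wells_with_role("vehicle")
    if not vehicle:
        raise NormalizationError("batch has no vehicle wells")
    vehicle_median = float(np.median([counts[(w.plate_id, w.well)] for w in vehicle]))
    if vehicle_median <= 0:
        raise NormalizationError("vehicle wells contain no cells")

    records = []
    kept: set[tuple[str, str]] = set()
    for w in batch.platemap:
        n = counts[(w.plate_id, w.well)]
        reduction = 1.0 - n / vehicle_median
        if n < params.min_cells:
            records.append((w.plate_id, w.well, "low_count", n))
        elif reduction > params.max_count_reduction:
            records.append((w.plate_id, w.well, "high_reduction", n))
        else:
            kept.add((w.plate_id, w.well))
    exclusions = pd.DataFrame(records, columns=["plate_id", "well", "reason", "n_cells"])
    if not any((w.plate_id, w.well) in kept for w in vehicle):
        raise NormalizationError("all vehicle wells excluded by QC; no reference remains")
    if len(records):
        logger.info("QC excluded %d well(s)", len(records))
    return batch.subset_wells(kept), exclusions


def _median_and_mad(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    med = np.median(values, axis=0)
    mad = np.median(np.abs(values - med), axis=0)
    return med, mad


def normalize_cell_level(
    batch: Batch, params: NormalizationParams = NormalizationParams()
) -> tuple[pd.DataFrame, list[str]]:
    """Robust z-score every cell against the batch's vehicle-cell statistics.

    Returns the per-cell normalized table (plate_id, well + features) and the
    list of features dropped for zero vehicle MAD (empty under fallback_sd).
    """
    df = batch.cells.data
    vehicle_keys = {
        f"{w.plate_id}:{w.well}" for w in batch.platemap.wells_with_role("vehicle")
    }
    is_vehicle = df["plate_id"].str.cat(df["well"], sep=":").isin(vehicle_keys)
    if not is_vehicle.any():
        raise NormalizationError("no vehicle cells in batch")
    feats = batch.feature_names
    X = df[feats].to_numpy(float)
    V = X[is_vehicle.to_numpy()]
    med, raw_mad = _median_and_mad(V)
    scale = params.mad_scale_constant * raw_mad

    dropped: list[str] = []
    zero = scale == 0
    if zero.any():
        if params.zero_mad_policy == "fallback_sd":
            sd = V.std(axis=0, ddof=1)
            scale = np.where(zero, sd, scale)
            still = scale == 0
            dropped = [f for f, z in zip(feats, still) if z]
        else:
            dropped = [f for f, z in zip(feats, zero) if z]
        if dropped:
            logger.info("dropped %d zero-spread feature(s): %s", len(dropped), dropped[:5])
    keep = [i for i, f in enumerate(feats) if f not in dropped]
    if not keep:
        raise NormalizationError("all features dropped during cell-level normalization")
    Z = (X[:, keep] - med[keep]) / scale[keep]
    out = pd.concat(
        [
            df[["plate_id", "well"]].reset_index(drop=True),
            pd.DataFrame(Z, columns=[feats[i] for i in keep]),
        ],
        axis=1,
    )
    return out, dropped


def aggregate_to_wells(z_table: pd.DataFrame) -> pd.DataFrame:
    """Per-well median of every normalized feature; index (plate_id, well).

    Equivalent to ``groupby(["plate_id","well"]).median()`` but computed with
    one numpy pass per well, which is several-fold faster on large batches.
    """
    keys = pd.MultiIndex.from_arrays(
        [z_table["plate_id"], z_table["well"]], names=["plate_id", "well"]
    )
    codes, uniques = pd.factorize(keys, sort=False)
    feats = [c for c in z_table.columns if c not in ("plate_id", "well")]
    X = z_table[feats].to_numpy(float)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    splits = np.nonzero(np.diff(sorted_codes))[0] + 1
    med = np.vstack(
        [np.median(g, axis=0) for g in np.split(X[order], splits)]
    )
    index = pd.MultiIndex.from_tuples(list(uniques), names=["plate_id", "well"])
    return pd.DataFrame(med, index=index, columns=feats)


def scale_by_dmso_sd(
    well_medians: pd.DataFrame,
    platemap: PlateMap,
    params: NormalizationParams = NormalizationParams(),
    reference_keys: set[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Divide well medians by the per-feature SD of the reference-well medians.

    ``reference_keys`` defaults to the vehicle wells; the background-variability
    module passes row/column subsets instead.  Sample SD (n-1 denominator).
    """
    if reference_keys is None:
        reference_keys = {
            (w.plate_id, w.well) for w in platemap.wells_with_role("vehicle")
        }
    ref_idx = [k for k in well_medians.index if k in reference_keys]
    if len(ref_idx) < 2:
        raise NormalizationError(
            f"need >= 2 reference wells to estimate SD, got {len(ref_idx)}"
        )
    sd = well_medians.loc[ref_idx].std(axis=0, ddof=1)
    dropped = list(sd.index[sd == 0])
    if dropped:
        logger.info("dropped %d feature(s) with zero reference SD", len(dropped))
    kept = [f for f in well_medians.columns if f not in dropped]
    if not kept:
        raise NormalizationError("all features dropped during SD scaling")
    return well_medians[kept] / sd[kept], dropped


def normalize_batch(
    batch: Batch, params: NormalizationParams = NormalizationParams()
) -> NormalizedWellProfile:
    """Full QC + three-step normalization for one batch."""
    counts = well_cell_counts(batch)
    filtered, exclusions = filter_wells(batch, params)
    z, dropped_cell = normalize_cell_level(filtered, params)
    medians = aggregate_to_wells(z)
    profile, dropped_sd = scale_by_dmso_sd(medians, filtered.platemap, params)
    meta = pd.DataFrame(
        [
            {
                "chemical": filtered.platemap.get(p, w).chemical,
                "concentration": filtered.platemap.get(p, w).concentration,
                "role": filtered.platemap.get(p, w).role,
            }
            for p, w in profile.index
        ],
        index=profile.index,
    )
    return NormalizedWellProfile(
        profile=profile,
        meta=meta,
        cell_counts=counts,
        exclusions=exclusions,
        dropped_features=dropped_cell + dropped_sd,
    )
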