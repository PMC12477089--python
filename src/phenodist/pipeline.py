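"""End-to-end orchestration: ingest/simulate -> normalize -> distances ->
concentration-response fits -> result bundle on disk."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import concentration_response as cr
from .multivariate_distance import (
    categorical_distances,
    fit_pca,
    mahalanobis_distances,
    write_distances_csv,
)
from .normalization import NormalizationParams, NormalizedWellProfile, normalize_batch
from .plate_model import Batch, FeatureCatalog, PlateMap

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results"
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    variance_threshold: float = 0.95
    sqrt_distances: bool = False
    models: tuple[str, ...] = cr.DEFAULT_MODELS
    n_boot: int = 500
    hitcall_threshold: float = 0.9
    categorical: bool = False
    batch_mode: str = "batch"  # "batch" or "per_plate"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    profile: NormalizedWellProfile
    global_distances: pd.Series
    benchmark: cr.BenchmarkResponse
    fits: dict[str, cr.FitResult]
    fit_table: pd.DataFrame
    categorical_tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def chemical_series(
    profile: NormalizedWellProfile, distances: pd.Series,
    baseline: float = 0.0,
) -> dict[str, cr.ConcResponseSeries]:
    """Group per-well distances into one concentration-response series per
    non-vehicle chemical.  ``baseline`` (the vehicle-median distance) is
    subtracted so responses are anchored at zero for null chemicals."""
    meta = profile.meta
    out: dict[str, cr.ConcResponseSeries] = {}
    for chem in meta.loc[meta["role"] != "vehicle", "chemical"].unique():
        mask = (meta["chemical"] == chem).to_numpy()
        conc = meta.loc[mask, "concentration"].to_numpy(float)
        resp = distances.to_numpy()[mask] - baseline
        ok = conc > 0
        if ok.sum() < 2 or len(np.unique(conc[ok])) < 2:
            logger.warning("chemical %s: too few dosed wells, skipped", chem)
            continue
        out[chem] = cr.ConcResponseSeries(chem, conc[ok], resp[ok])
    return out


def analyze_batch(batch: Batch, config: RunConfig,
                  catalog: FeatureCatalog | None = None) -> PipelineResult:
    """Run the full analysis for one batch (in memory)."""
    profile = normalize_batch(batch, config.normalization)
    space = fit_pca(profile, config.variance_threshold)
    dist = mahalanobis_distances(space, profile)
    distances = dist.sqrt() if config.sqrt_distances else dist.distances

    vehicle = distances.loc[profile.vehicle_index()]
    benchmark = cr.compute_bmr(
        vehicle.to_numpy(), config.normalization.mad_scale_constant
    )
    series = chemical_series(profile, distances, baseline=benchmark.dmso_median)
    fits: dict[str, cr.FitResult] = {}
    for i, (chem, s) in enumerate(sorted(series.items())):
        fits[chem] = cr.analyze_series(
            s, benchmark, models=config.models, n_boot=config.n_boot,
            seed=config.seed * 10007 + i, hitcall_threshold=config.hitcall_threshold,
        )
    result = PipelineResult(
        profile=profile,
        global_distances=distances,
        benchmark=benchmark,
        fits=fits,
        fit_table=cr.results_to_frame(fits),
    )
    if config.categorical:
        if catalog is None:
            raise ValueError("categorical analysis requires a feature catalog")
        cat_dists = categorical_distances(profile, catalog, config.variance_threshold)
        for cat, dres in cat_dists.items():
            d = dres.sqrt() if config.sqrt_distances else dres.distances
            bm = cr.compute_bmr(d.loc[profile.vehicle_index()].to_numpy(),
                                config.normalization.mad_scale_constant)
            cat_fits = {}
            cat_series = chemical_series(profile, d, baseline=bm.dmso_median)
            for i, (chem, s) in enumerate(sorted(cat_series.items())):
                try:
                    cat_fits[chem] = cr.analyze_series(
                        s, bm, models=config.models, n_boot=config.n_boot,
                        seed=config.seed * 10007 + i,
                        hitcall_threshold=config.hitcall_threshold,
                    )
                except cr.FitError as exc:
                    logger.warning("category %s / %s: %s", cat, chem, exc)
            result.categorical_tables[cat] = cr.results_to_frame(
                cat_fits, scope=f"category:{cat}"
            )
    return result


def run_pipeline(batch: Batch, config: RunConfig,
                 catalog: FeatureCatalog | None = None) -> list[PipelineResult]:
    """Analyze and write outputs; per-plate mode yields one result per plate."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.batch_mode == "per_plate":
        units = []
        for pid in batch.platemap.plate_ids:
            keys = {(w.plate_id, w.well) for w in batch.platemap if w.plate_id == pid}
            units.append((pid, batch.subset_wells(keys)))
    elif config.batch_mode == "batch":
        units = [("batch", batch)]
    else:
        raise ValueError(f"unknown batch_mode {config.batch_mode!r}")

    results = []
    manifest = {"config": config.to_dict(), "config_hash": config.digest(),
                "outputs": []}
    for name, unit in units:
        res = analyze_batch(unit, config, catalog)
        prefix = "" if len(units) == 1 else f"{name}_"
        res.profile.write_csv(out / f"{prefix}normalized_profile.csv")
        res.profile.write_exclusion_log(out / f"{prefix}exclusions.csv")
        dist_df = pd.DataFrame(
            {
                "plate_id": [p for p, _ in res.global_distances.index],
                "well": [w for _, w in res.global_distances.index],
                "chemical": res.profile.meta["chemical"].to_numpy(),
                "concentration": res.profile.meta["concentration"].to_numpy(),
                "scope": "global",
                "distance": res.global_distances.to_numpy(),
            }
        )
        dist_df.to_csv(out / f"{prefix}distances.csv", index=False)
        tables = [res.fit_table, *res.categorical_tables.values()]
        pd.concat(tables, ignore_index=True).to_csv(
            out / f"{prefix}fits.csv", index=False
        )
        manifest["outputs"].extend(
            [f"{prefix}normalized_profile.csv", f"{prefix}exclusions.csv",
             f"{prefix}distances.csv", f"{prefix}fits.csv"]
        )
        manifest[f"{name}_dropped_features"] = res.profile.dropped_features
        manifest[f"{name}_bmr"] = res.benchmark.bmr
        results.append(res)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return results
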