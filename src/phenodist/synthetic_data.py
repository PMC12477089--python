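"""Synthetic 96-well plate batches with implanted ground truth.

The layout mirrors a manual medium-throughput design: column 1 holds eight
vehicle wells, column 2 an inert eight-concentration series, column 3 a
cytotoxic eight-concentration series, and columns 4-12 three test chemicals
in triplicate, eight half-log concentrations each with the top dose in row A.

Cells carry ``F`` correlated features grouped into ``K`` categories; a
chemical shifts the mean of its affected features by a Hill function of
concentration (in vehicle-SD units), and cytotoxicity thins the per-well cell
count by a declining Hill factor.  A multiplicative row gradient reproduces
the decreasing A-to-H count trend seen on real plates.

:func:`oracle_bmc` computes the true benchmark concentration analytically,
deliberately bypassing the production pipeline, for use as an independent
ground truth in end-to-end checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .plate_model import (
    Batch,
    CellFeatureTable,
    FeatureCatalog,
    PlateMap,
    ROWS,
    WellMeta,
    well_name,
)

HALF_LOG = 10.0 ** 0.5

#: variance of the sample median of n iid normals, relative to sigma^2 / n
_MEDIAN_VAR_FACTOR = math.pi / 2.0


def half_log_series(top: float, n: int = 8) -> np.ndarray:
    """Descending concentration series: top, then half-log spaced below."""
    return top / HALF_LOG ** np.arange(n)


@dataclass
class ChemicalTruth:
    """Ground-truth effect of one chemical."""

    name: str
    role: str = "test"
    top_conc: float = 100.0           # uM; 8 half-log concentrations below
    affected_features: tuple[int, ...] = ()
    max_shift: float = 0.0            # E, in vehicle cell-SD units
    ac50: float = 1.0                 # uM
    hill: float = 1.5
    ac50_spread: float = 0.0          # log10 half-width of per-feature AC50s
    hill_spread: float = 0.0          # relative spread of per-feature slopes
    cytotox_ec50: float | None = None # uM; None = no count reduction
    cytotox_hill: float = 2.0

    def concentrations(self) -> np.ndarray:
        return half_log_series(self.top_conc)

    def feature_ac50s(self) -> np.ndarray:
        """Per-affected-feature AC50s, spread deterministically on a log grid
        around ``ac50`` (real chemicals perturb features with heterogeneous
        potencies; a rank-1 shift understates the distance response)."""
        m = len(self.affected_features)
        if m <= 1 or self.ac50_spread == 0.0:
            return np.full(max(m, 1), self.ac50)
        # upward-only spread: the most potent features sit at the nominal
        # AC50, later-responding features boost the distance near the top
        u = np.linspace(0.0, 1.0, m)
        return self.ac50 * 10.0 ** (self.ac50_spread * u)

    def feature_hills(self) -> np.ndarray:
        """Per-affected-feature Hill slopes, cycling deterministically around
        ``hill`` when ``hill_spread`` > 0."""
        m = len(self.affected_features)
        if m <= 1 or self.hill_spread == 0.0:
            return np.full(max(m, 1), self.hill)
        pattern = 1.0 + self.hill_spread * np.array([-0.4, 0.0, 0.8])
        return self.hill * pattern[np.arange(m) % 3]

    def shift_profile(self, conc: float) -> np.ndarray:
        """Mean shift of each affected feature at ``conc``:
        E * c^h_f / (ac50_f^h_f + c^h_f)."""
        if self.max_shift == 0.0 or conc <= 0 or not self.affected_features:
            return np.zeros(len(self.affected_features))
        h = self.feature_hills()
        ch = conc ** h
        return self.max_shift * ch / (self.feature_ac50s() ** h + ch)

    def shift_at(self, conc: float) -> float:
        """Hill-shaped mean shift at the central AC50 (scalar convenience)."""
        if self.max_shift == 0.0 or conc <= 0:
            return 0.0
        ch = conc ** self.hill
        return self.max_shift * ch / (self.ac50 ** self.hill + ch)

    def count_factor(self, conc: float) -> float:
        """Multiplicative survival factor on the expected cell count."""
        if self.cytotox_ec50 is None or conc <= 0:
            return 1.0
        return 1.0 / (1.0 + (conc / self.cytotox_ec50) ** self.cytotox_hill)


def default_chemicals(n_features: int = 120) -> list[ChemicalTruth]:
    """Three active test chemicals, an inert negative and a cytotoxic control.

    Affected feature blocks are sized relative to ``n_features`` so defaults
    stay valid for small desk-scale feature counts.
    """

    def seg(lo_frac: float, hi_frac: float) -> tuple[int, ...]:
        lo = min(int(round(lo_frac * n_features)), n_features - 1)
        hi = min(max(int(round(hi_frac * n_features)), lo + 1), n_features)
        return tuple(range(lo, hi))

    return [
        ChemicalTruth("inert_ctrl", role="negative_control", top_conc=25.0,
                      max_shift=0.0),
        ChemicalTruth("cytotox_ctrl", role="cytotoxic_control", top_conc=0.5,
                      max_shift=0.0, cytotox_ec50=0.05),
        ChemicalTruth("chem_a", top_conc=100.0,
                      affected_features=seg(0.0, 0.3),
                      max_shift=4.0, ac50=1.0, hill=1.5,
                      ac50_spread=1.25, hill_spread=0.6),
        ChemicalTruth("chem_b", top_conc=100.0,
                      affected_features=seg(0.3, 0.6),
                      max_shift=3.0, ac50=5.0, hill=2.0,
                      ac50_spread=1.25, hill_spread=0.6),
        ChemicalTruth("chem_c", top_conc=10.0,
                      affected_features=seg(0.6, 0.9),
                      max_shift=2.5, ac50=0.3, hill=1.5,
                      ac50_spread=1.25, hill_spread=0.6),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    plates_per_batch: int = 4
    n_features: int = 120
    n_categories: int = 49
    mean_cells: float = 1200.0
    row_gradient: float = 0.97        # multiplicative decline per row A->H
    rho: float = 0.5                  # within-category feature correlation
    well_effect_sd: float = 0.06      # intrinsic well-to-well mean variability
    count_dispersion: float = 50.0    # negative-binomial size parameter
    count_coupling: float = 0.0       # feature shift per relative count excess
    heavy_tails: bool = False         # t(5) cell noise instead of normal
    zero_noise: bool = False
    chemicals: list[ChemicalTruth] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.n_categories > self.n_features:
            raise ValueError("more categories than features")
        if self.chemicals is None:
            self.chemicals = default_chemicals(self.n_features)
        for c in self.chemicals:
            if c.affected_features and max(c.affected_features) >= self.n_features:
                raise ValueError(
                    f"chemical {c.name}: affected feature index out of range"
                )
        test = [c for c in self.chemicals if c.role == "test"]
        if len(test) != 3:
            raise ValueError("layout needs exactly 3 test chemicals")

    def category_sizes(self) -> list[int]:
        base, extra = divmod(self.n_features, self.n_categories)
        return [base + (1 if i < extra else 0) for i in range(self.n_categories)]

    def feature_catalog(self) -> FeatureCatalog:
        mapping = {}
        i = 0
        for k, size in enumerate(self.category_sizes()):
            for _ in range(size):
                mapping[f"f_{i:04d}"] = f"cat_{k:02d}"
                i += 1
        return FeatureCatalog(mapping)

    def feature_names(self) -> list[str]:
        return [f"f_{i:04d}" for i in range(self.n_features)]


@dataclass
class TruthRecord:
    """Serializable ground truth for one generated batch."""

    config: SimulationConfig
    oracle_bmcs: dict[str, float | None] = field(default_factory=dict)

    def write_json(self, path: str | Path) -> None:
        payload = asdict(self.config)
        payload["chemicals"] = [asdict(c) for c in self.config.chemicals]
        with open(path, "w") as fh:
            json.dump({"config": payload, "oracle_bmcs": self.oracle_bmcs}, fh,
                      indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

def plate_layout(config: SimulationConfig, plate_id: str) -> list[WellMeta]:
    """96 wells: 8 vehicle + 8 inert + 8 cytotoxic + 3 x 8 x 3 test wells."""
    chems = {c.role: [] for c in config.chemicals}
    for c in config.chemicals:
        chems.setdefault(c.role, []).append(c)
    inert = chems["negative_control"][0]
    cyto = chems["cytotoxic_control"][0]
    tests = chems["test"]
    wells: list[WellMeta] = []
    for i, row in enumerate(ROWS):
        wells.append(WellMeta(plate_id, row, 1, "DMSO", 0.0, "vehicle"))
        wells.append(WellMeta(plate_id, row, 2, inert.name,
                              float(inert.concentrations()[i]), inert.role))
        wells.append(WellMeta(plate_id, row, 3, cyto.name,
                              float(cyto.concentrations()[i]), cyto.role))
        for t, chem in enumerate(tests):
            conc = float(chem.concentrations()[i])
            for rep in range(3):
                wells.append(WellMeta(plate_id, row, 4 + 3 * t + rep,
                                      chem.name, conc, "test"))
    if len(wells) != 96:  # pragma: no cover - layout arithmetic guard
        raise RuntimeError(f"layout produced {len(wells)} wells, expected 96")
    return wells


# ---------------------------------------------------------------------------
# Cell generation
# ---------------------------------------------------------------------------

def _draw_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))

def _crowding_deficit(n: float, reference: float) -> float:
    """One-sided count coupling: sparse wells shift morphology, dense wells
    saturate (sub-confluent cells spread; crowded wells all look alike)."""
    return max((reference - n) / reference, 0.0)


def _cell_noise(
    rng: np.random.Generator, n: int, config: SimulationConfig
) -> np.ndarray:
    """Category-block correlated noise, unit marginal variance."""
    if config.zero_noise:
        return np.zeros((n, config.n_features))
    sizes = config.category_sizes()
    if config.heavy_tails:
        scale = math.sqrt(3.0 / 5.0)  # unit-variance t(5)
        draw = lambda shape: rng.standard_t(5, size=shape) * scale
    else:
        draw = rng.standard_normal
    z_feat = draw((n, config.n_features))
    z_cat = draw((n, config.n_categories))
    shared = np.repeat(z_cat, sizes, axis=1)
    return math.sqrt(config.rho) * shared + math.sqrt(1.0 - config.rho) * z_feat


def generate_plate(
    config: SimulationConfig, plate_id: str, rng: np.random.Generator
) -> tuple[CellFeatureTable, list[WellMeta]]:
    wells = plate_layout(config, plate_id)
    truth = {c.name: c for c in config.chemicals}
    feature_names = config.feature_names()

    counts = np.zeros(len(wells), dtype=int)
    offsets = np.zeros((len(wells), config.n_features))
    for i, w in enumerate(wells):
        mean = config.mean_cells * config.row_gradient ** ROWS.index(w.row)
        chem = truth.get(w.chemical)
        if chem is not None:
            mean *= chem.count_factor(w.concentration)
        n = _draw_count(rng, mean, config.count_dispersion)
        if config.zero_noise:
            n = max(int(round(mean)), 1)
        counts[i] = n
        if chem is not None and chem.max_shift != 0.0:
            offsets[i, list(chem.affected_features)] = chem.shift_profile(
                w.concentration
            )
        if config.count_coupling != 0.0:
            offsets[i] += config.count_coupling * _crowding_deficit(
                n, config.mean_cells
            )
    if config.well_effect_sd > 0 and not config.zero_noise:
        offsets += config.well_effect_sd * _cell_noise(rng, len(wells), config)

    X = _cell_noise(rng, int(counts.sum()), config)
    X += np.repeat(offsets, counts, axis=0)
    data = pd.DataFrame(X, columns=feature_names)
    data.insert(0, "well", np.repeat([w.well for w in wells], counts))
    data.insert(0, "plate_id", plate_id)
    return CellFeatureTable(data, feature_names), wells


def generate_batch(
    config: SimulationConfig,
) -> tuple[Batch, FeatureCatalog, TruthRecord]:
    """Full multi-plate batch + catalog + truth (oracle BMCs filled in)."""
    rng = np.random.default_rng(config.seed)
    tables, wells = [], []
    for p in range(config.plates_per_batch):
        table, meta = generate_plate(config, f"P{p + 1}", rng)
        tables.append(table)
        wells.extend(meta)
    data = pd.concat([t.data for t in tables], ignore_index=True)
    batch = Batch(CellFeatureTable(data, config.feature_names()),
                  PlateMap(wells), batch_id=f"sim{config.seed}")
    truth = TruthRecord(config=config, oracle_bmcs=oracle_bmcs(config))
    return batch, config.feature_catalog(), truth


def generate_dmso_plate(
    seed: int = 0,
    mean_cells: float = 1200.0,
    row_gradient: float = 0.94,
    count_coupling: float = 1.0,
    n_features: int = 120,
    n_categories: int = 49,
    rho: float = 0.5,
    well_effect_sd: float = 0.03,
    column_effect_sd: float = 0.08,
    count_dispersion: float = 50.0,
) -> Batch:
    """One vehicle-only 96-well plate with a row count gradient,
    count-coupled feature shifts, and a column-structured nuisance effect
    (mimicking per-column pipetting variation), for the
    background-variability study."""
    config = SimulationConfig(
        seed=seed, plates_per_batch=1, n_features=n_features,
        n_categories=n_categories, mean_cells=mean_cells,
        row_gradient=row_gradient, rho=rho, well_effect_sd=well_effect_sd,
        count_dispersion=count_dispersion, count_coupling=count_coupling,
    )
    rng = np.random.default_rng(seed)
    feature_names = config.feature_names()
    column_effects = column_effect_sd * _cell_noise(rng, 12, config)
    frames = []
    wells = []
    for row in ROWS:
        for col in range(1, 13):
            mean = mean_cells * row_gradient ** ROWS.index(row)
            n = max(_draw_count(rng, mean, count_dispersion), 1)
            X = _cell_noise(rng, n, config)
            if well_effect_sd > 0:
                X += well_effect_sd * _cell_noise(rng, 1, config)
            X += column_effects[col - 1]
            X += count_coupling * _crowding_deficit(n, mean_cells)
            df = pd.DataFrame(X, columns=feature_names)
            df.insert(0, "well", well_name(row, col))
            df.insert(0, "plate_id", "DMSO1")
            frames.append(df)
            wells.append(WellMeta("DMSO1", row, col, "DMSO", 0.0, "vehicle"))
    data = pd.concat(frames, ignore_index=True)
    return Batch(CellFeatureTable(data, feature_names), PlateMap(wells),
                 batch_id=f"dmso{seed}")


# ---------------------------------------------------------------------------
# Analytic oracle
# ---------------------------------------------------------------------------

def _category_correlation(config: SimulationConfig) -> np.ndarray:
    C = np.zeros((config.n_features, config.n_features))
    i = 0
    for size in config.category_sizes():
        C[i : i + size, i : i + size] = config.rho
        i += size
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class _OracleGeometry:
    """Population-level mirror of the pipeline's normalization + PC geometry.

    All quantities derive from the simulation truth only: expected normalized
    well profiles over the plate-layout design, the population correlation
    matrix of wells (design spread + well-median sampling noise), its
    eigendecomposition truncated at 95% cumulative variance, and the
    chi-square-mixture distribution of vehicle-well distances.
    """

    sd: float                      # expected per-feature SD of vehicle medians
    mean_profile: np.ndarray       # ensemble mean of expected well profiles
    col_scale: np.ndarray          # per-feature SD over the well ensemble
    loadings: np.ndarray           # retained eigenvectors of the correlation
    eigvals: np.ndarray            # retained eigenvalues
    mu: np.ndarray                 # score of the vehicle expectation
    noise_corr: np.ndarray         # C / (col_scale col_scale')
    vehicle_alphas: np.ndarray     # noise variance scale per vehicle row
    bmr_increment: float = 0.0
    background_offset: float = 0.0

    def score(self, profile: np.ndarray) -> np.ndarray:
        return self.loadings.T @ ((profile - self.mean_profile) / self.col_scale)

    def signal_distance(self, profile: np.ndarray) -> float:
        t = self.score(profile) - self.mu
        return float(np.sum(t * t / self.eigvals))


def _oracle_geometry(
    config: SimulationConfig, variance_threshold: float = 0.95
) -> _OracleGeometry:
    C = _category_correlation(config)
    row_counts = config.mean_cells * config.row_gradient ** np.arange(len(ROWS))
    tau2 = config.well_effect_sd ** 2
    # variance of a well median of n cells ~ (pi/2) / n for unit-variance
    # cells, plus the intrinsic well-to-well effect variance
    sd2 = float(np.mean(tau2 + _MEDIAN_VAR_FACTOR / row_counts))
    sd = math.sqrt(sd2)

    truth = {c.name: c for c in config.chemicals}
    profiles, alphas = [], []
    qc_floor = max(100.0, 0.5 * float(np.median(row_counts)))
    for plate in range(config.plates_per_batch):
        for w in plate_layout(config, f"P{plate + 1}"):
            n_w = row_counts[ROWS.index(w.row)]
            chem = truth.get(w.chemical)
            s = np.zeros(config.n_features)
            if chem is not None:
                n_w *= chem.count_factor(w.concentration)
                if chem.max_shift != 0.0:
                    s[list(chem.affected_features)] = chem.shift_profile(
                        w.concentration
                    )
            if n_w < qc_floor and n_w < row_counts.max():
                # mirrors the production QC exclusion; the second clause keeps
                # desk-scale configs (mean counts below 100) analyzable
                continue
            profiles.append(s / sd)
            alphas.append((tau2 + _MEDIAN_VAR_FACTOR / n_w) / sd2)
    P = np.array(profiles)
    sigma_wells = np.cov(P, rowvar=False, ddof=1) + float(np.mean(alphas)) * C
    col_scale = np.sqrt(np.diag(sigma_wells))
    R = sigma_wells / np.outer(col_scale, col_scale)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = np.clip(eigvals[order], 1e-12, None), eigvecs[:, order]
    cum = np.cumsum(eigvals) / eigvals.sum()
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    geom = _OracleGeometry(
        sd=sd,
        mean_profile=P.mean(axis=0),
        col_scale=col_scale,
        loadings=eigvecs[:, :k],
        eigvals=eigvals[:k],
        mu=np.zeros(k),
        noise_corr=C / np.outer(col_scale, col_scale),
        vehicle_alphas=(tau2 + _MEDIAN_VAR_FACTOR / row_counts) / sd2,
    )
    geom.mu = geom.score(np.zeros(config.n_features))
    med, mad, mean = _oracle_background(geom)
    geom.bmr_increment = 1.4826 * mad
    geom.background_offset = mean - med
    return geom


def _oracle_background(
    geom: _OracleGeometry, n_samples: int = 40000
) -> tuple[float, float, float]:
    """Median, raw MAD and mean of the vehicle-well distance distribution
    (eigenvalue-weighted chi-square mixture over the row count profile)."""
    rng = np.random.default_rng(987654321)  # internal, fixed: oracle-only
    samples = []
    per_row = max(n_samples // len(geom.vehicle_alphas), 1)
    W = geom.loadings
    for alpha in geom.vehicle_alphas:
        ns_cov = alpha * (W.T @ geom.noise_corr @ W)
        # weights of the chi-square mixture: eig of diag(1/lam) @ ns_cov
        lam = np.real(np.linalg.eigvals(ns_cov / geom.eigvals[:, None]))
        lam = np.clip(lam, 0.0, None)
        z = rng.standard_normal((per_row, len(lam)))
        samples.append((z * z) @ lam)
    d = np.concatenate(samples)
    med = float(np.median(d))
    return med, float(np.median(np.abs(d - med))), float(d.mean())


def _shift_vector(config: SimulationConfig, chem: ChemicalTruth, conc: float) -> np.ndarray:
    s = np.zeros(config.n_features)
    if chem.max_shift != 0.0 and conc > 0:
        s[list(chem.affected_features)] = chem.shift_profile(conc)
    return s


def oracle_distance_curve(
    config: SimulationConfig, chemical: ChemicalTruth, concs: np.ndarray,
    geom: _OracleGeometry | None = None,
) -> np.ndarray:
    """Expected distance response (relative to the vehicle median) at each
    concentration: signal through the truncated PC geometry plus the small
    mean-vs-median background offset."""
    geom = geom or _oracle_geometry(config)
    return np.array(
        [
            geom.signal_distance(_shift_vector(config, chemical, float(c)) / geom.sd)
            + geom.background_offset
            for c in concs
        ]
    )


def oracle_bmcs(
    config: SimulationConfig,
    n_grid: int = 600,
    rel_tol: float = 1e-6,
) -> dict[str, float | None]:
    """True BMC per chemical: first crossing of the analytic response curve
    above the analytic BMR increment, located by bisection on a log grid."""
    geom = _oracle_geometry(config)
    bmr = geom.bmr_increment

    def response(chem: ChemicalTruth, c: float) -> float:
        return (
            geom.signal_distance(_shift_vector(config, chem, c) / geom.sd)
            + geom.background_offset
        )

    out: dict[str, float | None] = {}
    for chem in config.chemicals:
        concs = chem.concentrations()
        lo, hi = float(concs.min()) / 100.0, float(concs.max())
        grid = np.geomspace(lo, hi, n_grid)
        vals = np.array([response(chem, c) for c in grid]) - bmr
        if chem.max_shift == 0.0 or not np.any(vals >= 0):
            out[chem.name] = None
            continue
        if vals[0] >= 0:
            out[chem.name] = float(grid[0])
            continue
        i = int(np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0][0])
        a, b = grid[i], grid[i + 1]
        while (b - a) / b > rel_tol:
            m = math.sqrt(a * b)
            if response(chem, m) - bmr >= 0:
                b = m
            else:
                a = m
        out[chem.name] = float(math.sqrt(a * b))
    return out


# ---------------------------------------------------------------------------
# Serialization helpers for the CLI
# ---------------------------------------------------------------------------

def write_batch_csvs(
    batch: Batch, catalog: FeatureCatalog, truth: TruthRecord, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    batch.platemap.write_csv(out / "platemap.csv")
    catalog.write_csv(out / "feature_catalog.csv")
    for plate_id in batch.platemap.plate_ids:
        sub = batch.cells.data[batch.cells.data["plate_id"] == plate_id]
        sub.to_csv(out / f"cells_{plate_id}.csv", index=False)
    truth.write_json(out / "truth.json")
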