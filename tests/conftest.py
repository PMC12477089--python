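import numpy as np
import pandas as pd
import pytest

from phenodist.plate_model import (
    Batch,
    CellFeatureTable,
    PlateMap,
    WellMeta,
)

ROWS = "ABCDEFGH"


def platemap_96(plate_id: str = "P1") -> PlateMap:
    """Column 1 vehicle, columns 2-12 one test chemical, 8 half-log concs."""
    wells = []
    for i, row in enumerate(ROWS):
        conc = 100.0 / (10.0 ** 0.5) ** i
        wells.append(WellMeta(plate_id, row, 1, "DMSO", 0.0, "vehicle"))
        for col in range(2, 13):
            wells.append(WellMeta(plate_id, row, col, "chemX", conc, "test"))
    return PlateMap(wells)


def make_batch(
    cells_per_well: dict[str, int],
    feature_values: dict[str, np.ndarray] | None = None,
    n_features: int = 3,
    plate_id: str = "P1",
    roles: dict[str, str] | None = None,
    seed: int = 0,
) -> Batch:
    """Small hand-rolled batch.  ``cells_per_well`` maps well label -> count;
    ``feature_values`` optionally fixes the full cell x feature block per
    well; wells default to role=vehicle unless ``roles`` overrides."""
    rng = np.random.default_rng(seed)
    feats = [f"f{i}" for i in range(n_features)]
    frames, wells = [], []
    roles = roles or {}
    for well, n in cells_per_well.items():
        row, col = well[0], int(well[1:])
        role = roles.get(well, "vehicle")
        conc = 1.0 if role != "vehicle" else 0.0
        chem = "DMSO" if role == "vehicle" else "chemX"
        wells.append(WellMeta(plate_id, row, col, chem, conc, role))
        if n == 0:
            continue
        if feature_values is not None and well in feature_values:
            X = np.asarray(feature_values[well], float).reshape(n, n_features)
        else:
            X = rng.standard_normal((n, n_features))
        df = pd.DataFrame(X, columns=feats)
        df.insert(0, "well", well)
        df.insert(0, "plate_id", plate_id)
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    return Batch(CellFeatureTable(data, feats), PlateMap(wells))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim_config():
    """Desk-scale simulation config reused across tests."""
    from phenodist.synthetic_data import SimulationConfig

    return SimulationConfig(
        seed=7, plates_per_batch=1, n_features=24, n_categories=8,
        mean_cells=150.0,
    )


def exact_correlation_data(R: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """n x p data whose *sample* correlation matrix equals R exactly."""
    p = R.shape[0]
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X -= X.mean(axis=0)
    C = np.cov(X, rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    Cm12 = evecs @ np.diag(evals ** -0.5) @ evecs.T
    evals, evecs = np.linalg.eigh(R)
    R12 = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None))) @ evecs.T
    return X @ Cm12 @ R12
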