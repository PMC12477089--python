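"""Concentration-response modeling of per-well distances.

The benchmark response (BMR) is one (scaled) MAD above the median distance of
the vehicle wells.  Each chemical's (concentration, distance) series is fitted
by maximum likelihood to a family of ten curve shapes under a Student-t(df=4)
error model; the lowest-AIC fit wins, a continuous hitcall in [0, 1] scores
confidence in activity, and the benchmark concentration (BMC) is the smallest
concentration at which the winning curve crosses the BMR.  Confidence limits
come from a seeded nonparametric bootstrap over wells within concentration
groups.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

T_DF = 4  # degrees of freedom of the robust error model

# closed-form Student-t(4) log-density; scipy.stats.t.logpdf is far too slow
# inside the optimizer loop
_T4_CONST = (
    math.lgamma((T_DF + 1) / 2.0)
    - math.lgamma(T_DF / 2.0)
    - 0.5 * math.log(T_DF * math.pi)
)


def _t_logpdf(x: np.ndarray) -> np.ndarray:
    return _T4_CONST - ((T_DF + 1) / 2.0) * np.log1p(x * x / T_DF)


class FitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Benchmark response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkResponse:
    bmr: float
    dmso_median: float
    dmso_mad: float  # scaled MAD actually added to the median


def compute_bmr(
    dmso_distances: Sequence[float] | np.ndarray,
    mad_scale_constant: float = 1.4826,
) -> BenchmarkResponse:
    """BMR = median + mad_scale_constant * rawMAD of the vehicle distances."""
    d = np.asarray(dmso_distances, float)
    if d.size == 0:
        raise FitError("no vehicle distances supplied")
    med = float(np.median(d))
    raw_mad = float(np.median(np.abs(d - med)))
    if raw_mad == 0.0:
        warnings.warn("vehicle distance MAD is zero; BMR degenerates to the median")
    scaled = mad_scale_constant * raw_mad
    return BenchmarkResponse(bmr=med + scaled, dmso_median=med, dmso_mad=scaled)


# ---------------------------------------------------------------------------
# Model family (x = concentration; er = log error scale, shared by all)
# ---------------------------------------------------------------------------

def _f_constant(x, p):
    return np.zeros_like(x)

def _f_poly1(x, p):
    return p[0] * x

def _f_poly2(x, p):
    t = x / p[1]
    return p[0] * (t + t * t)

def _f_power(x, p):
    return p[0] * np.power(x, p[1])

def _f_hill(x, p):
    tp, ga, h = p
    return tp / (1.0 + np.power(ga / x, h))

def _f_gain_loss(x, p):
    tp, ga, h, la, q = p
    gain = 1.0 / (1.0 + np.power(ga / x, h))
    loss = 1.0 / (1.0 + np.power(x / la, q))
    return tp * gain * loss

def _f_exp2(x, p):
    return p[0] * (np.exp(np.minimum(x / p[1], 100.0)) - 1.0)

def _f_exp3(x, p):
    return p[0] * (np.exp(np.minimum(np.power(x / p[1], p[2]), 100.0)) - 1.0)

def _f_exp4(x, p):
    return p[0] * (1.0 - np.power(2.0, -x / p[1]))

def _f_exp5(x, p):
    return p[0] * (1.0 - np.power(2.0, -np.power(x / p[1], p[2])))


@dataclass(frozen=True)
class _ModelSpec:
    name: str
    func: Callable[[np.ndarray, Sequence[float]], np.ndarray]
    param_names: tuple[str, ...]  # curve parameters, excluding er

    @property
    def n_params(self) -> int:
        return len(self.param_names) + 1  # + er


MODEL_SPECS: dict[str, _ModelSpec] = {
    s.name: s
    for s in (
        _ModelSpec("constant", _f_constant, ()),
        _ModelSpec("poly1", _f_poly1, ("a",)),
        _ModelSpec("poly2", _f_poly2, ("a", "b")),
        _ModelSpec("power", _f_power, ("a", "p")),
        _ModelSpec("hill", _f_hill, ("tp", "ga", "p")),
        _ModelSpec("gain_loss", _f_gain_loss, ("tp", "ga", "p", "la", "q")),
        _ModelSpec("exp2", _f_exp2, ("a", "b")),
        _ModelSpec("exp3", _f_exp3, ("a", "b", "p")),
        _ModelSpec("exp4", _f_exp4, ("tp", "ga")),
        _ModelSpec("exp5", _f_exp5, ("tp", "ga", "p")),
    )
}

DEFAULT_MODELS = tuple(MODEL_SPECS)


@dataclass
class ConcResponseSeries:
    """One chemical's (concentration, response) pairs; concentrations > 0."""

    chemical: str
    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, float)
        self.responses = np.asarray(self.responses, float)
        if self.concentrations.shape != self.responses.shape:
            raise FitError("concentration/response length mismatch")
        if np.any(self.concentrations <= 0):
            raise FitError("concentrations must be strictly positive")
        if len(np.unique(self.concentrations)) < 2:
            raise FitError("need at least 2 distinct concentrations")

    @property
    def top_concentration(self) -> float:
        return float(self.concentrations.max())

    @property
    def min_concentration(self) -> float:
        return float(self.concentrations.min())

    def group_medians(self) -> tuple[np.ndarray, np.ndarray]:
        df = pd.DataFrame({"c": self.concentrations, "r": self.responses})
        med = df.groupby("c")["r"].median()
        return med.index.to_numpy(), med.to_numpy()


@dataclass
class FitResult:
    """One fitted model (and, on the winner, the downstream summary)."""

    model: str
    params: dict[str, float]
    loglik: float
    aic: float
    converged: bool
    hitcall: float | None = None
    bmc: float | None = None
    bmcl: float | None = None
    bmcu: float | None = None
    bmc_flag: str | None = None
    excluded: bool = False
    reason: str | None = None

    def predict(self, conc: np.ndarray) -> np.ndarray:
        spec = MODEL_SPECS[self.model]
        p = [self.params[n] for n in spec.param_names]
        return spec.func(np.asarray(conc, float), p)


def _neg_loglik(theta, x, y, spec):
    er = theta[-1]
    sigma = np.exp(er)
    with np.errstate(over="ignore", invalid="ignore"):
        mu = spec.func(x, theta[:-1])
    resid = (y - mu) / sigma
    if not np.all(np.isfinite(resid)):
        return 1e10
    return -(np.sum(_t_logpdf(resid)) - len(y) * er)


def _starting_points(spec, x, y):
    """Heuristic initial values + box bounds, tcplfit2-flavoured."""
    cmax, cmin = x.max(), x.min()
    resp = y[np.argmax(np.abs(y))] if len(y) else 1.0
    if resp == 0:
        resp = 1e-3
    rmad = stats.median_abs_deviation(y, scale=1.0)
    er0 = float(np.log(max(rmad, 1e-8)))
    er_b = (er0 - 12.0, er0 + 12.0)
    big = 1e8
    amp = 1.2 * max(np.max(np.abs(y)), 1e-8)
    conc_b = (cmin / 100.0, cmax * 100.0)
    ga0 = np.sqrt(cmin * cmax)
    starts: list[list[float]] = []
    if spec.name == "constant":
        starts = [[er0]]
        bounds = [er_b]
    elif spec.name == "poly1":
        starts = [[resp / cmax, er0]]
        bounds = [(-big, big), er_b]
    elif spec.name == "poly2":
        starts = [[resp / 2.0, cmax, er0]]
        bounds = [(-big, big), (cmax / 1000.0, cmax * 1000.0), er_b]
    elif spec.name == "power":
        starts = [[resp / cmax, 1.2, er0], [resp / cmax**0.5, 0.5, er0]]
        bounds = [(-big, big), (0.3, 8.0), er_b]
    elif spec.name == "hill":
        starts = [[resp, ga0, 1.2, er0], [resp, cmax / 10.0, 3.0, er0]]
        bounds = [(-amp, amp), conc_b, (0.3, 8.0), er_b]
    elif spec.name == "gain_loss":
        starts = [[resp, ga0, 1.2, cmax * 10.0, 1.0, er0]]
        bounds = [(-amp, amp), conc_b, (0.3, 8.0), conc_b, (0.3, 8.0), er_b]
    elif spec.name == "exp2":
        starts = [[resp / 10.0, cmax / 2.0, er0]]
        bounds = [(-big, big), (cmax / 1000.0, cmax * 1000.0), er_b]
    elif spec.name == "exp3":
        starts = [[resp / 10.0, cmax / 2.0, 1.2, er0]]
        bounds = [(-big, big), (cmax / 1000.0, cmax * 1000.0), (0.3, 8.0), er_b]
    elif spec.name == "exp4":
        starts = [[resp, ga0, er0]]
        bounds = [(-amp, amp), conc_b, er_b]
    elif spec.name == "exp5":
        starts = [[resp, ga0, 1.2, er0], [resp, cmax / 10.0, 3.0, er0]]
        bounds = [(-amp, amp), conc_b, (0.3, 8.0), er_b]
    else:  # pragma: no cover
        raise FitError(f"unknown model {spec.name}")
    return starts, bounds


def fit_one_model(
    name: str,
    series: ConcResponseSeries,
    theta0: Sequence[float] | None = None,
) -> FitResult:
    """Maximum-likelihood fit of a single model; non-convergence flagged.

    ``theta0`` warm-starts the optimizer (used by the bootstrap), replacing
    the heuristic multistart.
    """
    spec = MODEL_SPECS[name]
    x, y = series.concentrations, series.responses
    starts, bounds = _starting_points(spec, x, y)
    if theta0 is not None:
        starts = [list(theta0)]
    best = None
    for theta0 in starts:
        clipped = [min(max(v, lo), hi) for v, (lo, hi) in zip(theta0, bounds)]
        res = optimize.minimize(
            _neg_loglik, clipped, args=(x, y, spec),
            method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    ll = -float(best.fun)
    ok = bool(best.success or best.fun < 1e9) and np.isfinite(ll)
    params = dict(zip((*spec.param_names, "er"), map(float, best.x)))
    return FitResult(
        model=name,
        params=params,
        loglik=ll,
        aic=2.0 * spec.n_params - 2.0 * ll,
        converged=ok,
    )


def fit_models(
    series: ConcResponseSeries,
    models: Sequence[str] = DEFAULT_MODELS,
) -> list[FitResult]:
    """Fit every requested model; raise only if all of them fail."""
    fits = []
    for name in models:
        try:
            fits.append(fit_one_model(name, series))
        except Exception as exc:  # noqa: BLE001 - a model family member may die
            logger.warning("model %s failed for %s: %s", name, series.chemical, exc)
    if not any(f.converged for f in fits):
        raise FitError(f"all models failed for chemical {series.chemical}")
    return fits


def select_winner(fits: Sequence[FitResult]) -> FitResult:
    converged = [f for f in fits if f.converged]
    # tie-break on name so selection is invariant to fitting order
    return min(converged, key=lambda f: (f.aic, f.model))


# ---------------------------------------------------------------------------
# Hitcall
# ---------------------------------------------------------------------------

def compute_hitcall(
    fits: Sequence[FitResult],
    bmr: float,
    series: ConcResponseSeries,
) -> float:
    """Continuous hitcall = P1 * P2 * P3.

    P1: probability (under the winner's t error model) that at least one
    concentration group's median response exceeds the cutoff; P2: probability
    the winning curve's maximum fitted response on the tested range exceeds
    the cutoff; P3: one minus the two-model Akaike weight of the constant
    model against the winner.  A constant winner scores 0.
    """
    winner = select_winner(fits)
    if winner.model == "constant":
        return 0.0
    sigma = float(np.exp(winner.params["er"]))
    cutoff = bmr
    _, rmds = series.group_medians()
    p1 = 1.0 - float(np.prod(stats.t.cdf((cutoff - rmds) / sigma, df=T_DF)))
    grid = np.geomspace(series.min_concentration, series.top_concentration, 200)
    top = float(np.max(winner.predict(grid)))
    p2 = 1.0 - float(stats.t.cdf((cutoff - top) / sigma, df=T_DF))
    const = next((f for f in fits if f.model == "constant" and f.converged), None)
    if const is None:
        p3 = 1.0
    else:
        delta = (winner.aic - const.aic) / 2.0
        p3 = 1.0 / (1.0 + np.exp(delta))  # 1 - akaike weight of the constant
    hit = p1 * p2 * p3
    return float(min(max(hit, 0.0), 1.0))


# ---------------------------------------------------------------------------
# BMC
# ---------------------------------------------------------------------------

def compute_bmc(
    winner: FitResult,
    bmr: float,
    series: ConcResponseSeries,
    rel_tol: float = 1e-6,
) -> tuple[float | None, str | None]:
    """Smallest concentration where the winning curve equals the BMR.

    The search range is [lowest tested conc / 100, top tested conc].  Returns
    (bmc, flag); flag is ``no_crossing`` when the curve never reaches the BMR
    and ``below_range`` when the curve is already above the BMR at the floor.
    """
    lo = series.min_concentration / 100.0
    hi = series.top_concentration
    grid = np.geomspace(lo, hi, 800)
    vals = winner.predict(grid) - bmr
    if vals[0] >= 0:
        return float(grid[0]), "below_range"
    sign_change = np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0]
    if sign_change.size == 0:
        return None, "no_crossing"
    i = int(sign_change[0])
    root = optimize.brentq(
        lambda c: float(winner.predict(np.array([c]))[0]) - bmr,
        grid[i], grid[i + 1], rtol=rel_tol,
    )
    return float(root), None


def bootstrap_bmc_ci(
    series: ConcResponseSeries,
    winner_model: str,
    bmr: float,
    n_boot: int = 500,
    seed: int = 0,
    max_missing_frac: float = 0.5,
) -> tuple[float | None, float | None]:
    """Percentile 95% CI for the BMC from a within-group wells bootstrap.

    Each resample redraws wells with replacement inside every concentration
    group, refits the winning model family member, and recomputes the BMC.
    Resamples without a BMR crossing are missing; when more than
    ``max_missing_frac`` of resamples are missing both limits are absent.
    """
    rng = np.random.default_rng(seed)
    conc = series.concentrations
    groups = {c: np.nonzero(conc == c)[0] for c in np.unique(conc)}
    spec = MODEL_SPECS[winner_model]
    parent = fit_one_model(winner_model, series)
    theta0 = [parent.params[n] for n in (*spec.param_names, "er")]
    bmcs = []
    for _ in range(n_boot):
        idx = np.concatenate(
            [rng.choice(g, size=len(g), replace=True) for g in groups.values()]
        )
        sub = ConcResponseSeries(series.chemical, conc[idx], series.responses[idx])
        try:
            fit = fit_one_model(winner_model, sub, theta0=theta0)
            bmc, flag = compute_bmc(fit, bmr, sub)
        except Exception:  # noqa: BLE001
            bmc, flag = None, "fit_failed"
        bmcs.append(bmc if flag in (None, "below_range") else None)
    valid = np.array([b for b in bmcs if b is not None], float)
    if len(valid) < (1.0 - max_missing_frac) * n_boot or len(valid) < 2:
        return None, None
    return float(np.percentile(valid, 2.5)), float(np.percentile(valid, 97.5))


# ---------------------------------------------------------------------------
# Exclusion rules and the per-chemical driver
# ---------------------------------------------------------------------------

HITCALL_THRESHOLD = 0.9


def apply_exclusion_rules(
    result: FitResult,
    series: ConcResponseSeries,
    hitcall_threshold: float = HITCALL_THRESHOLD,
) -> FitResult:
    """Flag the winner excluded when hitcall < threshold, the BMC exceeds the
    top tested concentration, or either confidence limit is missing."""
    if result.hitcall is None:
        raise FitError("apply_exclusion_rules needs a hitcall")
    if result.hitcall < hitcall_threshold:
        result.excluded, result.reason = True, "low_hitcall"
    elif result.bmc is None:
        result.excluded, result.reason = True, "missing_ci"
    elif result.bmc > series.top_concentration:
        result.excluded, result.reason = True, "above_top_conc"
    elif result.bmcl is None or result.bmcu is None:
        result.excluded, result.reason = True, "missing_ci"
    else:
        result.excluded, result.reason = False, None
    return result


def analyze_series(
    series: ConcResponseSeries,
    benchmark: BenchmarkResponse,
    models: Sequence[str] = DEFAULT_MODELS,
    n_boot: int = 500,
    seed: int = 0,
    hitcall_threshold: float = HITCALL_THRESHOLD,
) -> FitResult:
    """Full per-chemical analysis: fit family, pick winner, hitcall, BMC, CI,
    exclusions.

    ``series.responses`` must be expressed relative to the vehicle-median
    distance (the model family is anchored at f(0) = 0), so the BMR crossing
    happens at the MAD increment ``benchmark.bmr - benchmark.dmso_median``.
    The bootstrap is skipped when the hitcall already excludes the chemical or
    there is no BMR crossing.
    """
    cutoff = benchmark.bmr - benchmark.dmso_median
    fits = fit_models(series, models)
    winner = select_winner(fits)
    winner.hitcall = compute_hitcall(fits, cutoff, series)
    bmc, flag = compute_bmc(winner, cutoff, series)
    winner.bmc, winner.bmc_flag = bmc, flag
    if bmc is not None and winner.hitcall >= hitcall_threshold:
        winner.bmcl, winner.bmcu = bootstrap_bmc_ci(
            series, winner.model, cutoff, n_boot=n_boot, seed=seed
        )
    return apply_exclusion_rules(winner, series, hitcall_threshold)


def results_to_frame(results: dict[str, FitResult], scope: str = "global") -> pd.DataFrame:
    rows = []
    for chem, r in results.items():
        rows.append(
            {
                "chemical": chem,
                "scope": scope,
                "model": r.model,
                "params": json.dumps(r.params),
                "aic": r.aic,
                "hitcall": r.hitcall,
                "bmc": r.bmc,
                "bmcl": r.bmcl,
                "bmcu": r.bmcu,
                "excluded": r.excluded,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)
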