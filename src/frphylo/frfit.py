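"""Type II functional response over depleting resources.

Rogers' random-predator equation describes total consumption Ne of an
initial resource amount N over a trial of length T when the resource is not
replaced as it is eaten:

    Ne = N * (1 - exp(a * (Ne * h - T)))          (implicit)

with attack (cropping) rate ``a`` (per hour) and handling (chewing and
digestion) time ``h`` (hours per gram). The implicit equation has the
explicit solution

    Ne = N - W(a * h * N * exp(-a * (T - h * N))) / (a * h)

where W is the principal branch of the Lambert W function. The maximum
feeding rate is 1/h.

This module evaluates the model, estimates (a, h) per species × temperature
by nonlinear least squares on the log-parameter scale, averages parameters
within origin groups, and builds bootstrap confidence bands around
group-mean response curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import lambertw

__all__ = [
    "FRParameters",
    "FRCurveBand",
    "rogers_predict",
    "rogers_residual",
    "fit_fr",
    "fit_fr_frame",
    "group_mean_params",
    "bootstrap_group_band",
    "params_to_frame",
]

_A_BOUNDARY = 1e-12  # attack-rate floor reported for all-zero consumption


@dataclass
class FRParameters:
    """Fitted functional-response parameters for one species × temperature."""

    species: str
    temperature_C: float
    a: float
    h: float
    n_points: int
    converged: bool
    sse: float

    @property
    def max_rate(self) -> float:
        return 1.0 / self.h


@dataclass
class FRCurveBand:
    """Pointwise 95% bootstrap band around a group-mean response curve."""

    group: str
    temperature_C: float
    grid_N: np.ndarray
    mean: np.ndarray  # point-estimate curve from the unresampled fit
    lower: np.ndarray
    upper: np.ndarray
    n_bootstrap: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "temperature_C": self.temperature_C,
                "N_g": self.grid_N,
                "mean_Ne_g": self.mean,
                "lower95_Ne_g": self.lower,
                "upper95_Ne_g": self.upper,
                "n_bootstrap": self.n_bootstrap,
            }
        )


def rogers_predict(N, a: float, h: float, T: float):
    """Consumption Ne predicted by Rogers' equation (Lambert W solution).

    Vectorized over ``N``. Continuous limits: a = 0 gives Ne = 0; h = 0
    gives exponential depletion Ne = N * (1 - exp(-a * T)).
    """
    N = np.asarray(N, dtype=float)
    scalar = N.ndim == 0
    N = np.atleast_1d(N)
    if np.any(N < 0) or a < 0 or h < 0 or T <= 0:
        raise ValueError("rogers_predict requires N, a, h >= 0 and T > 0")
    if a == 0:
        out = np.zeros_like(N)
    elif h == 0:
        out = N * (1.0 - math.exp(-a * T))
    else:
        out = np.zeros_like(N)
        pos = N > 0
        s = a * h * N[pos]
        # log of the W argument; exponentiating can overflow when h*N >> T
        logarg = np.log(s) + a * (h * N[pos] - T)
        w = np.empty_like(s)
        small = logarg < 600.0
        arg = np.exp(logarg[small])
        # argument is >= 0 for admissible parameters; guard the branch point
        # against pathological round-off anyway
        arg = np.maximum(arg, -1.0 / math.e + 1e-12)
        w[small] = lambertw(arg).real
        if not np.all(small):
            # asymptotic W(e^L) ~ L - log(L) + ..., refined by iteration
            L = logarg[~small]
            wl = L - np.log(L)
            for _ in range(4):
                wl = L - np.log(wl)
            w[~small] = wl
        out[pos] = N[pos] - w / (a * h)
        out = np.clip(out, 0.0, N)
    return float(out[0]) if scalar else out


def rogers_residual(Ne, N, a: float, h: float, T: float):
    """Residual of the implicit form: Ne − N(1 − exp(a(Ne·h − T))).

    Zero exactly when Ne solves Rogers' equation; serves as the independent
    oracle that the Lambert W solution must satisfy.
    """
    Ne = np.asarray(Ne, dtype=float)
    N = np.asarray(N, dtype=float)
    return Ne - N * (1.0 - np.exp(a * (Ne * h - T)))


def _initial_values(N: np.ndarray, Ne: np.ndarray, T: float) -> tuple[float, float]:
    """Heuristic NLS starting point.

    a0 from the low-density regression slope of Ne/T on N (attack rate
    dominates when handling is negligible); h0 from the saturation level,
    T / max(Ne).
    """
    order = np.argsort(N)
    low = order[: max(2, min(6, len(order) // 2))]
    x, y = N[low], Ne[low] / T
    denom = float(np.sum(x * x))
    a0 = float(np.sum(x * y) / denom) if denom > 0 else 0.01
    if not np.isfinite(a0) or a0 <= 0:
        a0 = 0.01
    ne_max = float(np.max(Ne))
    h0 = T / ne_max if ne_max > 0 else 1.0
    return a0, h0

# deterministic log-scale jitters for multi-start refits
_JITTERS = [
    (0.0, 0.0),
    (1.0, -1.0),
    (-1.0, 1.0),
    (1.5, 1.5),
    (-1.5, -1.5),
    (0.5, -0.5),
]


def fit_fr(
    records: Iterable, T: float, species: str | None = None,
    temperature_C: float | None = None,
) -> FRParameters:
    """Fit (a, h) to one species × temperature cell by nonlinear least squares.

    ``records`` may be ConsumptionRecord objects or a DataFrame with columns
    ``N_initial_g`` and ``net_g``. Parameters are optimized on the log scale
    (enforcing positivity), with deterministic multi-start jitters before a
    fit is declared non-converged. All-zero consumption is reported as a
    boundary fit (a at the floor, converged=False).
    """
    if isinstance(records, pd.DataFrame):
        N = records["N_initial_g"].to_numpy(dtype=float)
        Ne = records["net_g"].to_numpy(dtype=float)
        if species is None and "species" in records.columns and len(records):
            species = str(records["species"].iloc[0])
        if temperature_C is None and "temperature_C" in records.columns and len(records):
            temperature_C = float(records["temperature_C"].iloc[0])
    else:
        records = list(records)
        N = np.array([r.N_initial_g for r in records], dtype=float)
        Ne = np.array([r.net_g for r in records], dtype=float)
        if species is None and records:
            species = records[0].species
        if temperature_C is None and records:
            temperature_C = records[0].temperature_C
    species = species or ""
    temperature_C = float("nan") if temperature_C is None else temperature_C

    if len(N) < 3 or len(np.unique(N)) < 3:
        raise ValueError("need >= 3 records with distinct N values")
    if np.any(Ne < -1e-12) or np.any(Ne > N + 1e-9):
        raise ValueError("net consumption must lie in [0, N]")

    if np.all(Ne <= 0):
        return FRParameters(species, temperature_C, _A_BOUNDARY, 1.0,
                            len(N), False, float(np.sum(Ne**2)))

    a0, h0 = _initial_values(N, Ne, T)
    x0 = np.array([math.log(a0), math.log(h0)])

    def resid(theta: np.ndarray) -> np.ndarray:
        return Ne - rogers_predict(N, math.exp(theta[0]), math.exp(theta[1]), T)

    best = None
    for da, dh in _JITTERS:
        try:
            sol = optimize.least_squares(resid, x0 + [da, dh], method="lm",
                                         xtol=1e-12, ftol=1e-12)
        except (ValueError, OverflowError):
            continue
        sse = float(np.sum(sol.fun**2))
        if sol.success and (best is None or sse < best[0] - 1e-12):
            best = (sse, sol)
        if best is not None and best[1].success and (da, dh) == (0.0, 0.0):
            break  # default start converged; jitters only guard failures

    if best is None:
        return FRParameters(species, temperature_C, a0, h0, len(N), False,
                            float(np.sum(resid(x0) ** 2)))
    sse, sol = best
    a, h = math.exp(sol.x[0]), math.exp(sol.x[1])
    return FRParameters(species, temperature_C, a, h, len(N), True, sse)


def fit_fr_frame(trials: pd.DataFrame, T: float) -> list[FRParameters]:
    """Fit every species × temperature cell of a corrected trials table."""
    out = []
    for (species, temp), cell in trials.groupby(["species", "temperature_C"], sort=True):
        out.append(fit_fr(cell, T, species=str(species), temperature_C=float(temp)))
    return out


def params_to_frame(params: Sequence[FRParameters]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [p.species for p in params],
            "temperature_C": [p.temperature_C for p in params],
            "a": [p.a for p in params],
            "h": [p.h for p in params],
            "max_rate": [p.max_rate for p in params],
            "n_points": [p.n_points for p in params],
            "converged": [p.converged for p in params],
            "sse": [p.sse for p in params],
        }
    )


def group_mean_params(
    params: Sequence[FRParameters],
    group_of: dict[str, str],
) -> pd.DataFrame:
    """Arithmetic means of a and h per (group, temperature).

    ``group_of`` maps species name -> group label (familiar | novel).
    Every species in ``group_of`` must have a converged fit at each
    temperature present.
    """
    df = params_to_frame(params)
    df["group"] = df["species"].map(group_of)
    df = df.dropna(subset=["group"])
    expected = set(group_of)
    for temp, cell in df.groupby("temperature_C"):
        missing = expected - set(cell["species"])
        if missing:
            raise ValueError(
                f"missing converged fits at {temp}: {sorted(missing)}"
            )
        if not cell["converged"].all():
            bad = sorted(cell.loc[~cell["converged"], "species"])
            raise ValueError(f"non-converged fits at {temp}: {bad}")
    out = (
        df.groupby(["group", "temperature_C"], as_index=False)
        .agg(a=("a", "mean"), h=("h", "mean"), n_species=("species", "size"))
    )
    out["max_rate"] = 1.0 / out["h"]
    return out


def bootstrap_group_band(
    records: pd.DataFrame,
    group: str,
    temperature_C: float,
    T: float,
    n_boot: int = 2000,
    grid: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    group_of: dict[str, str] | None = None,
    by_species: bool = False,
    max_retries_factor: int = 5,
) -> FRCurveBand:
    """95% pointwise bootstrap band around one group-mean response curve.

    Records of all species in the group at one temperature are pooled,
    resampled with replacement (the individual trial record is the
    resampling unit; ``by_species=True`` switches to a species-block
    bootstrap), Rogers' equation refit to each resample, and each fitted
    curve evaluated on ``grid``; percentile 2.5/97.5 bounds are returned
    together with the point-estimate curve from the original records.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub = records
    if group_of is not None:
        sub = sub[sub["species"].map(group_of) == group]
    if "temperature_C" in sub.columns:
        sub = sub[np.isclose(sub["temperature_C"].astype(float), temperature_C)]
    if sub.empty:
        raise ValueError(f"no records for group {group!r} at {temperature_C}")
    N = sub["N_initial_g"].to_numpy(dtype=float)
    Ne = sub["net_g"].to_numpy(dtype=float)
    species_codes = pd.factorize(sub["species"])[0] if "species" in sub.columns else np.zeros(len(sub), int)
    if grid is None:
        grid = np.linspace(np.min(N), np.max(N), 50)
    grid = np.asarray(grid, dtype=float)

    point = _fit_arrays(N, Ne, T)
    if point is None:
        raise ValueError("point-estimate fit failed for the pooled records")
    mean_curve = rogers_predict(grid, point[0], point[1], T)

    curves = np.empty((n_boot, grid.size))
    n = len(N)
    max_tries = max_retries_factor * n_boot
    tries = 0
    got = 0
    while got < n_boot:
        if tries >= max_tries:
            raise RuntimeError(
                f"bootstrap retry cap exceeded ({got}/{n_boot} resamples fit)"
            )
        tries += 1
        if by_species:
            chosen = rng.integers(0, species_codes.max() + 1, species_codes.max() + 1)
            idx = np.concatenate([np.flatnonzero(species_codes == c) for c in chosen])
        else:
            idx = rng.integers(0, n, n)
        fit = _fit_arrays(N[idx], Ne[idx], T, start=point)
        if fit is None:
            continue
        curves[got] = rogers_predict(grid, fit[0], fit[1], T)
        got += 1

    lower = np.percentile(curves, 2.5, axis=0)
    upper = np.percentile(curves, 97.5, axis=0)
    return FRCurveBand(group, temperature_C, grid, mean_curve, lower, upper, n_boot)


def _fit_arrays(
    N: np.ndarray, Ne: np.ndarray, T: float,
    start: tuple[float, float] | None = None,
) -> tuple[float, float] | None:
    """Fast (a, h) fit on raw arrays; returns None on failure.

    Used by the bootstrap, where resample refits start from the
    point-estimate parameters.
    """
    if np.all(Ne <= 0) or len(np.unique(N)) < 2:
        return None
    if start is not None:
        a0, h0 = start
    else:
        a0, h0 = _initial_values(N, Ne, T)

    def resid(theta: np.ndarray) -> np.ndarray:
        return Ne - rogers_predict(N, math.exp(theta[0]), math.exp(theta[1]), T)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = optimize.least_squares(
                resid, [math.log(a0), math.log(h0)], method="lm",
                xtol=1e-10, ftol=1e-10,
            )
    except (ValueError, OverflowError):
        return None
    if not sol.success or not np.all(np.isfinite(sol.x)):
        return None
    return math.exp(sol.x[0]), math.exp(sol.x[1])
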