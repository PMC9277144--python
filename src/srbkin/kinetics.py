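"""Plug-flow kinetics of sulfate reduction and rate-law fitting.

Sulfate removal along an ideal plug-flow reactor with an irreversible
rate law r_A = k·C^n integrates in closed form along the residence-time
coordinate τ = V/F:

    n = 1:  C_A(τ) = C0 · exp(−k·τ)
    n ≠ 1:  C_A(τ) = [C0^(1−n) + (n−1)·k·τ]^(1/(1−n))

For n < 1 the bracket can reach zero in finite time, at which point the
substrate is exhausted and C_A is clamped to 0 (complete conversion).
The observable fitted against the data is the segment-mean volumetric
rate (F/V)·(C0 − C_A), one point per cumulative reactor volume per
steady state.  (k, n) are estimated by multi-start nonlinear least
squares; goodness of fit is summarised by SSE, R², the standard error
SE = sqrt(SSE/dof) and a two-tailed 95 % Student-t confidence band of
constant half-width t_crit·SE in rate units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateFitError, InsufficientDataError, MissingFeedError
from .reactor import ReactorConfig, SteadyStateObservation

#: Search bounds for the reaction order when it is free.
ORDER_BOUNDS = (0.2, 6.0)
#: Multi-start grid: reaction orders × log10 rate constants.
START_ORDERS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
START_LOG10K = tuple(float(v) for v in range(-9, 1))


@dataclass(frozen=True)
class KineticModel:
    """An nth-order irreversible rate law r = k·C^n.

    ``k`` has units mg^(1−n)·L^(n−1)·h⁻¹ (plain h⁻¹ when n = 1).
    """

    k: float
    n: float = 1.0
    order_fixed: bool = True

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("rate constant k must be >= 0")
        if self.n <= 0:
            raise ValueError("reaction order n must be > 0")

    @property
    def k_units(self) -> str:
        if abs(self.n - 1.0) < 1e-12:
            return "1/h"
        return f"mg^{1 - self.n:g}·L^{self.n - 1:g}/h"


@dataclass(frozen=True)
class RatePoint:
    """One observed segment-mean rate at a cumulative reactor volume.

    ``flow_per_volume`` is F/V for the segment (h⁻¹), C0/CA are the
    sulfate concentrations entering/leaving it, and y is the observed
    mean volumetric rate (F/V)·(C0 − CA).
    """

    flow_per_volume: float
    C0: float
    CA: float
    y: float
    segment_volume: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.C0 <= 0:
            raise ValueError("C0 must be > 0")
        expected = self.flow_per_volume * (self.C0 - self.CA)
        scale = max(abs(expected), abs(self.y), 1e-30)
        if abs(self.y - expected) > 1e-9 * scale:
            raise ValueError(
                f"inconsistent rate point: y={self.y} but F/V·(C0−CA)={expected}"
            )


@dataclass
class KineticFitResult:
    """Estimated rate law with goodness-of-fit statistics."""

    model: KineticModel
    sse: float
    r2: float
    se: float
    dof: int
    t_crit: float
    n_points: int
    optimizer_trace: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k": self.model.k,
            "n": self.model.n,
            "order_fixed": self.model.order_fixed,
            "k_units": self.model.k_units,
            "sse": self.sse,
            "r2": self.r2,
            "se": self.se,
            "dof": self.dof,
            "t_crit": self.t_crit,
            "n_points": self.n_points,
            "optimizer_trace": self.optimizer_trace,
        }


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def pfr_outlet_concentration(C0: float, model: KineticModel, residence_time: float) -> float:
    """Outlet concentration after residence time τ in an ideal PFR."""
    if C0 < 0:
        raise ValueError("C0 must be >= 0")
    if residence_time < 0:
        raise ValueError("residence_time must be >= 0")
    k, n = model.k, model.n
    if C0 == 0.0 or k == 0.0 or residence_time == 0.0:
        return C0
    if abs(n - 1.0) < 1e-9:
        return C0 * math.exp(-k * residence_time)
    base = C0 ** (1.0 - n) + (n - 1.0) * k * residence_time
    if base <= 0.0:  # substrate exhausted mid-segment (possible for n < 1)
        return 0.0
    return base ** (1.0 / (1.0 - n))


def mean_rate(C0: float, model: KineticModel, flow_per_volume: float) -> float:
    """Segment-mean volumetric rate (F/V)·(C0 − C_A) at the given F/V."""
    if flow_per_volume <= 0:
        raise ValueError("flow_per_volume must be > 0")
    ca = pfr_outlet_concentration(C0, model, 1.0 / flow_per_volume)
    return flow_per_volume * (C0 - ca)


def _mean_rate_grid(
    C0: np.ndarray, fv: np.ndarray, k: np.ndarray, n: np.ndarray
) -> np.ndarray:
    """Vectorised mean rate; broadcasts (k, n) against (C0, fv)."""
    tau = 1.0 / fv
    one_minus_n = 1.0 - n
    near_first = np.abs(one_minus_n) < 1e-9
    safe = np.where(near_first, 1.0, one_minus_n)
    with np.errstate(over="ignore", invalid="ignore"):
        base = C0**one_minus_n + (n - 1.0) * k * tau
        ca = np.where(base > 0.0, np.abs(base) ** (1.0 / safe), 0.0)
        if np.any(near_first):
            ca = np.where(near_first, C0 * np.exp(-k * tau), ca)
    ca = np.clip(ca, 0.0, C0)
    return fv * (C0 - ca)


# ---------------------------------------------------------------------------
# Rate-point assembly
# ---------------------------------------------------------------------------

_CUMULATIVE_LABELS = {0: "inlet", 1: "inlet+middle", 2: "whole"}


def build_rate_points(
    observations: Iterable[SteadyStateObservation], config: ReactorConfig
) -> list[RatePoint]:
    """Cumulative-volume rate points from zone-boundary sulfate observations.

    For each non-excluded steady state, the sulfate means at the zone
    outlets yield up to three points with C0 = feed sulfate, CA = the
    outlet concentration, and F/V = dilution_rate × working_volume / V
    for the cumulative volume V of that boundary.  Excluded rows
    contribute nothing.
    """
    sulfate = [o for o in observations if o.analyte == "sulfate"]
    by_rate: dict[float, dict[str, SteadyStateObservation]] = {}
    for o in sulfate:
        by_rate.setdefault(o.dilution_rate, {})[o.zone_boundary] = o

    zone_index = {z.name: i for i, z in enumerate(config.zones)}
    points: list[RatePoint] = []
    for d in sorted(by_rate):
        rows = by_rate[d]
        outlet_rows = [
            rows[z.name]
            for z in config.zones
            if z.name in rows and not rows[z.name].excluded
        ]
        if not outlet_rows:
            continue
        feed = rows.get("feed")
        if feed is None:
            raise MissingFeedError(
                f"no feed sulfate row for dilution rate {d} h^-1"
            )
        if feed.excluded:
            continue
        flow = d * config.working_volume
        for o in outlet_rows:
            zone = config.zone(o.zone_boundary)
            v_cum = zone.cumulative_volume
            fv = flow / v_cum
            name = _CUMULATIVE_LABELS.get(zone_index[zone.name], zone.name)
            points.append(
                RatePoint(
                    flow_per_volume=fv,
                    C0=feed.mean_conc,
                    CA=o.mean_conc,
                    y=fv * (feed.mean_conc - o.mean_conc),
                    segment_volume=v_cum,
                    label=f"{name} {v_cum:g} L",
                )
            )
    return points


def filter_rate_points(points: Sequence[RatePoint], dataset: str) -> list[RatePoint]:
    """Select the inlet / composite / whole-reactor subset, or all (joint)."""
    if dataset == "joint":
        return list(points)
    prefix = {"inlet": "inlet ", "composite": "inlet+middle ", "whole": "whole "}.get(dataset)
    if prefix is None:
        raise ValueError("dataset must be one of inlet|composite|whole|joint")
    return [p for p in points if p.label.startswith(prefix)]


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------


def goodness_of_fit(
    y: Sequence[float], yfit: Sequence[float], n_params: int
) -> tuple[float, float, float, int]:
    """(SSE, R², SE, dof) for observed vs fitted rates.

    SSE = Σ(y − y_fit)²; R² = 1 − SSE/Σ(y − ȳ)²; dof = N − n_params;
    SE = sqrt(SSE/dof) (NaN when dof = 0).
    """
    y = np.asarray(y, dtype=float)
    yfit = np.asarray(yfit, dtype=float)
    if y.shape != yfit.shape:
        raise ValueError("y and yfit must have equal length")
    if y.size < n_params:
        raise ValueError("need at least n_params observations")
    sse = float(np.sum((y - yfit) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        if sse > 0.0:
            raise ValueError("R² undefined: zero variance in y with nonzero SSE")
        r2 = 1.0
    else:
        r2 = 1.0 - sse / sst
    dof = int(y.size - n_params)
    se = math.sqrt(sse / dof) if dof > 0 else math.nan
    return sse, r2, se, dof


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _sse_for(points_arrays, k: float, n: float) -> float:
    C0, fv, y = points_arrays
    yfit = _mean_rate_grid(C0, fv, np.asarray(k), np.asarray(n))
    return float(np.sum((y - yfit) ** 2))


def fit_kinetics(
    points: Sequence[RatePoint],
    order_fixed: float | None = None,
    *,
    order_bounds: tuple[float, float] = ORDER_BOUNDS,
    n_polish: int = 8,
) -> KineticFitResult:
    """Estimate (k, n) by multi-start nonlinear least squares.

    SSE = Σ(y − mean_rate(C0, model, F/V))² is minimised over k > 0 and,
    when ``order_fixed`` is None, over n within ``order_bounds``.  An
    80-point grid of starts (orders × decades of k) is screened and the
    best ``n_polish`` starts are refined with a bounded trust-region
    least-squares solver; ties in SSE break toward the smaller order.
    """
    points = list(points)
    free = order_fixed is None
    min_points = 3 if free else 1
    if len(points) < min_points:
        raise InsufficientDataError(
            f"need >= {min_points} rate points for this fit, got {len(points)}"
        )
    C0 = np.array([p.C0 for p in points])
    fv = np.array([p.flow_per_volume for p in points])
    y = np.array([p.y for p in points])
    arrays = (C0, fv, y)
    n_params = 2 if free else 1

    if np.allclose(y, 0.0):
        model = KineticModel(k=0.0, n=(order_fixed if not free else 1.0), order_fixed=not free)
        sse, r2, se, dof = 0.0, 1.0, 0.0, len(points) - n_params
        result = KineticFitResult(model, sse, r2, se, dof, math.nan, len(points))
        raise DegenerateFitError("all observed rates are zero; k = 0", result)

    # exact single-point fixed-order solution: mean_rate is monotone in k
    if not free and len(points) == 1:
        k = _solve_single_point(C0[0], fv[0], y[0], order_fixed)
        model = KineticModel(k=k, n=order_fixed, order_fixed=True)
        yfit = [mean_rate(C0[0], model, fv[0])]
        sse, r2, se, dof = float((y[0] - yfit[0]) ** 2), 1.0, math.nan, 0
        return KineticFitResult(
            model, sse, r2, se, dof, math.nan, 1, {"method": "single-point root solve"}
        )

    if free:
        grid_k = np.array([10.0**e for e in START_LOG10K])
        grid_n = np.array(START_ORDERS)
        kk, nn = np.meshgrid(grid_k, grid_n, indexing="ij")
        yfit = _mean_rate_grid(C0[None, None, :], fv[None, None, :], kk[..., None], nn[..., None])
        sse_grid = np.sum((y[None, None, :] - yfit) ** 2, axis=-1)
        order = np.argsort(sse_grid, axis=None)
        starts = [
            (math.log10(kk.flat[i]), float(nn.flat[i])) for i in order[:n_polish]
        ]
        lo = [-15.0, order_bounds[0]]
        hi = [3.0, order_bounds[1]]

        def residuals(theta):
            k, n = 10.0 ** theta[0], theta[1]
            return y - _mean_rate_grid(C0, fv, np.asarray(k), np.asarray(n))

    else:
        starts = [(e, float(order_fixed)) for e in START_LOG10K]
        lo, hi = [-15.0], [3.0]

        def residuals(theta):
            k = 10.0 ** theta[0]
            return y - _mean_rate_grid(C0, fv, np.asarray(k), np.asarray(order_fixed))

    candidates: list[tuple[float, float, float]] = []  # (sse, n, log10k)
    for start in starts:
        x0 = list(start) if free else [start[0]]
        x0 = np.clip(x0, lo, hi)
        try:
            sol = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        k_hat = 10.0 ** sol.x[0]
        n_hat = float(sol.x[1]) if free else float(order_fixed)
        candidates.append((_sse_for(arrays, k_hat, n_hat), n_hat, float(sol.x[0])))
    if not candidates:
        raise InsufficientDataError("optimizer failed from every start")

    best_sse = min(c[0] for c in candidates)
    tol = 1e-9 * max(best_sse, 1e-300)
    near = [c for c in candidates if c[0] <= best_sse + tol]
    sse_b, n_b, logk_b = min(near, key=lambda c: c[1])  # ties -> smaller order
    model = KineticModel(k=10.0**logk_b, n=n_b, order_fixed=not free)

    yfit = _mean_rate_grid(C0, fv, np.asarray(model.k), np.asarray(model.n))
    sse, r2, se, dof = goodness_of_fit(y, yfit, n_params)
    t_crit = float(stats.t.ppf(0.975, dof)) if dof >= 1 else math.nan
    trace = {
        "n_starts_screened": len(starts) if not free else len(START_ORDERS) * len(START_LOG10K),
        "n_starts_polished": len(candidates),
        "best_sse": sse,
        "complete_conversion_clamp": bool(
            model.n < 1.0
            and np.any(
                C0 ** (1.0 - model.n) + (model.n - 1.0) * model.k / fv <= 0.0
            )
        ),
    }
    return KineticFitResult(model, sse, r2, se, dof, t_crit, len(points), trace)


def _solve_single_point(C0: float, fv: float, y: float, n: float) -> float:
    """k such that mean_rate(C0, (k, n), fv) = y; monotone bracket + brentq."""
    y_max = fv * C0
    if y <= 0.0:
        return 0.0
    if y >= y_max:
        return 10.0**3

    def f(log10k: float) -> float:
        return mean_rate(C0, KineticModel(k=10.0**log10k, n=n), fv) - y

    return 10.0 ** optimize.brentq(f, -20.0, 6.0, xtol=1e-14)


def grid_search_sse(
    points: Sequence[RatePoint],
    *,
    n_grid: int = 40,
    log10k_bounds: tuple[float, float] = (-9.0, 0.0),
    order_bounds: tuple[float, float] = ORDER_BOUNDS,
    order_fixed: float | None = None,
) -> float:
    """Best SSE over a dense (log k × n) grid — the fit's reference bound."""
    C0 = np.array([p.C0 for p in points])
    fv = np.array([p.flow_per_volume for p in points])
    y = np.array([p.y for p in points])
    ks = np.logspace(log10k_bounds[0], log10k_bounds[1], n_grid)
    if order_fixed is None:
        ns = np.linspace(order_bounds[0], order_bounds[1], n_grid)
    else:
        ns = np.array([order_fixed])
    kk, nn = np.meshgrid(ks, ns, indexing="ij")
    yfit = _mean_rate_grid(C0[None, None, :], fv[None, None, :], kk[..., None], nn[..., None])
    sse = np.sum((y[None, None, :] - yfit) ** 2, axis=-1)
    return float(sse.min())


def confidence_band(
    result: KineticFitResult, C0: float, fv_grid: Sequence[float]
) -> pd.DataFrame:
    """Fitted mean-rate curve with the 95 % band fit ± t_crit·SE.

    The half-width is constant in rate units across the F/V grid.
    """
    if result.dof < 1:
        raise ValueError("confidence band requires dof >= 1")
    half = result.t_crit * result.se
    rows = []
    for fv in fv_grid:
        fit = mean_rate(C0, result.model, fv)
        rows.append({"fv": fv, "fit": fit, "lo": fit - half, "hi": fit + half})
    return pd.DataFrame(rows, columns=["fv", "fit", "lo", "hi"])
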