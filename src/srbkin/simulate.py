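"""Synthetic steady-state reactor data with known kinetic truth.

The generator runs the plug-flow rate law forward along the dilution-rate
ladder to produce zone-boundary sulfate profiles, then allocates electron
donors zone by zone with exactly the stoichiometric rules the attribution
ledger applies in reverse: a prescribed per-dilution-rate fermentation
schedule fixes propionate production in the inlet zone, remaining lactate
supplies sulfate demand by incomplete oxidation, propionate entering the
middle/effluent zones is oxidised next, and acetate (including the
yeast-extract credit) covers the residual.  Replicate measurements are
drawn with seeded Gaussian noise of fixed coefficient of variation,
truncated at zero, and summarised to mean/SD — mirroring how steady-state
tables arise from repeated sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import InfeasibleScenarioError
from .kinetics import KineticModel, pfr_outlet_concentration
from .reactor import (
    ReactorConfig,
    SteadyStateObservation,
    acetate_reactor_config,
    lactate_reactor_config,
    observations_to_frame,
    write_observations,
)
from .units import mg_per_l_to_mm, mm_to_mg_per_l

#: The dilution-rate ladder of the retention-time study, h^-1.
DEFAULT_DILUTION_LADDER = (
    0.010,
    0.014,
    0.016,
    0.018,
    0.021,
    0.024,
    0.028,
    0.032,
    0.042,
)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian relative measurement noise, truncated at zero.

    ``cv`` is the coefficient of variation applied to every replicate
    draw; it may be a single float or a per-analyte mapping.
    """

    cv: float | Mapping[str, float] = 0.05

    def cv_for(self, analyte: str) -> float:
        if isinstance(self.cv, Mapping):
            value = float(self.cv.get(analyte, 0.0))
        else:
            value = float(self.cv)
        if value < 0:
            raise ValueError("cv must be >= 0")
        return value


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to generate one reactor's observation table."""

    config: ReactorConfig
    kinetic_truth: KineticModel
    dilution_ladder: tuple[float, ...] = DEFAULT_DILUTION_LADDER
    #: net propionate produced in the inlet zone, mM, per dilution rate
    fermentation_schedule: Mapping[float, float] = field(default_factory=dict)
    #: dilution rates flagged non-steady (excluded=true in the table)
    non_steady_rates: tuple[float, ...] = ()
    noise: NoiseModel = NoiseModel()
    replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        ladder = tuple(self.dilution_ladder)
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("dilution_ladder must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def lactate_reactor_scenario(
    *, seed: int = 0, cv: float = 0.05, replicates: int = 5
) -> SimulationSpec:
    """First-order scenario: k = 0.06955 h⁻¹, fermentation upset at
    0.014–0.016 h⁻¹ (elevated propionate, flagged non-steady)."""
    schedule = {d: 2.3 for d in DEFAULT_DILUTION_LADDER}
    schedule[0.014] = 4.6
    schedule[0.016] = 3.9
    return SimulationSpec(
        config=lactate_reactor_config(),
        kinetic_truth=KineticModel(k=0.06955, n=1.0, order_fixed=True),
        fermentation_schedule=schedule,
        non_steady_rates=(0.014, 0.016),
        noise=NoiseModel(cv=cv),
        replicates=replicates,
        seed=seed,
    )


def acetate_reactor_scenario(
    *, seed: int = 0, cv: float = 0.05, replicates: int = 5
) -> SimulationSpec:
    """High-order scenario: n = 2.9, k = 1.5e-7 mg^-1.9·L^1.9·h⁻¹."""
    return SimulationSpec(
        config=acetate_reactor_config(),
        kinetic_truth=KineticModel(k=1.5e-7, n=2.9, order_fixed=False),
        non_steady_rates=(0.014,),
        noise=NoiseModel(cv=cv),
        replicates=replicates,
        seed=seed,
    )


SCENARIOS = {
    "lactate-reactor": lactate_reactor_scenario,
    "acetate-reactor": acetate_reactor_scenario,
}


def simulate_sulfate_profile(spec: SimulationSpec) -> dict[float, dict[str, float]]:
    """Noiseless sulfate (mg/L) at the feed and each zone boundary.

    Integrates the kinetic truth along cumulative volume; profiles are
    monotone non-increasing from feed to effluent.
    """
    c0 = spec.config.feed.get("sulfate", 0.0)
    out: dict[float, dict[str, float]] = {}
    for d in spec.dilution_ladder:
        flow = d * spec.config.working_volume
        profile = {"feed": c0}
        for zone in spec.config.zones:
            tau = zone.cumulative_volume / flow
            profile[zone.name] = pfr_outlet_concentration(c0, spec.kinetic_truth, tau)
        out[d] = profile
    return out


def simulate_donor_profiles(
    spec: SimulationSpec,
    sulfate_profile: Mapping[float, Mapping[str, float]] | None = None,
) -> dict[float, dict[str, dict[str, float]]]:
    """Zone-boundary compositions (mM) consistent with the donor ledger.

    Returns {dilution_rate: {boundary: {analyte: mM}}} including sulfate
    and sulfide.  Raises :class:`InfeasibleScenarioError` (naming the
    zone) when a zone's sulfate demand exceeds its electron-donor pool.
    """
    if sulfate_profile is None:
        sulfate_profile = simulate_sulfate_profile(spec)
    feed_mm = {a: mg_per_l_to_mm(c, a) for a, c in spec.config.feed.items()}
    feed_mm.setdefault("sulfide", 0.0)
    ye_mm = mg_per_l_to_mm(spec.config.yeast_extract_acetate_credit, "acetate")
    first_zone = spec.config.zones[0].name

    out: dict[float, dict[str, dict[str, float]]] = {}
    for d in spec.dilution_ladder:
        sprof = sulfate_profile[d]
        comps = {"feed": dict(feed_mm)}
        comps["feed"]["sulfate"] = mg_per_l_to_mm(sprof["feed"], "sulfate")
        upstream = comps["feed"]
        for zone in spec.config.zones:
            s_out = mg_per_l_to_mm(sprof[zone.name], "sulfate")
            demand = upstream["sulfate"] - s_out
            comp = dict(upstream)
            comp["sulfate"] = s_out
            comp["sulfide"] = upstream.get("sulfide", 0.0) + demand
            remaining = demand
            if zone.name == first_zone:
                # prescribed fermentation fixes propionate production
                f_prop = float(spec.fermentation_schedule.get(d, 0.0))
                fermented = 1.5 * f_prop
                if fermented > upstream.get("lactate", 0.0) + 1e-12:
                    raise InfeasibleScenarioError(
                        f"zone {zone.name!r} at D={d}: fermentation schedule needs "
                        f"{fermented:.3f} mM lactate, only "
                        f"{upstream.get('lactate', 0.0):.3f} available"
                    )
                comp["lactate"] = upstream.get("lactate", 0.0) - fermented
                comp["propionate"] = upstream.get("propionate", 0.0) + f_prop
                comp["acetate"] = upstream.get("acetate", 0.0) + 0.5 * f_prop + ye_mm
                # citrate is fully consumed in the inlet, outside the ledger
                if "citrate" in comp:
                    comp["citrate"] = 0.0
            else:
                # propionate oxidation supplies demand first (0.75 sulfate each)
                prop_used = min(comp.get("propionate", 0.0), remaining / 0.75)
                comp["propionate"] = comp.get("propionate", 0.0) - prop_used
                comp["acetate"] = comp.get("acetate", 0.0) + prop_used
                remaining -= 0.75 * prop_used
            # remaining lactate supplies demand by incomplete oxidation
            lact_used = min(comp.get("lactate", 0.0), remaining / 0.5)
            comp["lactate"] = comp.get("lactate", 0.0) - lact_used
            comp["acetate"] = comp.get("acetate", 0.0) + lact_used
            remaining -= 0.5 * lact_used
            # acetate covers the residual 1:1
            if remaining > comp.get("acetate", 0.0) + 1e-9:
                raise InfeasibleScenarioError(
                    f"zone {zone.name!r} at D={d}: residual sulfate demand "
                    f"{remaining:.3f} mM exceeds acetate pool "
                    f"{comp.get('acetate', 0.0):.3f} mM"
                )
            comp["acetate"] = comp.get("acetate", 0.0) - min(remaining, comp.get("acetate", 0.0))
            out.setdefault(d, {})
            comps[zone.name] = comp
            upstream = comp
        out[d] = comps
    return out


def emit_observations(spec: SimulationSpec) -> list[SteadyStateObservation]:
    """Draw replicate measurements and summarise them to observations.

    Feed rows carry the known composition exactly (SD 0); zone-outlet
    rows are means/SDs of ``replicates`` truncated-Gaussian draws around
    the noiseless truth.  Identical seeds give identical tables.
    """
    profiles = simulate_donor_profiles(spec)
    rng = np.random.default_rng(spec.seed)
    obs: list[SteadyStateObservation] = []
    analytes = [a for a in ("sulfate", "sulfide", "lactate", "propionate", "acetate", "citrate")
                if a in spec.config.feed or a == "sulfide"]
    for d in spec.dilution_ladder:
        excluded = d in spec.non_steady_rates
        note = "non-steady after dilution-rate step" if excluded else ""
        for boundary in ["feed"] + [z.name for z in spec.config.zones]:
            comp = profiles[d][boundary]
            for analyte in analytes:
                truth = mm_to_mg_per_l(comp.get(analyte, 0.0), analyte)
                if boundary == "feed":
                    mean, sd = truth, 0.0
                elif (cv := spec.noise.cv_for(analyte)) == 0.0:
                    mean, sd = truth, 0.0
                else:
                    draws = truth * (1.0 + cv * rng.standard_normal(spec.replicates))
                    draws = np.clip(draws, 0.0, None)
                    mean = float(draws.mean())
                    sd = float(draws.std(ddof=1)) if spec.replicates > 1 else 0.0
                obs.append(
                    SteadyStateObservation(
                        dilution_rate=d,
                        zone_boundary=boundary,
                        analyte=analyte,
                        mean_conc=mean,
                        sd_conc=sd,
                        n_samples=spec.replicates,
                        steady=not excluded,
                        excluded=excluded,
                        note=note,
                    )
                )
    return obs


def monte_carlo_order_recovery(
    truth: KineticModel,
    config: ReactorConfig,
    *,
    n_replicates: int = 200,
    cv: float = 0.05,
    n_samples: int = 5,
    seed: int = 0,
    dilution_ladder: Sequence[float] = DEFAULT_DILUTION_LADDER,
) -> np.ndarray:
    """Recovered reaction orders from repeated noisy ladder experiments.

    Each replicate draws ``n_samples`` truncated-Gaussian measurements of
    every zone-boundary sulfate concentration around the kinetic truth,
    summarises them to means, rebuilds the cumulative-volume rate points
    and refits (k, n) with the order free.  Returns the array of fitted
    orders; its median is the recovery statistic of interest.
    """
    from .kinetics import RatePoint, fit_kinetics  # local to keep import light

    c0 = config.feed.get("sulfate", 0.0)
    truths = []
    for d in dilution_ladder:
        flow = d * config.working_volume
        for zone in config.zones:
            tau = zone.cumulative_volume / flow
            ca = pfr_outlet_concentration(c0, truth, tau)
            truths.append((flow / zone.cumulative_volume, ca, zone.cumulative_volume))
    rng = np.random.default_rng(seed)
    orders = np.empty(n_replicates)
    for rep in range(n_replicates):
        points = []
        for fv, ca, v in truths:
            noisy = float(
                np.clip(ca * (1.0 + cv * rng.standard_normal(n_samples)), 0.0, None).mean()
            )
            noisy = min(noisy, c0)  # a mean above the feed carries no rate information
            points.append(RatePoint(fv, c0, noisy, fv * (c0 - noisy), v))
        orders[rep] = fit_kinetics(points).model.n
    return orders


def truth_sidecar(spec: SimulationSpec) -> dict:
    """Machine-readable record of the generating truth, for recovery tests."""
    return {
        "reactor_id": spec.config.reactor_id,
        "kinetic_truth": {
            "k": spec.kinetic_truth.k,
            "n": spec.kinetic_truth.n,
            "k_units": spec.kinetic_truth.k_units,
        },
        "dilution_ladder": list(spec.dilution_ladder),
        "fermentation_schedule_mM": {str(k): v for k, v in spec.fermentation_schedule.items()},
        "non_steady_rates": list(spec.non_steady_rates),
        "replicates": spec.replicates,
        "seed": spec.seed,
        "noise_cv": spec.noise.cv if not isinstance(spec.noise.cv, Mapping) else dict(spec.noise.cv),
        "sulfate_profile_mg_L": {str(d): p for d, p in simulate_sulfate_profile(spec).items()},
        "donor_profiles_mM": {
            str(d): {b: dict(c) for b, c in comps.items()}
            for d, comps in simulate_donor_profiles(spec).items()
        },
    }


def emit_observation_table(
    spec: SimulationSpec,
    path: str | Path | None = None,
    truth_path: str | Path | None = None,
):
    """Generate the observation table (and truth sidecar) for a scenario.

    Returns the table as a DataFrame in the canonical schema; when paths
    are given the CSV and JSON sidecar are written deterministically.
    """
    obs = emit_observations(spec)
    frame = observations_to_frame(obs)
    if path is not None:
        write_observations(obs, path)
    if truth_path is not None:
        with open(truth_path, "w", encoding="utf-8") as fh:
            json.dump(truth_sidecar(spec), fh, indent=2, sort_keys=True)
    return frame
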