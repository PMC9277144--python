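"""Stoichiometric attribution of sulfate reduction to electron donors.

Sulfate-reducing microorganisms (SRM) in these reactors can oxidise
acetate (1 sulfate per acetate), propionate (0.75 sulfate per propionate,
producing 1 acetate) or lactate — either incompletely to acetate
(0.5 sulfate per lactate) or completely to CO2 (1.5 sulfate per lactate).
Fermentative organisms additionally split lactate 3 → 1 acetate +
2 propionate without reducing any sulfate.  Given zone-boundary
concentrations, this module partitions lactate between fermentation and
sulfidogenesis, attributes the observed sulfate removal to the donor
reactions in a fixed order (propionate, then remaining lactate, then
acetate), and predicts the acetate concentration leaving each zone,
including the fixed acetate credit from yeast-extract fermentation in
the inlet zone.

All ledger arithmetic is molar (mM); mg/L appears only at I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import NotSulfidogenicError, OrderingError
from .reactor import ReactorConfig, SteadyStateObservation
from .units import mg_per_l_to_mm, mm_to_mg_per_l

_EPS = 1e-12


@dataclass(frozen=True)
class StoichiometricReaction:
    """A reaction with signed molar coefficients (negative = consumed)."""

    id: str
    stoichiometry: Mapping[str, float]
    delta_g: float  # kJ/reaction, standard transformed

    def coeff(self, species: str) -> float:
        return self.stoichiometry.get(species, 0.0)

    def sulfate_per_donor(self, donor: str) -> float:
        """Moles of sulfate consumed per mole of donor consumed."""
        d = self.coeff(donor)
        s = self.coeff("sulfate")
        if d >= 0:
            raise ValueError(f"{self.id} does not consume {donor}")
        if s >= 0:
            raise NotSulfidogenicError(f"{self.id} has no sulfate-consumption term")
        return s / d  # both negative -> positive ratio


def _rxn(id_: str, stoich: dict[str, float], dg: float) -> StoichiometricReaction:
    return StoichiometricReaction(id_, MappingProxyType(stoich), dg)


#: The canonical sulfidogenic and fermentative reactions of these reactors.
REACTIONS: Mapping[str, StoichiometricReaction] = MappingProxyType(
    {
        "ACETATE_OX": _rxn(
            "ACETATE_OX",
            {"acetate": -1.0, "sulfate": -1.0, "bicarbonate": 2.0, "sulfide": 1.0},
            -47.6,
        ),
        "PROPIONATE_OX": _rxn(
            "PROPIONATE_OX",
            {
                "propionate": -1.0,
                "sulfate": -0.75,
                "acetate": 1.0,
                "bicarbonate": 1.0,
                "sulfide": 0.75,
                "H+": 0.25,
            },
            -37.7,
        ),
        "LACTATE_INCOMPLETE": _rxn(
            "LACTATE_INCOMPLETE",
            {
                "lactate": -1.0,
                "sulfate": -0.5,
                "acetate": 1.0,
                "bicarbonate": 1.0,
                "sulfide": 0.5,
            },
            -80.2,
        ),
        "LACTATE_COMPLETE": _rxn(
            "LACTATE_COMPLETE",
            {
                "lactate": -2.0,
                "sulfate": -3.0,
                "bicarbonate": 6.0,
                "sulfide": 3.0,
                "H+": 1.0,
            },
            -225.3,
        ),
        "LACTATE_FERMENT": _rxn(
            "LACTATE_FERMENT",
            {
                "lactate": -3.0,
                "acetate": 1.0,
                "propionate": 2.0,
                "bicarbonate": 1.0,
                "H+": 1.0,
            },
            -70.0,
        ),
    }
)


@dataclass(frozen=True)
class FermentationSplit:
    """Lactate routed to fermentation, inferred from net propionate."""

    lactate_fermented: float  # mM
    fermented_fraction_pct: float
    acetate_credit: float  # mM acetate co-produced
    inconsistent: bool  # fermented > supplied


def lactate_fermentation_split(
    net_propionate_produced: float, lactate_supplied: float
) -> FermentationSplit:
    """Infer fermented lactate from net propionate production.

    The 3 lactate → 1 acetate + 2 propionate stoichiometry gives
    1.5 lactate and 0.5 acetate per propionate produced.  An inferred
    fermentation exceeding the supplied lactate is flagged, not raised.
    """
    if lactate_supplied <= 0:
        raise ValueError("lactate_supplied must be > 0")
    if net_propionate_produced < 0:
        raise ValueError("net_propionate_produced must be >= 0")
    fermented = 1.5 * net_propionate_produced
    return FermentationSplit(
        lactate_fermented=fermented,
        fermented_fraction_pct=100.0 * fermented / lactate_supplied,
        acetate_credit=0.5 * net_propionate_produced,
        inconsistent=fermented > lactate_supplied + _EPS,
    )


def theoretical_sulfate_capacity(
    donor: str,
    donor_mm: float,
    sulfate_mm: float,
    reaction: StoichiometricReaction,
) -> float:
    """Max % of the sulfate load reducible by a donor via one reaction."""
    if sulfate_mm <= 0:
        raise ValueError("sulfate_mm must be > 0")
    if donor_mm < 0:
        raise ValueError("donor_mm must be >= 0")
    ratio = reaction.sulfate_per_donor(donor)  # raises if not sulfidogenic
    return 100.0 * min(1.0, donor_mm * ratio / sulfate_mm)


@dataclass
class ZoneBalance:
    """Per-zone attribution ledger (all concentrations mM)."""

    zone: str
    dilution_rate: float
    inputs: dict[str, float]
    outputs: dict[str, float]
    lactate_fermented: float = 0.0
    lactate_to_srm: float = 0.0
    sulfate_via: dict[str, float] = field(default_factory=dict)
    acetate_produced: float = 0.0
    acetate_consumed: float = 0.0
    ye_acetate_credit: float = 0.0
    predicted_acetate_out: float = 0.0
    unexplained_sulfate: float = 0.0
    deficit_flags: list[str] = field(default_factory=list)
    chaining: str = "observed"

    @property
    def sulfate_removed(self) -> float:
        return self.inputs.get("sulfate", 0.0) - self.outputs.get("sulfate", 0.0)


def attribute_zone_sulfate(
    zone_in: Mapping[str, float],
    zone_out: Mapping[str, float],
    config: ReactorConfig,
    zone: str,
    *,
    dilution_rate: float = float("nan"),
    credit_citrate: bool = False,
) -> ZoneBalance:
    """Build the donor-attribution ledger for one zone (inputs in mM).

    Attribution order: (1) the net propionate change — production implies
    lactate fermentation (1.5 lactate and 0.5 acetate per propionate),
    consumption implies propionate oxidation (0.75 sulfate and 1 acetate
    per propionate); (2) lactate consumed beyond the fermented share is
    oxidised incompletely (0.5 sulfate, 1 acetate per lactate), capped at
    the remaining observed removal; (3) any residual removal debits the
    acetate pool 1:1; the inlet zone's pool includes the yeast-extract
    acetate credit.  Removal surviving acetate exhaustion is reported as
    unexplained with a deficit flag.  Negative intermediate quantities
    are flagged and floored, never raised.
    """
    flags: list[str] = []
    s_in = zone_in.get("sulfate", 0.0)
    s_out = zone_out.get("sulfate", 0.0)
    removal = s_in - s_out
    if removal < -_EPS:
        flags.append("negative-sulfate-removal")
    remaining = max(removal, 0.0)

    sulfate_via: dict[str, float] = {}
    acetate_produced = 0.0

    # (1) net propionate change
    d_prop = zone_out.get("propionate", 0.0) - zone_in.get("propionate", 0.0)
    fermented = 0.0
    if d_prop > _EPS:
        lact_in = zone_in.get("lactate", 0.0)
        if lact_in > 0:
            split = lactate_fermentation_split(d_prop, lact_in)
            fermented = split.lactate_fermented
            acetate_produced += split.acetate_credit
            if split.inconsistent:
                flags.append("fermented-exceeds-supplied-lactate")
        else:
            flags.append("propionate-produced-without-lactate")
    elif d_prop < -_EPS:
        prop_consumed = -d_prop
        s_prop = min(0.75 * prop_consumed, remaining)
        if s_prop < 0.75 * prop_consumed - _EPS:
            flags.append("propionate-consumption-exceeds-sulfate-removal")
        prop_reacted = s_prop / 0.75
        if s_prop > _EPS:
            sulfate_via["PROPIONATE_OX"] = s_prop
        acetate_produced += prop_reacted  # 1 acetate per propionate oxidised
        remaining -= s_prop

    # (2) lactate beyond the fermented share -> incomplete oxidation
    lactate_consumed = zone_in.get("lactate", 0.0) - zone_out.get("lactate", 0.0)
    if lactate_consumed < -_EPS:
        flags.append("net-lactate-production")
        lactate_consumed = 0.0
    available = max(lactate_consumed - fermented, 0.0)
    if fermented > lactate_consumed + _EPS:
        flags.append("fermented-exceeds-consumed-lactate")
    s_lact = min(0.5 * available, remaining)
    lact_reacted = s_lact / 0.5
    if s_lact > _EPS:
        sulfate_via["LACTATE_INCOMPLETE"] = s_lact
    acetate_produced += lact_reacted
    remaining -= s_lact

    # citrate: excluded from the sulfidogenic ledger; optionally credited
    if credit_citrate:
        cit_consumed = zone_in.get("citrate", 0.0) - zone_out.get("citrate", 0.0)
        if cit_consumed > _EPS:
            acetate_produced += cit_consumed

    # (3) residual removal debits the acetate pool
    ye_credit = 0.0
    first_zone = config.zones[0].name if config.zones else "inlet"
    if zone == first_zone:
        ye_credit = mg_per_l_to_mm(config.yeast_extract_acetate_credit, "acetate")
    pool = zone_in.get("acetate", 0.0) + acetate_produced + ye_credit
    acetate_consumed = min(remaining, pool)
    if acetate_consumed > _EPS:
        sulfate_via["ACETATE_OX"] = acetate_consumed
    unexplained = remaining - acetate_consumed
    if unexplained > 1e-9:
        flags.append("acetate-exhausted-unexplained-sulfate")
    else:
        unexplained = max(unexplained, 0.0)

    return ZoneBalance(
        zone=zone,
        dilution_rate=dilution_rate,
        inputs=dict(zone_in),
        outputs=dict(zone_out),
        lactate_fermented=fermented,
        lactate_to_srm=lact_reacted,
        sulfate_via=sulfate_via,
        acetate_produced=acetate_produced,
        acetate_consumed=acetate_consumed,
        ye_acetate_credit=ye_credit,
        predicted_acetate_out=pool - acetate_consumed,
        unexplained_sulfate=unexplained,
        deficit_flags=flags,
    )


def attribute_reactor(
    zone_profile: Sequence[tuple[str, Mapping[str, float], Mapping[str, float]]],
    config: ReactorConfig,
    *,
    dilution_rate: float = float("nan"),
    chaining: str = "observed",
    credit_citrate: bool = False,
) -> list[ZoneBalance]:
    """Attribute every zone of one steady state, inlet → effluent.

    ``zone_profile`` is an ordered list of (zone, inlet composition,
    outlet composition) in mM.  With ``chaining="predicted"`` each
    downstream zone's acetate input is replaced by the upstream zone's
    predicted acetate; the default uses the observed compositions.
    """
    if chaining not in ("observed", "predicted"):
        raise ValueError("chaining must be 'observed' or 'predicted'")
    expected = [z.name for z in config.zones]
    names = [z for z, _, _ in zone_profile]
    if names != expected[: len(names)]:
        raise OrderingError(f"zones {names} do not follow configured order {expected}")
    balances: list[ZoneBalance] = []
    prev: ZoneBalance | None = None
    for zone, zin, zout in zone_profile:
        zin = dict(zin)
        if chaining == "predicted" and prev is not None:
            zin["acetate"] = prev.predicted_acetate_out
        bal = attribute_zone_sulfate(
            zin,
            zout,
            config,
            zone,
            dilution_rate=dilution_rate,
            credit_citrate=credit_citrate,
        )
        bal.chaining = chaining
        balances.append(bal)
        prev = bal
    return balances


def profiles_from_observations(
    observations: Iterable[SteadyStateObservation], config: ReactorConfig
) -> dict[float, list[tuple[str, dict[str, float], dict[str, float]]]]:
    """Zone (inlet, outlet) composition pairs in mM, per dilution rate.

    The feed row supplies the first zone's inlet; each zone's observed
    outlet is the next zone's inlet.  Dilution rates whose sulfate rows
    are excluded are skipped entirely.
    """
    by_rate: dict[float, dict[tuple[str, str], SteadyStateObservation]] = {}
    excluded_rates: set[float] = set()
    for o in observations:
        if o.excluded:
            excluded_rates.add(o.dilution_rate)
            continue
        by_rate.setdefault(o.dilution_rate, {})[(o.zone_boundary, o.analyte)] = o

    profiles: dict[float, list[tuple[str, dict[str, float], dict[str, float]]]] = {}
    for d in sorted(by_rate):
        if d in excluded_rates:
            continue
        rows = by_rate[d]
        boundaries = ["feed"] + [z.name for z in config.zones]
        comps: dict[str, dict[str, float]] = {}
        for b in boundaries:
            comp = {
                analyte: mg_per_l_to_mm(o.mean_conc, analyte)
                for (bb, analyte), o in rows.items()
                if bb == b
            }
            if comp:
                comps[b] = comp
        profile = []
        for upstream, zone in zip(boundaries, boundaries[1:]):
            if upstream in comps and zone in comps:
                profile.append((zone, comps[upstream], comps[zone]))
        if profile:
            profiles[d] = profile
    return profiles


def predict_acetate_profile(
    balances: Sequence[ZoneBalance],
) -> list[dict[str, float | str]]:
    """Predicted acetate leaving each zone, in mM and mg/L.

    Balances must be ordered inlet → effluent; the chaining mode used to
    build them is carried through to the output.
    """
    order = {name: i for i, name in enumerate(("inlet", "middle", "effluent"))}
    idx = [order.get(b.zone, -1) for b in balances]
    if any(b < a for a, b in zip(idx, idx[1:])) or -1 in idx:
        raise OrderingError(f"balances are not in inlet→effluent order: {[b.zone for b in balances]}")
    return [
        {
            "zone": b.zone,
            "predicted_acetate_mM": b.predicted_acetate_out,
            "predicted_acetate_mg_L": mm_to_mg_per_l(b.predicted_acetate_out, "acetate"),
            "chaining": b.chaining,
        }
        for b in balances
    ]


@dataclass(frozen=True)
class PercentDifference:
    """Per-point |obs−pred|/obs in % and its mean across dilution rates."""

    per_point_pct: tuple[float, ...]
    mean_pct: float
    n_excluded_zero_observed: int


def percent_difference_profile(
    observed: Sequence[float], predicted: Sequence[float]
) -> PercentDifference:
    """Mean percent deviation of predictions from observations.

    Points with zero observed concentration are excluded from the mean
    (flagged by count) rather than producing an infinite percentage.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * np.abs(obs - pred) / obs
    valid = obs > 0
    mean = float(pct[valid].mean()) if valid.any() else float("nan")
    per_point = tuple(float(p) if v else float("nan") for p, v in zip(pct, valid))
    return PercentDifference(per_point, mean, int((~valid).sum()))
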