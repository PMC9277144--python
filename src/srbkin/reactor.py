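"""Reactor geometry, feed composition and steady-state observations.

An up-flow anaerobic packed-bed reactor (UAPBR) is described here as an
ordered sequence of zones sampled at their outlets; the feed row of an
observation table carries the inlet composition.  This module provides the
configuration and observation data model, delimited-text I/O, and the
simple derived performance quantities — sulfate conversion, volumetric
sulfate reduction rate (VSRR), volumetric sulfate loading rate (VSLR) and
biofilm cell densities — that the kinetic and mass-balance stages consume.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigError, ObservationParseError, WrongPhaseError
from .units import ANALYTES, mg_per_l_to_mm, mm_to_mg_per_l

ZONE_NAMES = ("inlet", "middle", "effluent")

#: Exact header of the observation table (UTF-8 delimited text).
OBSERVATION_COLUMNS = (
    "dilution_rate_h",
    "zone_boundary",
    "analyte",
    "mean_conc",
    "sd_conc",
    "n",
    "steady",
    "excluded",
    "unit",
    "note",
)


class ZoneSpec(BaseModel):
    """One reactor zone: its own volume and the cumulative volume from the inlet."""

    name: Literal["inlet", "middle", "effluent"]
    volume: float = Field(gt=0.0, description="zone volume, L")
    cumulative_volume: float = Field(gt=0.0, description="volume from reactor inlet, L")


class ReactorConfig(BaseModel):
    """Geometry and feed composition of one packed-bed reactor.

    Feed concentrations are mg/L of the dissolved anion.  The yeast-extract
    acetate credit is the fixed acetate concentration assumed to arise from
    fermentation of the yeast extract in the medium, applied to the inlet
    zone of the donor mass balance.
    """

    reactor_id: str = "reactor"
    working_volume: float = Field(default=1.0, gt=0.0, description="L")
    zones: list[ZoneSpec] = Field(default_factory=lambda: default_zones())
    foam_displacement_fraction: float = Field(default=0.04, ge=0.0, lt=1.0)
    subzone_volume: float = Field(default=0.167, gt=0.0, description="L")
    feed: dict[str, float] = Field(default_factory=lambda: {"sulfate": 1000.0})
    yeast_extract_acetate_credit: float = Field(default=268.0, ge=0.0, description="mg/L acetate")
    primary_donor: Literal["acetate", "lactate"] = "lactate"

    @model_validator(mode="after")
    def _check(self) -> "ReactorConfig":
        if abs(sum(z.volume for z in self.zones) - self.working_volume) > 1e-9:
            raise ValueError("zone volumes must sum to working_volume (±1e-9)")
        cum = [z.cumulative_volume for z in self.zones]
        if any(b <= a for a, b in zip(cum, cum[1:])):
            raise ValueError("cumulative_volume must be strictly increasing")
        for analyte, conc in self.feed.items():
            if analyte not in ANALYTES:
                raise ValueError(f"unknown feed analyte {analyte!r}")
            if conc < 0:
                raise ValueError(f"feed concentration for {analyte!r} must be >= 0")
        return self

    def zone(self, name: str) -> ZoneSpec:
        for z in self.zones:
            if z.name == name:
                return z
        raise KeyError(name)

    def feed_mm(self) -> dict[str, float]:
        """Feed composition in mM."""
        return {a: mg_per_l_to_mm(c, a) for a, c in self.feed.items()}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReactorConfig":
        """Load and schema-validate a reactor configuration file."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping of ReactorConfig fields")
        try:
            return cls.model_validate(raw)
        except Exception as exc:  # pydantic reports explicit error paths
            raise ConfigError(f"{path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def default_zones(working_volume: float = 1.0) -> list[ZoneSpec]:
    """Three equal sequential zones (inlet, middle, effluent)."""
    v = working_volume / 3.0
    # keep the exact 0.33/0.66/1.0 L demarcation for the standard 1 L reactor
    if abs(working_volume - 1.0) < 1e-12:
        vols = [0.33, 0.33, 0.34]
        cums = [0.33, 0.66, 1.0]
    else:
        vols = [v, v, v]
        cums = [v, 2 * v, 3 * v]
    return [
        ZoneSpec(name=n, volume=vol, cumulative_volume=c)
        for n, vol, c in zip(ZONE_NAMES, vols, cums)
    ]


def lactate_reactor_config() -> ReactorConfig:
    """The lactate-supplemented reactor: 13.3 mM lactate, 1.16 mM citrate."""
    return ReactorConfig(
        reactor_id="lactate-uapbr",
        primary_donor="lactate",
        feed={
            "sulfate": 1000.0,
            "lactate": mm_to_mg_per_l(13.3, "lactate"),
            "citrate": mm_to_mg_per_l(1.16, "citrate"),
            "acetate": 0.0,
            "propionate": 0.0,
        },
    )


def acetate_reactor_config() -> ReactorConfig:
    """The acetate-supplemented reactor: 15.3 mM acetate, 1.16 mM citrate."""
    return ReactorConfig(
        reactor_id="acetate-uapbr",
        primary_donor="acetate",
        feed={
            "sulfate": 1000.0,
            "acetate": mm_to_mg_per_l(15.3, "acetate"),
            "citrate": mm_to_mg_per_l(1.16, "citrate"),
            "lactate": 0.0,
            "propionate": 0.0,
        },
    )


@dataclass(frozen=True)
class SteadyStateObservation:
    """One measured concentration at a zone boundary under a dilution rate.

    ``zone_boundary`` names the zone whose outlet the sample represents, or
    ``"feed"`` for the inlet composition.  Concentrations are mg/L.
    """

    dilution_rate: float
    zone_boundary: str
    analyte: str
    mean_conc: float
    sd_conc: float = 0.0
    n_samples: int = 1
    steady: bool = True
    excluded: bool = False
    note: str = ""


@dataclass(frozen=True)
class CellCountRecord:
    """Total cells counted in one phase of one subzone."""

    phase: Literal["planktonic", "biofilm_attached", "biofilm_associated"]
    subzone_index: int | str
    total_cells: float
    reference_volume: float = 0.167  # L


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(raw: object) -> bool:
    if isinstance(raw, bool):
        return raw
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    raise ValueError(f"cannot interpret {raw!r} as a boolean")


def load_observations(
    path: str | Path | io.TextIOBase,
    config: ReactorConfig | None = None,
) -> list[SteadyStateObservation]:
    """Parse an observation table into validated records.

    The file must carry the exact :data:`OBSERVATION_COLUMNS` header
    (comma-delimited by default; tab accepted).  mM rows are converted to
    the canonical mg/L using anion molar masses.  Rows violating the data
    invariants are rejected collectively with row-numbered diagnostics.
    """
    zone_names = tuple(z.name for z in (config.zones if config else default_zones()))
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ObservationParseError(
            f"observation table is missing required column(s): {', '.join(missing)}"
        )

    out: list[SteadyStateObservation] = []
    row_errors: dict[int, str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        problems: list[str] = []
        analyte = str(getattr(row, "analyte")).strip()
        boundary = str(getattr(row, "zone_boundary")).strip()
        unit = str(getattr(row, "unit")).strip()
        if analyte not in ANALYTES:
            problems.append(f"unknown analyte {analyte!r}; allowed: {sorted(ANALYTES)}")
        if boundary != "feed" and boundary not in zone_names:
            problems.append(
                f"unknown zone_boundary {boundary!r}; allowed: ('feed',) + {zone_names}"
            )
        if unit not in ("mg/L", "mM"):
            problems.append(f"unknown unit {unit!r}; allowed: mg/L, mM")
        try:
            d = float(getattr(row, "dilution_rate_h"))
            mean = float(getattr(row, "mean_conc"))
            sd = float(getattr(row, "sd_conc"))
            n = int(float(getattr(row, "n")))
            steady = _parse_bool(getattr(row, "steady"))
            excluded = _parse_bool(getattr(row, "excluded"))
        except ValueError as exc:
            problems.append(str(exc))
        else:
            if d <= 0:
                problems.append(f"dilution_rate_h must be > 0, got {d}")
            if mean < 0:
                problems.append(f"mean_conc must be >= 0, got {mean}")
            if sd < 0:
                problems.append(f"sd_conc must be >= 0, got {sd}")
            if n < 1:
                problems.append(f"n must be >= 1, got {n}")
        if problems:
            row_errors[i] = "; ".join(problems)
            continue
        if unit == "mM" and analyte in ANALYTES:
            mean = mm_to_mg_per_l(mean, analyte)
            sd = mm_to_mg_per_l(sd, analyte)
        out.append(
            SteadyStateObservation(
                dilution_rate=d,
                zone_boundary=boundary,
                analyte=analyte,
                mean_conc=mean,
                sd_conc=sd,
                n_samples=n,
                steady=steady,
                excluded=excluded,
                note=str(getattr(row, "note")).strip(),
            )
        )
    if row_errors:
        lines = "; ".join(f"row {r}: {msg}" for r, msg in sorted(row_errors.items()))
        raise ObservationParseError(f"invalid observation rows — {lines}", row_errors)
    return out


def observations_to_frame(observations: Iterable[SteadyStateObservation]) -> pd.DataFrame:
    """Render observations in the canonical table schema (mg/L)."""
    rows = [
        {
            "dilution_rate_h": o.dilution_rate,
            "zone_boundary": o.zone_boundary,
            "analyte": o.analyte,
            "mean_conc": o.mean_conc,
            "sd_conc": o.sd_conc,
            "n": o.n_samples,
            "steady": o.steady,
            "excluded": o.excluded,
            "unit": "mg/L",
            "note": o.note,
        }
        for o in observations
    ]
    return pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))


def write_observations(
    observations: Iterable[SteadyStateObservation], path: str | Path
) -> None:
    """Write the canonical comma-delimited observation table."""
    observations_to_frame(observations).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Derived performance quantities
# ---------------------------------------------------------------------------


def conversion(c_in: float, c_out: float) -> float:
    """Fractional conversion X = (C_in − C_out)/C_in.

    May be negative when the outlet exceeds the inlet (net production);
    the value is reported as-is, not clamped.
    """
    if c_in <= 0:
        raise ValueError("conversion undefined for C_in <= 0")
    if c_out < 0:
        raise ValueError("C_out must be >= 0")
    return (c_in - c_out) / c_in


def vsrr(c_in: float, c_out: float, flow: float, volume: float) -> float:
    """Zone-mean volumetric sulfate reduction rate, mg·L⁻¹·h⁻¹.

    F·(C_in − C_out)/V; positive for net consumption.
    """
    if volume <= 0:
        raise ValueError("volume must be > 0")
    if flow <= 0:
        raise ValueError("flow must be > 0")
    return flow * (c_in - c_out) / volume


def vslr(c_in: float, flow: float, volume: float) -> float:
    """Volumetric sulfate loading rate F·C_in/V, mg·L⁻¹·h⁻¹."""
    if volume <= 0:
        raise ValueError("volume must be > 0")
    if flow < 0:
        raise ValueError("flow must be >= 0")
    return flow * c_in / volume


def biofilm_density(rec: CellCountRecord, config: ReactorConfig) -> float:
    """Biofilm cell density in cells/mL of foam-corrected subzone volume.

    The packing foam displaces a fraction of every subzone, so counts are
    normalised to subzone_volume × (1 − foam_displacement_fraction).
    """
    if rec.phase == "planktonic":
        raise WrongPhaseError(
            "planktonic densities come directly from counts per mL; "
            "biofilm_density applies to biofilm_attached/biofilm_associated records"
        )
    if rec.total_cells < 0:
        raise ValueError("total_cells must be >= 0")
    ml = config.subzone_volume * (1.0 - config.foam_displacement_fraction) * 1000.0
    return rec.total_cells / ml


def phase_ratio(associated: float, attached: float) -> float:
    """Ratio of biofilm-associated to biofilm-attached cell densities."""
    if attached <= 0:
        raise ValueError("phase ratio undefined for attached density <= 0")
    if associated < 0:
        raise ValueError("associated density must be >= 0")
    return associated / attached
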