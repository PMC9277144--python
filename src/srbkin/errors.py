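"""Exception hierarchy used across the package."""

from __future__ import annotations


class SrbkinError(Exception):
    """Base class for package errors."""


class ConfigError(SrbkinError):
    """Invalid reactor configuration."""


class ObservationParseError(SrbkinError):
    """One or more observation rows failed validation.

    ``row_errors`` maps 1-based data-row numbers to diagnostics.
    """

    def __init__(self, message: str, row_errors: dict[int, str] | None = None):
        super().__init__(message)
        self.row_errors = dict(row_errors or {})


class MissingFeedError(SrbkinError):
    """A dilution rate has zone-outlet rows but no feed sulfate row."""


class InsufficientDataError(SrbkinError):
    """Too few rate points to identify the requested parameters."""


class DegenerateFitError(SrbkinError):
    """All observed rates are zero; only k = 0 is identifiable."""

    def __init__(self, message: str, result=None):
        super().__init__(message)
        self.result = result


class NotSulfidogenicError(SrbkinError):
    """The reaction has no sulfate term (e.g. lactate fermentation)."""


class WrongPhaseError(SrbkinError):
    """A biofilm-only computation was asked of a planktonic record."""


class InfeasibleScenarioError(SrbkinError):
    """Simulated sulfate demand exceeds the electron-donor capacity."""


class OrderingError(SrbkinError):
    """Zone sequence does not follow the configured inlet→effluent order."""
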