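"""Exception hierarchy. Every error carries a short machine-parseable code."""

from __future__ import annotations


class WarfceaError(Exception):
    """Base class for all package errors."""

    code = "E_GENERIC"


class ConfigError(WarfceaError):
    """Configuration file missing, unparseable or invalid."""

    code = "E_CONFIG"


class InfeasibleParameterError(WarfceaError):
    """A transition-matrix row's residual stay probability is negative."""

    code = "E_INFEASIBLE"


class InsufficientDataError(WarfceaError):
    """Too few INR measurements to score a patient."""

    code = "E_INSUFFICIENT_DATA"


class SeriesOrderError(WarfceaError):
    """INR measurement days are not strictly increasing."""

    code = "E_SERIES_ORDER"


class ClassificationError(WarfceaError):
    """Cost-effectiveness class undefined for the given incremental result."""

    code = "E_CLASSIFY"


class InputFormatError(WarfceaError):
    """A data file row failed to parse; message names the line."""

    code = "E_INPUT_FORMAT"
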