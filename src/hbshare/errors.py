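"""Exception hierarchy.

Every error raised by the package derives from :class:`HbshareError` so callers
(and the CLI) can catch package failures without masking programming errors.
"""

from __future__ import annotations


class HbshareError(Exception):
    """Base class for all package errors."""


class ParseError(HbshareError):
    """A file could not be parsed; the message names the offending location."""


class StructureError(HbshareError):
    """Structurally inconsistent input (atom-count mismatch, empty structure...)."""


class QueryError(HbshareError):
    """Malformed atom-selection expression."""


class GeometryError(HbshareError):
    """Degenerate or invalid geometry (coincident atoms, too few points...)."""


class ParameterError(HbshareError, ValueError):
    """Invalid parameter value (non-positive cutoff, unknown element...)."""


class SamplingError(HbshareError):
    """Time series violates a sampling precondition (unequal spacing...)."""


class FeasibilityError(HbshareError):
    """A requested distance set violates a triangle inequality."""


class PackingError(HbshareError):
    """Rejection sampling could not place points at an acceptable rate."""


class DegenerateDistributionError(HbshareError):
    """All samples identical; no histogram / distribution can be formed."""


class FitError(HbshareError):
    """Nonlinear fit failed to converge.

    Carries the moment-based fallback estimates so callers can still proceed.
    """

    def __init__(self, message: str, moment_mu: float, moment_sigma: float):
        super().__init__(message)
        self.moment_mu = moment_mu
        self.moment_sigma = moment_sigma


class GridSizeError(HbshareError):
    """A requested volumetric grid exceeds the size guard."""


class ConfigError(HbshareError):
    """Invalid pipeline run configuration (unknown key, missing input...)."""
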