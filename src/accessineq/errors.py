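"""Exception hierarchy for accessineq."""

from __future__ import annotations


class AccessineqError(Exception):
    """Base class for all package-specific errors."""


class InputError(AccessineqError):
    """Malformed or inconsistent input data."""


class GeographicCoordinateError(InputError):
    """Coordinates look like geographic lat/lon rather than planar meters.

    All internal math is planar Euclidean; inputs must be in a projected
    coordinate system with meter units.
    """


class UnreachableError(AccessineqError):
    """Some origin-destination pairs are not connected on the road network.

    Carries the offending identifiers so callers can report which demand
    blocks (or nodes) could not be routed instead of silently producing
    infinite travel times, which would corrupt the inequality statistics.
    """

    def __init__(self, message: str, unreachable: list | None = None):
        super().__init__(message)
        self.unreachable = list(unreachable) if unreachable is not None else []


class DegenerateRegionError(AccessineqError):
    """Region polygon is invalid or has zero area; CSR sampling undefined."""


class ZeroMeanError(AccessineqError):
    """All access times are zero: the relative mean difference is undefined."""
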