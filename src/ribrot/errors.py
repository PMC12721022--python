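"""Exception hierarchy shared across the pipeline.

Each class maps to one CLI exit code so failure modes can be asserted
precisely: parse/IO problems (2), degenerate geometry (3), bad
configuration (4).
"""


class RibrotError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class StructureParseError(RibrotError):
    """Unreadable or empty coordinate file."""

    exit_code = 2


class DegenerateGeometryError(RibrotError):
    """Geometry that admits no answer: inseparable clouds, translation-
    dominated fields, too few retained atoms, collinear fit sets."""

    exit_code = 3


class ConfigError(RibrotError):
    """Invalid partition/name-map/analysis configuration."""

    exit_code = 4
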