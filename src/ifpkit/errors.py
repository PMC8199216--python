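"""Exception hierarchy shared across the package."""


class IfpkitError(Exception):
    """Base class for all package errors."""


class FormatError(IfpkitError):
    """Malformed input file (PDB, CSV, config)."""


class SelectionError(IfpkitError):
    """An atom/residue selector resolved to nothing."""


class GeometryError(IfpkitError):
    """Degenerate geometry (collinear ring, zero-length vector, ...)."""


class ConfigurationError(IfpkitError):
    """Inconsistent or unsatisfiable analysis/simulation configuration."""


class DegenerateDataError(IfpkitError):
    """Data carry no signal for the requested fit (e.g. flat dose-response)."""
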