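"""Exception hierarchy shared across the package."""


class ProgrnnError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ProgrnnError):
    """An invalid configuration value; the message names the offending field."""


class DimensionError(ProgrnnError):
    """Array/table dimensions inconsistent with the expected layout."""


class FormatError(ProgrnnError):
    """An input table is missing required columns or is otherwise malformed."""


class IntegrityError(ProgrnnError):
    """Keys or fold assignments violate a uniqueness/consistency contract."""


class StateError(ProgrnnError):
    """An operation was called before its required state was established."""


class RangeError(ProgrnnError):
    """A numeric value lies outside its documented range."""


class EmptyInputError(ProgrnnError):
    """A computation received no usable records."""


class TrainingDivergedError(ProgrnnError):
    """Optimization produced a non-finite loss."""
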