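"""Exception hierarchy.

Every error raised by the package derives from :class:`BindfoldError` so a
caller (the CLI in particular) can map failures onto exit codes: usage
problems, data/format problems, and fit failures are distinguished.
"""


class BindfoldError(Exception):
    """Base class for all package errors."""


class FormatError(BindfoldError):
    """Malformed or internally inconsistent input file."""


class EmptyInputError(BindfoldError):
    """An operation received an empty ensemble, selection or sample."""


class SelectionError(BindfoldError):
    """Unknown residue template or empty atom selection."""


class LookupError_(BindfoldError):
    """A requested chain/residue/site is absent from the ensemble."""


class GeometryError(BindfoldError):
    """Degenerate geometry (too few points, collinear sets, zero mass)."""


class CorrespondenceError(BindfoldError):
    """Two ensembles that must share a site list do not."""


class FitError(BindfoldError):
    """Nonlinear fit failed to converge or the model is unidentifiable."""


class UnidentifiableModelError(FitError):
    """The data cannot constrain the model (e.g. constant series)."""


class NoTransitionError(FitError):
    """A transition-probability series never crosses P = 0.5."""


class InsufficientDataError(BindfoldError):
    """Not enough frames/points for the requested statistic."""


class ConfigError(BindfoldError):
    """Invalid configuration value."""
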