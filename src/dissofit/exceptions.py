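"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`DissofitError`
so callers can catch one type at the pipeline boundary.
"""


class DissofitError(Exception):
    """Base class for all errors raised by dissofit."""


class FormatError(DissofitError):
    """A file or table does not have the expected layout (e.g. missing column)."""


class ProfileValidationError(DissofitError):
    """A dissolution profile violates an invariant (time order, release bounds)."""


class ComparisonError(DissofitError):
    """Two profiles cannot be compared (too few common points, zero reference)."""


class InsufficientDataError(DissofitError):
    """A kinetic fit was requested on fewer points than the model needs."""


class ModelSkipped(DissofitError):
    """Signal that a model cannot be fit to this profile (not a hard failure).

    ``analyze_profile`` catches this and records the reason in
    ``skipped_models`` instead of aborting the report.
    """


class AnalysisError(DissofitError):
    """A whole analysis stage failed (all models skipped, unknown id, ...)."""


class FormulationError(DissofitError):
    """Inconsistent formulation arithmetic (negative inferred mass, zero carrier)."""
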