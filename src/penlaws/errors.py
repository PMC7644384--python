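"""Exception hierarchy shared across the package."""


class PenlawsError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PenlawsError):
    """A session file does not match the documented CSV/JSON schema."""


class ValidationError(PenlawsError):
    """A trial violates a data-model invariant (carries subject/trial ids)."""


class EmptyTrialError(PenlawsError):
    """A trial has no pen-down samples where some are required."""


class TooShortError(PenlawsError):
    """Too few samples for the requested operation."""


class NonUniformSamplingError(PenlawsError):
    """Sampling is too irregular for the uniform-rate filter."""


class SegmentationError(PenlawsError):
    """Letter-transition search failed; trial needs manual boundaries."""


class MismatchError(PenlawsError):
    """Stroke count does not match the expected symbol count."""


class DegenerateError(PenlawsError):
    """A statistical test received degenerate input (e.g. all-zero diffs)."""


class IncompleteTrialError(PenlawsError):
    """A steering trial never reached the required progress landmarks."""


class ConfigError(PenlawsError):
    """Inconsistent analysis or cohort configuration."""
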