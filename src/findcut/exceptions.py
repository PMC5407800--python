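"""Exception hierarchy; each class carries the CLI exit code it maps to."""


class FindcutError(Exception):
    """Base class for all findcut errors."""

    exit_code = 1


class ConfigurationError(FindcutError):
    """Invalid user configuration: missing columns, bad argument ranges."""

    exit_code = 2


class CohortValidationError(FindcutError):
    """Input data violates an invariant (e.g. non-binary event indicator)."""

    exit_code = 3


class DegenerateDataError(FindcutError):
    """Data cannot support the requested fit (no events, one outcome class)."""

    exit_code = 3


class NoFeasibleSplitError(FindcutError):
    """No candidate cutpoint tuple satisfies the group-size/event constraints."""

    exit_code = 4
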