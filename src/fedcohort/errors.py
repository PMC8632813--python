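"""Exception hierarchy shared across the package."""


class FedcohortError(Exception):
    """Base class for all package-specific errors."""


class SpecValidationError(FedcohortError):
    """A distribution spec or schema violates its invariants."""


class FormatError(FedcohortError):
    """A file or serialized blob does not conform to the expected layout."""


class SchemaConflictError(FedcohortError):
    """Two schemas disagree on the kind of a shared variable."""


class CenterMismatchError(FedcohortError):
    """A per-center model was applied to data from a different center."""


class DegenerateDataError(FedcohortError):
    """Input data lacks the variation an operation requires (e.g. one class)."""


class ContractError(FedcohortError):
    """A learner operation was invoked outside its contract."""


class IncompatibleModelError(FormatError):
    """A serialized model envelope has an unsupported format version."""
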