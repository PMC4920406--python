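"""Exception types shared across the package."""


class MeadowForageError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MeadowForageError, ValueError):
    """A quantity lies outside the physically meaningful domain of a formula."""


class InputError(MeadowForageError, ValueError):
    """Malformed or inconsistent input records (mixed species, duplicates, empty)."""


class DegenerateObservationError(MeadowForageError, ValueError):
    """An observation for which an estimator is mathematically undefined."""


class InvalidEstimateError(MeadowForageError, ValueError):
    """An estimator produced a value outside its admissible range (e.g. a
    non-positive floral longevity); flagged rather than silently returned."""
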