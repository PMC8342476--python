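"""Exception hierarchy."""


class PhotoallocError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PhotoallocError):
    """Malformed or inconsistent configuration input."""


class ValidationError(PhotoallocError):
    """A domain object violates one of its invariants."""


class InfeasibleAllocationError(PhotoallocError):
    """An allocation implies a physically impossible state.

    The main case is a negative light-harvesting-complex abundance: at
    extreme values of the linear-electron-transport proportion ``p`` the
    chlorophyll bookkeeping of the thylakoid membrane cannot be satisfied
    with non-negative complex counts.
    """


class ConvergenceError(PhotoallocError):
    """An inner steady-state solve failed to converge."""
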