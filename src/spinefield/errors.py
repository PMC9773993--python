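"""Exception hierarchy."""


class SpinefieldError(Exception):
    """Base class for all package-specific errors."""


class AnatomyError(SpinefieldError):
    """Invalid anatomy parameters or failed anatomy invariant."""


class ResolutionError(AnatomyError):
    """Grid resolution too coarse to resolve a thin structure."""


class SegmentRangeError(SpinefieldError):
    """Queried z-coordinate lies outside the spinal-segment map."""


class TissueLookupError(SpinefieldError, KeyError):
    """Unknown tissue name in the conductivity table."""


class PlacementError(SpinefieldError):
    """Electrode cannot be stamped at the requested location."""


class AssemblyError(SpinefieldError):
    """Linear system could not be assembled (e.g. disconnected electrodes)."""


class ConvergenceError(SpinefieldError):
    """Iterative solver failed to reach the requested residual."""


class ConservationError(SpinefieldError):
    """Anode/cathode current mismatch beyond the discretization budget."""


class ComparisonError(SpinefieldError):
    """Montage comparison over incompatible runs."""
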