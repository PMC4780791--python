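"""Exception hierarchy shared across the package."""


class PermeonError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PermeonError):
    """Malformed input file (missing columns, unparsable values)."""


class ValidationError(PermeonError):
    """Input parses but violates a structural invariant."""


class EmptyTrajectoryError(ValidationError):
    """An operation produced or received a trajectory with no frames."""


class CapacityError(ValidationError):
    """More ions were assigned to a binding site than its capacity allows."""


class ThresholdEstimationError(PermeonError):
    """Density profile does not support the requested number of sites."""


class UndefinedRatioError(PermeonError):
    """Mechanism ratio requested with zero classified conduction events."""


class InfiniteDeltaGError(PermeonError):
    """Free-energy difference requested for a group with zero occupancy."""
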