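"""Exception hierarchy shared across the package."""


class RspGaitError(Exception):
    """Base class for all rspgait errors."""


class ConfigError(RspGaitError):
    """A trial configuration key is missing, malformed, or violates an invariant."""


class FormatError(RspGaitError):
    """A session file is structurally invalid (e.g. non-uniform time grid)."""


class VocabularyError(RspGaitError):
    """A results row uses a variable name outside the declared vocabulary."""


class ParameterError(RspGaitError):
    """A numeric parameter is outside its admissible range."""


class DataError(RspGaitError):
    """Input data are unusable (NaN, too short, overlapping intervals)."""


class GeometryError(RspGaitError):
    """A geometric precondition fails (e.g. contact length exceeds leg sweep)."""


class NonSteadyTrialError(RspGaitError):
    """Stride-average vertical force deviates too far from body weight."""


class MissingLegError(RspGaitError):
    """A per-leg aggregate was requested for a leg with no steps."""


class InsufficientDataError(RspGaitError):
    """Too few samples in a window to compute the requested quantity."""


class DegenerateInputError(RspGaitError):
    """An input combination makes the statistic undefined (zero denominator/variance)."""


class DesignError(RspGaitError):
    """The statistical design is unusable (single subject, aliased terms)."""


class SimulationError(RspGaitError):
    """Base class for spring-mass simulation failures."""


class FallError(SimulationError):
    """The simulated centre of mass reached the ground during stance."""


class NoGaitError(SimulationError):
    """No periodic running gait exists for the requested parameters."""
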