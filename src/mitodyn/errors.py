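"""Exception types shared across the package."""


class MitodynError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(MitodynError):
    """An input is structurally valid but makes a formula undefined
    (e.g. zero denominator in the ATP production factor, zero tumor volume)."""


class DivergenceError(MitodynError):
    """The integrator left the configured magnitude cap.

    Carries ``last_valid_time``, the last time at which the state was finite
    and within the cap.
    """

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class SchemaError(MitodynError):
    """A tabular input does not conform to its documented CSV schema."""


class ContractError(MitodynError):
    """Arguments violate an operation's contract (e.g. comparing trajectories
    from different cell lines)."""
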