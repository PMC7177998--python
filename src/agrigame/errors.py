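"""Exception hierarchy."""


class AgrigameError(Exception):
    """Base class for all package errors."""


class ParameterError(AgrigameError):
    """A parameter set violates a hard model constraint."""


class InsufficientParameterizationError(AgrigameError):
    """A payoff-level quantity needs a damage-complement field that was not supplied.

    The lumped damages ke*be and kh*bh drive the dynamics; the complements
    (1-ke)*be and (1-kh)*bh only enter individual payoff cells and are optional.
    """

    def __init__(self, field: str, context: str = "") -> None:
        self.field = field
        msg = f"insufficient parameterization: field '{field}' is required"
        if context:
            msg += f" for {context}"
        super().__init__(msg)


class IntegrationError(AgrigameError):
    """The ODE solver failed or left the unit cube beyond the clamping tolerance."""

    def __init__(self, message: str, t_reached: float | None = None) -> None:
        self.t_reached = t_reached
        if t_reached is not None:
            message = f"{message} (time reached: {t_reached})"
        super().__init__(message)


class ContractViolationError(AgrigameError):
    """An operation was called on input violating its precondition."""


class ConfigError(AgrigameError):
    """A run configuration file failed to parse or validate."""


class SamplingBudgetError(AgrigameError):
    """The rejection sampler exhausted its draw budget for a stability condition."""

    def __init__(self, condition: int, budget: int) -> None:
        self.condition = condition
        self.budget = budget
        super().__init__(
            f"sampling budget of {budget} draws exhausted for condition {condition}; "
            "the target parameter region is too thin under the uniform proposal"
        )
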