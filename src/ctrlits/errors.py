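"""Exception types shared across the package."""


class CtrlitsError(Exception):
    """Base class for package errors."""


class ParameterError(CtrlitsError, ValueError):
    """Invalid parameter value (negative length, rho outside [0, 1), ...)."""


class DegenerateDataError(CtrlitsError, ValueError):
    """Input data carries no usable information (e.g. constant time values)."""


class StructuralError(CtrlitsError, ValueError):
    """Data violates a structural requirement (e.g. unbalanced panel)."""


class SelectionError(CtrlitsError, RuntimeError):
    """Model selection failed for every candidate."""

    def __init__(self, failures):
        self.failures = dict(failures)
        msg = "; ".join(f"k={k}: {err}" for k, err in self.failures.items())
        super().__init__(f"all candidate fits failed ({msg})")


class ConfigError(CtrlitsError, ValueError):
    """Configuration file violates the schema."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration: " + "; ".join(self.problems))
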