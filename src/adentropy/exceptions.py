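"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration is internally inconsistent or infeasible.

    Raised e.g. when correlation targets do not admit a positive
    semi-definite completion, or when the requested correlation structure
    leaves no variance for the residual noise of an output.
    """


class DegenerateScaleError(ValueError):
    """A variable is constant where a non-zero scale is required."""


class DegenerateDistributionError(ValueError):
    """A sample is (numerically) a point mass; differential entropy diverges."""


class DependencyError(RuntimeError):
    """A pipeline stage was requested before its upstream artifacts exist."""
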