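"""Exception and warning types shared across the package."""


class InvalidParameterError(ValueError):
    """A scalar input is outside its admissible range."""


class SingularCovarianceError(RuntimeError):
    """A covariance or information matrix is not positive definite."""


class InfeasibleDesignError(ValueError):
    """No design satisfies the budgetary constraint (or the candidate set is empty)."""


class ConfigurationError(ValueError):
    """A configuration document contains unknown, out-of-range or conflicting keys."""


class SmallSampleWarning(UserWarning):
    """Fewer than 20 clusters: random cluster effects may not be trustworthy."""
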