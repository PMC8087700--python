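"""Exception hierarchy."""


class FeatPercError(Exception):
    """Base class for all package errors."""


class DomainError(FeatPercError, ValueError):
    """A parameter or argument lies outside its admissible domain."""


class TruncationError(FeatPercError, ValueError):
    """The degree truncation cap cannot reach the requested tail tolerance."""


class ConvergenceError(FeatPercError, RuntimeError):
    """An iterative routine failed to converge; carries the last iterate."""

    def __init__(self, message, last=None, iterations=None):
        super().__init__(message)
        self.last = last
        self.iterations = iterations


class BracketingError(FeatPercError, ValueError):
    """A root bracket does not enclose a sign change."""


class IntegrationError(FeatPercError, RuntimeError):
    """ODE integration diverged or exceeded its horizon without settling."""


class FitError(FeatPercError, RuntimeError):
    """Nonlinear least squares failed; carries best-so-far parameters."""

    def __init__(self, message, params=None, residuals=None):
        super().__init__(message)
        self.params = params
        self.residuals = residuals
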