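"""Exception hierarchy.

Exit-code mapping used by the CLI: :class:`InputError` (and subclasses) map to
exit code 2, estimation-stage failures (:class:`FitFailureError`,
:class:`EstimationError`, :class:`PhaseNotFoundError`) to exit code 3.
"""


class SprintMechError(Exception):
    """Base class for all package-specific errors."""


class InputError(SprintMechError, ValueError):
    """Invalid user-supplied input (bad spec, malformed file, bad argument)."""


class ParseError(InputError):
    """Malformed trace or table file; carries the first offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class FitFailureError(SprintMechError, RuntimeError):
    """Nonlinear velocity-model fit did not converge; carries the best RSS seen."""

    def __init__(self, message: str, best_rss: float | None = None):
        self.best_rss = best_rss
        super().__init__(message)


class EstimationError(SprintMechError, RuntimeError):
    """A profile/regression estimate is undefined on the given input."""


class PhaseNotFoundError(SprintMechError, RuntimeError):
    """No deceleration phase satisfying the definition exists in the trace."""
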