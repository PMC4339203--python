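"""Exception hierarchy for mnf3d.

All errors derive from :class:`MNFError` so callers can catch the package's
failures with a single except clause; the subclasses distinguish bad
parameters from data-driven failures (degenerate samples, non-convergence).
"""


class MNFError(Exception):
    """Base class for all mnf3d errors."""


class ParameterError(MNFError, ValueError):
    """An argument violates a precondition (non-positive shape/scale, bad size...)."""


class DegenerateSampleError(MNFError):
    """A sample is too uniform to estimate from (zero variance of the squared envelope)."""


class InsufficientDataError(MNFError):
    """Fewer usable samples than the configured minimum."""


class ConvergenceError(MNFError):
    """An iterative fit failed to converge; carries iterate diagnostics."""

    def __init__(self, message, iterates=None):
        super().__init__(message)
        self.iterates = iterates


class DegenerateProfileError(MNFError):
    """A multi-scale increment profile has fewer than two usable scales."""


class PipelineError(MNFError):
    """A pipeline stage failed; names the stage and the offending volume."""

    def __init__(self, stage, volume_id, message):
        super().__init__(f"stage '{stage}' failed for volume '{volume_id}': {message}")
        self.stage = stage
        self.volume_id = volume_id
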