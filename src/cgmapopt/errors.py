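"""Exception hierarchy.

The CLI maps :class:`ParameterError` / :class:`ConfigurationError` to exit
code 2 and :class:`DataError` / :class:`FormatError` to exit code 3.
"""


class CGMapError(Exception):
    """Base class for all package errors."""


class ParameterError(CGMapError, ValueError):
    """Invalid argument value (bad spring constant, out-of-range index, ...)."""


class ConfigurationError(CGMapError):
    """Inconsistent request, e.g. an analytic metric asked of a trajectory."""


class ConnectivityError(CGMapError):
    """The interaction graph of a network model is disconnected."""

    def __init__(self, message, components=None):
        super().__init__(message)
        self.components = components


class InvalidSystemError(CGMapError):
    """A matrix violates the harmonic-system invariants (e.g. negative mode)."""


class DegenerateMappingError(CGMapError):
    """Mapped covariance is rank-deficient beyond the single translation mode."""


class FormatError(CGMapError):
    """Unparseable input file (PDB, force-field config, score table)."""


class DataError(CGMapError):
    """Trajectory/feature data unusable (too short, overlapping splits, ...)."""


class SimulationBlowupError(CGMapError):
    """Non-finite energy encountered during integration."""

    def __init__(self, message, step=None):
        super().__init__(message)
        self.step = step
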