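"""Exception and warning classes shared across the package."""


class StampedeError(Exception):
    """Base class for all errors raised by this package."""


class ProtocolError(StampedeError, ValueError):
    """Invalid stimulus-block or timeline parameters."""


class OutOfRangeError(StampedeError, ValueError):
    """A query time or position fell outside its valid interval."""


class ConfigError(StampedeError, ValueError):
    """Malformed run configuration; the message names the offending key."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"{key}: {message}")


class InsufficientDataError(StampedeError, ValueError):
    """Not enough frames/samples to perform the requested estimate."""


class RenderError(StampedeError, ValueError):
    """A fly position fell outside the arena during rendering."""


class PipelineDependencyError(StampedeError, RuntimeError):
    """A pipeline stage is missing its upstream artifact."""


class StatisticalInputError(StampedeError, ValueError):
    """Degenerate input (n < 2 or zero variance) to a statistical test."""


class CalibrationWarning(UserWarning):
    """Tracked positions fall outside the arena beyond tolerance."""
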