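"""Package-level exception hierarchy."""


class ExotropyError(Exception):
    """Base class for all errors raised by exotropy."""


class ConfigError(ExotropyError, ValueError):
    """Invalid simulation or run configuration."""


class ParseError(ExotropyError, ValueError):
    """Malformed input file; message carries the offending line/column."""


class ConvergenceError(ExotropyError, RuntimeError):
    """Iterative fit failed to converge; carries the convergence record."""

    def __init__(self, message, record=None):
        super().__init__(message)
        self.record = record
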