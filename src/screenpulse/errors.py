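"""Exception hierarchy.

The CLI maps these onto fixed exit codes: configuration problems exit 2,
data/format problems exit 3, numerical failures exit 4.
"""


class ScreenPulseError(Exception):
    """Base class for all screenpulse errors."""


class ConfigError(ScreenPulseError):
    """Invalid run configuration or arguments (exit code 2)."""


class FormatError(ScreenPulseError):
    """Malformed input file (exit code 3)."""


class ConsistencyError(ScreenPulseError):
    """Inputs that are individually valid but mutually inconsistent (exit code 3)."""


class NormalizationError(ScreenPulseError):
    """Size-factor or control normalization could not be computed (exit code 4)."""


class FitError(ScreenPulseError):
    """Likelihood optimization failure (exit code 4)."""
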