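"""Exception hierarchy for the toolkit."""


class SuperletToolkitError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(SuperletToolkitError, ValueError):
    """An argument or configuration value is invalid."""


class InputError(SuperletToolkitError, ValueError):
    """An input array/file does not satisfy an operation's preconditions."""


class DegenerateInputError(InputError):
    """The input is formally valid but degenerate (e.g. an all-zero TFR)."""


class GuardrailError(SuperletToolkitError, ValueError):
    """A recording exceeds a processing guardrail (sample rate or length)."""


class FormatError(SuperletToolkitError, ValueError):
    """An audio file cannot be read or has an unsupported encoding."""
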