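"""Exception hierarchy shared across the pipeline stages."""


class InvscanError(Exception):
    """Base class for all invscan errors."""


class VcfFormatError(InvscanError):
    """The VCF input violates the format contract (header or data lines)."""


class InputError(InvscanError):
    """Structurally valid input that the operation cannot accept."""


class ParameterError(InvscanError):
    """A parameter is outside its documented domain."""
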