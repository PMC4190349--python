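"""Exception hierarchy.

``InputError`` maps to CLI exit code 1 (bad data), ``ConfigurationError``
to exit code 2 (bad parameters / unknown detector).
"""


class ApgwaveError(Exception):
    """Base class for all apgwave errors."""


class InputError(ApgwaveError):
    """A signal or annotation file failed validation."""


class ConfigurationError(ApgwaveError):
    """A parameter value is outside its admissible range."""
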