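"""Exception hierarchy.

PSSMFormatError covers unreadable or malformed inputs (CLI exit code 2);
ConfigError covers invalid run parameters (CLI exit code 3).
"""


class PSSMError(Exception):
    """Base class for all package errors."""


class PSSMFormatError(PSSMError):
    """Malformed PSSM or peptide input."""


class ConfigError(PSSMError):
    """Invalid configuration parameter."""
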