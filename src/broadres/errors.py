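"""Exception hierarchy shared by every stage.

Exit-code mapping used by the CLI: ConfigError -> 2, ValidationError and
FormatError -> 3, any other BroadresError -> 4.
"""


class BroadresError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(BroadresError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(BroadresError):
    """Inputs are well-formed but violate a domain invariant."""


class ConfigError(BroadresError):
    """A run configuration is invalid before any stage executes."""
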