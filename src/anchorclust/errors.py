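"""Exception hierarchy shared across the package."""


class AnchorClustError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AnchorClustError):
    """Invalid user-supplied configuration (bad column name, bad parameter)."""


class EmptyInputError(AnchorClustError):
    """An input file or table contained no usable sequences."""


class ContractError(AnchorClustError):
    """An internal precondition was violated (e.g. mixed sequence lengths)."""
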