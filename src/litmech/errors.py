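"""Exception hierarchy shared across the package."""


class LitmechError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LitmechError):
    """An input file violates the documented dialect."""


class ContractError(LitmechError):
    """A precondition of an operation was violated."""
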