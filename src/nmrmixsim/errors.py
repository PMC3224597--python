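"""Exception types shared across the package."""


class NmrMixSimError(Exception):
    """Base class for all package errors."""


class ValidationError(NmrMixSimError, ValueError):
    """Input violates a documented contract (bad value, inconsistent table...)."""


class FormatError(NmrMixSimError, ValueError):
    """A file on disk cannot be parsed in the declared dialect."""
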