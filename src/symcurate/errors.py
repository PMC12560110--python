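class SymcurateError(Exception):
    """Base class for all errors raised by this package."""


class DataError(SymcurateError):
    """Malformed or inconsistent input data (bad record, bounds violation...)."""
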