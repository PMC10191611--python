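"""Exception hierarchy."""


class FrugalignError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FrugalignError, ValueError):
    """Invalid parameters or incompatible widths."""


class InputError(FrugalignError, ValueError):
    """Malformed user input (files, CIGARs, flags)."""


class InternalError(FrugalignError, RuntimeError):
    """A condition that is unreachable by construction; indicates a bug."""


class OutOfRegionError(InternalError):
    """A traceback touched a store cell that was discarded by trimming."""
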