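"""Exception types shared across the package."""


class AmplicladeError(Exception):
    """Base class for all package errors."""


class FormatError(AmplicladeError):
    """A file violated its declared format; message names the line where possible."""


class AlphabetError(AmplicladeError):
    """A sequence contained a character outside its declared alphabet."""


class PrimerDesignError(AmplicladeError):
    """A candidate primer could not be produced (gaps, degeneracy cap, ...)."""
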