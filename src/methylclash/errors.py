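"""Exception hierarchy."""


class MethylClashError(Exception):
    """Base class for all package errors."""


class StructureFormatError(MethylClashError):
    """The coordinate file could not be parsed under the requested dialect."""


class StructureContentError(MethylClashError):
    """The structure lacks content required for analysis (e.g. no DNA chain)."""


class GraftingError(MethylClashError):
    """Methyl grafting failed, e.g. base atoms required for superposition are missing."""
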