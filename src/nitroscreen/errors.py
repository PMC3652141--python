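"""Exception hierarchy shared across the package."""


class NitroscreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NitroscreenError):
    """A tabular input is malformed (missing column, bad header, ...)."""


class ParseError(NitroscreenError):
    """A cell or token could not be parsed as the expected type."""


class StructureError(NitroscreenError):
    """A SMILES string or molecular fragment is chemically invalid."""


class InputError(NitroscreenError):
    """A record lacks a field required by the requested computation."""
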