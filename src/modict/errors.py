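"""Exception hierarchy shared by all modules.

Exit-code mapping used by the CLI: usage errors are handled by click (2),
:class:`FormatError` maps to 3, :class:`ContractError` to 4.
"""


class ModictError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ModictError):
    """Malformed input file (PDB, rmsd, weight, conservation, TSV)."""


class ContractError(ModictError):
    """Inputs violate a documented precondition of an operation."""
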