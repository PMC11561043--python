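"""Exception types shared across the package."""


class CogmapError(Exception):
    """Base class for all package errors."""


class SmilesParseError(CogmapError):
    """Raised when a SMILES string cannot be parsed or sanitized.

    Carries the offending string and the record id so batch callers can
    log and skip rather than abort.
    """

    def __init__(self, smiles: str, mol_id: str, reason: str = "") -> None:
        self.smiles = smiles
        self.mol_id = mol_id
        msg = f"cannot parse SMILES for {mol_id!r}: {smiles!r}"
        if reason:
            msg += f" ({reason})"
        super().__init__(msg)


class SchemaError(CogmapError):
    """A tabular input is missing a required column or malformed."""


class InputError(CogmapError):
    """Input values violate an operation's preconditions."""


class GraphBuildError(CogmapError):
    """Referential integrity violation while assembling the graph."""
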