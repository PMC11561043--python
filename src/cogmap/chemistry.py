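"""Small-molecule similarity primitives.

Two similarity measures are implemented:

* **PARITY** — the proportion of atoms residing in identical topology.
  The largest connected common substructure (MCS) of the two heavy-atom
  graphs is found under element-identity atom matching, ignoring bond
  order, aromaticity and formal charge, and scored with the Jaccard
  normalization ``|MCS| / (N_a + N_b - |MCS|)``. A score of 1 means the
  heavy-atom graphs are isomorphic under element labels; 0 means no
  common atom environment at all.

* **MACCS/Tanimoto** — 166-key MACCS structural fingerprints with
  Tanimoto (Jaccard) similarity on the bit sets, used to compare cognate
  ligands with one another when profiling domain chemistry.

All chemistry is 2D topological; hydrogens are implicit and excluded
from every atom count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys, rdFMCS

from .errors import InputError, SmilesParseError

logger = logging.getLogger(__name__)

# RDKit logs every sanitization failure to stderr; we surface those as
# exceptions/warnings ourselves.
RDLogger.DisableLog("rdApp.error")

MACCS_N_BITS = 166
MACCS_KEY_VERSION = "MACCS-166-rdkit"

#: default per-pair MCS search budget in seconds
DEFAULT_MCS_TIMEOUT_S = 10.0


@dataclass(frozen=True)
class Molecule:
    """A sanitized heavy-atom molecular graph parsed from SMILES.

    ``smiles`` is the RDKit canonical form of the (largest fragment of
    the) input; ``n_heavy`` counts non-hydrogen atoms only.
    """

    id: str
    smiles: str
    n_heavy: int
    rdkit_mol: Chem.Mol = field(repr=False, compare=False, hash=False)

    def elements(self) -> list[str]:
        """Element symbols of the heavy atoms, in RDKit atom order."""
        return [a.GetSymbol() for a in self.rdkit_mol.GetAtoms()]

    def bonds(self) -> list[tuple[int, int]]:
        """Heavy-atom bond list as (begin, end) atom-index pairs."""
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx())
            for b in self.rdkit_mol.GetBonds()
        ]


@dataclass(frozen=True)
class ParityResult:
    """Outcome of one PARITY comparison.

    ``timed_out`` marks scores where the MCS search hit its time budget;
    the score is then a lower bound (best substructure found so far),
    never silently presented as exact.
    """

    score: float
    mcs_atom_count: int
    timed_out: bool = False


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length 166-bit MACCS structural key vector."""

    bits: np.ndarray
    key_version: str = MACCS_KEY_VERSION

    def __post_init__(self) -> None:
        if self.bits.shape != (MACCS_N_BITS,):
            raise InputError(
                f"fingerprint must have {MACCS_N_BITS} bits, "
                f"got shape {self.bits.shape}"
            )

    def popcount(self) -> int:
        return int(self.bits.sum())


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the largest fragment by heavy-atom count.

    Salt/solvate SMILES carry several dot-separated fragments; ties are
    broken by lexicographically smallest canonical SMILES so the choice
    is deterministic.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    return min(frags, key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))


def parse_smiles(smiles: str, id: str) -> Molecule:
    """Parse and sanitize a SMILES string into a heavy-atom :class:`Molecule`.

    Multi-fragment inputs keep the largest fragment by heavy-atom count
    (lexicographic canonical-SMILES tie-break). Raises
    :class:`SmilesParseError` on empty, unparseable or valence-invalid
    input.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles, id, "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, id)
    mol = _largest_fragment(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - rdkit raises many types
        raise SmilesParseError(smiles, id, str(exc)) from exc
    mol = Chem.RemoveHs(mol)
    n_heavy = mol.GetNumHeavyAtoms()
    if n_heavy < 1:
        raise SmilesParseError(smiles, id, "no heavy atoms")
    return Molecule(id=id, smiles=Chem.MolToSmiles(mol), n_heavy=n_heavy,
                    rdkit_mol=mol)


def parse_smiles_batch(
    records: list[tuple[str, str]], on_error: str = "skip"
) -> list[Molecule]:
    """Parse ``(id, smiles)`` pairs; failures are logged and skipped.

    With ``on_error="raise"`` the first failure aborts instead.
    """
    out: list[Molecule] = []
    for mol_id, smi in records:
        try:
            out.append(parse_smiles(smi, mol_id))
        except SmilesParseError:
            if on_error == "raise":
                raise
            logger.warning("skipping unparseable SMILES for %r: %r", mol_id, smi)
    return out


def _mcs_atom_count(
    a: Molecule,
    b: Molecule,
    timeout_s: float,
    ring_matches_ring_only: bool,
) -> tuple[int, bool]:
    """Connected-MCS heavy-atom count under element-label matching."""
    res = rdFMCS.FindMCS(
        [a.rdkit_mol, b.rdkit_mol],
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareAny,
        matchValences=False,
        ringMatchesRingOnly=ring_matches_ring_only,
        completeRingsOnly=False,
        maximizeBonds=False,
        timeout=max(1, int(round(timeout_s))),
    )
    return res.numAtoms, bool(res.canceled)


def parity_score(
    a: Molecule,
    b: Molecule,
    timeout_s: float = DEFAULT_MCS_TIMEOUT_S,
    ring_matches_ring_only: bool = False,
) -> ParityResult:
    """PARITY similarity of two molecules.

    The connected maximum common substructure is matched on element
    identity only (bond order, aromaticity and charge ignored) and
    scored as ``|MCS| / (N_a + N_b - |MCS|)`` over heavy atoms, giving a
    value in [0, 1] that is symmetric in its arguments.

    ``ring_matches_ring_only`` optionally restricts ring atoms/bonds to
    match ring atoms/bonds; it is off by default.
    """
    mcs, timed_out = _mcs_atom_count(a, b, timeout_s, ring_matches_ring_only)
    if mcs == 0:
        return ParityResult(score=0.0, mcs_atom_count=0, timed_out=timed_out)
    score = mcs / (a.n_heavy + b.n_heavy - mcs)
    return ParityResult(score=score, mcs_atom_count=mcs, timed_out=timed_out)


def maccs_fingerprint(m: Molecule) -> Fingerprint:
    """166-key MACCS fingerprint of a molecule.

    RDKit emits 167 bits with bit 0 always unset as a placeholder; keys
    1..166 are returned as a dense uint8 vector.
    """
    bv = MACCSkeys.GenMACCSKeys(m.rdkit_mol)
    bits = np.zeros(MACCS_N_BITS, dtype=np.uint8)
    for i in bv.GetOnBits():
        if i >= 1:
            bits[i - 1] = 1
    return Fingerprint(bits=bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity of two 166-bit fingerprints.

    Defined as 1.0 when both fingerprints are all-zero (two molecules
    with no MACCS features are indistinguishable to the keys).
    """
    if a.bits.shape != b.bits.shape:
        raise InputError("fingerprint length mismatch")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        return 1.0
    return inter / union
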