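"""TSV readers for the pipeline's tabular inputs.

All tables are UTF-8, tab-separated with a header row and no quoting of
SMILES. Semicolons separate multi-valued fields (EC lists, roles).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .chemistry import Molecule, parse_smiles_batch
from .cognate_matching import CognateLigand
from .ec_completion import ChainAnnotation
from .errors import SchemaError


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} missing column(s): {', '.join(missing)}")


def load_ligand_table(path: str | Path, id_col: str | None = None,
                      smiles_col: str = "smiles") -> list[Molecule]:
    """Read a generic ligand TSV (id, name, smiles, ...) into Molecules.

    The identifier column is auto-detected among common names (``id``,
    ``cognate_id``, ``ligand_instance``) unless given explicitly. Rows
    whose SMILES fail sanitization are logged and skipped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if id_col is None:
        candidates = [c for c in ("id", "cognate_id", "ligand_instance")
                      if c in df.columns]
        id_col = candidates[0] if candidates else "id"
    _require(df, [id_col, smiles_col], "ligand table")
    return parse_smiles_batch(
        [(r[id_col], r[smiles_col]) for _, r in df.iterrows()]
    )


def load_bound_entities(path: str | Path) -> tuple[pd.DataFrame, list[Molecule]]:
    """Read the bound-entity table and parse each instance's SMILES.

    Returns the raw table plus Molecules keyed by ligand instance id.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ["structure_id", "chain", "ligand_instance", "smiles"],
             "bound-entity table")
    mols = parse_smiles_batch(
        [(r["ligand_instance"], r["smiles"]) for _, r in df.iterrows()]
    )
    return df, mols


def load_cognate_table(path: str | Path) -> list[CognateLigand]:
    """Read the cognate-ligand table (cognate_id, name, smiles, ec_ids, ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ["cognate_id", "name", "smiles", "ec_ids"], "cognate table")
    out = []
    for _, r in df.iterrows():
        out.append(
            CognateLigand(
                cognate_id=r["cognate_id"],
                name=r["name"],
                smiles=r["smiles"],
                ec_ids=tuple(e for e in str(r["ec_ids"]).split(";") if e),
                is_cofactor=str(r.get("is_cofactor", "false")).lower()
                in ("true", "1", "yes"),
                roles=tuple(
                    x for x in str(r.get("roles", "") or "").split(";") if x
                ),
            )
        )
    return out


def load_chain_annotations(path: str | Path) -> list[ChainAnnotation]:
    """Read the chain-annotation table (structure_id, chain, ec_ids)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ["structure_id", "chain", "ec_ids"], "chain-annotation table")
    return [
        ChainAnnotation(
            structure_id=r["structure_id"],
            chain=r["chain"],
            ec_ids=tuple(e for e in str(r["ec_ids"]).split(";") if e),
        )
        for _, r in df.iterrows()
    ]
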