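"""Domain–ligand contact filtering and interaction-mode classification.

Per-residue contact tables (one row per contacting residue of a domain
against a bound-ligand instance) are reduced to one record per
domain–ligand pair, filtered for spurious touches, and classified into a
six-mode taxonomy by each domain's share of the ligand's contacts:

========================  =====================================================
mode                      rule
========================  =====================================================
``exclusive``             single contacting domain
``minor``                 multi-domain, fraction < 0.10
``dominant``              sole nonminor domain, fraction >= 0.90
``major``                 sole nonminor domain, 0.10 <= fraction < 0.90
``major_partner``         two or more nonminor domains, fraction >= 0.50
``partner``               two or more nonminor domains, 0.10 <= fraction < 0.50
========================  =====================================================

Domains from different domain databases (CATH, SCOP, Pfam, ...) are
classified independently — a CATH and a Pfam domain never share a
fraction denominator. The Gini index of per-domain contact shares
quantifies how unequally a multi-domain interaction is split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError

logger = logging.getLogger(__name__)

MIN_RESIDUES_DEFAULT = 3

MODES = ("exclusive", "dominant", "major", "major_partner", "partner", "minor")
NONMINOR_MODES = frozenset(m for m in MODES if m != "minor")

DOMAIN_DBS = ("CATH", "SCOP", "SCOP2", "Pfam", "SUPERFAMILY", "Gene3D")

_CONTACT_COLUMNS = [
    "structure_id",
    "ligand_instance",
    "chain",
    "residue",
    "domain_id",
    "domain_db",
    "n_contacts",
]


@dataclass(frozen=True)
class ContactRecord:
    """One contacting residue between a domain and a ligand instance."""

    structure_id: str
    ligand_instance: str
    chain: str
    residue: str
    domain_id: str
    domain_db: str
    n_contacts: int
    domain_family: str = ""

    def family(self) -> str:
        return self.domain_family or self.domain_id


@dataclass(frozen=True)
class DomainLigandInteraction:
    """A classified domain–ligand interaction.

    ``fraction`` is the domain's share of all contacts to the ligand
    instance within its domain database; ``chains`` lists the protein
    chains through which the domain touches the ligand.
    """

    structure_id: str
    ligand_instance: str
    domain_id: str
    domain_db: str
    domain_family: str
    n_residues: int
    n_contacts: int
    fraction: float
    mode: str
    chains: tuple[str, ...]


@dataclass(frozen=True)
class GiniReport:
    ligand_instance: str
    domain_db: str
    gini: float
    n_domains: int


@dataclass(frozen=True)
class CombinatorialInteraction:
    """A multi-domain (nonminor) interaction with a cognate-mapped ligand.

    ``combination`` is the sorted multiset of domain family identifiers;
    duplicates are preserved, so two domains of the same superfamily
    jointly binding one ligand yield a duplicated key.
    """

    ligand_instance: str
    domain_db: str
    combination: tuple[str, ...]
    best_score: float


def load_contacts(path: str | Path) -> list[ContactRecord]:
    """Read a per-residue contact TSV into validated records.

    Duplicate (ligand_instance, domain, chain, residue) rows are merged
    by summing their contact counts, with a warning. An empty file yields
    an empty list.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _CONTACT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"contact table missing column(s): {', '.join(missing)}")
    if "domain_family" not in df.columns:
        df["domain_family"] = df["domain_id"]
    df["domain_family"] = df["domain_family"].fillna(df["domain_id"])
    if df.empty:
        logger.warning("contact table %s is empty", path)
        return []
    df["n_contacts"] = df["n_contacts"].astype(int)
    if (df["n_contacts"] < 1).any():
        raise SchemaError("n_contacts must be >= 1")
    key = ["structure_id", "ligand_instance", "domain_db", "domain_id",
           "domain_family", "chain", "residue"]
    if df.duplicated(subset=key).any():
        logger.warning("merging duplicated contact rows in %s", path)
        df = df.groupby(key, as_index=False)["n_contacts"].sum()
    return [
        ContactRecord(
            structure_id=r.structure_id,
            ligand_instance=r.ligand_instance,
            chain=r.chain,
            residue=str(r.residue),
            domain_id=r.domain_id,
            domain_db=r.domain_db,
            n_contacts=int(r.n_contacts),
            domain_family=r.domain_family,
        )
        for r in df.itertuples(index=False)
    ]


def _records_frame(records: list[ContactRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.structure_id, r.ligand_instance, r.chain, r.residue,
             r.domain_id, r.domain_db, r.n_contacts, r.family())
            for r in records
        ],
        columns=_CONTACT_COLUMNS + ["domain_family"],
    )


def filter_min_residues(
    records: list[ContactRecord],
    min_residues: int = MIN_RESIDUES_DEFAULT,
) -> list[ContactRecord]:
    """Drop spurious domain–ligand touches with too few residues.

    A (domain, ligand instance) pair survives only if the domain
    contacts the ligand through at least ``min_residues`` distinct
    residues. Ligand instances left with no qualifying domain disappear
    entirely, removing peripheral ligands along with sparse domain
    interactions.
    """
    if not records:
        return []
    df = _records_frame(records)
    grp = ["ligand_instance", "domain_db", "domain_id"]
    n_res = df.groupby(grp)[["chain", "residue"]].apply(
        lambda g: len(g.drop_duplicates())
    )
    keep = set(n_res[n_res >= min_residues].index)
    return [
        r for r in records
        if (r.ligand_instance, r.domain_db, r.domain_id) in keep
    ]


def gini(values) -> float:
    """Gini index of a non-negative vector, mean-absolute-difference form.

    ``G = sum_ij |x_i - x_j| / (2 n^2 mu)``: 0 for perfect equality,
    approaching 1 as one element takes everything. Scale-invariant.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InputError("gini of empty vector is undefined")
    if (x < 0).any():
        raise InputError("gini requires non-negative values")
    mu = x.mean()
    if mu == 0:
        raise InputError("gini of all-zero vector is undefined")
    diffs = np.abs(x[:, None] - x[None, :]).sum()
    return float(diffs / (2 * x.size**2 * mu))


def classify_fractions(fractions: list[float]) -> list[str]:
    """Assign interaction modes to the contact shares of one ligand.

    ``fractions`` are the per-domain shares (one ligand instance, one
    domain database). The single-domain case is always ``exclusive``;
    boundary values follow the inclusive conventions >=0.10 nonminor,
    >=0.50 major partner, >=0.90 dominant.
    """
    if len(fractions) == 1:
        return ["exclusive"]
    nonminor = [f >= 0.10 for f in fractions]
    n_nonminor = sum(nonminor)
    modes = []
    for f, nm in zip(fractions, nonminor):
        if not nm:
            modes.append("minor")
        elif n_nonminor == 1:
            modes.append("dominant" if f >= 0.90 else "major")
        else:
            modes.append("major_partner" if f >= 0.50 else "partner")
    return modes


def contact_totals(
    records: list[ContactRecord], fraction_basis: str = "contacts"
) -> dict[tuple[str, str], float]:
    """Total contact weight per (ligand_instance, domain_db).

    Computed on *unfiltered* records, this provides the pre-filter
    denominators for :func:`assign_interaction_modes`.
    """
    totals: dict[tuple[str, str], float] = {}
    seen_res: set[tuple] = set()
    for r in records:
        key = (r.ligand_instance, r.domain_db)
        if fraction_basis == "contacts":
            totals[key] = totals.get(key, 0.0) + r.n_contacts
        else:
            rk = (r.ligand_instance, r.domain_db, r.domain_id, r.chain, r.residue)
            if rk not in seen_res:
                seen_res.add(rk)
                totals[key] = totals.get(key, 0.0) + 1.0
    return totals


def assign_interaction_modes(
    records: list[ContactRecord],
    fraction_basis: str = "contacts",
    totals: dict[tuple[str, str], float] | None = None,
) -> list[DomainLigandInteraction]:
    """Aggregate filtered contacts and classify each domain–ligand pair.

    Contact shares are computed on summed contact counts by default
    (``fraction_basis="residues"`` switches to distinct-residue counts).
    By default the denominator is the post-filter total for the ligand,
    so shares sum to 1 over surviving domains; passing pre-filter
    ``totals`` (from :func:`contact_totals` on the unfiltered records)
    keeps the original denominators instead.
    """
    if fraction_basis not in ("contacts", "residues"):
        raise InputError(f"unknown fraction_basis {fraction_basis!r}")
    if not records:
        return []
    df = _records_frame(records)
    grp = ["structure_id", "ligand_instance", "domain_db", "domain_id",
           "domain_family"]
    agg = df.groupby(grp).agg(
        n_contacts=("n_contacts", "sum"),
        n_residues=("residue", "size"),
        chains=("chain", lambda s: tuple(sorted(set(s)))),
    ).reset_index()
    out: list[DomainLigandInteraction] = []
    basis = "n_contacts" if fraction_basis == "contacts" else "n_residues"
    for (lig, db), group in agg.groupby(
        ["ligand_instance", "domain_db"], sort=True
    ):
        group = group.sort_values("domain_id")
        weights = group[basis].to_numpy(dtype=float)
        total = totals.get((lig, db), weights.sum()) if totals else weights.sum()
        fractions = (weights / total).tolist()
        modes = classify_fractions(fractions)
        for (row, frac, mode) in zip(group.itertuples(index=False), fractions, modes):
            out.append(
                DomainLigandInteraction(
                    structure_id=row.structure_id,
                    ligand_instance=row.ligand_instance,
                    domain_id=row.domain_id,
                    domain_db=row.domain_db,
                    domain_family=row.domain_family,
                    n_residues=int(row.n_residues),
                    n_contacts=int(row.n_contacts),
                    fraction=float(frac),
                    mode=mode,
                    chains=row.chains,
                )
            )
    return out


def gini_reports(
    interactions: list[DomainLigandInteraction],
) -> list[GiniReport]:
    """Gini index of contact shares for every multi-domain interaction."""
    by_key: dict[tuple[str, str], list[float]] = {}
    for it in interactions:
        by_key.setdefault((it.ligand_instance, it.domain_db), []).append(it.fraction)
    return [
        GiniReport(ligand_instance=k[0], domain_db=k[1],
                   gini=gini(fr), n_domains=len(fr))
        for k, fr in sorted(by_key.items())
        if len(fr) > 1
    ]


def combinatorial_interactions(
    interactions: list[DomainLigandInteraction],
    matches,
    threshold: float = 0.4,
    entity_of: dict[str, str] | None = None,
) -> list[CombinatorialInteraction]:
    """Extract multi-domain binding events with a cognate-mapped ligand.

    One record per (ligand instance, domain database) with two or more
    nonminor domains whose ligand has at least one retained cognate
    match at or above ``threshold``. ``entity_of`` maps ligand instances
    to the bound-entity id used in the similarity matches (identity by
    default). The combination key preserves duplicated families.
    """
    best_by_entity: dict[str, float] = {}
    for m in matches:
        if m.score >= threshold:
            prev = best_by_entity.get(m.bound_id, -1.0)
            best_by_entity[m.bound_id] = max(prev, m.score)
    by_key: dict[tuple[str, str], list[DomainLigandInteraction]] = {}
    for it in interactions:
        if it.mode in NONMINOR_MODES:
            by_key.setdefault((it.ligand_instance, it.domain_db), []).append(it)
    out = []
    for (lig, db), its in sorted(by_key.items()):
        if len(its) < 2:
            continue
        entity = entity_of.get(lig, lig) if entity_of else lig
        if entity not in best_by_entity:
            continue
        combo = tuple(sorted(i.domain_family for i in its))
        out.append(
            CombinatorialInteraction(
                ligand_instance=lig,
                domain_db=db,
                combination=combo,
                best_score=best_by_entity[entity],
            )
        )
    return out


def interactions_to_frame(
    interactions: list[DomainLigandInteraction],
) -> pd.DataFrame:
    """Tabular view (one row per domain–ligand pair) for TSV export."""
    return pd.DataFrame(
        [
            {
                "structure_id": it.structure_id,
                "ligand_instance": it.ligand_instance,
                "domain_db": it.domain_db,
                "domain_id": it.domain_id,
                "domain_family": it.domain_family,
                "n_residues": it.n_residues,
                "n_contacts": it.n_contacts,
                "fraction": it.fraction,
                "mode": it.mode,
                "chains": ";".join(it.chains),
            }
            for it in interactions
        ]
    )
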