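"""Synthetic data generation with planted ground truth.

Every pipeline stage can be exercised without any external download:
this module fabricates a small enzyme world — structures, chains,
domains, bound ligand instances, per-residue contact tables, cognate
tables and (partial) EC annotations — in which the intended interaction
mode of every domain and the true EC of every chain are planted by
construction. Contact counts are built as integer percentages so the
classifier recovers the planted fractions exactly, and each chain's
bound entity is chemically identical to the cognate ligand of its true
EC, making that cognate the unique best match.

The homologous-series ligand library (n-alkanols and relatives) gives
closed-form PARITY expectations: embedding a k-atom chain into an
m-atom chain scores k/m under the Jaccard normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemistry import Molecule, parse_smiles
from .cognate_matching import CognateLigand
from .contacts import ContactRecord, classify_fractions
from .ec_completion import ChainAnnotation
from .errors import InputError

# Curated 2D structures for the two worked similarity examples: an
# aromatic diol bound in a dioxygenase beta-barrel and an S-substituted
# glutathione pair from a lyase active site formed at a domain dimer
# interface.
WORKED_EXAMPLE_SMILES = {
    "catechol": "Oc1ccccc1O",
    "3-chlorocatechol": "Oc1cccc(Cl)c1O",
    "s-hexylglutathione": "CCCCCCSC[C@H](NC(=O)CC[C@H](N)C(=O)O)C(=O)NCC(=O)O",
    "(R)-S-lactoylglutathione":
        "C[C@@H](O)C(=O)SC[C@H](NC(=O)CC[C@H](N)C(=O)O)C(=O)NCC(=O)O",
}


def worked_example_molecules() -> dict[str, Molecule]:
    """The four worked-example molecules, parsed and sanitized."""
    return {
        name: parse_smiles(smi, name)
        for name, smi in WORKED_EXAMPLE_SMILES.items()
    }


def fingerprint_blobs(
    n_clusters: int,
    n_per_cluster: int = 20,
    seed: int = 0,
    flip_bits: int = 3,
    n_bits: int = 166,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted binary fingerprint blobs for cluster-recovery tests.

    Each cluster gets a random binary prototype; members flip
    ``flip_bits`` random bits of it. Random prototypes differ in ~half
    of all bits, so planted blobs are far better separated than the
    within-blob spread. Returns ``(X, labels)``.
    """
    rng = np.random.default_rng(seed)
    X = np.empty((n_clusters * n_per_cluster, n_bits), dtype=float)
    labels = np.empty(n_clusters * n_per_cluster, dtype=int)
    row = 0
    for c in range(n_clusters):
        proto = rng.integers(0, 2, size=n_bits)
        for _ in range(n_per_cluster):
            member = proto.copy()
            flip = rng.choice(n_bits, size=flip_bits, replace=False)
            member[flip] = 1 - member[flip]
            X[row] = member
            labels[row] = c
            row += 1
    return X, labels


_SCAFFOLDS = [
    "c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "C1CCCCC1", "C1CCNCC1",
]
_SUBSTITUENTS = ["O", "N", "Cl", "Br", "F", "C(=O)O", "C(=O)N", "S", "OC", "C#N"]


def ligand_library(n: int = 220) -> list[Molecule]:
    """A deterministic library of >=200 small organic molecules.

    Built combinatorially from homologous aliphatic series (alkanes,
    alcohols, diols, amines, thiols, carboxylic acids) and mono-/di-
    substituted ring scaffolds; duplicates (by canonical SMILES) are
    removed and the first ``n`` kept in generation order.
    """
    smiles: list[str] = []
    for k in range(1, 13):
        chain = "C" * k
        smiles += [chain, chain + "O", chain + "N", chain + "S",
                   chain + "C(=O)O", "OC" + chain + "O"]
    for scaf in _SCAFFOLDS:
        smiles.append(scaf)
        for sub in _SUBSTITUENTS:
            smiles.append(scaf + sub if not scaf[0].isupper() else scaf + sub)
    for scaf in ["c1ccccc1", "C1CCCCC1"]:
        for s1 in _SUBSTITUENTS:
            for s2 in _SUBSTITUENTS:
                smiles.append(f"{s1}c1ccccc1{s2}" if scaf == "c1ccccc1"
                              else f"{s1}C1CCCCC1{s2}")
    mols: list[Molecule] = []
    seen: set[str] = set()
    for i, smi in enumerate(smiles):
        try:
            mol = parse_smiles(smi, f"lib{i:04d}")
        except Exception:
            continue
        if mol.smiles in seen:
            continue
        seen.add(mol.smiles)
        mols.append(mol)
        if len(mols) >= n:
            break
    return mols


def _default_ec_universe(n_ecs: int = 12) -> list[CognateLigand]:
    """A one-cognate-per-EC universe over a single partial class.

    Each EC ``3.2.1.x`` gets a distinct n-alkanol cognate, so a bound
    entity identical to one of them has a unique perfect best match.
    Two cofactor-flagged cognates sit outside the class.
    """
    out = []
    for x in range(1, n_ecs + 1):
        smi = "C" * (x + 1) + "O"
        out.append(
            CognateLigand(
                cognate_id=f"COG{x:03d}", name=f"alkanol-C{x + 1}",
                smiles=smi, ec_ids=(f"3.2.1.{x}",), is_cofactor=False,
            )
        )
    out.append(
        CognateLigand(cognate_id="COGNAD", name="pyridine-carboxamide",
                      smiles="NC(=O)c1cccnc1", ec_ids=("1.1.1.1",),
                      is_cofactor=True)
    )
    out.append(
        CognateLigand(cognate_id="COGFMN", name="methyl-quinoxalinedione",
                      smiles="Cc1ccc2nc(O)c(O)nc2c1", ec_ids=("1.1.1.2",),
                      is_cofactor=True)
    )
    return out


#: interaction-mode fraction vectors used when planting modes at random;
#: integer percents so recovery from contact counts is exact
DEFAULT_FRACTION_VOCABULARY: tuple[tuple[float, ...], ...] = (
    (1.0,),
    (0.93, 0.07),
    (0.60, 0.40),
    (0.85, 0.08, 0.07),
    (0.50, 0.50),
)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic world.

    ``planted_modes`` maps ligand instances to fraction vectors (filled
    at random from ``fraction_vocabulary`` when absent); ``planted_ec``
    maps (structure_id, chain) to the true complete EC. With
    ``annotate_partial`` the chain-annotation table truncates the true
    EC to its class (e.g. ``3.2.1.-``), which is what the EC-completion
    stage must undo.
    """

    seed: int = 42
    n_structures: int = 10
    n_chains_per_structure: int = 1
    n_families: int = 6
    domain_db: str = "CATH"
    fraction_vocabulary: tuple[tuple[float, ...], ...] = DEFAULT_FRACTION_VOCABULARY
    cognates: list[CognateLigand] = field(default_factory=_default_ec_universe)
    planted_modes: dict[str, tuple[float, ...]] = field(default_factory=dict)
    planted_ec: dict[tuple[str, str], str] = field(default_factory=dict)
    annotate_partial: bool = True
    total_contacts: int = 100

    def validate(self) -> None:
        if self.n_structures < 1 or self.n_chains_per_structure < 1:
            raise InputError("need at least one structure and one chain")
        for vec in list(self.fraction_vocabulary) + list(
            self.planted_modes.values()
        ):
            arr = np.asarray(vec, dtype=float)
            if arr.size == 0 or (arr <= 0).any():
                raise InputError(f"invalid fraction vector {vec!r}")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise InputError(f"fraction vector {vec!r} does not sum to 1")
            if not np.allclose(arr * self.total_contacts,
                               np.round(arr * self.total_contacts)):
                raise InputError(
                    f"fraction vector {vec!r} not representable as integer "
                    f"counts out of {self.total_contacts}"
                )


@dataclass
class FixtureWorld:
    """In-memory fixture: inputs for every stage plus the planted truth."""

    bound_entities: pd.DataFrame
    bound_molecules: list[Molecule]
    cognates: list[CognateLigand]
    contacts: list[ContactRecord]
    chain_annotations: list[ChainAnnotation]
    planted_modes: dict[str, tuple[str, ...]]
    planted_ec: dict[tuple[str, str], str]


def build_fixture(spec: FixtureSpec) -> FixtureWorld:
    """Construct the synthetic world described by ``spec`` in memory."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    class_ecs = sorted(
        {e for c in spec.cognates for e in c.ec_ids if not c.is_cofactor}
    )
    cognate_by_ec = {
        e: c for c in spec.cognates for e in c.ec_ids if not c.is_cofactor
    }
    families = [f"{i + 1}.10.{(i + 1) * 10}.10" for i in range(spec.n_families)]

    bound_rows = []
    bound_molecules: list[Molecule] = []
    contacts: list[ContactRecord] = []
    annotations: list[ChainAnnotation] = []
    planted_modes: dict[str, tuple[str, ...]] = {}
    planted_fracs: dict[str, tuple[float, ...]] = dict(spec.planted_modes)
    planted_ec: dict[tuple[str, str], str] = dict(spec.planted_ec)

    for si in range(spec.n_structures):
        sid = f"S{si + 1:04d}"
        for ci in range(spec.n_chains_per_structure):
            chain = chr(ord("A") + ci)
            key = (sid, chain)
            if key not in planted_ec:
                planted_ec[key] = class_ecs[int(rng.integers(len(class_ecs)))]
            true_ec = planted_ec[key]
            cog = cognate_by_ec[true_ec]
            lig = f"{sid}_{chain}_L1"
            bound_rows.append(
                {"structure_id": sid, "chain": chain, "ligand_instance": lig,
                 "ccd_code": cog.cognate_id[-3:], "smiles": cog.smiles}
            )
            bound_molecules.append(parse_smiles(cog.smiles, lig))
            if lig not in planted_fracs:
                vocab = spec.fraction_vocabulary
                planted_fracs[lig] = vocab[int(rng.integers(len(vocab)))]
            fractions = planted_fracs[lig]
            planted_modes[lig] = tuple(classify_fractions(list(fractions)))
            fam_idx = rng.permutation(len(families))[: len(fractions)]
            for di, frac in enumerate(fractions):
                count = int(round(frac * spec.total_contacts))
                n_res = max(3, min(count, 6))
                per_res = np.full(n_res, count // n_res, dtype=int)
                per_res[: count % n_res] += 1
                dom_id = f"{sid}{chain}{di:02d}"
                for ri, c in enumerate(per_res):
                    contacts.append(
                        ContactRecord(
                            structure_id=sid, ligand_instance=lig,
                            chain=chain, residue=str(10 + ri),
                            domain_id=dom_id, domain_db=spec.domain_db,
                            n_contacts=int(c),
                            domain_family=families[fam_idx[di]],
                        )
                    )
            annotated = (
                ".".join(true_ec.split(".")[:3]) + ".-"
                if spec.annotate_partial else true_ec
            )
            annotations.append(
                ChainAnnotation(structure_id=sid, chain=chain,
                                ec_ids=(annotated,))
            )
    return FixtureWorld(
        bound_entities=pd.DataFrame(bound_rows),
        bound_molecules=bound_molecules,
        cognates=list(spec.cognates),
        contacts=contacts,
        chain_annotations=annotations,
        planted_modes=planted_modes,
        planted_ec=planted_ec,
    )


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write the fixture world as four TSVs plus a truth/manifest JSON.

    Outputs are byte-identical across runs with the same spec.
    """
    world = build_fixture(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    paths = {
        "bound_entities": outdir / "bound_entities.tsv",
        "cognates": outdir / "cognate_ligands.tsv",
        "contacts": outdir / "contacts.tsv",
        "chain_annotations": outdir / "chain_annotations.tsv",
    }
    world.bound_entities.to_csv(paths["bound_entities"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"cognate_id": c.cognate_id, "name": c.name, "smiles": c.smiles,
             "ec_ids": ";".join(c.ec_ids),
             "is_cofactor": str(c.is_cofactor).lower()}
            for c in world.cognates
        ]
    ).to_csv(paths["cognates"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"structure_id": r.structure_id, "ligand_instance": r.ligand_instance,
             "chain": r.chain, "residue": r.residue, "domain_id": r.domain_id,
             "domain_db": r.domain_db, "n_contacts": r.n_contacts,
             "domain_family": r.domain_family}
            for r in world.contacts
        ]
    ).to_csv(paths["contacts"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"structure_id": a.structure_id, "chain": a.chain,
             "ec_ids": ";".join(a.ec_ids)}
            for a in world.chain_annotations
        ]
    ).to_csv(paths["chain_annotations"], sep="\t", index=False)

    manifest = {
        "files": {k: str(v) for k, v in paths.items()},
        "planted_modes": {k: list(v) for k, v in world.planted_modes.items()},
        "planted_ec": {f"{s}:{c}": ec for (s, c), ec in world.planted_ec.items()},
        "seed": spec.seed,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
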