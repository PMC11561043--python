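"""Graph assembly and bulk-import flat-file export.

The pipeline's products — structures, chains, domains, bound entities,
cognate ligands and EC classes — are assembled into node and edge
tables with referential-integrity checking, then written as one CSV per
node label and per relationship type using bulk-import header
conventions (``:ID`` / ``:LABEL`` / ``:START_ID`` / ``:END_ID`` /
``:TYPE``, with ``:long`` / ``:double`` / ``:boolean`` type suffixes on
property columns). Three analysis-friendly distribution TSVs accompany
the graph: a domain–cognate mapping and a domain–bound-entity mapping
per domain database, and the ligand–cognate similarity mapping.

Writing is deterministic (rows sorted) and round-trips exactly through
:func:`load_graph`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

from .cognate_matching import CognateLigand, SimilarityMatch
from .contacts import DomainLigandInteraction
from .ec_completion import ChainAnnotation
from .errors import GraphBuildError

NODE_LABELS = (
    "Structure", "ProteinChain", "Domain", "BoundEntity", "CognateLigand", "EC",
)
EDGE_TYPES = (
    "CONTAINS", "HAS_DOMAIN", "INTERACTS_WITH", "MAPS_TO", "IN_EC_CLASS",
)

#: chain/domain assignment row: (structure_id, chain, domain_db, domain_id,
#: domain_family)
DomainAssignment = tuple[str, str, str, str, str]


@dataclass(frozen=True)
class NodeRow:
    node_id: str
    label: str
    properties: tuple[tuple[str, object], ...] = ()

    def props(self) -> dict:
        return dict(self.properties)


@dataclass(frozen=True)
class EdgeRow:
    start_id: str
    end_id: str
    type: str
    properties: tuple[tuple[str, object], ...] = ()

    def props(self) -> dict:
        return dict(self.properties)


def _props(d: dict) -> tuple[tuple[str, object], ...]:
    # empty/None values are omitted so that a written-then-loaded graph
    # compares equal to the in-memory one
    return tuple(sorted((k, v) for k, v in d.items() if v is not None and v != ""))


def structure_node_id(sid: str) -> str:
    return f"structure:{sid}"


def chain_node_id(sid: str, chain: str) -> str:
    return f"chain:{sid}:{chain}"


def domain_node_id(db: str, domain_id: str) -> str:
    return f"domain:{db}:{domain_id}"


def bound_node_id(instance: str) -> str:
    return f"bound:{instance}"


def cognate_node_id(cid: str) -> str:
    return f"cognate:{cid}"


def ec_node_id(ec: str) -> str:
    return f"ec:{ec}"


def build_graph(
    structures: list[str],
    chains: list[ChainAnnotation],
    interactions: list[DomainLigandInteraction],
    matches: list[SimilarityMatch],
    cognates: list[CognateLigand],
    ecs: list[str],
    domains: list[DomainAssignment] | None = None,
    entity_of: dict[str, str] | None = None,
) -> tuple[list[NodeRow], list[EdgeRow]]:
    """Assemble a referentially intact node/edge set.

    ``domains`` optionally lists chain→domain assignments explicitly;
    when omitted they are derived from the interactions. ``entity_of``
    maps ligand instances to the bound-entity id used in similarity
    matches (identity by default). Dangling references raise
    :class:`GraphBuildError` naming the offender.
    """
    entity_of = entity_of or {}
    nodes: dict[str, NodeRow] = {}
    edges: list[EdgeRow] = []

    def add_node(node_id: str, label: str, props: dict) -> None:
        if node_id not in nodes:
            nodes[node_id] = NodeRow(node_id, label, _props(props))

    for sid in structures:
        add_node(structure_node_id(sid), "Structure", {"structure_id": sid})

    ec_set = set(ecs)
    for ec in ecs:
        add_node(ec_node_id(ec), "EC", {"ec": ec})

    for ca in chains:
        if structure_node_id(ca.structure_id) not in nodes:
            raise GraphBuildError(
                f"chain {ca.structure_id}/{ca.chain} references unknown "
                f"structure {ca.structure_id!r}"
            )
        add_node(
            chain_node_id(ca.structure_id, ca.chain),
            "ProteinChain",
            {"structure_id": ca.structure_id, "chain": ca.chain,
             "ec_ids": ";".join(ca.ec_ids)},
        )
        edges.append(
            EdgeRow(structure_node_id(ca.structure_id),
                    chain_node_id(ca.structure_id, ca.chain), "CONTAINS")
        )
        for ec in ca.ec_ids:
            if ec in ec_set:
                edges.append(
                    EdgeRow(chain_node_id(ca.structure_id, ca.chain),
                            ec_node_id(ec), "IN_EC_CLASS")
                )

    if domains is None:
        derived: dict[tuple, DomainAssignment] = {}
        for it in interactions:
            for ch in it.chains:
                key = (it.structure_id, ch, it.domain_db, it.domain_id)
                derived.setdefault(
                    key, (it.structure_id, ch, it.domain_db, it.domain_id,
                          it.domain_family)
                )
        domains = [derived[k] for k in sorted(derived)]

    for sid, ch, db, dom_id, family in domains:
        cnode = chain_node_id(sid, ch)
        if cnode not in nodes:
            raise GraphBuildError(
                f"domain {dom_id} references unknown chain {sid}/{ch}"
            )
        add_node(domain_node_id(db, dom_id), "Domain",
                 {"domain_db": db, "domain_id": dom_id, "domain_family": family})
        edges.append(EdgeRow(cnode, domain_node_id(db, dom_id), "HAS_DOMAIN"))

    for it in interactions:
        dnode = domain_node_id(it.domain_db, it.domain_id)
        if dnode not in nodes:
            raise GraphBuildError(
                f"interaction references unknown domain {it.domain_id!r}"
            )
        add_node(bound_node_id(it.ligand_instance), "BoundEntity",
                 {"ligand_instance": it.ligand_instance,
                  "structure_id": it.structure_id})
        edges.append(
            EdgeRow(
                dnode, bound_node_id(it.ligand_instance), "INTERACTS_WITH",
                _props({
                    "mode": it.mode,
                    "fraction": float(it.fraction),
                    "n_residues": int(it.n_residues),
                    "n_contacts": int(it.n_contacts),
                    "chains": ";".join(it.chains),
                }),
            )
        )

    cognate_ids = set()
    for cog in cognates:
        cognate_ids.add(cog.cognate_id)
        add_node(
            cognate_node_id(cog.cognate_id), "CognateLigand",
            {"cognate_id": cog.cognate_id, "name": cog.name,
             "smiles": cog.smiles, "is_cofactor": bool(cog.is_cofactor)},
        )
        for ec in cog.ec_ids:
            if ec in ec_set:
                edges.append(
                    EdgeRow(cognate_node_id(cog.cognate_id), ec_node_id(ec),
                            "IN_EC_CLASS")
                )

    instance_by_entity: dict[str, list[str]] = {}
    for node in nodes.values():
        if node.label == "BoundEntity":
            inst = node.props()["ligand_instance"]
            instance_by_entity.setdefault(
                entity_of.get(inst, inst), []
            ).append(inst)
    for m in matches:
        if m.cognate_id not in cognate_ids:
            raise GraphBuildError(
                f"match for {m.bound_id!r} references unknown cognate "
                f"{m.cognate_id!r}"
            )
        instances = instance_by_entity.get(m.bound_id)
        if not instances:
            raise GraphBuildError(
                f"match references unknown bound entity {m.bound_id!r}"
            )
        for inst in instances:
            edges.append(
                EdgeRow(
                    bound_node_id(inst), cognate_node_id(m.cognate_id),
                    "MAPS_TO",
                    _props({"score": float(m.score), "is_best": bool(m.is_best)}),
                )
            )

    return sorted(nodes.values(), key=lambda n: n.node_id), edges


_SUFFIX = {bool: "boolean", int: "long", float: "double", str: "string"}


def _typed(value: object) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def _parse_typed(text: str, suffix: str):
    if text == "":
        return None
    if suffix == "boolean":
        return text == "true"
    if suffix == "long":
        return int(text)
    if suffix == "double":
        return float(text)
    return text


def _prop_columns(rows: list[dict]) -> list[tuple[str, str]]:
    """(key, type-suffix) pairs for the union of property keys."""
    cols: dict[str, str] = {}
    for props in rows:
        for k, v in props.items():
            if k not in cols and v is not None:
                cols[k] = _SUFFIX[type(v)]
    return sorted(cols.items())


def write_flatfiles(
    nodes: list[NodeRow],
    edges: list[EdgeRow],
    outdir: str | Path,
    interactions: list[DomainLigandInteraction] | None = None,
    matches: list[SimilarityMatch] | None = None,
    entity_of: dict[str, str] | None = None,
) -> dict:
    """Write the graph as bulk-import CSVs plus distribution TSVs.

    Layout: ``nodes/<Label>.csv``, ``relationships/<TYPE>.csv``,
    ``distribution/*.tsv`` and a ``manifest.json`` index. Row order is
    deterministic (sorted); values containing delimiters are quoted per
    RFC 4180. Returns the manifest.
    """
    outdir = Path(outdir)
    (outdir / "nodes").mkdir(parents=True, exist_ok=True)
    (outdir / "relationships").mkdir(exist_ok=True)
    (outdir / "distribution").mkdir(exist_ok=True)
    manifest: dict = {"nodes": {}, "relationships": {}, "distribution": {}}

    by_label: dict[str, list[NodeRow]] = {}
    for n in nodes:
        by_label.setdefault(n.label, []).append(n)
    for label in sorted(by_label):
        rows = sorted(by_label[label], key=lambda n: n.node_id)
        cols = _prop_columns([n.props() for n in rows])
        path = outdir / "nodes" / f"{label}.csv"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["node_id:ID", ":LABEL"] + [f"{k}:{t}" for k, t in cols])
            for n in rows:
                props = n.props()
                w.writerow(
                    [n.node_id, n.label]
                    + [_typed(props[k]) if k in props else "" for k, _ in cols]
                )
        manifest["nodes"][label] = str(path.relative_to(outdir))

    by_type: dict[str, list[EdgeRow]] = {}
    for e in edges:
        by_type.setdefault(e.type, []).append(e)
    for etype in sorted(by_type):
        rows = sorted(
            by_type[etype], key=lambda e: (e.start_id, e.end_id, e.properties)
        )
        cols = _prop_columns([e.props() for e in rows])
        path = outdir / "relationships" / f"{etype}.csv"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(
                [":START_ID", ":END_ID", ":TYPE"] + [f"{k}:{t}" for k, t in cols]
            )
            for e in rows:
                props = e.props()
                w.writerow(
                    [e.start_id, e.end_id, e.type]
                    + [_typed(props[k]) if k in props else "" for k, _ in cols]
                )
        manifest["relationships"][etype] = str(path.relative_to(outdir))

    if interactions is not None:
        _write_distribution(
            outdir, manifest, interactions, matches or [], entity_of or {}
        )

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_distribution(outdir, manifest, interactions, matches, entity_of):
    import pandas as pd

    match_df = pd.DataFrame(
        [(m.bound_id, m.cognate_id, m.score, m.is_best) for m in matches],
        columns=["bound_id", "cognate_id", "score", "is_best"],
    ).sort_values(["bound_id", "cognate_id"])
    path = outdir / "distribution" / "ligand_cognate_similarity.tsv"
    match_df.to_csv(path, sep="\t", index=False)
    manifest["distribution"]["ligand_cognate_similarity"] = str(
        path.relative_to(outdir)
    )

    by_db: dict[str, list[DomainLigandInteraction]] = {}
    for it in interactions:
        by_db.setdefault(it.domain_db, []).append(it)
    cogs_by_entity: dict[str, list[SimilarityMatch]] = {}
    for m in matches:
        cogs_by_entity.setdefault(m.bound_id, []).append(m)
    for db in sorted(by_db):
        its = by_db[db]
        dbe = pd.DataFrame(
            [
                (it.domain_family, it.domain_id, it.ligand_instance,
                 it.mode, it.fraction)
                for it in its
            ],
            columns=["domain_family", "domain_id", "ligand_instance",
                     "mode", "fraction"],
        ).sort_values(["domain_family", "domain_id", "ligand_instance"])
        p1 = outdir / "distribution" / f"domain_bound_entity_{db}.tsv"
        dbe.to_csv(p1, sep="\t", index=False)
        manifest["distribution"][f"domain_bound_entity_{db}"] = str(
            p1.relative_to(outdir)
        )
        rows = []
        for it in its:
            entity = entity_of.get(it.ligand_instance, it.ligand_instance)
            for m in cogs_by_entity.get(entity, []):
                rows.append(
                    (it.domain_family, it.domain_id, m.cognate_id,
                     m.score, it.mode)
                )
        dcg = pd.DataFrame(
            rows,
            columns=["domain_family", "domain_id", "cognate_id", "score", "mode"],
        ).drop_duplicates().sort_values(
            ["domain_family", "domain_id", "cognate_id"]
        )
        p2 = outdir / "distribution" / f"domain_cognate_{db}.tsv"
        dcg.to_csv(p2, sep="\t", index=False)
        manifest["distribution"][f"domain_cognate_{db}"] = str(
            p2.relative_to(outdir)
        )


def load_graph(outdir: str | Path) -> tuple[list[NodeRow], list[EdgeRow]]:
    """Read flat files written by :func:`write_flatfiles` back into memory."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    nodes: list[NodeRow] = []
    for label, rel in sorted(manifest["nodes"].items()):
        with open(outdir / rel, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            prop_cols = [
                (h.rsplit(":", 1)[0], h.rsplit(":", 1)[1]) for h in header[2:]
            ]
            for row in reader:
                props = {
                    k: _parse_typed(v, t)
                    for (k, t), v in zip(prop_cols, row[2:])
                    if _parse_typed(v, t) is not None
                }
                nodes.append(NodeRow(row[0], row[1], _props(props)))
    edges: list[EdgeRow] = []
    for etype, rel in sorted(manifest["relationships"].items()):
        with open(outdir / rel, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            prop_cols = [
                (h.rsplit(":", 1)[0], h.rsplit(":", 1)[1]) for h in header[3:]
            ]
            for row in reader:
                props = {
                    k: _parse_typed(v, t)
                    for (k, t), v in zip(prop_cols, row[3:])
                    if _parse_typed(v, t) is not None
                }
                edges.append(EdgeRow(row[0], row[1], row[2], _props(props)))
    return nodes, edges
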