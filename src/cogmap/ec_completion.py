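"""Completion of partial EC annotations via cognate-ligand evidence.

Many enzyme chains carry only a partial EC number (e.g. ``3.2.1.-``,
a glycosidase of unspecified substrate). When such a chain binds a
ligand through a nonminor domain interaction, and that ligand maps to
cognate ligands of reactions *within* the partial class, the cognate
evidence can pin down the missing field: per bound entity the
highest-scoring in-class cognates are taken, and an assignment is made
only when the candidate EC numbers agree on a single identity across
all contributing bound entities. Chains that already carry a specific
EC alongside the partial one are excluded — the annotation is not
missing there.
"""

from __future__ import annotations

from dataclasses import dataclass

from .calibration import DEFAULT_THRESHOLD
from .cognate_matching import CognateLigand, SimilarityMatch
from .contacts import NONMINOR_MODES, DomainLigandInteraction
from .errors import InputError


@dataclass(frozen=True)
class ChainAnnotation:
    """EC annotation of one protein chain; entries may be partial."""

    structure_id: str
    chain: str
    ec_ids: tuple[str, ...]


@dataclass(frozen=True)
class ECAssignment:
    """Outcome of EC completion for one chain's partial annotation.

    ``supporting`` lists the (bound_id, cognate_id, score) evidence
    behind the decision; ``perfect_support`` marks assignments backed
    exclusively by score-1.0 (identical-structure) matches.
    """

    structure_id: str
    chain: str
    partial_ec: str
    assigned_ec: str | None
    status: str  # assigned | ambiguous | no_candidates | excluded_has_specific
    supporting: tuple[tuple[str, str, float], ...] = ()
    perfect_support: bool = False


def parse_ec(ec: str) -> tuple[str, ...]:
    """Split an EC string into its specified fields.

    Accepts 1–4 dot-separated fields with an optional wildcard tail
    (``-`` or simply truncated, e.g. ``3.2.1.-`` or ``3.2.1``). A
    wildcard anywhere but the suffix is malformed.
    """
    if not ec or not ec.strip():
        raise InputError("empty EC string")
    fields = [f.strip() for f in ec.strip().split(".")]
    while fields and fields[-1] in ("-", ""):
        fields.pop()
    if not fields or len(fields) > 4:
        raise InputError(f"malformed EC string: {ec!r}")
    for f in fields:
        if f in ("-", "") or not all(ch.isalnum() for ch in f):
            raise InputError(f"malformed EC string: {ec!r}")
    return tuple(fields)


def is_partial_ec(ec: str) -> bool:
    return len(parse_ec(ec)) < 4


def expand_partial_ec(partial: str, ec_universe: list[str]) -> list[str]:
    """All complete ECs in the universe within the partial's class.

    A complete EC input expands to itself (if present in the universe).
    """
    if not ec_universe:
        raise InputError("empty EC universe")
    prefix = parse_ec(partial)
    out = []
    seen = set()
    for ec in ec_universe:
        fields = parse_ec(ec)
        if len(fields) != 4:
            continue
        if fields[: len(prefix)] == prefix and ec not in seen:
            seen.add(ec)
            out.append(ec)
    return sorted(out)


def _chain_ligand_instances(
    chain: ChainAnnotation, interactions: list[DomainLigandInteraction]
) -> list[str]:
    """Ligand instances this chain binds through nonminor interactions."""
    seen: set[str] = set()
    out = []
    for it in interactions:
        if (
            it.structure_id == chain.structure_id
            and chain.chain in it.chains
            and it.mode in NONMINOR_MODES
            and it.ligand_instance not in seen
        ):
            seen.add(it.ligand_instance)
            out.append(it.ligand_instance)
    return out


def assign_specific_ec(
    chain: ChainAnnotation,
    interactions: list[DomainLigandInteraction],
    matches: list[SimilarityMatch],
    cognates: list[CognateLigand],
    threshold: float = DEFAULT_THRESHOLD,
    strict_above: bool = False,
    best_scope: str = "within_class",
    entity_of: dict[str, str] | None = None,
    partial_ec: str | None = None,
) -> ECAssignment:
    """Complete one chain's partial EC annotation from cognate evidence.

    Procedure: (1) chains carrying a specific EC alongside the partial
    one are excluded; (2) candidate cognates are those matched at or
    above ``threshold`` (strictly above with ``strict_above``) to bound
    entities the chain binds nonminorly, with at least one EC inside the
    expanded partial class; (3) per bound entity only the best-scoring
    in-class cognates count (``best_scope="global"`` instead uses the
    entity's globally best retained matches); (4) the assignment is made
    iff the intersection of candidate EC sets across contributing bound
    entities is a single EC.
    """
    partials = [e for e in chain.ec_ids if is_partial_ec(e)]
    specifics = [e for e in chain.ec_ids if not is_partial_ec(e)]
    if partial_ec is None:
        if not partials:
            raise InputError(
                f"chain {chain.structure_id}/{chain.chain} has no partial EC"
            )
        partial_ec = partials[0]
    if specifics:
        return ECAssignment(
            structure_id=chain.structure_id,
            chain=chain.chain,
            partial_ec=partial_ec,
            assigned_ec=None,
            status="excluded_has_specific",
        )

    universe = sorted({e for c in cognates for e in c.ec_ids})
    in_class = set(expand_partial_ec(partial_ec, universe)) if universe else set()
    cognate_by_id = {c.cognate_id: c for c in cognates}
    entity_of = entity_of or {}

    def passes(score: float) -> bool:
        return score > threshold if strict_above else score >= threshold

    matches_by_entity: dict[str, list[SimilarityMatch]] = {}
    for m in matches:
        if passes(m.score) and not m.timed_out:
            matches_by_entity.setdefault(m.bound_id, []).append(m)

    candidate_sets: list[set[str]] = []
    supporting: list[tuple[str, str, float]] = []
    for lig in _chain_ligand_instances(chain, interactions):
        entity = entity_of.get(lig, lig)
        cands = []
        for m in matches_by_entity.get(entity, []):
            cog = cognate_by_id.get(m.cognate_id)
            if cog is None:
                continue
            ecs = set(cog.ec_ids) & in_class
            if ecs:
                cands.append((m, ecs))
        if not cands:
            continue
        if best_scope == "global":
            chosen = [(m, ecs) for m, ecs in cands if m.is_best]
        else:
            top = max(m.score for m, _ in cands)
            chosen = [(m, ecs) for m, ecs in cands if m.score == top]
        if not chosen:
            continue
        entity_ecs: set[str] = set()
        for m, ecs in chosen:
            entity_ecs |= ecs
            supporting.append((m.bound_id, m.cognate_id, m.score))
        candidate_sets.append(entity_ecs)

    if not candidate_sets:
        return ECAssignment(
            structure_id=chain.structure_id, chain=chain.chain,
            partial_ec=partial_ec, assigned_ec=None, status="no_candidates",
        )
    final = set.intersection(*candidate_sets)
    if len(final) == 1:
        assigned = next(iter(final))
        status = "assigned"
    else:
        # several surviving candidates, or bound entities that disagree
        # outright (empty intersection): either way the evidence does not
        # single out one EC
        assigned, status = None, "ambiguous"
    return ECAssignment(
        structure_id=chain.structure_id,
        chain=chain.chain,
        partial_ec=partial_ec,
        assigned_ec=assigned,
        status=status,
        supporting=tuple(supporting),
        perfect_support=(
            status == "assigned"
            and all(s == 1.0 for _, _, s in supporting)
        ),
    )


def complete_annotations(
    chains: list[ChainAnnotation],
    interactions: list[DomainLigandInteraction],
    matches: list[SimilarityMatch],
    cognates: list[CognateLigand],
    **kwargs,
) -> list[ECAssignment]:
    """Run :func:`assign_specific_ec` over every partial EC of every chain."""
    out = []
    for chain in chains:
        for ec in chain.ec_ids:
            if is_partial_ec(ec):
                out.append(
                    assign_specific_ec(
                        chain, interactions, matches, cognates,
                        partial_ec=ec, **kwargs,
                    )
                )
    return out
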