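"""Assignment of cognate ligands to bound entities by PARITY similarity.

Every bound entity observed in a structure is compared against the full
cognate-ligand table; matches at or above the calibrated threshold
(default 0.4) are retained, and within each bound entity the match(es)
attaining the maximum score carry the *best cognate* flag. Multiple
valid cognates per bound entity are deliberately kept — the threshold
removes poor matches, but choosing among several plausible cognates is
left to the consumer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .calibration import DEFAULT_THRESHOLD
from .chemistry import Molecule, parity_score, parse_smiles
from .errors import SmilesParseError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CognateLigand:
    """A cognate ligand (substrate, product or cofactor) with EC membership.

    ``ec_ids`` are complete four-field EC numbers of the reactions the
    ligand participates in; ``source_ids`` keeps contributing database
    accessions when records were deduplicated on canonical SMILES.
    """

    cognate_id: str
    name: str
    smiles: str
    ec_ids: tuple[str, ...]
    is_cofactor: bool = False
    roles: tuple[str, ...] = ()
    source_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class SimilarityMatch:
    """One retained bound-entity/cognate pair."""

    bound_id: str
    cognate_id: str
    score: float
    is_best: bool
    passed_threshold: bool
    timed_out: bool = False


@dataclass(frozen=True)
class MatchSummary:
    n_bound: int
    n_matched: int
    n_matches: int
    n_perfect: int
    n_cofactor_matches: int
    cofactor_fraction: float


def parse_cognates(cognates: list[CognateLigand]) -> list[tuple[CognateLigand, Molecule]]:
    """Parse cognate SMILES; unparseable entries are skipped with a warning."""
    out = []
    for c in cognates:
        try:
            out.append((c, parse_smiles(c.smiles, c.cognate_id)))
        except SmilesParseError:
            logger.warning("skipping cognate %s: unparseable SMILES %r",
                           c.cognate_id, c.smiles)
    return out


def match_bound_to_cognates(
    bound: list[Molecule],
    cognates: list[CognateLigand],
    threshold: float = DEFAULT_THRESHOLD,
    timeout_s: float = 10.0,
) -> list[SimilarityMatch]:
    """Score every bound entity against every cognate; keep matches >= threshold.

    All retained matches are returned (several cognates may map to one
    bound entity). ``is_best`` is set on the match(es) with the maximum
    score per bound entity — ties all flagged; pairs whose MCS search
    timed out never compete for best, though they are retained when
    above threshold (flagged ``timed_out``).
    """
    parsed = parse_cognates(cognates)
    matches: list[SimilarityMatch] = []
    for bm in bound:
        retained: list[tuple[str, float, bool]] = []
        for cog, cm in parsed:
            res = parity_score(bm, cm, timeout_s=timeout_s)
            if res.score >= threshold:
                retained.append((cog.cognate_id, res.score, res.timed_out))
        exact = [s for _, s, to in retained if not to]
        best = max(exact) if exact else None
        for cog_id, score, timed_out in retained:
            matches.append(
                SimilarityMatch(
                    bound_id=bm.id,
                    cognate_id=cog_id,
                    score=score,
                    is_best=(not timed_out and best is not None and score == best),
                    passed_threshold=True,
                    timed_out=timed_out,
                )
            )
    return matches


def summarize_matches(
    matches: list[SimilarityMatch],
    cognates: list[CognateLigand],
    n_bound: int | None = None,
) -> MatchSummary:
    """Counts of matched entities, perfect matches and cofactor matches.

    A *perfect match* is a score of exactly 1.0 (heavy-atom graphs
    isomorphic under element labels). The cofactor fraction is over
    matched bound entities with at least one cofactor-flagged match.
    """
    cofactor_ids = {c.cognate_id for c in cognates if c.is_cofactor}
    matched = {m.bound_id for m in matches}
    perfect = {m.bound_id for m in matches if m.score == 1.0}
    cof = {m.bound_id for m in matches if m.cognate_id in cofactor_ids}
    return MatchSummary(
        n_bound=n_bound if n_bound is not None else len(matched),
        n_matched=len(matched),
        n_matches=len(matches),
        n_perfect=len(perfect),
        n_cofactor_matches=len(cof),
        cofactor_fraction=(len(cof) / len(matched)) if matched else 0.0,
    )


def dedupe_cognates(cognates: list[CognateLigand]) -> list[CognateLigand]:
    """Merge cognates sharing a canonical SMILES across source databases.

    The merged record unions EC ids, roles and source ids; the cofactor
    flag is set if any contributing record carries it. Unparseable
    entries pass through untouched.
    """
    by_canon: dict[str, list[CognateLigand]] = {}
    passthrough: list[CognateLigand] = []
    order: list[str] = []
    for c in cognates:
        try:
            canon = parse_smiles(c.smiles, c.cognate_id).smiles
        except SmilesParseError:
            passthrough.append(c)
            continue
        if canon not in by_canon:
            order.append(canon)
        by_canon.setdefault(canon, []).append(c)
    out = []
    for canon in order:
        group = by_canon[canon]
        first = group[0]
        out.append(
            CognateLigand(
                cognate_id=first.cognate_id,
                name=first.name,
                smiles=canon,
                ec_ids=tuple(sorted({e for c in group for e in c.ec_ids})),
                is_cofactor=any(c.is_cofactor for c in group),
                roles=tuple(sorted({r for c in group for r in c.roles})),
                source_ids=tuple(
                    sorted({s for c in group for s in (c.source_ids or (c.cognate_id,))})
                ),
            )
        )
    return out + passthrough


def matches_to_frame(matches: list[SimilarityMatch]) -> pd.DataFrame:
    """Similarity-mapping table: bound_id, cognate_id, score, is_best."""
    return pd.DataFrame(
        [
            {
                "bound_id": m.bound_id,
                "cognate_id": m.cognate_id,
                "score": m.score,
                "is_best": m.is_best,
            }
            for m in matches
        ],
        columns=["bound_id", "cognate_id", "score", "is_best"],
    )
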