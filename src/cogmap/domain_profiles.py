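"""Domain promiscuity and cognate chemical-space profiling.

A domain family is *promiscuous* when it has nonminor interactions with
four or more distinct cognate ligands — the four-ligand floor avoids
flagging a family that merely binds the cofactor, substrate and product
of a single reaction. Promiscuous families are further split by the
chemistry of their cognate set: *specialized* families bind mutually
similar ligands (mean pairwise MACCS Tanimoto at or above the strict
0.575 threshold), *generalized* families bind a chemically diverse set.
The cognate chemical space itself is visualized by t-SNE on MACCS
fingerprints with k-means clusters selected by silhouette analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .chemistry import maccs_fingerprint, tanimoto
from .cognate_matching import CognateLigand, SimilarityMatch, parse_cognates
from .contacts import NONMINOR_MODES, DomainLigandInteraction
from .ec_completion import ChainAnnotation, is_partial_ec
from .errors import InputError

PROMISCUITY_MIN_COGNATES = 4
TANIMOTO_STRICT = 0.575
TANIMOTO_PERMISSIVE = 0.431


@dataclass(frozen=True)
class DomainProfile:
    """Chemical profile of one domain family's cognate-ligand repertoire."""

    domain_family_id: str
    domain_db: str
    cognate_ids: frozenset[str]
    n_cognates: int
    is_promiscuous: bool
    mean_pairwise_tanimoto: float | None
    klass: str  # specialized | generalized | not_promiscuous
    ec_diversity: int = 0


@dataclass(frozen=True)
class ClusterAssignment:
    cognate_id: str
    cluster: int
    embedding: tuple[float, float]


@dataclass(frozen=True)
class ClusterSpaceResult:
    assignments: tuple[ClusterAssignment, ...]
    chosen_k: int | None
    silhouette: float | None
    degenerate: bool = False


def mean_pairwise_tanimoto(fps) -> float | None:
    """Mean Tanimoto over all unordered fingerprint pairs; None if < 2."""
    if len(fps) < 2:
        return None
    sims = [tanimoto(a, b) for a, b in combinations(fps, 2)]
    return float(np.mean(sims))


def build_domain_profiles(
    interactions: list[DomainLigandInteraction],
    matches: list[SimilarityMatch],
    cognates: list[CognateLigand],
    entity_of: dict[str, str] | None = None,
    strict_threshold: float = TANIMOTO_STRICT,
) -> list[DomainProfile]:
    """Aggregate each family's cognate set and classify its chemistry.

    The cognate set per (domain database, family) is the union over all
    structures of cognates matched (any retained match, best or not) to
    ligand instances the family binds nonminorly. Duplicate structures
    contributing the same (family, cognate) pair count once.
    """
    entity_of = entity_of or {}
    cogs_by_entity: dict[str, set[str]] = {}
    for m in matches:
        cogs_by_entity.setdefault(m.bound_id, set()).add(m.cognate_id)

    family_cognates: dict[tuple[str, str], set[str]] = {}
    for it in interactions:
        if it.mode not in NONMINOR_MODES:
            continue
        entity = entity_of.get(it.ligand_instance, it.ligand_instance)
        cogs = cogs_by_entity.get(entity)
        if not cogs:
            continue
        family_cognates.setdefault((it.domain_db, it.domain_family), set()).update(cogs)

    fps = {}
    for cog, mol in parse_cognates(cognates):
        fps[cog.cognate_id] = maccs_fingerprint(mol)

    profiles = []
    for (db, family), cog_ids in sorted(family_cognates.items()):
        n = len(cog_ids)
        promiscuous = n >= PROMISCUITY_MIN_COGNATES
        mpt = mean_pairwise_tanimoto(
            [fps[c] for c in sorted(cog_ids) if c in fps]
        )
        if not promiscuous:
            klass = "not_promiscuous"
        elif mpt is not None and mpt >= strict_threshold:
            klass = "specialized"
        else:
            klass = "generalized"
        profiles.append(
            DomainProfile(
                domain_family_id=family,
                domain_db=db,
                cognate_ids=frozenset(cog_ids),
                n_cognates=n,
                is_promiscuous=promiscuous,
                mean_pairwise_tanimoto=mpt,
                klass=klass,
            )
        )
    return profiles


def ec_diversity(
    profile: DomainProfile,
    chains: list[ChainAnnotation],
    interactions: list[DomainLigandInteraction],
    matches: list[SimilarityMatch],
    entity_of: dict[str, str] | None = None,
) -> int:
    """Distinct complete ECs over chains where the family binds a mapped ligand."""
    entity_of = entity_of or {}
    matched_entities = {m.bound_id for m in matches}
    chain_keys: set[tuple[str, str]] = set()
    for it in interactions:
        if (
            it.domain_db == profile.domain_db
            and it.domain_family == profile.domain_family_id
            and it.mode in NONMINOR_MODES
            and entity_of.get(it.ligand_instance, it.ligand_instance)
            in matched_entities
        ):
            for ch in it.chains:
                chain_keys.add((it.structure_id, ch))
    ecs: set[str] = set()
    for ca in chains:
        if (ca.structure_id, ca.chain) in chain_keys:
            ecs.update(e for e in ca.ec_ids if not is_partial_ec(e))
    return len(ecs)


def annotate_ec_diversity(
    profiles: list[DomainProfile],
    chains: list[ChainAnnotation],
    interactions: list[DomainLigandInteraction],
    matches: list[SimilarityMatch],
    entity_of: dict[str, str] | None = None,
) -> list[DomainProfile]:
    """Return profiles with their ``ec_diversity`` fields filled in."""
    return [
        dataclasses.replace(
            p, ec_diversity=ec_diversity(p, chains, interactions, matches, entity_of)
        )
        for p in profiles
    ]


def embed_fingerprints(
    X: np.ndarray, seed: int = 0, perplexity: float = 30.0
) -> np.ndarray:
    """2D t-SNE embedding of a fingerprint matrix (PCA init, fixed seed).

    Perplexity is capped below the sample count so small sets embed
    without error.
    """
    n = X.shape[0]
    eff_perp = min(perplexity, max(1.0, (n - 1) / 3.0))
    return TSNE(
        n_components=2, perplexity=eff_perp, init="pca", random_state=seed
    ).fit_transform(X)


def silhouette_select_k(
    data: np.ndarray, k_range: range, seed: int = 0
) -> tuple[int, np.ndarray, float] | None:
    """k-means over ``k_range`` keeping the k with best mean silhouette.

    Returns ``(k, labels, silhouette)`` or None when no k produces two
    or more distinct clusters (degenerate data).
    """
    best = None
    n = data.shape[0]
    for k in k_range:
        if k >= n:
            break
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(data)
        if len(set(labels)) < 2:
            continue
        sil = float(silhouette_score(data, labels))
        if best is None or sil > best[2]:
            best = (k, labels, sil)
    return best


def cluster_cognate_space(
    cognates: list[CognateLigand],
    k_range: range = range(2, 21),
    seed: int = 0,
    perplexity: float = 30.0,
    cluster_on: str = "embedding",
) -> ClusterSpaceResult:
    """Embed cognate fingerprints in 2D and cluster, selecting k by silhouette.

    MACCS fingerprints are reduced to 2D with t-SNE (PCA initialization,
    fixed seed, perplexity capped below the sample count), then k-means
    is run for each k in ``k_range`` and the k with the highest mean
    silhouette coefficient is kept. ``cluster_on="fingerprints"``
    clusters the raw 166-bit vectors instead of the embedding. An
    all-identical fingerprint set is reported as degenerate with no
    clustering.
    """
    parsed = parse_cognates(cognates)
    if len(parsed) < max(k_range.start, 2):
        raise InputError(
            f"need at least {max(k_range.start, 2)} cognates to cluster, "
            f"got {len(parsed)}"
        )
    ids = [c.cognate_id for c, _ in parsed]
    X = np.array([maccs_fingerprint(m).bits for _, m in parsed], dtype=float)
    if np.all(X == X[0]):
        return ClusterSpaceResult(
            assignments=(), chosen_k=None, silhouette=None, degenerate=True
        )
    emb = embed_fingerprints(X, seed=seed, perplexity=perplexity)
    data = emb if cluster_on == "embedding" else X
    best = silhouette_select_k(data, k_range, seed=seed)
    if best is None:
        return ClusterSpaceResult(
            assignments=(), chosen_k=None, silhouette=None, degenerate=True
        )
    k, labels, sil = best
    # relabel to contiguous ints ordered by first appearance
    remap: dict[int, int] = {}
    for lb in labels:
        if lb not in remap:
            remap[lb] = len(remap)
    assignments = tuple(
        ClusterAssignment(
            cognate_id=i, cluster=remap[int(lb)],
            embedding=(float(e[0]), float(e[1])),
        )
        for i, lb, e in zip(ids, labels, emb)
    )
    return ClusterSpaceResult(assignments=assignments, chosen_k=k, silhouette=sil)


def profiles_to_frame(profiles: list[DomainProfile]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "domain_db": p.domain_db,
                "domain_family_id": p.domain_family_id,
                "n_cognates": p.n_cognates,
                "is_promiscuous": p.is_promiscuous,
                "mean_pairwise_tanimoto": p.mean_pairwise_tanimoto,
                "class": p.klass,
                "ec_diversity": p.ec_diversity,
                "cognate_ids": ";".join(sorted(p.cognate_ids)),
            }
            for p in profiles
        ]
    )
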