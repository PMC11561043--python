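"""Domain promiscuity, specialization and cognate-space clustering."""

import numpy as np
import pytest

from cogmap import CognateLigand, InputError, build_domain_profiles, cluster_cognate_space
from cogmap.cognate_matching import SimilarityMatch
from cogmap.contacts import DomainLigandInteraction
from cogmap.domain_profiles import (
    annotate_ec_diversity,
    embed_fingerprints,
    silhouette_select_k,
)
from cogmap.ec_completion import ChainAnnotation
from cogmap.fixtures import fingerprint_blobs
from oracles import brute_force_family_cognates


def _interaction(lig, family="F1", mode="exclusive", sid="S1", chain="A",
                 dom=None):
    return DomainLigandInteraction(
        structure_id=sid, ligand_instance=lig, domain_id=dom or f"{sid}{lig}d",
        domain_db="CATH", domain_family=family, n_residues=4, n_contacts=40,
        fraction=1.0, mode=mode, chains=(chain,),
    )


def _match(bound, cognate, score=0.8):
    return SimilarityMatch(bound_id=bound, cognate_id=cognate, score=score,
                          is_best=True, passed_threshold=True)


def _cognate(cid, smiles, ecs=("1.1.1.1",)):
    return CognateLigand(cognate_id=cid, name=cid, smiles=smiles, ec_ids=ecs)


# four near-identical long-chain alcohols: pairwise MACCS Tanimoto is high
SIMILAR = [_cognate(f"sim{k}", "C" * k + "O") for k in range(8, 12)]
# four chemically unrelated scaffolds
DIVERSE = [
    _cognate("div1", "CCCCCCCC"),
    _cognate("div2", "c1ccc2ccccc2c1"),
    _cognate("div3", "OP(=O)(O)OP(=O)(O)O"),
    _cognate("div4", "NC(CS)C(=O)O"),
]


class TestBuildDomainProfiles:
    def test_four_similar_cognates_specialized(self):
        inter = [_interaction(f"L{i}") for i in range(4)]
        matches = [_match(f"L{i}", f"sim{8 + i}") for i in range(4)]
        (profile,) = build_domain_profiles(inter, matches, SIMILAR)
        assert profile.n_cognates == 4
        assert profile.is_promiscuous
        assert profile.mean_pairwise_tanimoto >= 0.575
        assert profile.klass == "specialized"

    def test_three_cognates_not_promiscuous(self):
        inter = [_interaction(f"L{i}") for i in range(3)]
        matches = [_match(f"L{i}", f"sim{8 + i}") for i in range(3)]
        (profile,) = build_domain_profiles(inter, matches, SIMILAR)
        assert not profile.is_promiscuous
        assert profile.klass == "not_promiscuous"

    def test_four_diverse_cognates_generalized(self):
        inter = [_interaction(f"L{i}") for i in range(4)]
        matches = [_match(f"L{i}", f"div{1 + i}") for i in range(4)]
        (profile,) = build_domain_profiles(inter, matches, DIVERSE)
        assert profile.is_promiscuous
        assert profile.klass == "generalized"
        assert profile.mean_pairwise_tanimoto < 0.575

    def test_duplicate_structures_do_not_inflate_counts(self):
        inter = [_interaction("L0", sid=f"S{i}", dom=f"S{i}d") for i in range(5)]
        matches = [_match("L0", "sim8")]
        (profile,) = build_domain_profiles(inter, matches, SIMILAR)
        assert profile.n_cognates == 1

    def test_minor_interactions_excluded(self):
        inter = [_interaction(f"L{i}", mode="minor") for i in range(4)]
        matches = [_match(f"L{i}", f"sim{8 + i}") for i in range(4)]
        assert build_domain_profiles(inter, matches, SIMILAR) == []

    def test_partition_exhaustive_and_exclusive(self, world_interactions,
                                                world_matches, world):
        profiles = build_domain_profiles(
            world_interactions, world_matches, world.cognates
        )
        for p in profiles:
            if p.is_promiscuous:
                assert p.klass in ("specialized", "generalized")
            else:
                assert p.klass == "not_promiscuous"

    def test_matches_brute_force_recount(self, world_interactions,
                                         world_matches, world):
        profiles = build_domain_profiles(
            world_interactions, world_matches, world.cognates
        )
        expected = brute_force_family_cognates(world_interactions, world_matches)
        got = {
            (p.domain_db, p.domain_family_id): set(p.cognate_ids)
            for p in profiles
        }
        assert got == expected


class TestEcDiversity:
    def _setup(self, n_ecs):
        chains = [
            ChainAnnotation(f"S{i}", "A", (f"1.1.1.{i + 1}",))
            for i in range(n_ecs)
        ]
        inter = [
            _interaction(f"L{i}", sid=f"S{i}", dom=f"S{i}d")
            for i in range(n_ecs)
        ]
        matches = [_match(f"L{i}", "sim8") for i in range(n_ecs)]
        profiles = build_domain_profiles(inter, matches, SIMILAR)
        return annotate_ec_diversity(profiles, chains, inter, matches)

    def test_single_ec(self):
        (p,) = self._setup(1)
        assert p.ec_diversity == 1

    def test_five_ecs(self):
        (p,) = self._setup(5)
        assert p.ec_diversity == 5

    def test_no_annotated_chains(self):
        inter = [_interaction("L0")]
        matches = [_match("L0", "sim8")]
        profiles = build_domain_profiles(inter, matches, SIMILAR)
        (p,) = annotate_ec_diversity(profiles, [], inter, matches)
        assert p.ec_diversity == 0


class TestClusterCognateSpace:
    def test_three_separated_blobs_recovered(self):
        bases = ["CCCCCCCCO", "Nc1ccc(C(=O)O)cc1", "OP(=O)(O)OCC(O)C(O)CO"]
        cogs = [
            _cognate(f"b{b}_{i}", smi)
            for b, smi in enumerate(bases)
            for i in range(12)
        ]
        res = cluster_cognate_space(cogs, k_range=range(2, 8), seed=3)
        assert res.chosen_k == 3
        assert res.silhouette > 0.5
        assert not res.degenerate
        labels = sorted({a.cluster for a in res.assignments})
        assert labels == [0, 1, 2]

    def test_identical_fingerprints_degenerate(self):
        cogs = [_cognate(f"c{i}", "CCO") for i in range(10)]
        res = cluster_cognate_space(cogs, k_range=range(2, 5), seed=0)
        assert res.degenerate
        assert res.chosen_k is None

    def test_deterministic_under_seed(self):
        cogs = [_cognate(f"c{k}_{i}", "C" * k + ("O" if i else "N"))
                for k in range(3, 10) for i in range(2)]
        r1 = cluster_cognate_space(cogs, k_range=range(2, 6), seed=5)
        r2 = cluster_cognate_space(cogs, k_range=range(2, 6), seed=5)
        assert r1.assignments == r2.assignments
        assert r1.chosen_k == r2.chosen_k

    def test_too_few_cognates_rejected(self):
        with pytest.raises(InputError):
            cluster_cognate_space([_cognate("only", "CCO")],
                                  k_range=range(2, 5), seed=0)


class TestSilhouetteSelection:
    @pytest.mark.parametrize("planted", [2, 3, 5])
    def test_planted_blob_count_recovered(self, planted):
        X, _ = fingerprint_blobs(planted, n_per_cluster=15, seed=1)
        emb = embed_fingerprints(X, seed=1)
        k, _, sil = silhouette_select_k(emb, range(2, 9), seed=1)
        assert k == planted
        assert sil > 0.5
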