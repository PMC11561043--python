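# Methods notes

## PARITY similarity

Two molecules are compared on their heavy-atom graphs only; hydrogens are
stripped at parse time and never counted. The maximum common substructure
is found with RDKit's FMCS configured to (i) match atoms on element
identity, ignoring valence, charge and aromaticity, (ii) treat all bonds
as equivalent (bond order ignored), (iii) require a *connected* common
substructure, and (iv) maximize atom count rather than bond count. The
score is the Jaccard index over atoms, |MCS| / (N_a + N_b − |MCS|).

Two properties motivated this exact contract. Bond-order-insensitive
matching is required for pairs in which a thioether chain in one molecule
corresponds to a thioester in the other (an S-hexyl vs S-lactoyl
glutathione conjugate pair scores 23/28 ≈ 0.82 only when the C=O carbon
may match a CH2 carbon). And the Jaccard normalization — rather than,
say, |MCS| / max(N_a, N_b) — is the unique simple normalization that
reproduces both curated reference scores (8/9 → 0.89 and 23/28 → 0.82;
the max form would give 23/26 ≈ 0.885 for the latter). An independent
brute-force connected-common-subgraph enumerator in the test suite
verifies MCS sizes on all small-molecule pairs.

Ring-membership matching (ring atoms only matching ring atoms) is off by
default and exposed as `ring_matches_ring_only`; the reference pairs do
not discriminate this choice. The MCS search carries a 10 s per-pair
budget; a timed-out comparison reports the best substructure found so
far, is flagged `timed_out`, and never competes for best-cognate status.

Degenerate inputs: single-atom molecules match by element presence;
multi-fragment SMILES (salts) keep the largest fragment by heavy-atom
count, ties broken by lexicographically smallest canonical SMILES so the
result is input-order independent. Molecules that fail sanitization are
logged and skipped in batch operations rather than aborting a run.

## Threshold calibration

Random ligand pairs estimate the similarity distribution of non-cognate
pairs. Per replicate set the 95th percentile is computed with linear
interpolation between order statistics (no method is canonical here;
linear interpolation is numpy's default and the one assumed by the closed
forms in the tests). The matching threshold is the mean per-set
percentile plus an additive margin of 0.10 on the score scale, rounded to
one decimal. The additive reading is deliberate: a mean percentile of
0.29 plus 0.10 rounds to the working threshold 0.4, whereas a
multiplicative +10% (0.319) does not; the multiplicative variant remains
available via `margin_mode`. Pair sampling excludes self-pairs but allows
a pair to recur across draws.

The packaged ligand library (~220 molecules built from homologous
aliphatic series and substituted ring scaffolds) exists to exercise the
calibration machinery deterministically, not to reproduce any particular
corpus value: being built from homologous series it is far more
self-similar than a full chemical dictionary, so its random-pair
percentile (~0.78) sits well above what a diverse ligand corpus would
give. Calibration against a real corpus is a matter of pointing
`cogmap calibrate` at the corresponding ligand table. Stability tests run
5 sets of 300 pairs per seed, a size at which the per-seed mean
percentile varies by well under 0.01 on this library.

## Contact filtering and interaction modes

The ≥ 3-distinct-residue cutoff is applied per (domain, ligand-instance)
pair; a ligand instance whose every domain partner fails the cutoff
disappears entirely. This single rule removes both peripheral ligands and
sparse domain touches. Contact *shares* are computed on summed contact
counts (`fraction_basis="residues"` switches to distinct-residue counts),
and after filtering the denominators are renormalized over surviving
domains so shares sum to 1; passing pre-filter totals via
`contact_totals` preserves the original denominators instead.

Domains from different annotation databases (CATH, SCOP, SCOP2, Pfam,
SUPERFAMILY, Gene3D) never share a denominator — each database yields an
independent classification of the same ligand. Boundary conventions are
inclusive as printed: minor is strictly < 0.10, dominant ≥ 0.90,
major-partner ≥ 0.50, so a 50/50 split yields two major partners. The
Gini index uses the mean-absolute-difference form Σᵢⱼ|xᵢ−xⱼ| / (2n²μ),
which is 0 for perfect equality, (n−1)/n for a single non-zero value, and
scale-invariant.

## Cognate matching and EC completion

All matches at or above threshold are retained (deliberately not just the
top hit); best-cognate flags mark the maximum score per bound entity with
ties all flagged. A *perfect* match means score exactly 1.0, i.e.
element-isomorphic heavy-atom graphs — not a rounded 1.0. Cognate records
sharing a canonical SMILES across source databases can be merged with
`dedupe_cognates`, unioning EC memberships and keeping all source ids.

EC completion treats ≥ (not >) threshold as qualifying, consistent with
matching (a strict flag exists). Candidate selection is *best within the
partial class*: if a bound entity's globally best cognate lies outside the
class, the best in-class cognate still votes. The alternative (restrict
to globally best matches first) is exposed via `best_scope="global"`.
When one cognate carries several ECs inside the class, each counts as a
candidate; assignment requires the intersection of candidate EC sets
across contributing bound entities to be a singleton. Outright
disagreement between bound entities (empty intersection) is reported as
`ambiguous` — the chain has evidence, it just conflicts — while
`no_candidates` is reserved for chains with no qualifying in-class
cognate at all. Chains carrying a specific EC alongside the partial one
are excluded up front. Minor-mode interactions never contribute evidence.

## Domain profiles and clustering

Promiscuity counts *distinct* cognate ligands reached through nonminor
interactions anywhere in the corpus, so duplicate structures cannot
inflate a family's count; the floor of four avoids crowning a family that
merely binds one reaction's cofactor, substrate and product. Families
aggregate at the identifier supplied in the optional `domain_family`
contact column (intended to be the homologous-superfamily code for CATH);
absent that, the domain id itself.

Specialization uses the *mean* pairwise MACCS-166 Tanimoto of the
family's cognate set against the strict 0.575 threshold (the permissive
0.431 constant is exported but does not set the class boundary). The mean
was chosen over a fraction-of-pairs criterion as the simplest statistic
with an obvious degenerate case (undefined below two cognates).

Chemical-space clustering embeds fingerprints with t-SNE (PCA
initialization, fixed seed, perplexity capped at (n−1)/3 so small sets
embed) and k-means is run on the 2-D projection for each candidate k,
keeping the k with the highest mean silhouette; clustering the raw
166-bit vectors instead is a config switch. An all-identical fingerprint
set is reported as degenerate rather than clustered.

## Graph export

Node ids are namespaced (`structure:…`, `chain:S:A`, `domain:DB:id`,
`bound:…`, `cognate:…`, `ec:…`) for global uniqueness. One CSV per node
label and relationship type uses bulk-import headers (`:ID`, `:LABEL`,
`:START_ID`, `:END_ID`, `:TYPE`) with `:long`/`:double`/`:boolean` typed
property columns, RFC 4180 quoting, UTF-8 and sorted rows, so output is
byte-deterministic and round-trips exactly through `load_graph`.
Interaction mode and contact fraction live as properties on the
INTERACTS_WITH edge; score and best flag on MAPS_TO. The per-domain
chain list is serialized onto the interaction edge rather than modelled
as residue nodes, keeping graph size linear in interactions. Empty-string
properties are omitted at build time so written and loaded graphs compare
equal.

## Synthetic worlds

The fixture generator plants its ground truth by construction rather than
simulation: contact counts are integer percentages of a 100-contact
total, so the classifier's recovered fractions equal the planted vector
exactly; every chain's bound entity is chemically identical to the
cognate of its true EC, making that cognate the unique perfect best match
and the planted EC recoverable whenever the pipeline is correct. Mode
vectors are drawn from a vocabulary spanning all six modes
({1.0}, {0.93, 0.07}, {0.6, 0.4}, {0.85, 0.08, 0.07}, {0.5, 0.5}).
The default world (10 structures, one chain each, six domain families,
a 12-EC universe with one n-alkanol cognate per EC plus two out-of-class
cofactors) is intentionally small; tests that need scale (50-chain EC
recovery) raise `n_structures` only.

What the fixtures do *not* emulate: real contact geometry (counts are
synthesized, not measured from coordinates), chemically heterogeneous
bound entities (every planted entity is a perfect match, so recovery
tests exercise bookkeeping, not borderline similarity judgments), partial
classes spanning multiple EC branches, and corpus-scale statistics.
Passing fixture tests therefore demonstrates correctness of the
machinery, not performance on noisy real annotations.

## Problem sizes

Default test and script sizes — 220-molecule calibration library with
5 × 300 random pairs per seed, 161 800-vector exhaustive mode grid,
50-chain EC-recovery world, 100 randomized round-trip graphs, 30
blob-recovery clustering runs — were chosen so the whole suite completes
in well under a minute on one core while still covering every code path
at non-trivial scale.

## Known limitations

- Similarity is purely 2D topological; no conformers, no stereochemistry
  in the MCS (stereo descriptors survive in canonical SMILES but do not
  affect matching), no InChI input.
- The MCS is exact, so adversarial pairs (large near-symmetric molecules)
  can hit the timeout; timed-out scores are flagged lower bounds.
- Contacts are consumed as tables; computing them from coordinates, and
  typing them (hydrogen bonds vs van der Waals), is out of scope.
- EC completion trusts the cognate→EC table; a cognate mapped to the
  wrong reaction propagates directly into assignments.
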