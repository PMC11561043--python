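"""Contact filtering, Gini inequality and interaction-mode classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogmap import (
    ContactRecord,
    InputError,
    SchemaError,
    assign_interaction_modes,
    classify_fractions,
    combinatorial_interactions,
    filter_min_residues,
    gini,
    load_contacts,
)
from cogmap.cognate_matching import SimilarityMatch
from cogmap.contacts import MODES, contact_totals, gini_reports
from oracles import brute_force_gini


def _rec(lig="L1", dom="D1", chain="A", residue="1", n=5, db="CATH",
         family="", sid="S1"):
    return ContactRecord(
        structure_id=sid, ligand_instance=lig, chain=chain, residue=residue,
        domain_id=dom, domain_db=db, n_contacts=n, domain_family=family,
    )


def _domain_rows(lig, dom, n_res, contacts_per_res=5, family="", db="CATH"):
    return [
        _rec(lig=lig, dom=dom, residue=str(i), n=contacts_per_res,
             family=family, db=db)
        for i in range(n_res)
    ]


class TestLoadContacts:
    HEADER = ("structure_id\tligand_instance\tchain\tresidue\tdomain_id"
              "\tdomain_db\tn_contacts\n")

    def _write(self, tmp_path, rows):
        path = tmp_path / "contacts.tsv"
        path.write_text(self.HEADER + "".join(rows))
        return path

    def test_reads_every_row(self, tmp_path):
        rows = [f"S1\tL1\tA\t{i}\tD1\tCATH\t2\n" for i in range(12)]
        assert len(load_contacts(self._write(tmp_path, rows))) == 12

    def test_duplicate_rows_merged_with_warning(self, tmp_path, caplog):
        rows = ["S1\tL1\tA\t1\tD1\tCATH\t2\n", "S1\tL1\tA\t1\tD1\tCATH\t3\n"]
        with caplog.at_level("WARNING"):
            recs = load_contacts(self._write(tmp_path, rows))
        assert len(recs) == 1
        assert recs[0].n_contacts == 5
        assert any("merg" in r.message for r in caplog.records)

    def test_empty_file_yields_empty_list(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            assert load_contacts(self._write(tmp_path, [])) == []
        assert caplog.records

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("structure_id\tligand_instance\n")
        with pytest.raises(SchemaError, match="domain_id"):
            load_contacts(path)


class TestFilterMinResidues:
    def test_two_residue_domain_removed(self):
        records = _domain_rows("L1", "D1", 4) + _domain_rows("L1", "D2", 2)
        kept = filter_min_residues(records)
        assert {r.domain_id for r in kept} == {"D1"}

    def test_three_residue_boundary_inclusive(self):
        kept = filter_min_residues(_domain_rows("L1", "D1", 3))
        assert {r.domain_id for r in kept} == {"D1"}

    def test_ligand_with_no_qualifying_domain_dropped_entirely(self):
        records = _domain_rows("L1", "D1", 2) + _domain_rows("L2", "D2", 5)
        kept = filter_min_residues(records)
        assert {r.ligand_instance for r in kept} == {"L2"}


class TestGini:
    def test_perfect_equality(self):
        assert gini([5, 5, 5]) == pytest.approx(0.0)

    def test_two_values_half(self):
        assert gini([0, 1]) == pytest.approx(0.5)

    def test_single_nonzero_closed_form(self):
        # one non-zero among n gives (n-1)/n
        assert gini([1, 0, 0, 0]) == pytest.approx(0.75)

    def test_scale_invariance(self):
        v = [0.1, 0.4, 0.5]
        assert gini(v) == pytest.approx(gini([100 * x for x in v]))

    @pytest.mark.parametrize("bad", [[], [0, 0, 0]])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(InputError):
            gini(bad)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=8)
        .filter(lambda v: sum(v) > 0)
    )
    def test_matches_brute_force_double_sum(self, values):
        assert gini(values) == pytest.approx(brute_force_gini(values))


class TestClassifyFractions:
    @pytest.mark.parametrize(
        "fractions,expected",
        [
            ([1.0], ["exclusive"]),
            ([0.93, 0.07], ["dominant", "minor"]),
            ([0.60, 0.40], ["major_partner", "partner"]),
            ([0.85, 0.08, 0.07], ["major", "minor", "minor"]),
            ([0.50, 0.50], ["major_partner", "major_partner"]),
            # boundary: exactly 0.90 with one nonminor partner is dominant
            ([0.90, 0.05, 0.05], ["dominant", "minor", "minor"]),
            # boundary: exactly 0.10 is already nonminor
            ([0.90, 0.10], ["major_partner", "partner"]),
        ],
    )
    def test_printed_rule_examples(self, fractions, expected):
        assert classify_fractions(fractions) == expected

    def test_modes_from_closed_label_set(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            d = int(rng.integers(1, 5))
            v = rng.dirichlet(np.ones(d))
            modes = classify_fractions(list(v))
            assert set(modes) <= set(MODES)
            if d == 1:
                assert modes == ["exclusive"]


class TestAssignInteractionModes:
    def test_fractions_sum_to_one_after_filtering(self, world):
        interactions = assign_interaction_modes(filter_min_residues(world.contacts))
        by_lig = {}
        for it in interactions:
            by_lig.setdefault((it.ligand_instance, it.domain_db), []).append(
                it.fraction
            )
        for fracs in by_lig.values():
            assert sum(fracs) == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_row_order(self, world):
        fwd = assign_interaction_modes(world.contacts)
        rev = assign_interaction_modes(list(reversed(world.contacts)))
        assert sorted(fwd, key=str) == sorted(rev, key=str)

    def test_domain_databases_classified_independently(self):
        # same ligand seen by one CATH and one Pfam domain: each is the
        # only domain in its own database and must be exclusive
        records = (
            _domain_rows("L1", "D1", 4, db="CATH")
            + _domain_rows("L1", "PF1", 4, db="Pfam")
        )
        interactions = assign_interaction_modes(records)
        assert [it.mode for it in interactions] == ["exclusive", "exclusive"]

    def test_prefilter_totals_preserved_when_requested(self):
        records = _domain_rows("L1", "D1", 4, contacts_per_res=20) + _domain_rows(
            "L1", "D2", 2, contacts_per_res=10
        )
        totals = contact_totals(records)
        kept = filter_min_residues(records)
        its = assign_interaction_modes(kept, totals=totals)
        assert its[0].fraction == pytest.approx(80 / 100)

    def test_residue_basis_option(self):
        records = _domain_rows("L1", "D1", 6, contacts_per_res=1) + _domain_rows(
            "L1", "D2", 3, contacts_per_res=10
        )
        by_contacts = {
            it.domain_id: it.fraction
            for it in assign_interaction_modes(records)
        }
        by_residues = {
            it.domain_id: it.fraction
            for it in assign_interaction_modes(records, fraction_basis="residues")
        }
        assert by_contacts["D1"] == pytest.approx(6 / 36)
        assert by_residues["D1"] == pytest.approx(6 / 9)


class TestGiniReports:
    def test_multi_domain_interactions_reported(self):
        records = _domain_rows("L1", "D1", 3, contacts_per_res=30) + _domain_rows(
            "L1", "D2", 3, contacts_per_res=10
        )
        reports = gini_reports(assign_interaction_modes(records))
        assert len(reports) == 1
        assert reports[0].n_domains == 2
        assert reports[0].gini == pytest.approx(0.25)  # |0.75-0.25| / (2*2*0.5)


def _match(bound, cognate="C1", score=0.82):
    return SimilarityMatch(bound_id=bound, cognate_id=cognate, score=score,
                          is_best=True, passed_threshold=True)


class TestCombinatorialInteractions:
    def test_two_nonminor_domains_with_match(self):
        records = _domain_rows("L1", "D1", 3, 60, family="X") + _domain_rows(
            "L1", "D2", 3, 40, family="Y"
        )
        combos = combinatorial_interactions(
            assign_interaction_modes(records), [_match("L1")]
        )
        assert len(combos) == 1
        assert combos[0].combination == ("X", "Y")
        assert combos[0].best_score == pytest.approx(0.82)

    def test_single_domain_yields_no_record(self):
        records = _domain_rows("L1", "D1", 4, family="X")
        combos = combinatorial_interactions(
            assign_interaction_modes(records), [_match("L1")]
        )
        assert combos == []

    def test_duplicated_family_key_preserved(self):
        # two domain instances of the same superfamily sharing one ligand
        records = _domain_rows("L1", "D1", 3, 50, family="X") + _domain_rows(
            "L1", "D2", 3, 50, family="X"
        )
        combos = combinatorial_interactions(
            assign_interaction_modes(records), [_match("L1")]
        )
        assert combos[0].combination == ("X", "X")

    def test_unmatched_ligand_excluded(self):
        records = _domain_rows("L1", "D1", 3, 60, family="X") + _domain_rows(
            "L1", "D2", 3, 40, family="Y"
        )
        combos = combinatorial_interactions(
            assign_interaction_modes(records), [_match("L1", score=0.3)]
        )
        assert combos == []
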