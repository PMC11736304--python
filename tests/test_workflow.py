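import dataclasses

import pandas as pd
import pytest

from taxonscrub import (ColumnMapping, Config, SuggestionRow, apply_corrections,
                        build_suggestions, collect_names, read_occurrences,
                        summarize)
from taxonscrub.errors import ConfigError, ConflictError, ValidationError

from conftest import make_checklist, write_csv


def _table(tmp_path, text, mapping=None):
    p = write_csv(tmp_path / "occ.csv", text)
    return read_occurrences(p, mapping or ColumnMapping.identity())


def _accept_all(suggestions):
    return [dataclasses.replace(s, change="yes") for s in suggestions]


FULL_HEADER = "kingdom,phylum,class,order,family,genus,species,scientificName\n"


class TestCollectNames:
    def test_frequency_and_rows(self, tmp_path):
        t = _table(tmp_path, "kingdom\nAnimalia\nAnimalia\nAnimalia\n",
                   ColumnMapping.from_columns(["kingdom"]))
        idx = collect_names(t)
        assert idx.by_slot["kingdom"] == {"Animalia": [1, 2, 3]}
        assert idx.frequency("kingdom", "Animalia") == 3

    def test_empty_cells_ignored_and_raw_case_kept_distinct(self, tmp_path):
        t = _table(tmp_path, "kingdom,species\nAnimalia,\nanimalia,\n",
                   ColumnMapping.from_columns(
                       ["kingdom", None, None, None, None, None, "species"]))
        idx = collect_names(t)
        assert set(idx.by_slot["kingdom"]) == {"Animalia", "animalia"}
        assert idx.by_slot["species"] == {}


class TestBuildSuggestions:
    def test_worked_example_three_suggestions(self, worked_table, worked_checklist):
        sugg, summary = build_suggestions(worked_table, worked_checklist, Config())
        assert len(sugg) == 3
        by_slot = {s.rank_type: s for s in sugg}
        assert by_slot["kingdom"].wrong_name == "Aanimalia"
        assert by_slot["kingdom"].suggested_name == "Animalia"
        assert by_slot["order"].suggested_name == "Uropygi"
        assert by_slot["genus"].suggested_name == "Thelyphonelus"
        assert all(s.change == "no" for s in sugg)
        assert all(s.id_source for s in sugg)
        assert summary.total_occurrences == 3

    def test_clean_table_yields_nothing(self, worked_example, worked_checklist):
        t = read_occurrences(worked_example.clean_path, ColumnMapping.identity())
        sugg, _ = build_suggestions(t, worked_checklist, Config())
        assert sugg == []

    def test_unmatchable_name_becomes_flag_only_row(self, tmp_path):
        cl = make_checklist([("T1", "Animalia", "kingdom")])
        t = _table(tmp_path, "kingdom\nXqzzk\n",
                   ColumnMapping.from_columns(["kingdom"]))
        sugg, _ = build_suggestions(t, cl, Config())
        assert len(sugg) == 1
        assert sugg[0].is_flag_only and sugg[0].suggested_name == ""
        assert sugg[0].id_source == ""

    def test_empty_checklist_is_config_error(self, tmp_path, worked_checklist):
        t = _table(tmp_path, "kingdom\nAnimalia\n",
                   ColumnMapping.from_columns(["kingdom"]))
        empty = dataclasses.replace(worked_checklist, records=[])
        with pytest.raises(ConfigError):
            build_suggestions(t, empty, Config())

    def test_bare_epithet_joined_with_genus(self, tmp_path):
        cl = make_checklist([("T1", "Thelyphonelus", "genus"),
                             ("T2", "Thelyphonelus amazonicus", "species")])
        m = ColumnMapping.from_columns(
            [None, None, None, None, None, "genus", "species"])
        t = _table(tmp_path, "genus,species\nThelyphonelus,amazonicuss\n", m)
        sugg, _ = build_suggestions(t, cl, Config())
        species = [s for s in sugg if s.rank_type == "species"]
        assert len(species) == 1
        assert species[0].wrong_name == "amazonicuss"
        assert species[0].suggested_name == "amazonicus"  # epithet written back

    def test_unjoinable_epithet_is_flag_only(self, tmp_path):
        cl = make_checklist([("T2", "Thelyphonelus amazonicus", "species")])
        m = ColumnMapping.from_columns(
            [None, None, None, None, None, None, "species"])
        t = _table(tmp_path, "species\namazonicus\n", m)
        sugg, _ = build_suggestions(t, cl, Config())
        assert len(sugg) == 1 and sugg[0].is_flag_only

    def test_scientific_name_with_authorship_matches_exactly(self, tmp_path):
        cl = make_checklist([("T2", "Thelyphonelus amazonicus", "species")])
        m = ColumnMapping.from_columns(
            [None, None, None, None, None, None, None, "scientificName"])
        t = _table(tmp_path,
                   'scientificName\n"Thelyphonelus amazonicus (Butler, 1872)"\n', m)
        sugg, _ = build_suggestions(t, cl, Config())
        assert sugg == []


class TestApplyCorrections:
    def test_all_no_is_identity(self, worked_table, worked_checklist):
        sugg, _ = build_suggestions(worked_table, worked_checklist, Config())
        out = apply_corrections(worked_table, sugg)
        assert out.frame.equals(worked_table.frame)

    def test_accept_all_restores_clean_table(self, worked_table, worked_checklist,
                                             worked_example):
        sugg, _ = build_suggestions(worked_table, worked_checklist, Config())
        out = apply_corrections(worked_table, _accept_all(sugg))
        clean = pd.read_csv(worked_example.clean_path, dtype=str,
                            keep_default_na=False)
        assert out.frame.equals(clean)
        # idempotence: a second check pass finds nothing
        sugg2, _ = build_suggestions(out, worked_checklist, Config())
        assert sugg2 == []

    def test_partial_acceptance_changes_only_accepted_cells(
            self, worked_table, worked_checklist):
        sugg, _ = build_suggestions(worked_table, worked_checklist, Config())
        mixed = [dataclasses.replace(s, change="yes" if s.rank_type == "order"
                                     else "no") for s in sugg]
        out = apply_corrections(worked_table, mixed)
        diffs = (out.frame != worked_table.frame).to_numpy().sum()
        assert diffs == 1
        assert out.cell(3, "order") == "Uropygi"
        assert out.cell(1, "kingdom") == "Aanimalia"

    def test_conservation_cell_count(self, worked_table, worked_checklist):
        sugg, _ = build_suggestions(worked_table, worked_checklist, Config())
        accepted = _accept_all(sugg)
        out = apply_corrections(worked_table, accepted)
        diffs = (out.frame != worked_table.frame).to_numpy().sum()
        assert diffs == sum(len(s.row_refs) for s in accepted)

    def test_out_of_range_row_ref_rejected_before_mutation(self, worked_table):
        bad = [SuggestionRow(row_refs=(99,), rank_type="kingdom",
                             wrong_name="Aanimalia", suggested_name="Animalia",
                             id_source="T1", source_id=11, change="yes")]
        before = worked_table.frame.copy()
        with pytest.raises(ValidationError):
            apply_corrections(worked_table, bad)
        assert worked_table.frame.equals(before)

    def test_stale_wrong_name_is_conflict_error(self, worked_table):
        bad = [SuggestionRow(row_refs=(1,), rank_type="kingdom",
                             wrong_name="NotWhatIsThere", suggested_name="Animalia",
                             id_source="T1", source_id=11, change="yes")]
        with pytest.raises(ConflictError) as err:
            apply_corrections(worked_table, bad)
        assert any("kingdom" in d and "row 1" in d for d in err.value.details)

    def test_flag_only_rows_never_act(self, worked_table):
        flag = [SuggestionRow(row_refs=(1,), rank_type="kingdom",
                              wrong_name="Aanimalia", suggested_name="",
                              id_source="", source_id=11, change="yes")]
        out = apply_corrections(worked_table, flag)
        assert out.frame.equals(worked_table.frame)


class TestSummarize:
    def test_worked_example_panels(self, worked_table, worked_checklist):
        sugg, summary = build_suggestions(worked_table, worked_checklist, Config())
        assert summary.total_occurrences == 3
        # 11 distinct (slot, raw name) pairs: 8 slots, 3 with a typo variant
        assert summary.total_taxon_names == 11
        assert dict(summary.top3_ranks) == {"kingdom": 1, "order": 1, "genus": 1}
        # tie broken by slot order
        assert [s for s, _ in summary.top3_ranks] == ["kingdom", "order", "genus"]

    def test_zero_suggestions_empty_top3(self, worked_table):
        summary = summarize(worked_table, [])
        assert summary.top3_ranks == []
        assert all(n == 0 for n in summary.errors_by_rank.values())

    def test_unique_name_count(self, tmp_path):
        t = _table(tmp_path, "kingdom\n" + "Animalia\n" * 7 + "Plantae\n" * 3,
                   ColumnMapping.from_columns(["kingdom"]))
        summary = summarize(t, [])
        assert summary.total_occurrences == 10
        assert summary.total_taxon_names == 2
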