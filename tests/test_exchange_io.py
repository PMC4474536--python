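import textwrap

import pytest

from windtome import exchange_io
from windtome.exchange_io import (
    FormatError,
    SourceAssociationRecord,
    TrialLabelTable,
)
from windtome.scoring import WeightedAssociation

HEADER = "\t".join(exchange_io.ASSOCIATION_COLUMNS)


def write_assoc(tmp_path, *rows):
    path = tmp_path / "assoc.tsv"
    path.write_text("\n".join([HEADER, *rows]) + "\n")
    return path


class TestReadAssociations:
    def test_basic_row_parses_with_split_references(self, tmp_path):
        path = write_assoc(
            tmp_path, "src1\taspirin\tC100\t\t\t\tuniprot-ac\tP1\t9606\t11;12")
        records, rejects = exchange_io.read_associations(path)
        assert rejects == []
        (rec,) = records
        assert rec.drug_xrefs == {"cid": "C100"}
        assert rec.raw_target == ("uniprot-ac", "P1")
        assert rec.references == {"11", "12"}

    def test_empty_reference_cell_gives_empty_set(self, tmp_path):
        path = write_assoc(tmp_path, "src1\taspirin\t\t\t\t\tgene-id\tg1\t9606\t")
        records, _ = exchange_io.read_associations(path)
        assert records[0].references == frozenset()
        assert records[0].drug_xrefs == {}

    def test_empty_file_returns_empty_list(self, tmp_path):
        records, rejects = exchange_io.read_associations(
            write_assoc(tmp_path))
        assert records == [] and rejects == []

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("source\tdrug_name\n")
        with pytest.raises(FormatError, match="target_ns"):
            exchange_io.read_associations(path)

    def test_malformed_taxon_is_rejected_not_fatal(self, tmp_path):
        path = write_assoc(
            tmp_path,
            "src1\taspirin\t\t\t\t\tgene-id\tg1\tnine\t",
            "src1\tibuprofen\t\t\t\t\tgene-id\tg2\t9606\t",
        )
        records, rejects = exchange_io.read_associations(path)
        assert len(records) == 1 and len(rejects) == 1
        assert rejects[0].reason == "malformed-taxon"

    def test_no_row_is_silently_dropped(self, tmp_path):
        rows = [
            "src1\tok\t\t\t\t\tgene-id\tg1\t9606\t",
            "src1\tbadtaxon\t\t\t\t\tgene-id\tg1\tx\t",
            "src1\t  \t\t\t\t\tgene-id\tg1\t9606\t",  # blank name
        ]
        records, rejects = exchange_io.read_associations(
            write_assoc(tmp_path, *rows))
        assert len(records) + len(rejects) == len(rows)


class TestReadMappings:
    def test_synonym_keys_casefolded_and_merged(self, tmp_path):
        p = tmp_path / "syn.tsv"
        p.write_text("synonym\tcid\nAspirin\tC100\nASPIRIN \tC100\n")
        maps = exchange_io.read_mappings(synonyms=p)
        assert maps.synonym_to_cid == {"aspirin": "C100"}

    def test_conflicting_synonym_keeps_smallest_cid(self, tmp_path, caplog):
        p = tmp_path / "syn.tsv"
        p.write_text("synonym\tcid\nfoo\tC2\nfoo\tC1\n")
        with caplog.at_level("WARNING"):
            maps = exchange_io.read_mappings(synonyms=p)
        assert maps.synonym_to_cid["foo"] == "C1"
        assert any("conflict" in r.message for r in caplog.records)

    def test_uniprot_accumulates_gene_sets(self, tmp_path):
        p = tmp_path / "uni.tsv"
        p.write_text("uniprot_ac\tgene_id\nP1\tg1\nP1\tg2\n")
        maps = exchange_io.read_mappings(uniprot=p)
        assert maps.uniprot_to_gene["P1"] == {"g1", "g2"}

    def test_gene_info_requires_symbol_and_positive_taxon(self, tmp_path):
        p = tmp_path / "gi.tsv"
        p.write_text("gene_id\tsymbol\ttaxon\ng1\t\t9606\n")
        with pytest.raises(FormatError):
            exchange_io.read_mappings(gene_info=p)


class TestPPI:
    def test_reversed_duplicate_edge_stored_once(self, tmp_path):
        p = tmp_path / "ppi.tsv"
        p.write_text("gene_a\tgene_b\ng1\tg2\ng2\tg1\n")
        graph = exchange_io.read_ppi(p)
        assert graph.number_of_edges() == 1

    def test_self_loop_dropped_and_counted(self, tmp_path):
        p = tmp_path / "ppi.tsv"
        p.write_text("gene_a\tgene_b\ng1\tg1\ng1\tg2\n")
        graph = exchange_io.read_ppi(p)
        assert graph.number_of_edges() == 1
        assert graph.graph["self_loops_dropped"] == 1


class TestRoundTrips:
    def test_interactome_round_trip_preserves_scores(self, tmp_path):
        assocs = [
            WeightedAssociation(
                drug_uid=f"CID:C{i}", gene_id="g1",
                sources=frozenset({"src1", "src2"}),
                references=frozenset({"11"}),
                score_s=2, score_r=1.234567890123 * (i + 1))
            for i in range(5)
        ]
        path = tmp_path / "inter.tsv"
        exchange_io.write_interactome(assocs, path)
        back = exchange_io.read_interactome(path)
        assert {a.drug_uid for a in back} == {a.drug_uid for a in assocs}
        for orig, rt in zip(sorted(assocs, key=lambda a: a.drug_uid),
                            sorted(back, key=lambda a: a.drug_uid)):
            assert rt.score_r == pytest.approx(orig.score_r, rel=1e-12)
            assert rt.sources == orig.sources

    def test_association_round_trip(self, tmp_path):
        rec = SourceAssociationRecord(
            source="src1", drug_name="aspirin",
            drug_xrefs={"cid": "C100", "chebi_id": "15365"},
            target_ns="uniprot-ac", target_value="P1", taxon=9606,
            references=frozenset({"11", "12"}))
        path = tmp_path / "a.tsv"
        exchange_io.write_associations([rec], path)
        back, rejects = exchange_io.read_associations(path)
        assert rejects == [] and back == [rec]

    def test_trials_round_trip(self, tmp_path):
        table = TrialLabelTable()
        table.add("Citalopram", "scz", 13)
        table.add("Citalopram", "mental", 2)
        path = tmp_path / "t.tsv"
        exchange_io.write_trials(table, path)
        assert exchange_io.read_trials(path).counts == table.counts


class TestTrialLabelTable:
    def test_duplicate_key_rejected(self):
        table = TrialLabelTable()
        table.add("DrugA", "scz", 1)
        with pytest.raises(ValueError):
            table.add("druga", "scz", 2)  # same key after case-folding

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            TrialLabelTable().add("DrugA", "scz", -1)
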