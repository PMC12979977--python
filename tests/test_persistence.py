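"""Store, audit trail, CSV template exchange, DOT export."""

import io
from fractions import Fraction

import pytest

from pedkit import (
    CorruptLogError,
    FormatError,
    Individual,
    Pedigree,
    PedigreeStore,
    Sex,
    export_audit_csv,
    export_dot,
    export_table,
    import_table,
    inbreeding,
    replay,
    restore,
    snapshot,
)
from pedkit.persistence import AuditEntry


def _inbred_chain_csv() -> str:
    buf = io.StringIO()
    from pedkit import make_example_pedigrees
    export_table(make_example_pedigrees()["inbred_chain"], buf)
    return buf.getvalue()


class TestCsvRoundTrip:
    def test_export_reimport_reproduces_f_values(self, inbred_chain):
        ped, report = import_table(io.StringIO(_inbred_chain_csv()))
        assert report.is_valid
        for ident in ("Jochen", "Merle", "Carl", "Luise"):
            assert inbreeding(ped, ident).f == inbreeding(inbred_chain, ident).f
        assert ped == inbred_chain

    def test_second_export_is_byte_identical(self):
        first = _inbred_chain_csv()
        ped, _ = import_table(io.StringIO(first))
        buf = io.StringIO()
        export_table(ped, buf)
        assert buf.getvalue() == first

    def test_header_only_file_gives_empty_valid_pedigree(self):
        ped, report = import_table(io.StringIO("id,sex,sire,dam,f,label\n"))
        assert len(ped) == 0
        assert report.is_valid

    def test_missing_columns_rejected(self):
        with pytest.raises(FormatError):
            import_table(io.StringIO("id,sire\nA,\n"))

    def test_stated_f_mismatch_warns_but_recomputed_wins(self):
        csv_text = (
            "id,sex,sire,dam,f,label\n"
            "Cora,2,,,,\n"
            "Bandit,1,?,Cora,,\n"
            "Jochen,1,Bandit,Cora,0.30,\n"
        )
        ped, report = import_table(io.StringIO(csv_text))
        assert inbreeding(ped, "Jochen").f == Fraction(1, 4)
        assert any(v.rule_code == "F_MISMATCH" for v in report.violations)

    def test_inbred_founder_f_is_adopted(self):
        csv_text = "id,sex,sire,dam,f,label\nZelda,2,,,0.125,\n"
        ped, report = import_table(io.StringIO(csv_text))
        assert report.is_valid
        assert ped["Zelda"].founder_f == Fraction(1, 8)

    def test_row_order_never_matters(self):
        fwd = ("id,sex,sire,dam,f,label\n"
               "Cora,2,,,,\nBandit,1,?,Cora,,\nJochen,1,Bandit,Cora,,\n")
        rev = ("id,sex,sire,dam,f,label\n"
               "Jochen,1,Bandit,Cora,,\nBandit,1,?,Cora,,\nCora,2,,,,\n")
        ped_a, _ = import_table(io.StringIO(fwd))
        ped_b, _ = import_table(io.StringIO(rev))
        assert ped_a == ped_b

    def test_strict_mode_rejects_atomically_lenient_skips(self):
        bad = ("id,sex,sire,dam,f,label\n"
               "A,1,,,,\nA,2,,,,\nB,2,,,,\n")          # duplicate id A
        with pytest.raises(FormatError):
            import_table(io.StringIO(bad), strict=True)
        ped, report = import_table(io.StringIO(bad), strict=False)
        assert set(ped.ids()) == {"A", "B"}
        assert not report.is_valid

    def test_word_sex_codes_accepted(self):
        csv_text = "id,sex,sire,dam,f,label\nA,Male,,,,\nB,f,,,,\n"
        ped, _ = import_table(io.StringIO(csv_text))
        assert ped["A"].sex is Sex.MALE
        assert ped["B"].sex is Sex.FEMALE

    def test_extra_columns_preserved_verbatim(self):
        csv_text = "id,sex,sire,dam,f,label,coat\nA,1,,,,,tabby\n"
        ped, _ = import_table(io.StringIO(csv_text))
        assert ped["A"].meta["coat"] == "tabby"
        buf = io.StringIO()
        export_table(ped, buf)
        assert "coat" in buf.getvalue().splitlines()[0]
        assert "tabby" in buf.getvalue()


class TestAuditAndReplay:
    def test_replay_of_empty_log_is_empty_pedigree(self):
        assert len(replay([])) == 0

    def test_add_delete_replay(self):
        store = PedigreeStore()
        store.add_individual(Individual(id="A", sex=Sex.MALE))
        store.remove_individual("A")
        assert len(store.log) == 2
        assert len(replay(store.log)) == 0

    def test_every_mutation_is_logged_and_replayable(self, inbred_chain):
        store = PedigreeStore()
        store.import_pedigree(inbred_chain)
        assert len(store.log) == len(inbred_chain)      # one entry per record
        assert replay(store.log) == store.pedigree
        for ident in ("Jochen", "Merle", "Carl", "Luise"):
            assert inbreeding(replay(store.log), ident).f == \
                inbreeding(inbred_chain, ident).f

    def test_replay_since_supports_snapshot_deltas(self):
        store = PedigreeStore()
        store.add_individual(Individual(id="A", sex=Sex.MALE))
        cut = store.log[-1].seq
        store.add_individual(Individual(id="B", sex=Sex.FEMALE))
        delta = replay(store.log, since=cut)
        assert delta.ids() == ["B"]

    def test_corrupt_entries_rejected(self):
        with pytest.raises(CorruptLogError):
            AuditEntry.from_json({"timestamp": "x"})
        with pytest.raises(CorruptLogError):
            AuditEntry.from_json({
                "timestamp": "t", "seq": 1, "action": "explode",
                "entity_id": "A", "payload": {}})

    def test_sequence_numbers_are_monotonic(self):
        store = PedigreeStore()
        store.add_individual(Individual(id="A", sex=Sex.FEMALE))
        store.add_individual(Individual(id="B", sire_id="X", dam_id="A"))
        seqs = [e.seq for e in store.log]
        assert seqs == sorted(seqs)
        assert len(set(seqs)) == len(seqs)

    def test_audit_csv_export(self, tmp_path):
        store = PedigreeStore()
        out = tmp_path / "audit.csv"
        export_audit_csv(store, out)
        assert out.read_text().splitlines() == [
            "timestamp,seq,action,entity_id,payload"]
        store.add_individual(Individual(id="A", sex=Sex.MALE))
        export_audit_csv(store, out)
        lines = out.read_text().splitlines()
        assert len(lines) == 2 and ",add,A," in lines[1]


class TestSnapshotRestore:
    def test_round_trip_preserves_members_and_log(self, tmp_path, inbred_chain):
        store = PedigreeStore()
        store.import_pedigree(inbred_chain)
        path = tmp_path / "store.json"
        snapshot(store, path)
        loaded = restore(path)
        assert loaded.pedigree == store.pedigree
        assert loaded.log == store.log
        # a second snapshot of the restored store is byte-identical
        path2 = tmp_path / "store2.json"
        snapshot(loaded, path2)
        assert path.read_text() == path2.read_text()

    def test_restore_rejects_foreign_files(self, tmp_path):
        path = tmp_path / "junk.json"
        path.write_text("{}")
        with pytest.raises(CorruptLogError):
            restore(path)


class TestDotExport:
    def test_mother_son_graph_structure(self, tmp_path, mother_son):
        out = tmp_path / "ped.dot"
        export_dot(mother_son, out)
        text = out.read_text()
        assert text.startswith("digraph pedigree {")
        assert text.count(" -> ") == len(mother_son.edge_list()) == 4
        assert '"Jochen" [shape=box' in text
        assert "F=0.2500" in text
        assert 'fillcolor="tomato"' in text        # Very High band
        assert '"?" [shape=diamond' in text

    def test_empty_pedigree_gives_empty_digraph(self, tmp_path):
        out = tmp_path / "empty.dot"
        export_dot(Pedigree(), out)
        text = out.read_text()
        assert "->" not in text and "shape=" not in text

    def test_counts_match_structure_on_synthetic_pedigree(self, tmp_path):
        from pedkit import GenParams, generate
        ped = generate(GenParams(n_founders=4, n_generations=2, seed=7))
        out = tmp_path / "syn.dot"
        export_dot(ped, out)
        text = out.read_text()
        assert text.count("shape=") == len(ped)
        assert text.count(" -> ") == len(ped.edge_list())
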