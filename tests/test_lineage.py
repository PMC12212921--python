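"""Lineage store: schema, registration, tracing, import/export."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mabflow.errors import (
    HeaderValidationError,
    ReferentialIntegrityError,
    RowValidationError,
    SchemaError,
)
from mabflow.lineage import (
    ID_BYTE_LENGTH,
    LineageStore,
    RecordID,
    Schema,
    TableDef,
    default_schema,
)


class TestSchema:
    def test_default_schema_has_19_tables(self, schema):
        assert len(schema) == 19

    def test_documented_key_fields_present(self, schema):
        assert schema["Picking"].fk_fields == {"FK_Plating_ID": "Plating"}
        for table, id_field in [
            ("Plating", "Plating_ID"),
            ("Picking", "Picking_ID"),
            ("Working_Stock", "Working_Stock_ID"),
            ("Safe_Stock", "Safe_Stock_ID"),
            ("Transfection", "Transfection_ID"),
            ("AB", "AB_ID"),
        ]:
            assert schema[table].id_field == id_field

    def test_schema_is_acyclic_and_resolvable(self, schema):
        schema.validate()  # raises on cycles or dangling FKs
        assert schema.roots == ["FACS"]

    def test_transfection_references_two_plasmids(self, schema):
        parents = set(schema["Transfection"].fk_fields.values())
        assert parents == {"Working_Stock"}
        assert len(schema["Transfection"].fk_fields) == 2

    def test_extension_with_dangling_fk_rejected(self, schema):
        bad = TableDef("AB_Assay1", "Assay1_ID", {"FK_Missing_ID": "NoSuchTable"}, ("value",))
        with pytest.raises(SchemaError):
            schema.extend(bad)


class TestRegistration:
    def test_ids_are_16_bytes_and_unique(self, store):
        ids = [store.register("FACS", {"donor_id": f"D{i}"}) for i in range(50)]
        assert all(len(r.bytes) == ID_BYTE_LENGTH for r in ids)
        assert len(set(ids)) == 50

    def test_child_inherits_parent_id(self, store):
        trfo = _register_minimal_trfo(store)
        plating = store.register("Plating", {"plate_barcode": "BP1"}, {"FK_TRFO_ID": trfo})
        picking = store.register("Picking", {"colony_number": 1}, {"FK_Plating_ID": plating})
        assert store.get(picking).fk_values["FK_Plating_ID"] == plating

    def test_multiple_pickings_from_one_plating(self, store):
        trfo = _register_minimal_trfo(store)
        plating = store.register("Plating", {"plate_barcode": "BP1"}, {"FK_TRFO_ID": trfo})
        p1 = store.register("Picking", {"colony_number": 1}, {"FK_Plating_ID": plating})
        p2 = store.register("Picking", {"colony_number": 2}, {"FK_Plating_ID": plating})
        assert p1 != p2
        assert store.get(p1).fk_values == store.get(p2).fk_values

    def test_dangling_parent_rejected(self, store):
        with pytest.raises(ReferentialIntegrityError, match="FK_Plating_ID"):
            store.register("Picking", {"colony_number": 1}, {"FK_Plating_ID": RecordID.new()})

    def test_missing_parent_rejected(self, store):
        with pytest.raises(ReferentialIntegrityError):
            store.register("cDNA", {"plate_barcode": "X"})

    def test_natural_key_never_creates_twin(self, store):
        trfo = _register_minimal_trfo(store)
        first = store.register("Plating", {"plate_barcode": "BP9"}, {"FK_TRFO_ID": trfo})
        again = store.register("Plating", {"plate_barcode": "BP9"}, {"FK_TRFO_ID": trfo})
        assert first == again
        assert store.count("Plating") == 1


class TestLineageTracing:
    def test_root_record_chain_of_one(self, store):
        facs = store.register("FACS", {"donor_id": "D1"})
        chain = store.trace_lineage(facs)
        assert [r.table for r in chain] == ["FACS"]

    def test_five_stage_chain_in_construction_order(self, store):
        built = _register_chain_through(store, "cELE1")
        chain = store.trace_lineage(built["cELE1"])
        assert [r.table for r in chain] == ["FACS", "cDNA", "PCR1", "PCR2", "cELE1"]

    def test_transfection_has_exactly_two_plasmid_ancestors(self, store):
        traf = _register_transfection(store)
        stocks = [r for r in store.trace_lineage(traf) if r.table == "Working_Stock"]
        assert len(stocks) == 2
        chains = sorted(r.payload["chain"] for r in stocks)
        assert chains == ["Heavy", "Kappa"]

    def test_extended_table_traces_to_root(self, store):
        traf = _register_transfection(store)
        ab = store.register("AB", {"harvest_date": "2025-02-01"}, {"FK_Transfection_ID": traf})
        store.extend_schema(TableDef("AB_Assay1", "Assay1_ID", {"FK_AB_ID": "AB"}, ("value",)))
        assay = store.register("AB_Assay1", {"value": "0.92"}, {"FK_AB_ID": ab})
        chain = store.trace_lineage(assay)
        assert chain[0].table == "FACS"
        assert chain[-1].table == "AB_Assay1"

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_tracing_terminates_and_is_acyclic(self, seed):
        rng = random.Random(seed)
        store = LineageStore(id_rng=rng)
        built = _register_chain_through(store, "cELE1")
        for rid in built.values():
            chain = store.trace_lineage(rid)
            ids = [r.id for r in chain]
            assert len(set(ids)) == len(ids)
        store.close()


class TestImportExport:
    def test_round_trip(self, store, schema, tmp_path):
        for i in range(3):
            store.register("FACS", {"donor_id": f"D{i}", "plate_barcode": "F1", "well": "A1"})
        out = tmp_path / "facs.csv"
        assert store.export_table("FACS", out) == 3
        fresh = LineageStore(schema)
        imported = fresh.import_file(out)
        assert len(imported) == 3
        for rid in imported:
            assert fresh.get(rid).payload == store.get(rid).payload
        fresh.close()

    def test_renamed_column_named_in_error(self, store, tmp_path):
        store.register("FACS", {"donor_id": "D1"})
        out = tmp_path / "facs.csv"
        store.export_table("FACS", out)
        text = out.read_text().replace("donor_id", "donor")
        (tmp_path / "bad.csv").write_text(text)
        with pytest.raises(HeaderValidationError) as err:
            store.import_file(tmp_path / "bad.csv")
        assert "donor_id" in err.value.missing

    def test_empty_id_rejected(self, store, schema, tmp_path):
        store.register("FACS", {"donor_id": "D1"})
        out = tmp_path / "facs.csv"
        store.export_table("FACS", out)
        lines = out.read_text().splitlines()
        cells = lines[1].split(",")
        cells[0] = ""
        (tmp_path / "bad.csv").write_text("\n".join([lines[0], ",".join(cells)]) + "\n")
        fresh = LineageStore(schema)
        with pytest.raises(RowValidationError) as err:
            fresh.import_file(tmp_path / "bad.csv")
        assert any("empty FACS_ID" in e for e in err.value.row_errors)
        fresh.close()

    def test_conflicting_payload_for_existing_id_rejected(self, store, tmp_path):
        store.register("FACS", {"donor_id": "D1"})
        out = tmp_path / "facs.csv"
        store.export_table("FACS", out)
        (tmp_path / "bad.csv").write_text(out.read_text().replace("D1", "D2"))
        with pytest.raises(RowValidationError) as err:
            store.import_file(tmp_path / "bad.csv")
        assert any("different payload" in e for e in err.value.row_errors)

    def test_reimport_identical_rows_is_idempotent(self, store, tmp_path):
        store.register("FACS", {"donor_id": "D1"})
        out = tmp_path / "facs.csv"
        store.export_table("FACS", out)
        assert store.import_file(out) == []
        assert store.count("FACS") == 1


def test_bulk_random_registration_preserves_uniqueness_and_integrity():
    rng = random.Random(42)
    store = LineageStore(id_rng=rng)
    facs = [store.register("FACS", {"donor_id": f"D{i}"}) for i in range(200)]
    cdnas = [
        store.register("cDNA", {"plate_barcode": "C1"}, {"FK_FACS_ID": rng.choice(facs)})
        for _ in range(400)
    ]
    all_ids = facs + cdnas
    assert len(set(all_ids)) == len(all_ids)
    for c in cdnas:
        parent = store.get(c).fk_values["FK_FACS_ID"]
        assert store.table_of(parent) == "FACS"
    store.close()


# -- helpers ---------------------------------------------------------------

_CHAIN_ORDER = ["FACS", "cDNA", "PCR1", "PCR2", "cELE1", "SEQ1", "PCR3", "cELE2",
                "GiAs", "TRFO"]


def _register_chain_through(store, last_table):
    ids = {}
    for table in _CHAIN_ORDER[: _CHAIN_ORDER.index(last_table) + 1]:
        tdef = store.schema[table]
        parents = {fk: ids[parent] for fk, parent in tdef.fk_fields.items()}
        ids[table] = store.register(table, {}, parents)
    return ids


def _register_minimal_trfo(store):
    return _register_chain_through(store, "TRFO")["TRFO"]


def _register_stock(store, chain):
    trfo = _register_minimal_trfo(store)
    plating = store.register(
        "Plating", {"plate_barcode": f"BP_{chain}_{store.count('Plating')}"},
        {"FK_TRFO_ID": trfo},
    )
    picking = store.register("Picking", {"colony_number": 1}, {"FK_Plating_ID": plating})
    return store.register("Working_Stock", {"chain": chain}, {"FK_Picking_ID": picking})


def _register_transfection(store):
    heavy = _register_stock(store, "Heavy")
    light = _register_stock(store, "Kappa")
    return store.register(
        "Transfection",
        {"plate_barcode": "T1", "well": "A1"},
        {"FK_Heavy_Working_Stock_ID": heavy, "FK_Light_Working_Stock_ID": light},
    )
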