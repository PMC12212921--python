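"""Heavy/light pairing, transfection planning, repicking."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mabflow.errors import CountMismatchError, LineageError
from mabflow.lineage import LineageStore
from mabflow.pairing import (
    PlasmidRecord,
    match_pairs,
    plan_transfection,
    repick_candidates,
    transfection_import_rows,
)


def plasmid(pid, cdna, chain, qc="passed"):
    return PlasmidRecord(plasmid_id=pid, cdna_id=cdna, chain=chain, qc=qc)


def brute_force_pair_count(plasmids):
    """Oracle: a cDNA pairs iff it has >=1 passed heavy and >=1 passed light
    of an unambiguous light type."""
    count = 0
    cdnas = {p.cdna_id for p in plasmids}
    for c in cdnas:
        group = [p for p in plasmids if p.cdna_id == c and p.qc == "passed"]
        h = any(p.chain == "Heavy" for p in group)
        k = any(p.chain == "Kappa" for p in group)
        l = any(p.chain == "Lambda" for p in group)
        if h and (k != l):  # exactly one light type present
            count += 1
    return count


class TestMatchPairs:
    def test_simple_pair(self):
        res = match_pairs([plasmid("h1", "c1", "Heavy"), plasmid("k1", "c1", "Kappa")])
        assert len(res.pairs) == 1
        assert res.pairs[0].heavy.plasmid_id == "h1"

    def test_missing_light_reported_unmatched(self):
        res = match_pairs([plasmid("h1", "c1", "Heavy")])
        assert not res.pairs
        assert [p.plasmid_id for p in res.unmatched_heavy] == ["h1"]

    def test_three_cdna_toy_set(self):
        res = match_pairs([
            plasmid("h1", "c1", "Heavy"), plasmid("k1", "c1", "Kappa"),
            plasmid("h2", "c2", "Heavy"),
            plasmid("k3", "c3", "Kappa"),
        ])
        assert len(res.pairs) == 1
        assert [p.plasmid_id for p in res.unmatched_heavy] == ["h2"]
        assert [p.plasmid_id for p in res.unmatched_light] == ["k3"]

    def test_kappa_lambda_ambiguity_goes_to_manual_review(self):
        res = match_pairs([
            plasmid("h1", "c1", "Heavy"),
            plasmid("k1", "c1", "Kappa"),
            plasmid("l1", "c1", "Lambda"),
        ])
        assert not res.pairs
        assert {p.plasmid_id for p in res.ambiguous} == {"h1", "k1", "l1"}

    def test_failed_plasmids_ignored(self):
        res = match_pairs([
            plasmid("h1", "c1", "Heavy", qc="failed"),
            plasmid("k1", "c1", "Kappa"),
        ])
        assert not res.pairs
        assert [p.plasmid_id for p in res.unmatched_light] == ["k1"]

    @given(seed=st.integers(0, 2**32 - 1))
    @settings(max_examples=200, deadline=None)
    def test_against_brute_force_on_random_cohorts(self, seed):
        rng = random.Random(seed)
        plasmids = []
        for c in range(rng.randint(1, 15)):
            for i in range(rng.randint(0, 3)):
                plasmids.append(plasmid(
                    f"p{c}_{i}", f"c{c}",
                    rng.choice(["Heavy", "Kappa", "Lambda"]),
                    rng.choice(["passed", "failed", "pending"]),
                ))
        res = match_pairs(plasmids)
        assert len(res.pairs) == brute_force_pair_count(plasmids)
        # every passed plasmid lands in exactly one bucket
        buckets = (
            [p.plasmid_id for pr in res.pairs for p in (pr.heavy, pr.light)]
            + [p.plasmid_id for p in res.unmatched_heavy]
            + [p.plasmid_id for p in res.unmatched_light]
            + [p.plasmid_id for p in res.ambiguous]
        )
        passed = [p.plasmid_id for p in plasmids if p.qc == "passed"]
        assert sorted(buckets) == sorted(passed)


class TestPlanTransfection:
    def test_scan_order_layout(self):
        heavy = [plasmid(f"h{i}", f"c{i}", "Heavy") for i in range(4)]
        light = [plasmid(f"k{i}", f"c{i}", "Kappa") for i in range(4)]
        layout = plan_transfection(heavy, light)
        assert [p.well for p in layout] == ["A1", "A2", "A3", "A4"]

    def test_uneven_counts_raise_before_layout(self):
        heavy = [plasmid(f"h{i}", f"c{i}", "Heavy") for i in range(5)]
        light = [plasmid(f"k{i}", f"c{i}", "Kappa") for i in range(4)]
        with pytest.raises(CountMismatchError, match="5 heavy vs 4 light"):
            plan_transfection(heavy, light)

    def test_empty_input_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert plan_transfection([], []) == []
        assert any("empty" in m for m in caplog.messages)

    @given(n_heavy=st.integers(0, 12), n_light=st.integers(0, 12))
    @settings(max_examples=100, deadline=None)
    def test_raises_iff_counts_differ(self, n_heavy, n_light):
        heavy = [plasmid(f"h{i}", f"c{i}", "Heavy") for i in range(n_heavy)]
        light = [plasmid(f"k{i}", f"c{i}", "Kappa") for i in range(n_light)]
        if n_heavy != n_light:
            with pytest.raises(CountMismatchError):
                plan_transfection(heavy, light)
        else:
            layout = plan_transfection(heavy, light)
            assert len(layout) == n_heavy


class TestRepick:
    @staticmethod
    def _store_with_stock(n_picks=1):
        store = LineageStore(id_rng=random.Random(0))
        ids = {}
        prev = None
        for table in ["FACS", "cDNA", "PCR1", "PCR2", "cELE1", "SEQ1", "PCR3",
                      "cELE2", "GiAs", "TRFO"]:
            tdef = store.schema[table]
            parents = {fk: ids[pt] for fk, pt in tdef.fk_fields.items()}
            ids[table] = store.register(table, {}, parents)
        plating = store.register("Plating", {"plate_barcode": "BP1"},
                                 {"FK_TRFO_ID": ids["TRFO"]})
        stock = None
        for i in range(n_picks):
            picking = store.register("Picking", {"colony_number": i + 1},
                                     {"FK_Plating_ID": plating})
            stock = store.register("Working_Stock", {"chain": "Heavy", "seq2_status": "failed"},
                                   {"FK_Picking_ID": picking})
        return store, plating, stock

    def test_failed_plasmid_reuses_original_plating_id(self):
        store, plating, stock = self._store_with_stock()
        cands = repick_candidates({str(stock): "failed"}, store, max_picks=3)
        assert len(cands) == 1
        assert cands[0].plating_id == str(plating)
        assert not cands[0].replate
        store.close()

    def test_all_passed_yields_empty_list(self):
        store, _, stock = self._store_with_stock()
        assert repick_candidates({str(stock): "passed"}, store) == []
        store.close()

    def test_exhausted_plate_flagged_replate(self):
        store, _, stock = self._store_with_stock(n_picks=3)
        cands = repick_candidates({str(stock): "failed"}, store, max_picks=3)
        assert cands[0].replate
        store.close()

    def test_plasmid_without_plating_ancestry_is_a_lineage_error(self):
        store = LineageStore(id_rng=random.Random(1))
        facs = store.register("FACS", {"donor_id": "D1"})
        with pytest.raises(LineageError):
            repick_candidates({str(facs): "failed"}, store)
        store.close()


def test_transfection_import_rows_have_two_plasmid_ancestors():
    """Cross-module: laying out a matched pair and importing it yields a
    transfection traceable to exactly two plasmid working stocks."""
    store, _, stock_h = TestRepick._store_with_stock()
    # second, light-chain stock through its own chain
    store2_ids = {}
    prev = None
    for table in ["FACS", "cDNA", "PCR1", "PCR2", "cELE1", "SEQ1", "PCR3",
                  "cELE2", "GiAs", "TRFO"]:
        tdef = store.schema[table]
        parents = {fk: store2_ids[pt] for fk, pt in tdef.fk_fields.items()}
        store2_ids[table] = store.register(table, {}, parents)
    plating = store.register("Plating", {"plate_barcode": "BP2"},
                             {"FK_TRFO_ID": store2_ids["TRFO"]})
    picking = store.register("Picking", {"colony_number": 1}, {"FK_Plating_ID": plating})
    stock_l = store.register("Working_Stock", {"chain": "Kappa"}, {"FK_Picking_ID": picking})

    heavy = [PlasmidRecord(str(stock_h), "c1", "Heavy", "passed")]
    light = [PlasmidRecord(str(stock_l), "c1", "Kappa", "passed")]
    layout = plan_transfection(heavy, light)
    (traf_id,) = transfection_import_rows(layout, store)
    stocks = [r for r in store.trace_lineage(traf_id) if r.table == "Working_Stock"]
    assert len(stocks) == 2
    store.close()
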