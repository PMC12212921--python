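"""Primer registry, chain typing, PCR scheduling, allele-specific lookup."""

import random
from dataclasses import dataclass

import pytest

from mabflow.errors import InputValidationError, PrimerLookupError, RegistryError
from mabflow.plates import PlateFormat, WellAddress
from mabflow.primers import (
    AlleleCall,
    PrimerRecord,
    PrimerRegistry,
    build_pcr3_lookup,
    chain_type_of,
    schedule_pcr1,
    select_pcr3_pair,
)
from mabflow.synthetic import FunnelConfig, allele_calls, generate_cohort


@dataclass
class Sample:
    sample_id: str
    plate_barcode: str
    well: str


def make_call(v="IGHV3-23*01", j="IGHJ4*01", chain="Heavy", evaluation="functional", sid="s1"):
    return AlleleCall(
        sample_id=sid, chain=chain, v_allele=v, j_allele=j,
        evaluation=evaluation, plate_barcode="P1", well=WellAddress(0, 0),
    )


class TestRegistry:
    def test_packaged_registry_has_69_final_pcr_primers(self, registry):
        assert len(registry.pcr3_records()) == 69

    def test_final_pcr_primers_span_all_chains_and_directions(self, registry):
        combos = {(r.chain, r.direction) for r in registry.pcr3_records()}
        assert combos == {(c, d) for c in ("Heavy", "Kappa", "Lambda")
                          for d in ("forward", "reverse")}

    def test_duplicate_primer_name_rejected(self):
        rec = PrimerRecord("dup", "PCR3", "Heavy", "forward", ("IGHV1-2",))
        with pytest.raises(RegistryError, match="dup"):
            PrimerRegistry([rec, rec])

    def test_lookup_on_empty_registry(self):
        empty = PrimerRegistry([])
        with pytest.raises(PrimerLookupError):
            empty.lookup("PCR3", "Heavy", "forward", "IGHV1-2*01")

    def test_final_pcr_primer_requires_allele_key(self):
        with pytest.raises(RegistryError):
            PrimerRecord("bad", "PCR3", "Heavy", "forward", ())


class TestChainTyping:
    @pytest.mark.parametrize(
        "allele,chain",
        [("IGHV3-23*01", "Heavy"), ("IGKV1-5*03", "Kappa"), ("IGLV2-14*01", "Lambda")],
    )
    def test_locus_prefix_rule(self, allele, chain):
        assert chain_type_of(allele) == chain

    def test_non_immunoglobulin_locus_rejected(self):
        with pytest.raises(InputValidationError):
            chain_type_of("TRBV5-1")


class TestPcr1Scheduling:
    def test_one_sample_three_reactions(self, registry):
        reactions = schedule_pcr1([Sample("s1", "CDNA_001", "A1")], registry)
        assert len(reactions) == 3
        assert sorted(r.chain for r in reactions) == ["Heavy", "Kappa", "Lambda"]

    @pytest.mark.parametrize("n", [2, 7, 96])
    def test_linearity(self, n, registry):
        samples = [Sample(f"s{i}", "CDNA_001", f"A{i % 12 + 1}") for i in range(n)]
        assert len(schedule_pcr1(samples, registry)) == 3 * n

    def test_full_plate_mirrors_layout_per_chain(self, registry):
        fmt = PlateFormat.plate_96()
        from mabflow.plates import index_to_well_label

        samples = [Sample(f"s{i}", "CDNA_001", index_to_well_label(i, fmt)) for i in range(96)]
        reactions = schedule_pcr1(samples, registry)
        by_chain = {}
        for r in reactions:
            by_chain.setdefault(r.chain, []).append(r)
        for chain, rs in by_chain.items():
            assert len(rs) == 96
            assert len({r.plate_barcode for r in rs}) == 1  # one plate per chain
            assert [r.well.label for r in rs] == [s.well for s in samples]

    def test_empty_input_rejected(self, registry):
        with pytest.raises(InputValidationError):
            schedule_pcr1([], registry)


class TestPairSelection:
    def test_unique_lookup(self, registry):
        fwd, rev = select_pcr3_pair(make_call(), registry)
        assert fwd.direction == "forward" and rev.direction == "reverse"
        assert any(k.startswith("IGHV3-23") for k in fwd.allele_keys)
        assert any(k.startswith("IGHJ4") for k in rev.allele_keys)

    def test_unmatched_allele_raises_carrying_it(self, registry):
        call = make_call(v="IGHV9-99*01")
        with pytest.raises(PrimerLookupError) as err:
            select_pcr3_pair(call, registry)
        assert err.value.allele == "IGHV9-99*01"

    def test_failed_evaluation_rejected(self, registry):
        with pytest.raises(InputValidationError):
            select_pcr3_pair(make_call(evaluation="failed"), registry)

    def test_gene_boundary_respected(self, registry):
        """A gene-level key must not match a longer gene name sharing its
        prefix: IGHV1-2 exists in the registry but IGHV1-24 does not."""
        with pytest.raises(PrimerLookupError):
            select_pcr3_pair(make_call(v="IGHV1-25*01"), registry)

    def test_longest_key_wins_ties_by_canonical_order(self):
        """Oracle: enumerate all matching candidates, apply the stated rule."""
        records = [
            PrimerRecord("broad", "PCR3", "Heavy", "forward", ("IGHV3",)),
            PrimerRecord("specific", "PCR3", "Heavy", "forward", ("IGHV3-23",)),
            PrimerRecord("rev", "PCR3", "Heavy", "reverse", ("IGHJ4",)),
        ]
        registry = PrimerRegistry(records)
        call = make_call(v="IGHV3-23*01")

        def oracle():
            matches = []
            for rec in records:
                if rec.direction != "forward":
                    continue
                for key in rec.allele_keys:
                    rest = call.v_allele[len(key):]
                    if call.v_allele.startswith(key) and (not rest or not rest[0].isdigit()):
                        matches.append((len(key), rec.name))
            best_len = max(m[0] for m in matches)
            return sorted(n for l, n in matches if l == best_len)[0]

        fwd, _ = select_pcr3_pair(call, registry)
        assert fwd.name == oracle() == "specific"

    def test_selection_invariant_under_registry_row_order(self, registry):
        shuffled = list(registry.records)
        random.Random(7).shuffle(shuffled)
        reshuffled = PrimerRegistry(shuffled)
        for call in [make_call(), make_call(v="IGKV1-5*03", j="IGKJ2*01", chain="Kappa")]:
            a = select_pcr3_pair(call, registry)
            b = select_pcr3_pair(call, reshuffled)
            assert (a[0].name, a[1].name) == (b[0].name, b[1].name)


class TestLookupTable:
    def test_scan_order_assignment(self, registry):
        calls = [make_call(sid="s1"), make_call(sid="s2")]
        rows, rejections = build_pcr3_lookup(calls, registry, ["PCR3_001"])
        assert [r.dest_well for r in rows] == ["A1", "A2"]
        assert not rejections

    def test_unresolvable_call_goes_to_rejections(self, registry):
        calls = [make_call(sid="ok"), make_call(sid="bad", v="IGHV9-99*01")]
        rows, rejections = build_pcr3_lookup(calls, registry, ["PCR3_001"])
        assert [r.sample_id for r in rows] == ["ok"]
        assert [c.sample_id for c, _ in rejections] == ["bad"]

    def test_empty_input_warns(self, registry, caplog):
        with caplog.at_level("WARNING"):
            rows, rejections = build_pcr3_lookup([], registry, [])
        assert rows == [] and rejections == []


def test_synthetic_alleles_all_resolve_against_packaged_registry(registry):
    """Coverage audit keeping the generator and registry consistent."""
    cohort = generate_cohort(FunnelConfig(n_cells=64, seed=5), registry)
    for call in allele_calls(cohort):
        fwd, rev = select_pcr3_pair(call, registry)
        assert fwd.chain == call.chain == rev.chain
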