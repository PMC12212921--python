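# mabflow

Data processing for high-throughput monoclonal-antibody (mAB) production
from single B-cells.

Producing antibodies at scale means shepherding thousands of samples
through a selection funnel: FACS-sorted B-cells → cDNA → three successive
PCRs per chain → capillary-electrophoresis quality gates → V/J allele calls
→ allele-specific final amplification → cloning, bacterial plating and
picking → plasmid QC → heavy/light pairing → transfection → harvested,
quantified antibody. At every arrow a lab needs machine-readable worklists,
validated intermediate files, batch bookkeeping and airtight sample
provenance. `mabflow` implements that layer for people running (or
simulating) such a workflow:

- **plate algebra** — well label ↔ index conversion on 96/384 grids in both
  scan orders, 96→384 quadrant stamping (interleaved or block), sequential
  plate barcodes;
- **lineage store** — an embedded 19-table relational store; every record
  gets a 16-byte unique ID and inherits its parents' IDs, so any harvested
  antibody traces back to the original sorted cell (`trace_lineage`),
  with CSV import/export and schema extension;
- **readout ingestion** — header-validated parsing of electrophoresis and
  concentration exports, band-size selection (`passed`/`failed` partition),
  C1·V1 = C2·V2 dilution planning;
- **primer selection** — per-chain PCR mix scheduling (3 reactions per
  cDNA) and deterministic selection of the specific final-PCR pair from a
  packaged 69-primer registry keyed by V/J alleles;
- **batching** — FIFO store lists, automatic full-batch computation with
  leftover persistence, transfer worklists for liquid handlers;
- **chain pairing** — one-to-one heavy/light matching per cDNA, transfection
  layouts that refuse uneven inputs, colony repick lists that reuse
  existing plating records;
- **synthetic cohorts** — a seed-reproducible generator of the whole funnel
  so everything above is testable without instrument data;
- **CLI** — one subcommand per workflow step, single TOML configuration,
  self-documenting run logs.

## Worked example

Generate a mock cohort and push its pending samples through the final-PCR
batching step:

```bash
$ mabflow generate --seed 3 --n-cells 250 --out mock
        sorted_cells: 250
                cdna: 250
        cele1_passed: 155
     seq1_functional: 109
        cele2_passed: 72
              cloned: 63
     colonies_picked: 57
         seq2_passed: 49
  transfection_pairs: 49
wrote 8 files to mock

$ mabflow pcr3 --store-list mock/PCR3_*.csv --last-barcode 7
327 samples pending -> 3 plate(s) of 96 to process
39 leftover samples saved to store_lists/PCR3_20260921T180719.csv
```

The funnel counts show how 250 sorted cells narrow to 49 cells whose heavy
*and* light chains survived every quality gate (each count is cells with
both chains still alive). The batching step found 327 chain samples queued
for the final PCR, formed ⌊327/96⌋ = 3 full plates, continued the barcode
sequence after plate 7 (so `PCR3_008`–`PCR3_010`, one transfer worklist
each under `05_PCR3_Out/`), and saved the 39 oldest-first leftovers as a
new store list. A run log in `logs/` records parameters, inputs and outputs
of each invocation.

The same operations are available as a library:

```python
from mabflow import FunnelConfig, generate_cohort, funnel_counts, form_batches
from mabflow.synthetic import pcr3_store_list

cohort = generate_cohort(FunnelConfig(n_cells=250, seed=3))
batches, leftover = form_batches(pcr3_store_list(cohort), 96)
```

## Documentation

See `docs/methods.md` for the data model, the matching and batching rules,
what the synthetic generator does and does not emulate, and the design
decisions taken where conventions were open.
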