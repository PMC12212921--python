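# Methods

`mabflow` models the data-processing layer of a high-throughput monoclonal
-antibody (mAB) production workflow: single B-cells are sorted into
microplates, their antibody heavy and light chains are amplified, sequenced,
cloned into expression plasmids, paired, and transfected into HEK cells for
antibody expression. The package implements the bookkeeping and decision
logic between wet-lab steps — not any wet-lab chemistry and not sequence
analysis itself (V/J allele calls are consumed as an upstream tool's output,
never computed).

## The workflow model

A sample's life is a chain of states:

```
FACS -> cDNA -> PCR1 -> PCR2 -> cELE1 -> SEQ1 -> PCR3 -> cELE2 -> GiAs
     -> TRFO -> Plating -> Picking -> Working_Stock -> (Safe_Stock, ConcAdj)
     -> Transfection -> AB -> quant          (Glyc branches off Picking)
```

Each state is one row in one of 19 interrelated tables. Rows carry a
16-byte unique identifier minted at entry and inherit their parents' IDs in
`FK_`-prefixed columns; payload data is stored exactly once and linked, not
copied. Bacterial *plating* and colony *picking* are deliberately separate
tables with a one-to-many relationship, so a failed plasmid can be repicked
against the already-registered plate. A transfection references exactly two
plasmid working stocks (one heavy, one light); the same plasmid pair may be
transfected many times. The six tables whose key fields are fixed by the
data model are Plating, Picking, Working_Stock, Safe_Stock, Transfection
and AB; the remaining thirteen are named after the workflow steps above.
There is no separate donor table: donor identity is payload on the FACS
root record, so "tracing to the donor" means reaching the FACS root.

The store is sqlite-backed (in-memory or single-file). IDs are random
128-bit UUIDs; the version/variant bits are not constrained because only
uniqueness and the 16-byte length are load-bearing. Timestamps are ISO-8601
with timezone and injectable, which is what makes generated stores
reproducible byte-for-byte.

## Plate algebra

Internally wells are 0-based (row, column) pairs; printed labels use the
universal `A1` convention. Row-major is the default scan order and every
worklist records the order used. The 96-to-384 quadrant mapping defaults to
the *interleaved* convention of plate-stamping liquid handlers — quadrant
`q` sends 96-well `(r, c)` to 384-well `(2r + q//2, 2c + q%2)` — with a
contiguous *block* convention selectable for tiling instruments. Both are
bijections onto the 384 grid; which one a given lab's hardware uses is a
configuration fact, not something the data can reveal. Barcodes are a
configurable prefix plus a zero-padded integer (default width 3); the user
supplies the last number already used on a step and new plates continue the
sequence, which keeps barcodes strictly increasing without central state.

## Selection funnel and thresholds

Capillary electrophoresis readouts are filtered by an amplicon-size window
in base pairs (`min_bp`, optional `max_bp`). A missing band is encoded as
0 bp rather than null so that the threshold comparison is total. The
default `min_band_bp = 300` in the packaged configuration is an
illustrative placeholder — real cutoffs depend on the amplicon design and
belong in each lab's config; all tests pass thresholds explicitly.

Concentration adjustment solves C1·V1 = C2·V2. A stock already below target
cannot be concentrated by dilution and is flagged `below_target` and used
neat; a computed stock volume exceeding the available volume sets
`insufficient_volume`. Volumes are clamped so stock + diluent equals the
final volume exactly despite floating-point rounding.

## Primer selection

Three PCRs amplify each chain: the first two with per-chain forward/reverse
primer mixes, the third with a specific pair chosen from a 69-primer
registry keyed by V- and J-allele patterns. The packaged registry preserves
that structure — Heavy 22 V-forward + 6 J-reverse, Kappa 15 + 5, Lambda
14 + 7 — using standard human immunoglobulin gene names and *synthetic
placeholder sequences*; counts and keys drive the pipeline, oligo sequences
do not.

The allele-to-primer matching rule is this package's own convention (the
upstream analysis tool's rule is not published): a key matches a call when
it is a prefix ending at a gene-name boundary, so the gene-level key
`IGHV1-2` matches `IGHV1-2*02` but never `IGHV1-24*01`; among matches the
longest key wins, and ties break by canonical registry order (registries
are sorted by stage, chain, direction, name at load, making selection
independent of file row order). Unresolvable calls are collected into a
rejection report instead of aborting the batch.

## Batching

Samples that pass a step accumulate on a *store list*, an ordered queue
persisted as a timestamped CSV. Batch formation takes `len(store) //
batch_size` full batches oldest-first and persists the leftover as a new
store list, so samples that have waited longest are always processed first
and `batches x size + leftover = input` holds exactly. The default batch
size is 96 (one plate); it is per-step configuration because manual
workflows use smaller chunks. Equal enqueue timestamps are impossible by
construction in generated data (strictly increasing injected clock) and
broken by insertion order otherwise.

## Pairing and repicking

Pairing is strictly one-to-one per cDNA: a transfection pair needs one
QC-passed heavy and one QC-passed light plasmid from the same cDNA. A cDNA
with both a passed kappa and a passed lambda is biologically unexpected
(light-chain isotype exclusion) and is set aside for manual review rather
than auto-resolved. Transfection layout refuses to produce anything when
the heavy and light input tables differ in length — uneven pivoting of
split samples is a real failure mode and must fail before any file is
written. Repicking reuses the existing plating record; after `max_picks`
(default 3, configurable) pickings a plate is flagged `replate` instead.

## Synthetic cohorts

The generator emulates the selection funnel so every module is testable
without laboratory data. Per cell: a light-chain type (kappa with
probability 0.6), then per chain independent Bernoulli gates — band at
either electrophoresis check (`p_pcr_band = 0.8`, applied at both),
functional sequence evaluation (`p_seq1_functional = 0.85`), cloning
(`p_clone = 0.9`), colony growth (`p_colony = 0.95`) and final sequencing
(`p_seq2 = 0.9`). A cell yields an antibody only if both chains pass
everything, so the analytic pair probability is
`(p_band^2 * p_seq1 * p_clone * p_colony * p_seq2)^2 ≈ 0.175` with
defaults, and the default cohort of 384 cells (four 96-well sort plates)
yields ~67 expected pairs. These rates are illustrative: real per-stage
survival is lab- and project-specific.

Band sizes come from two-component mixtures (passing amplicon peaks around
480/420/440 bp for heavy/kappa/lambda, sd 15; failures are no-band with
probability 0.7 or a short product around 120 bp), clipped to the correct
side of the configured 300 bp threshold so that re-thresholding an emitted
file reproduces the simulated outcomes exactly — the generator/parser loop
is closed. Allele calls are sampled from the packaged registry's keys so
every functional call resolves; an optional novel-allele rate exercises the
no-primer error path. Plasmid and antibody concentrations are lognormal.
All randomness flows from one seed through `numpy.random.default_rng`;
timestamps are injected, so identical seeds give byte-identical files.

What the generator does *not* model: repertoire biology (no somatic
hypermutation, clonality or allele usage bias), correlated failures within
plates or batches, instrument-specific file dialect quirks, and partial or
corrupted readouts beyond what the validators are tested with. Passing
tests therefore demonstrate the correctness of the data-processing logic
under clean funnel-shaped data, not robustness to every real instrument
export.

## Configuration, validation, logging

One TOML file holds every shared parameter; a duplicate key definition is
rejected by a pre-parse scan that names the key and section. Paths resolve
relative to an invocation root, so relocating the working tree changes
nothing. Intermediate files are validated against configured headers
(exact names and order), optional row-count expectations and optional
column types; validation returns a report and callers decide whether to
abort. Every CLI invocation that writes output writes exactly one run log
(text plus JSON sidecar: step, parameters, inputs, outputs, user,
timestamps, messages), and step outputs land in numbered directories
(`05_PCR3_Out`, `06_CELE2_Out`, ...) mirroring the workflow.

## Numerical and design notes

- Natural-key deduplication (e.g. the same bacteria plate barcode entered
  twice) returns the existing record ID with a warning instead of creating
  a twin row.
- Imports are transactional: any bad row (empty ID, dangling FK, existing
  ID with different payload) rejects the whole file with a per-row report;
  re-importing identical rows is an idempotent no-op.
- `trace_lineage` returns a root-first topological order with ties broken
  by (created_at, id); it is total and acyclic because the schema graph is
  validated acyclic and FKs cannot dangle.
- Problem sizes used by the acceptance script (a 384-cell cohort, 960
  exhaustive well round-trips, 10,000-record bulk registrations in tests)
  were chosen as representative desk-scale workloads; the whole suite runs
  in seconds.
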