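# Methods

## The mapping model

An epitope is a set of antigen residues, stated in 1-based UniProt
coordinates of a parent antigen: a linear epitope is the window
`[start, start+len)` (recovered by exact substring search when the
stated start is absent or disagrees with the parent sequence; the first
occurrence wins and a warning is emitted), a discontinuous epitope is an
explicit list of (residue, position) sites. A structure of the antigen
is addressed through a residue-level alignment keyed by (chain, UniProt
position); the value records the author numbering (number + insertion
code) that PDB files and viewers use, the residue's one-letter code,
and whether it is observed (has coordinates).

A position **matches** on a chain iff the alignment has an entry there,
the entry is observed, and its one-letter code equals the epitope's
letter at that position. The **mapped fraction** is matched/epitope
length; it deliberately conflates coverage and identity into a single
criterion, because both an unmodeled epitope and a sequence-divergent
placement are equally noninformative to a viewer. An epitope is
retained for a structure iff some chain reaches the cutoff
(default 0.20; the boundary is inclusive, so exactly 20% is retained).
An epitope mapping to several chains yields one output row per passing
chain but is counted once in the structure's epitope tally.

Unmatched positions carry one of three reasons — `no_mapping` (no
alignment entry), `not_observed` (unmodeled region),
`identity_mismatch` — and an epitope that passes nowhere is reported
with the dominant reason of its best-scoring chain (ties broken in the
order not_observed, identity_mismatch, no_mapping, on the view that an
unmodeled region is the most informative diagnosis).

### Predicted-model fallback

After the experimental pass, any antigen with zero mapped epitopes —
because it has no experimental structure, or because everything fell
below the cutoff — is retried against its predicted (AlphaFold-style)
model. The model's sequence is required to equal the parent sequence;
a mismatching model is skipped with a warning rather than aligned. The
alignment is then the identity (position i ↔ author number i, all
observed), and each matched residue carries the model's per-residue
pLDDT so downstream consumers can judge local reliability. Because the
fallback set is defined at the antigen level, the experimental and
predicted mapped counts are disjoint and the ledger

    total = mapped + unmapped,  mapped = experimental + predicted

holds exactly; this is asserted by tests rather than assumed.

### Structure prioritization

Candidate structures are totally ordered: mapped-epitope count
descending, resolution ascending (absent resolution — NMR, predicted —
sorts after any numeric value), structure ID as the final tie-break.
The display set is the first five (configurable) entries. The two
stated criteria (most epitopes, best resolution) do not come with a
combination rule; lexicographic count-then-resolution was chosen
because epitope coverage is the user-facing goal, with an optional
weighted score `w_count·n − w_res·resolution` exposed for callers who
want a different trade-off. Experimental structures and predicted
models never compete for the same antigen: the predicted route runs
only when the experimental route produced nothing.

## Response-frequency scoring

Per antigen position, the responded/tested counts of every epitope
covering that position are summed (positionwise pooling; the
accumulation is linear over disjoint epitope sets, a property the test
suite checks). The score is the lower bound of the 95% confidence
interval under a normal approximation,

    RF(r, t) = max(0, (r − 1.96·√(r·(1 − r/t))) / t),  RF(r, 0) = 0,

clamped to [0, 1]. The bound never exceeds the raw rate r/t, is 0 at
r = 0 and exactly 1 at r = t (the variance term vanishes). The formula
sits behind a single function so an alternative interval (e.g. Wilson)
could be swapped in.

If every count-contributing record carries the `mhc_ligand` assay-type
tag, the profile is identically zero: MHC binding or elution evidence
alone demonstrates presentation, not a T- or B-cell response. The
pooled counts are still reported so the evidence is not hidden.

Projection onto a structure follows the UniProt position through the
alignment — never the author numbering — and drops unobserved or
unaligned residues. Export uses the B-factor channel (RF×100, two
decimals; atoms of unprojected residues get 0.00) because any generic
viewer can color by B-factor, plus a plain-text per-residue command
list (chain, author number, `#RRGGBB`). The color ramp interpolates
componentwise from white (RF 0) to dark blue `(0, 0, 139)`; light blue
is the emergent midrange, not a pinned third color. The ramp ceiling
defaults to the profile maximum (so the antigen's own hotspot is
saturated); a flag pins it to 1.0 for cross-antigen comparability.

## Synthetic data

The generator builds a self-consistent world from one seeded NumPy
generator: a uniform-random antigen sequence (default length 150); an
experimental Cα-only structure missing one unmodeled gap (default
positions 40–52) with author numbers offset by +24 from the UniProt
positions; the SIFTS XML that encodes exactly that (gap residues
annotated `Not_Observed` with a `null` author number, as the real
resource writes them); a full-coverage predicted model whose B-factors
hold uniform-random pLDDT in [50, 95]; and a catalog of 12 linear plus
3 discontinuous epitopes (lengths 9–15, sites 4–7) with assay counts
drawn Binomial(20, p), where p = 0.8 for epitopes touching the hotspot
(positions 10–35) and 0.1 otherwise. Those response probabilities and
the 20 assays per epitope are the conditions under which hotspot
recovery is evaluated (mean RF over hot positions must exceed the cold
mean in at least 48 of 50 seeds).

The bundle is byte-deterministic per spec, and its JSON manifest is the
ground truth that parser tests compare against (generator–parser
closure). What the generator does **not** emulate: real 3D geometry
(coordinates are a straight chain — sufficient because mapping and
B-factor export are residue-level), multi-chain assemblies, isoform or
chimeric SIFTS segments, sequence divergence between structure and
parent, insertion codes (the parser handles them; a dedicated unit test
covers that path with hand-written XML), and non-uniform assay depth.
Passing tests therefore demonstrate the bookkeeping — numbering
offsets, unmodeled gaps, cutoff semantics, pooling — not robustness to
curation noise in real catalogs.

## Numerical and degenerate-input choices

- Cutoff comparison is `>=` on an exact float ratio of small integers;
  no tolerance is applied.
- Zero-length profiles, empty catalogs, empty alignments and empty
  projections are all valid values, not errors; hard errors are
  reserved for malformed inputs (missing columns, malformed XML,
  accession mismatches, unresolvable projected residues).
- Duplicate structure metadata rows keep the first occurrence;
  duplicate (chain, position) alignment entries likewise.
- All output tables are sorted on explicit keys, so identical inputs
  produce byte-identical outputs.
- The CLI cache keys on a hash of the structure/model set plus the
  cutoff and reuses results per antigen only when that antigen's
  epitope ID list is unchanged; any change remaps the whole antigen,
  because the fallback decision is antigen-level. `--fresh` bypasses
  the cache.

## Problem sizes

Tests and the acceptance script run on bundles of 150-residue antigens
with 15 epitopes (two antigens, 30 epitopes, for the combined ledger),
a 201×t/2 grid (~20k pairs) for the closed-form check, and 50 seeded
simulations for hotspot recovery. These sizes exercise every code path
while keeping the whole suite around a second of runtime.

## Known limitations

- One accession per SIFTS file: isoform segments are ignored with a
  warning rather than modeled.
- The per-epitope unmapped "reason" is a single dominant label; mixed
  failures are summarized, not enumerated.
- RF pooling weights every assay equally; there is no assay-type
  weighting, no smoothing, and no upper confidence bound.
- The mapper does not attempt approximate or gapped placement of an
  epitope whose sequence is absent from the parent; such records are
  reported unlocatable.
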