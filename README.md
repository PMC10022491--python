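# epistruct

Map immune epitopes onto the 3D structures of their source antigens, and
project per-position immunogenicity scores onto those structures for
visualization.

## Who this is for

Immunologists and structural bioinformaticians who hold a catalog of
epitopes — linear peptides or discontinuous residue sets, with positions
stated in the coordinates of a UniProt parent antigen — and want to see
where those epitopes sit on the antigen's experimental structures (or on
a predicted model when no usable experimental structure exists), and
which regions of the antigen are immunogenic hotspots.

## What it does

1. **Catalog handling.** Epitope tables (TSV or JSON) are parsed and
   validated; epitopes containing modified residues (any character
   outside the 20-letter standard alphabet) are excluded, since they
   cannot be matched residue-for-residue against a structure.
2. **Residue-level alignment.** SIFTS-style XML files provide the
   correspondence between UniProt sequence positions and structure
   residues (chain, author number, insertion code), including
   `Not_Observed` annotations for unmodeled regions.
3. **Mapping with a 20% cutoff.** Each epitope is mapped onto every
   chain of every candidate structure. A position matches when the
   aligned residue is observed and its one-letter code equals the
   epitope's. An epitope is kept for a structure only if its mapped
   fraction reaches the cutoff (default 0.20, boundary inclusive);
   below that the placement is considered noninformative.
4. **Predicted-model fallback.** Antigens with no experimental
   structure, or none on which any epitope passed the cutoff, are
   retried against AlphaFold-style models. There the model sequence is
   the UniProt sequence, so an identity alignment applies and every
   matched residue carries the model's per-residue pLDDT confidence.
5. **Structure ranking.** Candidate structures are ordered by number of
   mapped epitopes (descending), then resolution (ascending, absent
   last), then ID; the first five form the display set.
6. **Response-frequency (RF) profiles.** Per antigen position, the
   positive (`responded`) and total (`tested`) assay counts of all
   covering epitopes are pooled, and the score is the conservative
   lower bound of the 95% confidence interval on the response rate:

   RF(r, t) = max(0, (r − 1.96·√(r·(1 − r/t))) / t),  RF(r, 0) = 0.

   If the only evidence is from MHC ligand assays, the whole profile is
   0.0 by rule. Profiles are projected through the alignment into the
   PDB B-factor column (RF×100) and exported as per-residue hex colors
   on a white → dark-blue ramp (white = no immunogenicity).
7. **Synthetic bundles.** `epistruct.fixtures` generates complete,
   internally consistent test worlds: antigen FASTA, an experimental
   structure with an unmodeled gap and an author-numbering offset, the
   matching SIFTS XML, a full-coverage predicted model with pLDDT, and
   an epitope catalog with binomial assay counts concentrated in a
   designated hotspot.

## Worked example

```python
from pathlib import Path
from epistruct.fixtures import FixtureSpec, generate_bundle
from epistruct.catalog import parse_epitope_table
from epistruct.io import read_alphafold_model, read_fasta
from epistruct.mapper import AlphaFoldModel, run_full_mapping
from epistruct.rf import compute_rf_profile, rf_lower_bound
from epistruct.sifts import parse_sifts_xml
from epistruct.structures import build_index

outdir = Path("demo_bundle")
spec = FixtureSpec(seed=11)
manifest = generate_bundle(spec, outdir)

records = parse_epitope_table(outdir / "epitopes.tsv")
index = build_index(outdir / "structures.tsv")
alignment = parse_sifts_xml(outdir / "1XZA.sifts.xml")
parents = read_fasta(outdir / "P00001.fasta")
seq, plddt = read_alphafold_model(outdir / "AF-P00001-F1.pdb")
models = {"P00001": AlphaFoldModel("P00001", seq, tuple(plddt))}

result = run_full_mapping(records, index, {"1XZA": alignment}, parents, models)
print("ledger:", result.ledger())

profile = compute_rf_profile(records, "P00001", parents["P00001"])
print("RF at position 20 (hotspot):", round(profile.rf[19], 3))
print("RF at position 120 (cold):  ", round(profile.rf[119], 3))
print("rf_lower_bound(50, 100) =", rf_lower_bound(50, 100))
```

prints

```
ledger: {'total': 15, 'mapped': 15, 'unmapped': 0, 'mapped_experimental': 15, 'mapped_predicted': 0}
RF at position 20 (hotspot): 0.854
RF at position 120 (cold):   0.007
rf_lower_bound(50, 100) = 0.402
```

All 15 synthetic epitopes map onto the experimental structure despite
its unmodeled gap (positions 40–52) and +24 author-numbering offset, so
the predicted-model route is not needed; the RF profile clearly
separates the hotspot (response probability 0.8) from the cold region
(0.1); and the conservative lower bound for 50 positives in 100 assays
is 0.402 rather than the naive 0.5.

The same pipeline is available from the shell:

```sh
epistruct simulate --seed 11 --out demo_bundle
epistruct map --catalog demo_bundle/epitopes.tsv --structures demo_bundle/structures.tsv \
    --parents demo_bundle/P00001.fasta --sifts-dir demo_bundle \
    --alphafold-dir demo_bundle --out-dir demo_out
epistruct rf --catalog demo_bundle/epitopes.tsv --parents demo_bundle/P00001.fasta \
    --accession P00001 --map-dir demo_out --sifts-dir demo_bundle \
    --pdb-dir demo_bundle --alphafold-dir demo_bundle --out-dir demo_rf
```

`map` writes the epitope-based table (one row per mapped residue), the
structure-centric summary (resolution, covered length, number of
epitopes mapped), the unmapped report with per-epitope reasons, and the
JSON list of accessions lacking structures. `rf` writes the RF table,
colored PDB files for the display set, and per-residue color commands
for a viewer.

## Limitations

Coordinates in synthetic bundles are schematic (Cα chains along an
axis); the mapper is residue-level and does not compute contacts,
interfaces or superpositions — that is the job of the 3D viewer the
outputs are handed to.
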