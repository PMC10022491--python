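"""Synthetic antigen/structure/catalog bundles for testing and simulation.

The generator emulates the data constellation the mapping pipeline
consumes in production: a parent antigen sequence (FASTA), one
experimental structure of it with an unmodeled gap and an author-
numbering offset (Cα-only PDB), the matching residue-level alignment
XML (gap residues annotated ``Not_Observed`` with a ``null`` author
number, exactly as the real resource writes them), a full-coverage
predicted model carrying synthetic pLDDT in the B-factor column, and an
epitope catalog whose assay counts are binomial draws — epitopes
overlapping a designated hotspot respond with probability ``p_hot``,
the rest with ``p_cold``.

Everything is drawn from one seeded generator in a fixed order, so a
given spec always produces byte-identical files. The JSON manifest
records the ground truth (sequence, alignment entries, pLDDT, epitope
placements), making the generator the oracle for parser round-trip
tests. What it does NOT emulate: realistic 3D geometry (coordinates are
a straight chain), multi-chain assemblies, isoform mappings, and
sequence divergence between structure and parent.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator

from epistruct.catalog import STANDARD_AA, DiscontinuousSite, EpitopeRecord, write_epitope_table

AA_ORDER = "".join(sorted(STANDARD_AA))

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

Interval = tuple[int, int]


class FixtureSpec(BaseModel):
    """Parameters of one synthetic bundle.

    Defaults describe a mid-sized antigen with one disordered loop
    (positions 40–52 missing from the experimental structure), a +24
    author-numbering offset, one immunogenic hotspot at 10–35, and a
    catalog of 12 linear plus 3 discontinuous epitopes assayed 20 times
    each (response probability 0.8 inside the hotspot, 0.1 outside).
    """

    seed: int = 0
    accession: str = "P00001"
    structure_id: str = "1XZA"
    antigen_length: int = Field(default=150, ge=20)
    gap_ranges: tuple[Interval, ...] = ((40, 52),)
    author_offset: int = 24
    n_linear_epitopes: int = Field(default=12, ge=0)
    n_discontinuous_epitopes: int = Field(default=3, ge=0)
    epitope_length_range: Interval = (9, 15)
    hotspot_ranges: tuple[Interval, ...] = ((10, 35),)
    p_hot: float = Field(default=0.8, ge=0, le=1)
    p_cold: float = Field(default=0.1, ge=0, le=1)
    assays_per_epitope: int = Field(default=20, ge=1)
    resolution: float = Field(default=2.0, gt=0)
    assay_type: str = "t_cell"

    @model_validator(mode="after")
    def _check(self) -> "FixtureSpec":
        lo, hi = self.epitope_length_range
        if not (1 <= lo <= hi):
            raise ValueError("epitope_length_range must satisfy 1 <= lo <= hi")
        if hi > self.antigen_length:
            raise ValueError("epitope longer than antigen")
        for a, b in self.gap_ranges + self.hotspot_ranges:
            if not (1 <= a <= b <= self.antigen_length):
                raise ValueError(f"interval ({a},{b}) outside [1,{self.antigen_length}]")
        if self.p_cold > self.p_hot:
            raise ValueError("p_cold must not exceed p_hot")
        return self

    def gap_positions(self) -> set[int]:
        return {p for a, b in self.gap_ranges for p in range(a, b + 1)}

    def hotspot_positions(self) -> set[int]:
        return {p for a, b in self.hotspot_ranges for p in range(a, b + 1)}

    @property
    def model_id(self) -> str:
        return f"AF-{self.accession}-F1"


def simulate_catalog(
    spec: FixtureSpec,
) -> tuple[str, list[EpitopeRecord], dict]:
    """Draw the parent sequence and epitope catalog for a spec.

    Returns (parent sequence, records, ground truth). An epitope's
    per-assay response probability is ``p_hot`` when its span touches a
    hotspot, else ``p_cold``; responded counts are binomial draws at
    ``assays_per_epitope`` trials.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.antigen_length
    parent = "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=L))
    hot = spec.hotspot_positions()

    records: list[EpitopeRecord] = []
    truth: dict = {"epitopes": {}}
    lo, hi = spec.epitope_length_range
    for i in range(spec.n_linear_epitopes):
        n = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(1, L - n + 2))
        span = list(range(start, start + n))
        p = spec.p_hot if any(pos in hot for pos in span) else spec.p_cold
        responded = int(rng.binomial(spec.assays_per_epitope, p))
        eid = f"L{i + 1:03d}"
        records.append(
            EpitopeRecord(
                epitope_id=eid,
                classification="linear",
                sequence=parent[start - 1 : start - 1 + n],
                parent_accession=spec.accession,
                start_position=start,
                responded=responded,
                tested=spec.assays_per_epitope,
                assay_type=spec.assay_type,
            )
        )
        truth["epitopes"][eid] = {"positions": span, "p": p, "responded": responded}
    for i in range(spec.n_discontinuous_epitopes):
        k = int(rng.integers(4, 8))
        positions = sorted(int(p) + 1 for p in rng.choice(L, size=k, replace=False))
        p = spec.p_hot if any(pos in hot for pos in positions) else spec.p_cold
        responded = int(rng.binomial(spec.assays_per_epitope, p))
        eid = f"D{i + 1:03d}"
        records.append(
            EpitopeRecord(
                epitope_id=eid,
                classification="discontinuous",
                sites=tuple(
                    DiscontinuousSite(residue=parent[pos - 1], position=pos)
                    for pos in positions
                ),
                parent_accession=spec.accession,
                responded=responded,
                tested=spec.assays_per_epitope,
                assay_type=spec.assay_type,
            )
        )
        truth["epitopes"][eid] = {"positions": positions, "p": p, "responded": responded}

    plddt = [round(float(v), 2) for v in rng.uniform(50.0, 95.0, size=L)]
    truth["plddt"] = plddt
    return parent, records, truth


def _write_fasta(accession: str, sequence: str, path: Path) -> None:
    lines = [f">{accession}"]
    for i in range(0, len(sequence), 60):
        lines.append(sequence[i : i + 60])
    path.write_text("\n".join(lines) + "\n")


def _ca_line(serial: int, resname: str, chain: str, resnum: int, x: float, b: float) -> str:
    return (
        f"ATOM  {serial:5d}  CA  {resname} {chain}{resnum:4d}    "
        f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{b:6.2f}           C"
    )


def _write_ca_pdb(
    sequence: str,
    path: Path,
    chain: str,
    numbers: list[int],
    keep: list[int],
    bfactors: list[float],
) -> None:
    """Cα-only chain along the x axis; ``keep`` are the 1-based kept positions."""
    lines = []
    serial = 0
    for pos in keep:
        serial += 1
        lines.append(
            _ca_line(
                serial,
                THREE_LETTER[sequence[pos - 1]],
                chain,
                numbers[pos - 1],
                3.8 * (pos - 1),
                bfactors[pos - 1],
            )
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _write_sifts_xml(spec: FixtureSpec, sequence: str, path: Path) -> None:
    gaps = spec.gap_positions()
    L = spec.antigen_length
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<entry xmlns="http://www.ebi.ac.uk/pdbe/docs/sifts/eFamily.xsd" '
        f'dbSource="PDBe" dbAccessionId="{spec.structure_id}">',
        '  <entity type="protein" entityId="A">',
        f'    <segment segId="{spec.structure_id}_A_1_{L}" start="1" end="{L}">',
        "      <listResidue>",
    ]
    for pos in range(1, L + 1):
        aa = sequence[pos - 1]
        three = THREE_LETTER[aa]
        author = "null" if pos in gaps else str(pos + spec.author_offset)
        out.append(
            f'        <residue dbSource="PDBe" dbCoordSys="PDBe" dbResNum="{pos}" dbResName="{three}">'
        )
        out.append(
            f'          <crossRefDb dbSource="PDB" dbCoordSys="PDBresnum" '
            f'dbAccessionId="{spec.structure_id}" dbResNum="{author}" '
            f'dbResName="{three}" dbChainId="A"/>'
        )
        out.append(
            f'          <crossRefDb dbSource="UniProt" dbCoordSys="UniProt" '
            f'dbAccessionId="{spec.accession}" dbResNum="{pos}" dbResName="{aa}"/>'
        )
        if pos in gaps:
            out.append(
                '          <residueDetail dbSource="PDBe" property="Annotation">Not_Observed</residueDetail>'
            )
        out.append("        </residue>")
    out += ["      </listResidue>", "    </segment>", "  </entity>", "</entry>"]
    path.write_text("\n".join(out) + "\n")


def generate_bundle(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write a complete, internally consistent bundle; return its manifest.

    Files: ``<accession>.fasta``, ``<structure_id>.pdb`` (experimental,
    gap omitted, author numbers offset), ``<structure_id>.sifts.xml``,
    ``AF-<accession>-F1.pdb`` (full coverage, pLDDT B-factors),
    ``epitopes.tsv``, ``structures.tsv`` and ``manifest.json``.
    Deterministic per spec: the same spec yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    parent, records, truth = simulate_catalog(spec)
    L = spec.antigen_length
    gaps = spec.gap_positions()
    kept = [p for p in range(1, L + 1) if p not in gaps]

    files = {
        "fasta": f"{spec.accession}.fasta",
        "pdb": f"{spec.structure_id}.pdb",
        "sifts": f"{spec.structure_id}.sifts.xml",
        "alphafold": f"{spec.model_id}.pdb",
        "epitopes": "epitopes.tsv",
        "structures": "structures.tsv",
        "manifest": "manifest.json",
    }

    _write_fasta(spec.accession, parent, outdir / files["fasta"])
    _write_ca_pdb(
        parent,
        outdir / files["pdb"],
        chain="A",
        numbers=[p + spec.author_offset for p in range(1, L + 1)],
        keep=kept,
        bfactors=[0.0] * L,
    )
    _write_sifts_xml(spec, parent, outdir / files["sifts"])
    _write_ca_pdb(
        parent,
        outdir / files["alphafold"],
        chain="A",
        numbers=list(range(1, L + 1)),
        keep=list(range(1, L + 1)),
        bfactors=truth["plddt"],
    )
    write_epitope_table(records, outdir / files["epitopes"])
    with open(outdir / files["structures"], "w") as fh:
        fh.write("structure_id\taccession\tresolution\tcovered_length\tsource\n")
        fh.write(
            f"{spec.structure_id}\t{spec.accession}\t{spec.resolution:.2f}\t{len(kept)}\texperimental\n"
        )
        fh.write(f"{spec.model_id}\t{spec.accession}\t\t{L}\tpredicted\n")

    alignment_truth = [
        {
            "chain": "A",
            "uniprot_position": pos,
            "author_number": None if pos in gaps else pos + spec.author_offset,
            "insertion_code": "",
            "one_letter": parent[pos - 1],
            "observed": pos not in gaps,
        }
        for pos in range(1, L + 1)
    ]
    manifest = {
        "spec": json.loads(spec.model_dump_json()),
        "accession": spec.accession,
        "parent_sequence": parent,
        "files": files,
        "alignment": alignment_truth,
        "plddt": truth["plddt"],
        "epitopes": truth["epitopes"],
        "gap_positions": sorted(gaps),
        "hotspot_positions": sorted(spec.hotspot_positions()),
    }
    with open(outdir / files["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
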