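"""Small readers for the standard formats the pipeline consumes."""

from __future__ import annotations

from pathlib import Path

import gemmi
from Bio import SeqIO


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read parent antigen sequences; keys are the raw FASTA record ids."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_alphafold_model(path: str | Path) -> tuple[str, list[float]]:
    """Extract (sequence, per-residue pLDDT) from an AlphaFold-style PDB file.

    pLDDT lives in the B-factor column, identical for all atoms of a
    residue; the Cα value is taken (first atom as fallback).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    sequence: list[str] = []
    plddt: list[float] = []
    model = st[0]
    chain = model[0]
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        one = info.one_letter_code.upper() if info else "X"
        sequence.append(one if one.isalpha() else "X")
        ca = res.find_atom("CA", "*")
        atom = ca if ca is not None else res[0]
        plddt.append(atom.b_iso)
    return "".join(sequence), plddt
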