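"""Residue-level UniProt↔structure alignments from SIFTS-style XML.

SIFTS publishes, per PDB entry, one XML file whose ``<residue>``
elements cross-reference each deposited residue to its PDB identity
(chain, author number, possibly an insertion code) and to its UniProt
sequence position. Residues present in the construct but without
coordinates are annotated ``Not_Observed``; these are retained here with
``observed=False`` so callers can distinguish an unmodeled region from a
missing mapping. The alignment is keyed by (chain, UniProt position) —
the antigen coordinate system epitopes are stated in — and exposes the
author numbering that viewers and PDB files use.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from lxml import etree

log = logging.getLogger(__name__)

_AUTHOR_RE = re.compile(r"^(-?\d+)([A-Za-z]?)$")


@dataclass(frozen=True)
class StructureResidue:
    """One structure residue as addressed in the deposited file.

    ``author_number`` is ``None`` only for unobserved residues that the
    alignment leaves unnumbered (SIFTS writes ``null`` for them).
    """

    chain_id: str
    author_number: Optional[int]
    insertion_code: str = ""
    one_letter: str = "X"
    observed: bool = True

    def author_label(self) -> str:
        """Author number + insertion code as printed in PDB files, e.g. ``100A``."""
        if self.author_number is None:
            return ""
        return f"{self.author_number}{self.insertion_code}"


@dataclass
class ResidueAlignment:
    """Map from (chain, UniProt position) to the structure residue there."""

    structure_id: str
    accession: str
    entries: dict[tuple[str, int], StructureResidue] = field(default_factory=dict)
    skipped: int = 0  # residues without a UniProt cross-reference

    def lookup(self, chain_id: str, uniprot_position: int) -> Optional[StructureResidue]:
        return self.entries.get((chain_id, uniprot_position))

    def chains(self) -> list[str]:
        return sorted({chain for chain, _ in self.entries})

    def positions(self, chain_id: str) -> list[int]:
        return sorted(pos for chain, pos in self.entries if chain == chain_id)


def lookup(
    alignment: ResidueAlignment, chain_id: str, uniprot_position: int
) -> Optional[StructureResidue]:
    """Pure lookup; absent entries return ``None`` (caller decides on observed flag)."""
    return alignment.lookup(chain_id, uniprot_position)


def _parse_author_number(text: str) -> tuple[Optional[int], str]:
    text = text.strip()
    if not text or text.lower() in {"null", "none"}:
        return None, ""
    m = _AUTHOR_RE.match(text)
    if m is None:
        raise ValueError(f"unparseable author residue number {text!r}")
    return int(m.group(1)), m.group(2)


def parse_sifts_xml(path: str | Path, structure_id: Optional[str] = None) -> ResidueAlignment:
    """Parse a SIFTS residue-level XML file (plain or gzip) into an alignment.

    Every ``<residue>`` carrying a UniProt cross-reference yields one
    entry; residues without one are skipped and counted. Only the first
    UniProt accession encountered is used — segments mapped to other
    accessions (isoforms, chimeras) are ignored with a warning.
    Malformed XML and a file with no UniProt accession at all are hard
    errors.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rb") as fh:
        tree = etree.parse(fh)
    root = tree.getroot()
    if structure_id is None:
        structure_id = root.get("dbAccessionId") or path.stem.split(".")[0]

    accession: Optional[str] = None
    entries: dict[tuple[str, int], StructureResidue] = {}
    skipped = 0
    foreign: set[str] = set()

    for residue in root.iter("{*}residue"):
        pdb_ref = None
        uni_ref = None
        not_observed = False
        for child in residue:
            tag = etree.QName(child).localname
            if tag == "crossRefDb":
                src = child.get("dbSource")
                if src == "PDB":
                    pdb_ref = child
                elif src == "UniProt":
                    uni_ref = child
            elif tag == "residueDetail":
                if child.get("property") == "Annotation" and (child.text or "").strip() == "Not_Observed":
                    not_observed = True
        if uni_ref is None:
            skipped += 1
            continue
        acc = uni_ref.get("dbAccessionId")
        if accession is None:
            accession = acc
        elif acc != accession:
            foreign.add(acc)
            continue
        uni_pos = int(uni_ref.get("dbResNum"))
        one_letter = (uni_ref.get("dbResName") or "X").upper()
        if pdb_ref is not None:
            chain = pdb_ref.get("dbChainId") or "A"
            author, icode = _parse_author_number(pdb_ref.get("dbResNum") or "")
        else:
            chain, author, icode = "A", None, ""
        key = (chain, uni_pos)
        if key in entries:
            log.warning("%s: duplicate mapping for chain %s position %d ignored", structure_id, chain, uni_pos)
            continue
        entries[key] = StructureResidue(
            chain_id=chain,
            author_number=author,
            insertion_code=icode,
            one_letter=one_letter,
            observed=not not_observed and author is not None,
        )

    if accession is None:
        raise ValueError(f"{path}: no UniProt accession found in SIFTS file")
    if foreign:
        log.warning("%s: ignored segments mapped to other accessions: %s", structure_id, sorted(foreign))
    return ResidueAlignment(structure_id=structure_id, accession=accession, entries=entries, skipped=skipped)


def alignment_from_identity(
    accession: str,
    sequence: str,
    chain_id: str = "A",
    structure_id: Optional[str] = None,
) -> ResidueAlignment:
    """Identity alignment for predicted models whose sequence IS the UniProt sequence.

    Position *i* maps to author number *i* on one chain, all observed.
    This is the AlphaFold case, where no renumbering or unmodeled-region
    bookkeeping is needed.
    """
    if not sequence:
        raise ValueError("alignment_from_identity requires a non-empty sequence")
    sid = structure_id or f"AF-{accession}-F1"
    entries = {
        (chain_id, i): StructureResidue(
            chain_id=chain_id, author_number=i, one_letter=aa, observed=True
        )
        for i, aa in enumerate(sequence, start=1)
    }
    return ResidueAlignment(structure_id=sid, accession=accession, entries=entries)
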