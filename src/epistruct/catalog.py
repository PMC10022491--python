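"""Epitope catalog: parsing, validation and filtering of epitope records.

An epitope record describes either a linear peptide (a contiguous
substring of its parent antigen) or a discontinuous epitope (a set of
individual residues brought together in 3D). Positions are always
1-based UniProt coordinates of the parent antigen. Records may carry
assay counts (``responded`` positives out of ``tested`` assays) used
downstream for response-frequency scoring, and an optional assay-type
tag (``t_cell``, ``b_cell``, ``mhc_ligand``).
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

log = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes. Anything outside this
#: alphabet in an epitope description is treated as a modification marker
#: (phosphorylation, citrullination, adducts, lowercase annotations ...).
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Assay-type tag that contributes no response-frequency evidence.
MHC_LIGAND = "mhc_ligand"

LINEAR = "linear"
DISCONTINUOUS = "discontinuous"

REQUIRED_COLUMNS = (
    "epitope_id",
    "classification",
    "sequence_or_descriptor",
    "parent_accession",
)
OPTIONAL_COLUMNS = ("start_position", "responded", "tested", "assay_type")

_SITE_RE = re.compile(r"^(?:[A-Za-z]:)?([A-Z])(\d+)$")


class DiscontinuousSite(BaseModel):
    """One residue of a discontinuous epitope: one-letter code + UniProt position."""

    model_config = {"frozen": True}

    residue: str
    position: int = Field(ge=1)

    @field_validator("residue")
    @classmethod
    def _standard_residue(cls, v: str) -> str:
        if v not in STANDARD_AA:
            raise ValueError(f"residue {v!r} is not a standard amino acid")
        return v


class EpitopeRecord(BaseModel):
    """A single catalog entry.

    Linear records carry a non-empty ``sequence`` and no ``sites``;
    discontinuous records carry ``sites`` and an empty sequence. The
    sequence of a linear record is deliberately not restricted to the
    standard alphabet here: modified epitopes must survive parsing so
    that :func:`filter_modified_epitopes` can report them.
    """

    epitope_id: str
    classification: Literal["linear", "discontinuous"]
    sequence: str = ""
    parent_accession: str
    start_position: Optional[int] = Field(default=None, ge=1)
    sites: tuple[DiscontinuousSite, ...] = ()
    responded: Optional[int] = Field(default=None, ge=0)
    tested: Optional[int] = Field(default=None, ge=0)
    assay_type: Optional[str] = None

    @model_validator(mode="after")
    def _check_shape(self) -> "EpitopeRecord":
        if self.classification == LINEAR:
            if not self.sequence:
                raise ValueError("linear epitope requires a non-empty sequence")
            if self.sites:
                raise ValueError("linear epitope must not carry discontinuous sites")
        else:
            if not self.sites:
                raise ValueError("discontinuous epitope requires at least one site")
        if self.responded is not None and self.tested is not None:
            if self.responded > self.tested:
                raise ValueError(
                    f"responded ({self.responded}) exceeds tested ({self.tested})"
                )
        return self

    @property
    def length(self) -> int:
        return len(self.sequence) if self.classification == LINEAR else len(self.sites)

    def descriptor(self) -> str:
        """Round-trippable text form of the epitope description."""
        if self.classification == LINEAR:
            return self.sequence
        return ", ".join(f"{s.residue}{s.position}" for s in self.sites)


def parse_discontinuous_descriptor(text: str) -> list[DiscontinuousSite]:
    """Parse a discontinuous-epitope descriptor like ``"R17, K20, D21"``.

    Each token is ``<residue><position>`` with an optional ``chain:``
    prefix that is ignored. Sites are returned in ascending position
    order with exact duplicates collapsed.

    Raises
    ------
    ValueError
        On a malformed token, or when two tokens assign different
        residues to the same position.
    """
    sites: dict[int, DiscontinuousSite] = {}
    for token in text.split(","):
        token = token.strip()
        if not token:
            raise ValueError(f"malformed discontinuous token {token!r} in {text!r}")
        m = _SITE_RE.match(token)
        if m is None:
            raise ValueError(f"malformed discontinuous token {token!r} in {text!r}")
        site = DiscontinuousSite(residue=m.group(1), position=int(m.group(2)))
        prev = sites.get(site.position)
        if prev is not None and prev.residue != site.residue:
            raise ValueError(
                f"conflicting residues {prev.residue}/{site.residue} "
                f"at position {site.position} in {text!r}"
            )
        sites[site.position] = site
    return [sites[p] for p in sorted(sites)]


def _opt_int(value) -> Optional[int]:
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.lower() in {"nan", "none"}:
        return None
    return int(float(s))


def _record_from_row(row: dict) -> EpitopeRecord:
    classification = str(row["classification"]).strip().lower()
    desc = str(row["sequence_or_descriptor"]).strip()
    sites: tuple[DiscontinuousSite, ...] = ()
    sequence = ""
    if classification == DISCONTINUOUS:
        sites = tuple(parse_discontinuous_descriptor(desc))
    else:
        sequence = desc
    assay = row.get("assay_type")
    assay = str(assay).strip() if assay is not None and str(assay).strip() else None
    return EpitopeRecord(
        epitope_id=str(row["epitope_id"]).strip(),
        classification=classification,  # type: ignore[arg-type]
        sequence=sequence,
        parent_accession=str(row["parent_accession"]).strip(),
        start_position=_opt_int(row.get("start_position")),
        sites=sites,
        responded=_opt_int(row.get("responded")),
        tested=_opt_int(row.get("tested")),
        assay_type=assay,
    )


def parse_epitope_table(path: str | Path) -> list[EpitopeRecord]:
    """Read an epitope catalog from TSV (or a JSON array of objects).

    Required columns: ``epitope_id``, ``classification``,
    ``sequence_or_descriptor``, ``parent_accession``. Optional:
    ``start_position``, ``responded``, ``tested``, ``assay_type``.
    Rows that fail validation are reported with their row number and
    skipped; input order is preserved. A missing required column is a
    hard error.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw_rows = json.loads(path.read_text())
        if not isinstance(raw_rows, list):
            raise ValueError(f"{path}: JSON catalog must be an array of objects")
        rows = [dict(r) for r in raw_rows]
        present = set().union(*(r.keys() for r in rows)) if rows else set(REQUIRED_COLUMNS)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        present = set(frame.columns)
        rows = frame.to_dict(orient="records")
    for col in REQUIRED_COLUMNS:
        if col not in present:
            raise ValueError(f"{path}: missing required column {col!r}")

    records: list[EpitopeRecord] = []
    for i, row in enumerate(rows, start=2 if path.suffix.lower() != ".json" else 1):
        try:
            records.append(_record_from_row(row))
        except (ValueError, ValidationError, KeyError) as exc:
            log.warning("%s row %d skipped: %s", path.name, i, exc)
    return records


def write_epitope_table(records: list[EpitopeRecord], path: str | Path) -> None:
    """Write records back to the tabular format read by :func:`parse_epitope_table`."""
    frame = pd.DataFrame(
        {
            "epitope_id": [r.epitope_id for r in records],
            "classification": [r.classification for r in records],
            "sequence_or_descriptor": [r.descriptor() for r in records],
            "parent_accession": [r.parent_accession for r in records],
            "start_position": ["" if r.start_position is None else r.start_position for r in records],
            "responded": ["" if r.responded is None else r.responded for r in records],
            "tested": ["" if r.tested is None else r.tested for r in records],
            "assay_type": ["" if r.assay_type is None else r.assay_type for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def filter_modified_epitopes(
    records: list[EpitopeRecord],
) -> tuple[list[EpitopeRecord], list[EpitopeRecord]]:
    """Partition records into (kept, removed) by the modified-residue rule.

    Any record whose description contains a character outside the
    20-letter standard alphabet — lowercase annotations, ``(p)``-style
    modification markers, ``+`` adducts — is removed: such epitopes
    cannot be matched residue-for-residue against a structure.
    The partition conserves records: ``kept + removed == input``.
    """
    kept: list[EpitopeRecord] = []
    removed: list[EpitopeRecord] = []
    for rec in records:
        if rec.classification == LINEAR:
            modified = any(ch not in STANDARD_AA for ch in rec.sequence)
        else:
            # sites are validated to the standard alphabet at construction
            modified = any(s.residue not in STANDARD_AA for s in rec.sites)
        (removed if modified else kept).append(rec)
    return kept, removed


def locate_in_parent(record: EpitopeRecord, parent_seq: str) -> Optional[list[int]]:
    """Resolve a linear epitope to 1-based positions in its parent sequence.

    A stated ``start_position`` is verified against the parent substring;
    on mismatch (or when absent) an exact substring search is performed,
    taking the first occurrence. Returns ``None`` when the epitope does
    not occur in the parent at all.
    """
    if record.classification != LINEAR:
        raise ValueError("locate_in_parent applies to linear epitopes only")
    seq = record.sequence
    n = len(seq)
    if record.start_position is not None:
        start = record.start_position
        if parent_seq[start - 1 : start - 1 + n] == seq:
            return list(range(start, start + n))
        log.warning(
            "epitope %s: stated position %d does not match parent; "
            "falling back to substring search",
            record.epitope_id,
            start,
        )
    idx = parent_seq.find(seq)
    if idx < 0:
        log.warning("epitope %s: sequence not found in parent", record.epitope_id)
        return None
    if parent_seq.find(seq, idx + 1) >= 0:
        log.warning(
            "epitope %s: multiple occurrences in parent; using first at %d",
            record.epitope_id,
            idx + 1,
        )
    return list(range(idx + 1, idx + 1 + n))
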