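"""Per-antigen structure metadata and the experimental/predicted partition."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field

log = logging.getLogger(__name__)

EXPERIMENTAL = "experimental"
PREDICTED = "predicted"

COLUMNS = ("structure_id", "accession", "resolution", "covered_length", "source")


class StructureMeta(BaseModel):
    """Metadata for one candidate structure of an antigen.

    ``resolution`` is in Å and absent for NMR entries and predicted
    models; ``covered_length`` counts antigen residues with coordinates.
    """

    model_config = {"frozen": True}

    structure_id: str
    accession: str
    resolution: Optional[float] = Field(default=None, gt=0)
    covered_length: int = Field(ge=1)
    source: Literal["experimental", "predicted"]


def build_index(metadata: str | Path | pd.DataFrame) -> dict[str, list[StructureMeta]]:
    """Group structure metadata rows by accession.

    Accepts a TSV path (columns ``structure_id``, ``accession``,
    ``resolution`` — may be blank —, ``covered_length``, ``source``) or
    an equivalent DataFrame. Row order is preserved within each
    accession. A duplicate ``(structure_id, accession)`` pair is dropped
    with a warning (first wins); an unknown ``source`` string is a hard
    error.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata, sep="\t", dtype=str, keep_default_na=False)
    for col in COLUMNS:
        if col not in metadata.columns:
            raise ValueError(f"structure metadata: missing required column {col!r}")

    index: dict[str, list[StructureMeta]] = {}
    seen: set[tuple[str, str]] = set()
    for row in metadata.to_dict(orient="records"):
        res = str(row["resolution"]).strip()
        meta = StructureMeta(
            structure_id=str(row["structure_id"]).strip(),
            accession=str(row["accession"]).strip(),
            resolution=float(res) if res else None,
            covered_length=int(float(row["covered_length"])),
            source=str(row["source"]).strip(),  # type: ignore[arg-type]
        )
        key = (meta.structure_id, meta.accession)
        if key in seen:
            log.warning("duplicate structure row %s for %s ignored", *key)
            continue
        seen.add(key)
        index.setdefault(meta.accession, []).append(meta)
    return index


def partition_antigens(
    index: dict[str, list[StructureMeta]], accessions: list[str]
) -> tuple[list[str], list[str]]:
    """Split accessions into (with experimental structures, fallback).

    The fallback list holds accessions with zero experimental entries —
    these are the ones sent to the predicted-model (AlphaFold) route.
    The two lists are disjoint and jointly cover the input, preserving
    input order.
    """
    with_experimental: list[str] = []
    fallback: list[str] = []
    for acc in accessions:
        entries = index.get(acc, [])
        if any(m.source == EXPERIMENTAL for m in entries):
            with_experimental.append(acc)
        else:
            fallback.append(acc)
    return with_experimental, fallback


def write_no_structure_json(accessions: list[str], path: str | Path) -> None:
    """Write the sorted, de-duplicated accession list as a JSON array."""
    Path(path).write_text(json.dumps(sorted(set(accessions))) + "\n")
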