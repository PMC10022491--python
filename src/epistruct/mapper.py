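"""Core epitope→structure mapping.

Each epitope is mapped onto every chain of every candidate structure of
its parent antigen. A position counts as matched when the residue-level
alignment places an *observed* structure residue there whose one-letter
code equals the epitope's letter; otherwise the failure reason is
recorded (``no_mapping``, ``not_observed`` or ``identity_mismatch``).
The mapped fraction — matched positions over epitope length — is a
combined coverage/identity criterion: an epitope is kept for a structure
only if at least one chain reaches the cutoff (20% by default; an
epitope landing on a low-identity or unmodeled region is considered
noninformative and excluded).

Antigens for which no epitope passes on any experimental structure
(including antigens with no experimental structure at all) are forwarded
to the predicted-model route, where an identity alignment is used and
each matched residue additionally carries the model's pLDDT confidence.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from epistruct.catalog import LINEAR, EpitopeRecord, locate_in_parent
from epistruct.sifts import ResidueAlignment, StructureResidue, alignment_from_identity
from epistruct.structures import EXPERIMENTAL, StructureMeta

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.20

# per-residue failure reasons
NO_MAPPING = "no_mapping"
NOT_OBSERVED = "not_observed"
IDENTITY_MISMATCH = "identity_mismatch"

# per-epitope failure reasons
NO_STRUCTURE = "no_structure"
UNLOCATABLE = "unlocatable"

_REASON_PRIORITY = (NOT_OBSERVED, IDENTITY_MISMATCH, NO_MAPPING)


@dataclass(frozen=True)
class MatchedResidue:
    uniprot_position: int
    residue: StructureResidue
    plddt: Optional[float] = None


@dataclass
class EpitopeChainMapping:
    """Result of mapping one epitope onto one chain of one structure."""

    epitope_id: str
    structure_id: str
    chain_id: str
    matched: list[MatchedResidue]
    unmatched: list[tuple[int, str]]  # (uniprot position, reason)

    @property
    def epitope_length(self) -> int:
        return len(self.matched) + len(self.unmatched)

    @property
    def mapped_fraction(self) -> float:
        n = self.epitope_length
        return len(self.matched) / n if n else 0.0


@dataclass
class StructureSummary:
    """Structure-centric aggregate used for ranking and the PDB-centric output."""

    structure_id: str
    resolution: Optional[float]
    covered_length: int
    n_epitopes_mapped: int = 0
    accession: str = ""
    source: str = EXPERIMENTAL


@dataclass(frozen=True)
class UnmappedEpitope:
    epitope_id: str
    accession: str
    reason: str


@dataclass
class MappingResult:
    """Aggregate of one mapping pass over a catalog."""

    chain_mappings: list[EpitopeChainMapping] = field(default_factory=list)
    summaries: list[StructureSummary] = field(default_factory=list)
    unmapped: list[UnmappedEpitope] = field(default_factory=list)
    fallback_accessions: list[str] = field(default_factory=list)

    @property
    def mapped_epitope_ids(self) -> set[str]:
        return {m.epitope_id for m in self.chain_mappings}


def map_epitope_to_chain(
    record: EpitopeRecord,
    positions: list[int],
    letters: list[str],
    alignment: ResidueAlignment,
    chain_id: str,
    plddt: Optional[list[float]] = None,
) -> EpitopeChainMapping:
    """Match each epitope position against one chain of an alignment.

    ``positions`` and ``letters`` are parallel (from
    :func:`~epistruct.catalog.locate_in_parent` for linear epitopes,
    from the sites for discontinuous ones). When ``plddt`` is given
    (indexed by UniProt position − 1), matched residues carry their
    confidence value. Pure function.
    """
    if len(positions) != len(letters):
        raise ValueError("positions and letters must have equal length")
    matched: list[MatchedResidue] = []
    unmatched: list[tuple[int, str]] = []
    for pos, letter in zip(positions, letters):
        res = alignment.lookup(chain_id, pos)
        if res is None:
            unmatched.append((pos, NO_MAPPING))
        elif not res.observed:
            unmatched.append((pos, NOT_OBSERVED))
        elif res.one_letter != letter:
            unmatched.append((pos, IDENTITY_MISMATCH))
        else:
            conf = None
            if plddt is not None and 0 <= pos - 1 < len(plddt):
                conf = plddt[pos - 1]
            matched.append(MatchedResidue(uniprot_position=pos, residue=res, plddt=conf))
    return EpitopeChainMapping(
        epitope_id=record.epitope_id,
        structure_id=alignment.structure_id,
        chain_id=chain_id,
        matched=matched,
        unmatched=unmatched,
    )


def passes_cutoff(mapping: EpitopeChainMapping, threshold: float = DEFAULT_CUTOFF) -> bool:
    """True iff the mapped fraction reaches the cutoff (exactly 20% is retained)."""
    return mapping.mapped_fraction >= threshold


def resolve_epitope_positions(
    record: EpitopeRecord, parent_seq: Optional[str]
) -> Optional[tuple[list[int], list[str]]]:
    """Epitope description → parallel (positions, letters), or None if unlocatable."""
    if record.classification == LINEAR:
        if parent_seq is None:
            return None
        positions = locate_in_parent(record, parent_seq)
        if positions is None:
            return None
        return positions, list(record.sequence)
    positions = [s.position for s in record.sites]
    letters = [s.residue for s in record.sites]
    return positions, letters


def _dominant_reason(best: Optional[EpitopeChainMapping]) -> str:
    if best is None or not best.unmatched:
        return NO_MAPPING
    counts = Counter(reason for _, reason in best.unmatched)
    top = max(counts.values())
    for reason in _REASON_PRIORITY:
        if counts.get(reason) == top:
            return reason
    return counts.most_common(1)[0][0]


def map_catalog(
    records: list[EpitopeRecord],
    index: dict[str, list[StructureMeta]],
    alignments: dict[str, ResidueAlignment],
    parents: dict[str, str],
    threshold: float = DEFAULT_CUTOFF,
) -> MappingResult:
    """Map a catalog onto the experimental structures of each parent antigen.

    Per epitope × candidate structure, every chain is tried; an epitope
    counts as mapped to a structure iff at least one chain passes the
    cutoff (the structure-level count counts the epitope once, but one
    output row is kept per passing chain). Degeneracies never raise:
    unmapped epitopes are reported with the dominant per-residue failure
    reason of their best-scoring chain. Accessions with zero mapped
    epitopes — whether for lack of experimental structures or because
    everything fell below the cutoff — are returned as the
    predicted-model fallback set.
    """
    result = MappingResult()
    summaries: dict[str, StructureSummary] = {}
    mapped_per_structure: dict[str, set[str]] = {}
    acc_order: list[str] = []
    acc_mapped: dict[str, int] = {}

    for record in records:
        acc = record.parent_accession
        if acc not in acc_mapped:
            acc_order.append(acc)
            acc_mapped[acc] = 0
        candidates = [m for m in index.get(acc, []) if m.source == EXPERIMENTAL]
        if not candidates:
            result.unmapped.append(UnmappedEpitope(record.epitope_id, acc, NO_STRUCTURE))
            continue
        resolved = resolve_epitope_positions(record, parents.get(acc))
        if resolved is None:
            result.unmapped.append(UnmappedEpitope(record.epitope_id, acc, UNLOCATABLE))
            continue
        positions, letters = resolved

        passing: list[EpitopeChainMapping] = []
        best: Optional[EpitopeChainMapping] = None
        for meta in candidates:
            alignment = alignments.get(meta.structure_id)
            if alignment is None:
                log.warning("no alignment available for structure %s; skipped", meta.structure_id)
                continue
            if meta.structure_id not in summaries:
                summaries[meta.structure_id] = StructureSummary(
                    structure_id=meta.structure_id,
                    resolution=meta.resolution,
                    covered_length=meta.covered_length,
                    accession=acc,
                    source=meta.source,
                )
                mapped_per_structure[meta.structure_id] = set()
            for chain_id in alignment.chains():
                mapping = map_epitope_to_chain(record, positions, letters, alignment, chain_id)
                if best is None or mapping.mapped_fraction > best.mapped_fraction:
                    best = mapping
                if passes_cutoff(mapping, threshold):
                    passing.append(mapping)
                    mapped_per_structure[meta.structure_id].add(record.epitope_id)

        if passing:
            result.chain_mappings.extend(passing)
            acc_mapped[acc] += 1
        else:
            result.unmapped.append(
                UnmappedEpitope(record.epitope_id, acc, _dominant_reason(best))
            )

    for sid, summary in summaries.items():
        summary.n_epitopes_mapped = len(mapped_per_structure[sid])
    result.summaries = list(summaries.values())
    result.fallback_accessions = [acc for acc in acc_order if acc_mapped[acc] == 0]
    return result


@dataclass(frozen=True)
class AlphaFoldModel:
    """A predicted model: full-length sequence plus per-residue pLDDT."""

    accession: str
    sequence: str
    plddt: tuple[float, ...]
    model_id: str = ""

    @property
    def structure_id(self) -> str:
        return self.model_id or f"AF-{self.accession}-F1"


def map_catalog_alphafold(
    records: list[EpitopeRecord],
    models: dict[str, AlphaFoldModel],
    parents: dict[str, str],
    threshold: float = DEFAULT_CUTOFF,
) -> MappingResult:
    """Map a catalog onto predicted models via identity alignments.

    Same contract as :func:`map_catalog`, but the model sequence is the
    UniProt sequence itself, so the alignment is the identity and each
    matched residue carries its pLDDT. A model whose sequence disagrees
    with the parent sequence is skipped with a warning (its epitopes are
    reported as having no structure).
    """
    result = MappingResult()
    alignments: dict[str, ResidueAlignment] = {}
    summaries: dict[str, StructureSummary] = {}
    mapped_per_structure: dict[str, set[str]] = {}
    skipped_models: set[str] = set()

    for record in records:
        acc = record.parent_accession
        model = models.get(acc)
        if model is None or acc in skipped_models:
            result.unmapped.append(UnmappedEpitope(record.epitope_id, acc, NO_STRUCTURE))
            continue
        parent_seq = parents.get(acc, model.sequence)
        if model.sequence != parent_seq:
            log.warning(
                "model %s sequence differs from parent %s; model skipped",
                model.structure_id,
                acc,
            )
            skipped_models.add(acc)
            result.unmapped.append(UnmappedEpitope(record.epitope_id, acc, NO_STRUCTURE))
            continue
        if acc not in alignments:
            alignments[acc] = alignment_from_identity(
                acc, model.sequence, structure_id=model.structure_id
            )
            summaries[model.structure_id] = StructureSummary(
                structure_id=model.structure_id,
                resolution=None,
                covered_length=len(model.sequence),
                accession=acc,
                source="predicted",
            )
            mapped_per_structure[model.structure_id] = set()
        alignment = alignments[acc]
        resolved = resolve_epitope_positions(record, parent_seq)
        if resolved is None:
            result.unmapped.append(UnmappedEpitope(record.epitope_id, acc, UNLOCATABLE))
            continue
        positions, letters = resolved

        passing = []
        best: Optional[EpitopeChainMapping] = None
        for chain_id in alignment.chains():
            mapping = map_epitope_to_chain(
                record, positions, letters, alignment, chain_id, plddt=list(model.plddt)
            )
            if best is None or mapping.mapped_fraction > best.mapped_fraction:
                best = mapping
            if passes_cutoff(mapping, threshold):
                passing.append(mapping)
                mapped_per_structure[model.structure_id].add(record.epitope_id)
        if passing:
            result.chain_mappings.extend(passing)
        else:
            result.unmapped.append(
                UnmappedEpitope(record.epitope_id, acc, _dominant_reason(best))
            )

    for sid, summary in summaries.items():
        summary.n_epitopes_mapped = len(mapped_per_structure[sid])
    result.summaries = list(summaries.values())
    result.fallback_accessions = []
    return result


@dataclass
class PipelineResult:
    """Combined experimental + predicted mapping with its conservation ledger."""

    experimental: MappingResult
    predicted: MappingResult
    n_total: int

    @property
    def chain_mappings(self) -> list[EpitopeChainMapping]:
        return self.experimental.chain_mappings + self.predicted.chain_mappings

    @property
    def summaries(self) -> list[StructureSummary]:
        return self.experimental.summaries + self.predicted.summaries

    @property
    def unmapped(self) -> list[UnmappedEpitope]:
        fallback = set(self.experimental.fallback_accessions)
        kept = [u for u in self.experimental.unmapped if u.accession not in fallback]
        return kept + self.predicted.unmapped

    def ledger(self) -> dict[str, int]:
        exp = len(self.experimental.mapped_epitope_ids)
        pred = len(self.predicted.mapped_epitope_ids)
        return {
            "total": self.n_total,
            "mapped": exp + pred,
            "unmapped": self.n_total - exp - pred,
            "mapped_experimental": exp,
            "mapped_predicted": pred,
        }


def run_full_mapping(
    records: list[EpitopeRecord],
    index: dict[str, list[StructureMeta]],
    alignments: dict[str, ResidueAlignment],
    parents: dict[str, str],
    models: dict[str, AlphaFoldModel],
    threshold: float = DEFAULT_CUTOFF,
) -> PipelineResult:
    """Experimental pass, then predicted-model retry for fallback antigens."""
    experimental = map_catalog(records, index, alignments, parents, threshold)
    fallback = set(experimental.fallback_accessions)
    retry = [r for r in records if r.parent_accession in fallback]
    predicted = map_catalog_alphafold(retry, models, parents, threshold)
    return PipelineResult(experimental=experimental, predicted=predicted, n_total=len(records))


# ---------------------------------------------------------------------------
# tabular output


def mappings_to_frame(mappings: list[EpitopeChainMapping]) -> pd.DataFrame:
    """Epitope-based output: one row per mapped residue of each passing chain."""
    rows = []
    for m in mappings:
        for mr in m.matched:
            rows.append(
                {
                    "epitope_id": m.epitope_id,
                    "structure_id": m.structure_id,
                    "chain_id": m.chain_id,
                    "uniprot_position": mr.uniprot_position,
                    "residue_number": mr.residue.author_label(),
                    "one_letter": mr.residue.one_letter,
                    "plddt": "" if mr.plddt is None else f"{mr.plddt:.2f}",
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "epitope_id",
            "structure_id",
            "chain_id",
            "uniprot_position",
            "residue_number",
            "one_letter",
            "plddt",
        ],
    )
    return frame.sort_values(
        ["epitope_id", "structure_id", "chain_id", "uniprot_position"], kind="stable"
    ).reset_index(drop=True)


def summaries_to_frame(summaries: list[StructureSummary]) -> pd.DataFrame:
    """PDB-centric output: only structures with at least one mapped epitope."""
    rows = [
        {
            "structure_id": s.structure_id,
            "accession": s.accession,
            "resolution": "" if s.resolution is None else f"{s.resolution:.2f}",
            "covered_length": s.covered_length,
            "n_epitopes_mapped": s.n_epitopes_mapped,
            "source": s.source,
        }
        for s in summaries
        if s.n_epitopes_mapped > 0
    ]
    return pd.DataFrame(
        rows,
        columns=["structure_id", "accession", "resolution", "covered_length", "n_epitopes_mapped", "source"],
    )


def unmapped_to_frame(unmapped: list[UnmappedEpitope]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [{"epitope_id": u.epitope_id, "accession": u.accession, "reason": u.reason} for u in unmapped],
        columns=["epitope_id", "accession", "reason"],
    )
    return frame.sort_values(["epitope_id", "accession"], kind="stable").reset_index(drop=True)


def write_outputs(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write the epitope-based, PDB-centric and unmapped TSVs; return their paths."""
    from epistruct.prioritize import rank_structures

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "epitope": outdir / "epitope_mappings.tsv",
        "structure": outdir / "structure_summary.tsv",
        "unmapped": outdir / "unmapped.tsv",
    }
    mappings_to_frame(result.chain_mappings).to_csv(paths["epitope"], sep="\t", index=False)
    ranked = rank_structures([s for s in result.summaries if s.n_epitopes_mapped > 0])
    summaries_to_frame(ranked).to_csv(paths["structure"], sep="\t", index=False)
    unmapped_to_frame(result.unmapped).to_csv(paths["unmapped"], sep="\t", index=False)
    return paths
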