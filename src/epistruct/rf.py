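"""Per-position response-frequency (RF) immunogenicity profiles.

For each position of an antigen, the positive (``responded``) and total
(``tested``) assay counts of every epitope covering that position are
pooled. The RF score is a conservative estimate of the response rate:
the lower bound of the normal-approximation 95% confidence interval,

    RF(r, t) = max(0, (r − 1.96·√(r·(1 − r/t))) / t),      RF(r, 0) = 0,

clamped to [0, 1]. Positions covered by no epitope score 0. If the only
evidence for an antigen comes from MHC ligand assays (peptide binding or
elution, no T-/B-cell response readout), the whole profile is zero by
rule.

Profiles are projected onto structures through the residue-level
alignment and exported in the PDB B-factor channel (RF×100), which any
generic viewer can color by; a white→dark-blue ramp mirrors the
no-immunogenicity→hotspot semantics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import gemmi

from epistruct.catalog import LINEAR, MHC_LIGAND, EpitopeRecord
from epistruct.mapper import resolve_epitope_positions
from epistruct.sifts import ResidueAlignment, StructureResidue

log = logging.getLogger(__name__)

WHITE = (255, 255, 255)
DARK_BLUE = (0, 0, 139)

Z_95 = 1.96  # two-sided 95% normal quantile


@dataclass(frozen=True)
class PositionCounts:
    position: int
    responded: int = 0
    tested: int = 0

    def __post_init__(self) -> None:
        if self.responded > self.tested:
            raise ValueError("responded exceeds tested")


@dataclass
class RFProfile:
    accession: str
    length: int
    counts: list[PositionCounts]
    rf: list[float]

    def max_rf(self) -> float:
        return max(self.rf, default=0.0)


def accumulate_counts(
    records: list[EpitopeRecord], parent_seq: str
) -> list[PositionCounts]:
    """Pool responded/tested counts positionwise over all covering epitopes.

    Records without assay counts contribute nothing; records whose
    positions cannot be resolved in the parent are skipped with a
    warning. Positions covered by no epitope end up (0, 0).
    """
    length = len(parent_seq)
    responded = [0] * length
    tested = [0] * length
    for rec in records:
        if rec.responded is None or rec.tested is None:
            continue
        resolved = resolve_epitope_positions(rec, parent_seq)
        if resolved is None:
            log.warning("epitope %s has counts but is unlocatable in parent; skipped", rec.epitope_id)
            continue
        positions, _ = resolved
        if any(not (1 <= p <= length) for p in positions):
            log.warning("epitope %s has positions outside the parent; skipped", rec.epitope_id)
            continue
        for p in positions:
            responded[p - 1] += rec.responded
            tested[p - 1] += rec.tested
    return [
        PositionCounts(position=i + 1, responded=responded[i], tested=tested[i])
        for i in range(length)
    ]


def rf_lower_bound(responded: int, tested: int) -> float:
    """Lower 95% confidence bound on the response rate, clamped to [0, 1].

    Uses the normal approximation with variance r·(1 − r/t); no assays
    (t = 0) scores 0 and a fully positive record (r = t) scores exactly
    1 because the variance term vanishes.
    """
    if responded < 0 or tested < 0:
        raise ValueError("counts must be non-negative")
    if responded > tested:
        raise ValueError(f"responded ({responded}) exceeds tested ({tested})")
    if tested == 0:
        return 0.0
    p = responded / tested
    lower = (responded - Z_95 * math.sqrt(responded * (1.0 - p))) / tested
    return min(1.0, max(0.0, lower))


def compute_rf_profile(
    records: list[EpitopeRecord], accession: str, parent_seq: str
) -> RFProfile:
    """Accumulate counts and score every position of the antigen.

    If every record that contributes counts is tagged as an MHC ligand
    assay, the RF is identically zero over the whole antigen (binding
    evidence alone says nothing about a T- or B-cell response); the
    pooled counts are still reported.
    """
    counts = accumulate_counts(records, parent_seq)
    contributing = [
        r for r in records if r.responded is not None and r.tested is not None
    ]
    mhc_only = bool(contributing) and all(r.assay_type == MHC_LIGAND for r in contributing)
    if mhc_only:
        rf = [0.0] * len(parent_seq)
    else:
        rf = [rf_lower_bound(c.responded, c.tested) for c in counts]
    return RFProfile(accession=accession, length=len(parent_seq), counts=counts, rf=rf)


def project_rf_to_structure(
    profile: RFProfile, alignment: ResidueAlignment, chain_id: str
) -> list[tuple[StructureResidue, float]]:
    """Carry RF values onto the observed residues of one chain.

    RF follows the UniProt position, not the author numbering;
    unobserved or unaligned residues are absent from the projection.
    """
    if alignment.accession != profile.accession:
        raise ValueError(
            f"alignment accession {alignment.accession} does not match "
            f"profile accession {profile.accession}"
        )
    projection: list[tuple[StructureResidue, float]] = []
    for (chain, pos) in sorted(alignment.entries, key=lambda k: (k[0], k[1])):
        if chain != chain_id:
            continue
        res = alignment.entries[(chain, pos)]
        if not res.observed or not (1 <= pos <= profile.length):
            continue
        projection.append((res, profile.rf[pos - 1]))
    return projection


def rf_to_color(value: float, max_value: float) -> tuple[int, int, int]:
    """White → dark-blue ramp: 0 is white, the ceiling is dark blue.

    Intermediate scores interpolate componentwise (the midrange reads as
    light blue). A zero ceiling maps everything to white.
    """
    if max_value <= 0 or value <= 0:
        return WHITE
    t = min(1.0, value / max_value)
    return tuple(
        int(round(w + (d - w) * t)) for w, d in zip(WHITE, DARK_BLUE)
    )  # type: ignore[return-value]


def write_rf_table(profile: RFProfile, path: str | Path) -> None:
    """TSV of position, pooled counts and RF score."""
    with open(path, "w") as fh:
        fh.write("position\tresponded\ttested\trf\n")
        for c, score in zip(profile.counts, profile.rf):
            fh.write(f"{c.position}\t{c.responded}\t{c.tested}\t{score:.6f}\n")


def write_rf_pdb(
    structure_file: str | Path,
    projection: list[tuple[StructureResidue, float]],
    path: str | Path,
) -> None:
    """Write a copy of the structure with RF×100 in the B-factor column.

    Atoms of projected residues get their residue's score (2 decimals);
    every other atom gets 0.00. The atom content is unchanged. A
    projected residue that cannot be found in the file is a hard error.
    """
    st = gemmi.read_structure(str(structure_file))
    st.setup_entities()
    wanted: dict[tuple[str, int, str], float] = {}
    for res, score in projection:
        if res.author_number is None:
            raise KeyError(f"projected residue on chain {res.chain_id} has no author number")
        wanted[(res.chain_id, res.author_number, res.insertion_code or " ")] = score

    seen: set[tuple[str, int, str]] = set()
    model = st[0]
    for chain in model:
        for residue in chain:
            key = (chain.name, residue.seqid.num, residue.seqid.icode or " ")
            score = wanted.get(key)
            b = round(score * 100.0, 2) if score is not None else 0.0
            if score is not None:
                seen.add(key)
            for atom in residue:
                atom.b_iso = b
    missing = set(wanted) - seen
    if missing:
        chain, num, icode = sorted(missing)[0]
        raise KeyError(
            f"projected residue {chain} {num}{icode.strip()} not found in {structure_file}"
        )
    st.write_pdb(str(path))


def read_bfactor_profile(path: str | Path) -> dict[tuple[str, int, str], float]:
    """Per-residue B-factor (first atom) of a PDB file, keyed like the projection."""
    st = gemmi.read_structure(str(path))
    out: dict[tuple[str, int, str], float] = {}
    for chain in st[0]:
        for residue in chain:
            out[(chain.name, residue.seqid.num, residue.seqid.icode or " ")] = residue[0].b_iso
    return out


def write_color_commands(
    projection: list[tuple[StructureResidue, float]],
    path: str | Path,
    ceiling: Optional[float] = None,
) -> None:
    """Viewer hand-off: one line per residue — chain, author number, hex color.

    By default the ramp is normalized to the projection's maximum RF;
    pass ``ceiling=1.0`` to pin dark blue to a full response rate.
    """
    if ceiling is None:
        ceiling = max((score for _, score in projection), default=0.0)
    with open(path, "w") as fh:
        for res, score in projection:
            r, g, b = rf_to_color(score, ceiling)
            fh.write(f"{res.chain_id} {res.author_label()} #{r:02x}{g:02x}{b:02x}\n")
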