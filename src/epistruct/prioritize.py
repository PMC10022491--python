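"""Ranking of candidate structures and selection of the display set.

When an antigen has many deposited structures, users are shown a short
preselected list (up to five by default), ordered so that structures
carrying the most mapped epitopes come first and, among equals, the
best (lowest) resolution wins. Entries without a resolution (NMR,
predicted models) sort after any numeric resolution; the structure ID
breaks remaining ties, making the order total and deterministic.
"""

from __future__ import annotations

import math
from typing import Optional

from epistruct.mapper import StructureSummary

DEFAULT_DISPLAY_SET_SIZE = 5


def rank_structures(
    summaries: list[StructureSummary],
    weights: Optional[tuple[float, float]] = None,
) -> list[StructureSummary]:
    """Total, pure ordering of structure summaries.

    Default key: mapped-epitope count descending, then resolution
    ascending (absent last), then structure ID. Alternatively a
    ``(count_weight, resolution_weight)`` pair scores each structure as
    ``count_weight·n − resolution_weight·resolution`` (descending),
    with the same ID tie-break.
    """

    def resolution_key(s: StructureSummary) -> float:
        return s.resolution if s.resolution is not None else math.inf

    if weights is None:
        key = lambda s: (-s.n_epitopes_mapped, resolution_key(s), s.structure_id)
    else:
        w_count, w_res = weights
        key = lambda s: (
            -(w_count * s.n_epitopes_mapped - w_res * resolution_key(s)),
            s.structure_id,
        )
    return sorted(summaries, key=key)


def select_display_set(
    ranked: list[StructureSummary], k: int = DEFAULT_DISPLAY_SET_SIZE
) -> list[StructureSummary]:
    """First min(k, n) entries of the ranking — the files offered in the viewer."""
    if k < 1:
        raise ValueError("display set size must be at least 1")
    return ranked[:k]
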