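"""Independent brute-force references used by unit and acceptance tests."""

import math


def brute_force_matched(positions, letters, alignment):
    """Enumerate every (chain, entry) × epitope-position pair directly.

    Returns {chain: set of matched UniProt positions}. Deliberately
    ignores the alignment's keyed lookup: it scans the raw entry list.
    """
    matched: dict[str, set[int]] = {}
    entry_list = [(chain, pos, res) for (chain, pos), res in alignment.entries.items()]
    for chain in {c for c, _, _ in entry_list}:
        matched[chain] = set()
        for c, apos, res in entry_list:
            if c != chain or not res.observed:
                continue
            for p, letter in zip(positions, letters):
                if p == apos and res.one_letter == letter:
                    matched[chain].add(p)
    return matched


def rf_lower_bound_reference(r, t):
    """Closed-form lower 95% bound, written out independently."""
    if t == 0:
        return 0.0
    value = (r - 1.96 * math.sqrt(r * (1.0 - r / t))) / t
    return min(1.0, max(0.0, value))
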