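"""Independent brute-force oracles used by the test suite.

These deliberately re-state the pipeline's rules in the most literal,
unoptimized way possible so that the production implementations are checked
against an independent route.
"""

from itertools import product

import numpy as np


def rule_oracle(tumor: float, normal: float, fold: float = 2.0, zero: float = 0.6):
    """One-line-per-branch restatement of the differential-site rules.

    Returns "up"/"down"/None for a pair of aggregated scores. All-zero
    removal is the caller's job (an all-zero pair returns None here too).
    """
    if tumor > 0 and normal > 0:
        return "up" if tumor / normal > fold else ("down" if normal / tumor > fold else None)
    if tumor == 0 and normal == 0:
        return None
    if normal == 0:
        return "up" if tumor > zero else None
    return "down" if normal > zero else None


def brute_force_overlaps(sites, genes):
    """All (site_index, gene_id) pairs where the 1-bp site [pos0, pos0+1)
    overlaps the half-open gene interval, by exhaustive O(n*m) scan."""
    pairs = set()
    for i, (schrom, pos) in enumerate(zip(sites["chrom"], sites["pos0"])):
        for gchrom, start, end, gid in zip(
            genes["chrom"], genes["start"], genes["end"], genes["gene_id"]
        ):
            if schrom == gchrom and start < pos + 1 and pos < end:
                pairs.add((i, gid))
    return pairs


def brute_force_venn(flag_rows, flag_names):
    """Region counts of the 4-set Venn by enumerating all membership
    patterns per gene."""
    counts = {}
    for pattern in product([False, True], repeat=len(flag_names)):
        if not any(pattern):
            continue
        key = "+".join(n for n, p in zip(flag_names, pattern) if p)
        counts[key] = sum(1 for row in flag_rows if tuple(bool(x) for x in row) == pattern)
    return counts


def chi2_2x2_closed_form(a, b, c, d):
    """n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))"""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def empirical_survival(times, grid):
    """P(T > t) from fully observed (uncensored) times."""
    times = np.asarray(times, dtype=float)
    return np.array([(times > t).mean() for t in grid])
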