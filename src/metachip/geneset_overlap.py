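"""Gene-set overlap counts (Venn regions) and Fisher enrichment testing.

Overlap significance is the one-sided Fisher exact test on the 2x2 table
[[k, |A|-k], [|B|-k, N-|A|-|B|+k]], whose enrichment p-value is the
hypergeometric upper tail P(X >= k) with N draws of |A| successes taken
|B| at a time.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .types import DataError, GeneSet, check_same_universe

__all__ = [
    "OverlapResult",
    "overlap_counts",
    "fisher_overlap",
    "hypergeom_enrichment_p",
]


@dataclass(frozen=True)
class OverlapResult:
    set_names: tuple[str, ...]
    region_counts: dict[tuple[str, ...], int]
    universe_size: int
    k: int | None = None  # |A n B| for the pairwise test
    odds_ratio: float | None = None
    p_value: float | None = None


def overlap_counts(sets: list[GeneSet]) -> OverlapResult:
    """Exact Venn-region cardinalities for two or three gene sets.

    Each region is keyed by the sorted tuple of set names whose members
    fall exactly in those sets (and no others). Region counts sum to the
    size of the union.
    """
    if len(sets) not in (2, 3):
        raise DataError(f"overlap_counts takes 2 or 3 sets, got {len(sets)}")
    universe_size = check_same_universe(sets)
    names = tuple(s.name for s in sets)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(range(len(sets)), r):
            inside = frozenset.intersection(*[sets[i].members for i in combo])
            outside = frozenset.union(
                frozenset(), *[sets[i].members for i in range(len(sets)) if i not in combo]
            )
            key = tuple(names[i] for i in combo)
            regions[key] = len(inside - outside)
    k = len(sets[0].members & sets[1].members) if len(sets) == 2 else None
    return OverlapResult(names, regions, universe_size, k=k)


def hypergeom_enrichment_p(k, size_a: int, size_b: int, universe_size: int):
    """One-sided enrichment p-value: P(X >= k), X ~ Hypergeom(N, |A|, |B|).

    ``k`` may be a scalar or an array of overlap counts for one table shape.
    """
    k_arr = np.asarray(k)
    if min(int(k_arr.min()), size_a, size_b) < 0 or max(size_a, size_b) > universe_size:
        raise DataError("inconsistent overlap inputs")
    if k_arr.max() > min(size_a, size_b) or universe_size - size_a - size_b + k_arr.min() < 0:
        raise DataError("negative contingency-table cell: inconsistent overlap inputs")
    p = stats.hypergeom.sf(k_arr - 1, universe_size, size_a, size_b)
    return float(p) if np.isscalar(k) else p


def fisher_overlap(
    a: GeneSet, b: GeneSet, universe_size: int | None = None, two_sided: bool = False
) -> OverlapResult:
    """Fisher exact test for enrichment of the overlap between two gene sets.

    The universe size is a required, deliberate choice (the annotation's
    gene count by default via the GeneSet objects); there is no silent
    default. One-sided enrichment by default, two-sided on request.
    """
    if universe_size is None:
        universe_size = check_same_universe([a, b])
    n_a, n_b = len(a.members), len(b.members)
    if max(n_a, n_b) > universe_size:
        raise DataError("set larger than the stated universe")
    k = len(a.members & b.members)
    table = np.array(
        [[k, n_a - k], [n_b - k, universe_size - n_a - n_b + k]], dtype=np.int64
    )
    if (table < 0).any():
        raise DataError(f"negative contingency-table cell: {table.tolist()}")
    if two_sided:
        p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    else:
        p = hypergeom_enrichment_p(k, n_a, n_b, universe_size)
    ad = float(table[0, 0] * table[1, 1])
    bc = float(table[0, 1] * table[1, 0])
    odds = np.nan if (ad == 0 and bc == 0) else (np.inf if bc == 0 else ad / bc)
    counts = overlap_counts([a, b]).region_counts
    return OverlapResult(
        (a.name, b.name), counts, universe_size, k=k, odds_ratio=float(odds), p_value=p
    )
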