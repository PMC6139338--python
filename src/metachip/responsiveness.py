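"""Nutrient-responsiveness ranking and fold-change classification.

Two complementary views of responsiveness: (1) the per-gene change in
promoter ChIP signal between fed and starved samples (delta signal),
ranked so rank 1 is the largest fed-minus-starved difference, with fixed
bins of genes drawn from the top, middle and bottom of the ranking; and
(2) calls on expression data where a gene is responsive when
|log2 fold-change| meets an inclusive threshold (default 1.5, i.e. a
2.8-fold change on the linear scale).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import DataError, ExpressionMatrix, GeneProfile, GeneSet
from .ratio_stats import default_promoter_bins

logger = logging.getLogger(__name__)

__all__ = [
    "DeltaRecord",
    "ResponsivenessCall",
    "delta_signal",
    "select_rank_bins",
    "classify_responsive",
]


@dataclass(frozen=True)
class DeltaRecord:
    gene_id: str
    signal_fed: float
    signal_starved: float
    delta: float
    rank: int


@dataclass(frozen=True)
class ResponsivenessCall:
    gene_id: str
    log2fc: float
    call: str  # up_in_b | up_in_a | unresponsive


def _promoter_mean(profile: GeneProfile, promoter_bins: Sequence[int]) -> float:
    vals = profile.bin_means[list(promoter_bins)]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if len(vals) else np.nan


def delta_signal(
    profiles_fed: Sequence[GeneProfile],
    profiles_starved: Sequence[GeneProfile],
    promoter_bins: Sequence[int] | None = None,
) -> tuple[list[DeltaRecord], int]:
    """Rank genes by fed-minus-starved promoter signal.

    Promoter signal is the mean of the non-missing unsmoothed bin means
    over the promoter window. Records are sorted by descending delta (ties
    by gene_id); genes missing the whole window in either condition, or
    present in only one cohort, are excluded and counted.
    """
    promoter_bins = list(promoter_bins if promoter_bins is not None else default_promoter_bins())
    fed = {p.gene_id: p for p in profiles_fed}
    starved = {p.gene_id: p for p in profiles_starved}
    shared = set(fed) & set(starved)
    if not shared:
        raise DataError("fed and starved profiles share no genes")
    n_excluded = len(set(fed) | set(starved)) - len(shared)
    rows = []
    for gid in shared:
        sf = _promoter_mean(fed[gid], promoter_bins)
        ss = _promoter_mean(starved[gid], promoter_bins)
        if not (np.isfinite(sf) and np.isfinite(ss)):
            n_excluded += 1
            continue
        rows.append((gid, sf, ss, sf - ss))
    rows.sort(key=lambda r: (-r[3], r[0]))
    records = [
        DeltaRecord(gid, sf, ss, d, rank)
        for rank, (gid, sf, ss, d) in enumerate(rows, start=1)
    ]
    if n_excluded:
        logger.info("delta_signal: excluded %d genes", n_excluded)
    return records, n_excluded


def select_rank_bins(
    records: Sequence[DeltaRecord], bin_size: int = 100
) -> tuple[GeneSet, GeneSet, GeneSet]:
    """Top, middle and bottom rank bins of ``bin_size`` genes each.

    The middle bin is centered on the median rank: ranks
    floor((n-k)/2)+1 .. floor((n-k)/2)+k. The three sets are disjoint.
    """
    n, k = len(records), bin_size
    if n < 3 * k:
        raise DataError(
            f"need at least {3 * k} ranked genes for bins of {k}, have {n}; "
            "use a smaller bin_size"
        )
    by_rank = sorted(records, key=lambda r: r.rank)
    mid_start = (n - k) // 2  # 0-based offset of the centered middle bin
    top = frozenset(r.gene_id for r in by_rank[:k])
    middle = frozenset(r.gene_id for r in by_rank[mid_start : mid_start + k])
    bottom = frozenset(r.gene_id for r in by_rank[n - k :])
    return (
        GeneSet("delta_top", top, n),
        GeneSet("delta_middle", middle, n),
        GeneSet("delta_bottom", bottom, n),
    )


def classify_responsive(
    expr: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    threshold_log2: float = 1.5,
    floor: float = 1.0,
) -> list[ResponsivenessCall]:
    """Call each gene up_in_b / up_in_a / unresponsive by log2 fold change.

    Levels are floored at ``floor`` before the ratio so low values cannot
    produce unbounded fold changes. The threshold is inclusive: a gene at
    exactly |log2fc| = threshold is called responsive.
    """
    if floor <= 0:
        raise DataError("expression floor must be positive")
    for cond in (cond_a, cond_b):
        if cond not in expr.data.columns:
            raise DataError(f"condition {cond!r} absent from expression matrix")
    a = np.maximum(expr.data[cond_a].to_numpy(float), floor)
    b = np.maximum(expr.data[cond_b].to_numpy(float), floor)
    log2fc = np.log2(b / a)
    calls = []
    for gid, fc in zip(expr.genes, log2fc):
        if fc >= threshold_log2:
            call = "up_in_b"
        elif fc <= -threshold_log2:
            call = "up_in_a"
        else:
            call = "unresponsive"
        calls.append(ResponsivenessCall(gid, float(fc), call))
    return calls
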