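"""Promoter k-mer counting and enrichment versus background sequence.

k-mers are counted in overlapping windows, optionally collapsed with
their reverse complements under a canonical key (the lexicographic
minimum of the pair), so a GAGAGAGA run and its TCTCTCTC complement share
one tally. Enrichment of foreground (promoter) counts over background is
scored with an upper-tail binomial test per motif and Benjamini-Hochberg
correction across motifs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import DataError

__all__ = ["KmerCounts", "MotifEnrichment", "count_kmers", "enrichment", "revcomp"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerCounts:
    """Occurrence counts of canonical k-mers plus the number of valid windows."""

    k: int
    collapse_rc: bool
    counts: dict[str, int]
    windows: int


@dataclass(frozen=True)
class MotifEnrichment:
    motif: str
    fg_count: int
    fg_windows: int
    bg_count: int
    bg_windows: int
    fold: float
    p_value: float
    q_value: float


def count_kmers(
    sequences: Iterable[str], k: int = 8, collapse_rc: bool = True
) -> KmerCounts:
    """Count overlapping k-mer occurrences across sequences.

    Windows containing N are skipped and excluded from the window total,
    so rates are computed over informative windows only. Characters
    outside {A,C,G,T,N} are an error naming the offending position.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    counts: dict[str, int] = {}
    windows = 0
    for si, seq in enumerate(sequences):
        seq = seq.upper()
        bad = set(seq) - _VALID
        if bad:
            pos = min(seq.index(c) for c in bad)
            raise DataError(
                f"sequence {si}: invalid character {seq[pos]!r} at position {pos}"
            )
        for i in range(max(len(seq) - k + 1, 0)):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            windows += 1
            key = canonical(kmer) if collapse_rc else kmer
            counts[key] = counts.get(key, 0) + 1
    return KmerCounts(k, collapse_rc, counts, windows)


def enrichment(fg: KmerCounts, bg: KmerCounts) -> list[MotifEnrichment]:
    """Score per-motif foreground enrichment over background.

    Per motif, p is the upper-tail binomial probability of at least
    fg_count hits in fg_windows trials at the background per-window rate
    (floored at 0.5/bg_windows for motifs unseen in the background);
    q-values are Benjamini-Hochberg over all tested motifs. Motifs absent
    from both collections are not reported. Results are sorted by
    ascending (q, p).
    """
    if fg.k != bg.k or fg.collapse_rc != bg.collapse_rc:
        raise DataError("foreground and background counted with different k/collapse settings")
    if bg.windows <= 0:
        raise DataError("background has no valid windows")
    if fg.windows <= 0:
        raise DataError("foreground has no valid windows")
    motifs = sorted(set(fg.counts) | set(bg.counts))
    if not motifs:
        return []
    fg_counts = np.array([fg.counts.get(m, 0) for m in motifs])
    bg_counts = np.array([bg.counts.get(m, 0) for m in motifs])
    rates = np.maximum(bg_counts, 0.5) / bg.windows
    p = stats.binom.sf(fg_counts - 1, fg.windows, rates)
    p = np.minimum(p, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = (fg_counts / fg.windows) / np.where(bg_counts > 0, bg_counts / bg.windows, np.nan)
    fold = np.where(bg_counts > 0, fold, np.inf)
    results = [
        MotifEnrichment(
            motif=m,
            fg_count=int(fc),
            fg_windows=fg.windows,
            bg_count=int(bc),
            bg_windows=bg.windows,
            fold=float(f),
            p_value=float(pv),
            q_value=float(qv),
        )
        for m, fc, bc, f, pv, qv in zip(motifs, fg_counts, bg_counts, fold, p, q)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, -r.fg_count))
    return results


def enrichment_table(results: Sequence[MotifEnrichment]):
    """Tabulate enrichment results (one row per motif, sorted by q)."""
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in results])
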