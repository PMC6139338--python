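"""Promoter-peak / gene-body-nadir ratio with propagated error.

The promoter-bias statistic is the maximum aggregate signal over the
promoter window divided by the minimum over the gene-body window. Its
standard error follows by first-order (delta-method) propagation of the
two bin standard errors, assuming independence:

    se_ratio = ratio * sqrt((se_peak/peak)^2 + (se_nadir/nadir)^2)

Two conditions are compared either on the aggregate ratios via a normal
z statistic on the propagated SEs, or by a Welch unequal-variance t test
on per-gene ratios.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .types import BinScheme, DataError, GeneProfile, MetageneProfile
from .metagene import smooth

logger = logging.getLogger(__name__)

__all__ = [
    "RatioStat",
    "RatioComparison",
    "default_promoter_bins",
    "default_body_bins",
    "peak_nadir_ratio",
    "per_gene_ratios",
    "compare_ratios",
]

# Promoter window = all flank bins plus the first body decile (the peak sits
# at the start-codon boundary); nadir window = the remaining body deciles,
# so the promoter peak cannot bleed into the nadir search.


def default_promoter_bins(scheme: BinScheme | None = None) -> range:
    scheme = scheme or BinScheme()
    return range(0, scheme.n_flank_bins + 1)


def default_body_bins(scheme: BinScheme | None = None) -> range:
    scheme = scheme or BinScheme()
    return range(scheme.n_flank_bins + 1, scheme.n_bins)


@dataclass(frozen=True)
class RatioStat:
    """Promoter peak, body nadir, their ratio and its propagated SE."""

    peak: float
    se_peak: float
    peak_bin: int
    nadir: float
    se_nadir: float
    nadir_bin: int
    ratio: float
    se_ratio: float
    n_genes_at_peak: int
    n_genes_at_nadir: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class RatioComparison:
    stat_a: RatioStat
    stat_b: RatioStat
    method: str
    statistic: float
    p_value: float
    per_gene_n: tuple[int, int] | None = None


def propagate_ratio_se(peak: float, se_peak: float, nadir: float, se_nadir: float) -> float:
    ratio = peak / nadir
    return abs(ratio) * np.sqrt((se_peak / peak) ** 2 + (se_nadir / nadir) ** 2)


def _extreme(values: np.ndarray, bins: Sequence[int], find_max: bool) -> int:
    """Index of the max/min over ``bins``; ties go to the lowest bin index."""
    sub = values[list(bins)]
    if not np.all(np.isfinite(sub)):
        raise DataError("ratio window contains missing bin means")
    pos = int(np.argmax(sub)) if find_max else int(np.argmin(sub))
    return list(bins)[pos]


def peak_nadir_ratio(
    profile: MetageneProfile,
    promoter_bins: Sequence[int] | None = None,
    body_bins: Sequence[int] | None = None,
    use_smoothed: bool = True,
) -> RatioStat:
    """Promoter-window maximum over gene-body minimum, with propagated SE.

    Uses the smoothed aggregate curve by default (the raw curve is
    available with ``use_smoothed=False``). The nadir must be positive for
    the ratio to be defined on fold-enrichment data.
    """
    promoter_bins = list(promoter_bins if promoter_bins is not None else default_promoter_bins())
    body_bins = list(body_bins if body_bins is not None else default_body_bins())
    if not promoter_bins or not body_bins:
        raise DataError("promoter and body windows must be non-empty")
    if set(promoter_bins) & set(body_bins):
        raise DataError("promoter and body windows must be disjoint")
    mean = profile.smoothed_mean if use_smoothed else profile.mean
    se = profile.smoothed_se if use_smoothed else profile.se
    peak_bin = _extreme(mean, promoter_bins, find_max=True)
    nadir_bin = _extreme(mean, body_bins, find_max=False)
    peak, nadir = float(mean[peak_bin]), float(mean[nadir_bin])
    if nadir <= 0:
        raise DataError(f"gene-body nadir {nadir:.4g} <= 0: ratio undefined")
    se_peak, se_nadir = float(se[peak_bin]), float(se[nadir_bin])
    return RatioStat(
        peak=peak,
        se_peak=se_peak,
        peak_bin=peak_bin,
        nadir=nadir,
        se_nadir=se_nadir,
        nadir_bin=nadir_bin,
        ratio=peak / nadir,
        se_ratio=propagate_ratio_se(peak, se_peak, nadir, se_nadir),
        n_genes_at_peak=int(profile.n_genes[peak_bin]),
        n_genes_at_nadir=int(profile.n_genes[nadir_bin]),
    )


def per_gene_ratios(
    profiles: Sequence[GeneProfile],
    promoter_bins: Sequence[int] | None = None,
    body_bins: Sequence[int] | None = None,
    scheme: BinScheme | None = None,
) -> tuple[list[tuple[str, float]], int]:
    """Peak/nadir ratio per gene on its smoothed profile.

    Genes with a fully missing peak or nadir window, or a non-positive
    nadir, are excluded; the exclusion count is returned alongside.
    """
    if not profiles:
        raise DataError("per_gene_ratios requires at least one profile")
    scheme = scheme or BinScheme()
    promoter_bins = list(promoter_bins if promoter_bins is not None else default_promoter_bins(scheme))
    body_bins = list(body_bins if body_bins is not None else default_body_bins(scheme))
    out, n_excluded = [], 0
    for p in profiles:
        raw_prom = p.bin_means[promoter_bins]
        raw_body = p.bin_means[body_bins]
        # exclusion is decided on the raw windows: edge-truncated smoothing
        # would otherwise bleed flank signal into an empty body window
        if not (np.any(np.isfinite(raw_prom)) and np.any(np.isfinite(raw_body))):
            n_excluded += 1
            continue
        sm = smooth(p.bin_means, scheme.smooth_window)
        prom = sm[promoter_bins]
        body = sm[body_bins]
        peak = np.nanmax(prom)
        nadir = np.nanmin(body)
        if nadir <= 0:
            n_excluded += 1
            continue
        out.append((p.gene_id, float(peak / nadir)))
    if n_excluded:
        logger.info("per_gene_ratios: excluded %d genes", n_excluded)
    return out, n_excluded


def compare_ratios(
    a: RatioStat,
    b: RatioStat,
    method: str = "z_propagated",
    per_gene_a: Sequence[float] | None = None,
    per_gene_b: Sequence[float] | None = None,
) -> RatioComparison:
    """Two-sided comparison of two peak/nadir ratios.

    ``z_propagated`` tests (ratio_a - ratio_b) against the normal
    distribution with the propagated SEs; ``welch_per_gene`` runs a Welch
    unequal-variance t test on per-gene ratio samples.
    """
    if method == "z_propagated":
        denom = np.hypot(a.se_ratio, b.se_ratio)
        if denom == 0:
            if a.ratio == b.ratio:
                return RatioComparison(a, b, method, 0.0, 1.0)
            warnings.warn("both ratios have zero SE but differ; p = 0", stacklevel=2)
            stat = np.inf if a.ratio > b.ratio else -np.inf
            return RatioComparison(a, b, method, float(stat), 0.0)
        z = (a.ratio - b.ratio) / denom
        p = 2.0 * stats.norm.sf(abs(z))
        return RatioComparison(a, b, method, float(z), float(p))
    if method == "welch_per_gene":
        if per_gene_a is None or per_gene_b is None or len(per_gene_a) < 2 or len(per_gene_b) < 2:
            raise DataError("welch_per_gene needs per-gene ratio samples with n >= 2 each")
        res = stats.ttest_ind(np.asarray(per_gene_a), np.asarray(per_gene_b), equal_var=False)
        return RatioComparison(
            a, b, method, float(res.statistic), float(res.pvalue), (len(per_gene_a), len(per_gene_b))
        )
    raise DataError(f"unknown comparison method {method!r}")
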