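"""Metagene binning and cross-gene aggregation of tiling-probe signal.

Every gene is mapped onto a common model: 20 bins over a 3 kb upstream
flank (F1 most distal) followed by 10 equal gene-body segments (B1..B10,
5'->3'). Probe values are averaged per bin per gene first, then averaged
across genes, so the per-bin standard error is the cross-gene standard
deviation divided by the square root of the number of genes.

Bin arithmetic is done in a strand-oriented coordinate ``d`` measured in
bp from the translational start (negative upstream). ``d`` is invariant
under mirroring the genome, which makes per-gene profiles exactly
strand-symmetric.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .types import BinScheme, DataError, GeneModel, GeneProfile, MetageneProfile, SignalTrack

logger = logging.getLogger(__name__)

__all__ = [
    "assign_bins",
    "gene_profile",
    "profile_genes",
    "aggregate",
    "smooth",
    "metagene_profile",
]


def _bin_edges_d(gene: GeneModel, scheme: BinScheme) -> np.ndarray:
    """Bin edges in strand-oriented coordinates: [-flank, ..., 0, ..., L]."""
    flank_edges = np.linspace(-scheme.flank_bp, 0.0, scheme.n_flank_bins + 1)
    body_edges = np.linspace(0.0, float(gene.length), scheme.n_body_bins + 1)
    return np.concatenate([flank_edges, body_edges[1:]])


def _d_to_genomic(gene: GeneModel, d_lo: float, d_hi: float) -> tuple[float, float]:
    """Map a strand-oriented [d_lo, d_hi) range to a genomic interval."""
    if gene.strand == "+":
        return gene.start + d_lo, gene.start + d_hi
    return gene.end - d_hi, gene.end - d_lo


def assign_bins(
    gene: GeneModel, scheme: BinScheme, chrom_length: int
) -> list[tuple[int, tuple[float, float] | None]]:
    """Genomic interval of every metagene bin, 5'->3'.

    Indices 0..n_flank_bins-1 cover the upstream flank (index 0 most
    distal), the rest the gene body in equal segments. Bin edges are
    real-valued. Flank portions outside [0, chrom_length) are clipped;
    bins falling entirely outside are returned with a ``None`` interval.
    """
    if chrom_length < gene.end:
        raise DataError(f"gene {gene.gene_id!r} extends past chromosome length {chrom_length}")
    edges = _bin_edges_d(gene, scheme)
    out: list[tuple[int, tuple[float, float] | None]] = []
    for i in range(scheme.n_bins):
        lo, hi = _d_to_genomic(gene, edges[i], edges[i + 1])
        lo_c, hi_c = max(lo, 0.0), min(hi, float(chrom_length))
        out.append((i, (lo_c, hi_c) if hi_c > lo_c else None))
    return out


def _assign_probe_bins(
    midpoints: np.ndarray, gene: GeneModel, scheme: BinScheme
) -> np.ndarray:
    """Metagene bin index per probe midpoint, -1 when outside the model.

    A midpoint exactly on an internal bin edge goes to the 5' (lower
    metagene index) bin, keeping the assignment invariant under genome
    mirroring.
    """
    d = midpoints - gene.start if gene.strand == "+" else gene.end - midpoints
    edges = _bin_edges_d(gene, scheme)
    idx = np.searchsorted(edges, d, side="left") - 1
    # d == edges[0] is the region boundary: include it in bin 0.
    idx[d == edges[0]] = 0
    outside = (d < edges[0]) | (d > edges[-1])
    idx[outside] = -1
    return idx


def gene_profile(track: SignalTrack, gene: GeneModel, scheme: BinScheme) -> GeneProfile:
    """Bin one gene's probes: each probe joins the bin holding its midpoint.

    Bin mean is the unweighted mean of contributing probe values; bins with
    no probes are missing (NaN). A gene on a chromosome absent from the
    track yields an all-missing profile with a warning.
    """
    means = np.full(scheme.n_bins, np.nan)
    counts = np.zeros(scheme.n_bins, dtype=int)
    if gene.chrom not in track.data:
        logger.warning(
            "gene %s: chromosome %s absent from track %s", gene.gene_id, gene.chrom, track.sample_id
        )
        return GeneProfile(gene.gene_id, means, counts)
    starts, ends, values = track.intervals(gene.chrom)
    # Restrict to probes whose midpoint can fall in the gene model.
    if gene.strand == "+":
        lo, hi = gene.start - scheme.flank_bp, float(gene.end)
    else:
        lo, hi = float(gene.start), gene.end + scheme.flank_bp
    mid = (starts + ends) / 2.0
    i0, i1 = np.searchsorted(mid, [lo, hi + 1])
    mid = mid[i0:i1]
    vals = values[i0:i1]
    idx = _assign_probe_bins(mid, gene, scheme)
    keep = idx >= 0
    idx, vals = idx[keep], vals[keep]
    if len(idx):
        counts = np.bincount(idx, minlength=scheme.n_bins)
        sums = np.bincount(idx, weights=vals, minlength=scheme.n_bins)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return GeneProfile(gene.gene_id, means, counts)


def profile_genes(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    scheme: BinScheme | None = None,
    min_probes: int = 5,
) -> tuple[list[GeneProfile], int]:
    """Profile a cohort, excluding genes with too few probes overall.

    Returns the retained profiles and the number of excluded genes.
    """
    scheme = scheme or BinScheme()
    profiles, n_excluded = [], 0
    for gene in genes:
        p = gene_profile(track, gene, scheme)
        if int(p.probe_counts.sum()) < min_probes:
            n_excluded += 1
            continue
        profiles.append(p)
    if n_excluded:
        logger.info(
            "excluded %d/%d genes with < %d probes", n_excluded, len(genes), min_probes
        )
    return profiles, n_excluded


def aggregate(profiles: Sequence[GeneProfile], smooth_window: int = 5) -> MetageneProfile:
    """Cross-gene mean/SD/SE per bin; SE = sample SD / sqrt(n genes).

    ``n_genes`` counts profiles with a non-missing value in that bin; bins
    with fewer than two contributing genes have missing SD/SE. Smoothed
    mean and SE are centered moving averages (see :func:`smooth`).
    """
    if not profiles:
        raise DataError("aggregate requires at least one gene profile")
    n_bins = profiles[0].n_bins
    if any(p.n_bins != n_bins for p in profiles):
        raise DataError("gene profiles have differing bin counts")
    mat = np.vstack([p.bin_means for p in profiles])
    present = np.isfinite(mat)
    n_genes = present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_genes > 0, np.nansum(mat, axis=0) / np.maximum(n_genes, 1), np.nan)
        dev2 = np.where(present, (mat - mean) ** 2, 0.0)
        sd = np.where(n_genes > 1, np.sqrt(dev2.sum(axis=0) / np.maximum(n_genes - 1, 1)), np.nan)
        se = sd / np.sqrt(n_genes)
    labels = _default_labels(n_bins)
    return MetageneProfile(
        bin_labels=labels,
        mean=mean,
        sd=sd,
        se=se,
        n_genes=n_genes,
        smoothed_mean=smooth(mean, smooth_window),
        smoothed_se=smooth(se, smooth_window),
    )


def _default_labels(n_bins: int) -> list[str]:
    # Default 20+10 layout when it fits, else generic bin names.
    if n_bins == 30:
        return BinScheme().bin_labels
    return [f"bin{i}" for i in range(n_bins)]


def smooth(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average, truncated at the edges, skipping missing values.

    A window with no non-missing values yields a missing result. ``window``
    must be odd so the average is centered.
    """
    if window % 2 == 0 or window < 1:
        raise DataError(f"smoothing window must be odd and >= 1, got {window}")
    values = np.asarray(values, dtype=float)
    half = window // 2
    out = np.full_like(values, np.nan)
    for i in range(len(values)):
        w = values[max(0, i - half) : i + half + 1]
        w = w[np.isfinite(w)]
        if len(w):
            out[i] = w.mean()
    return out


def metagene_profile(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    scheme: BinScheme | None = None,
    min_probes: int = 5,
) -> MetageneProfile:
    """Convenience: profile a cohort and aggregate in one call."""
    scheme = scheme or BinScheme()
    profiles, _ = profile_genes(track, genes, scheme, min_probes=min_probes)
    return aggregate(profiles, smooth_window=scheme.smooth_window)
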