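"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generator emulates a whole-genome tiling-array ChIP experiment on a
toy chromosome: non-overlapping genes with clear upstream flanks, probes
tiling the genome at regular spacing, and per-probe fold-enrichment
values built from a flat baseline plus a Gaussian promoter bump centered
just upstream of the translational start, with condition/genotype
dependent amplitude and additive Gaussian noise. It also emits promoter
FASTA (optionally carrying planted purine/pyrimidine repeat runs) and
expression matrices with planted log2 fold changes.

Everything is deterministic under the configured seed; per-track noise
streams are derived from the seed and the condition/genotype labels.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .types import BinScheme, ConfigError, DataError, ExpressionMatrix, GeneModel, SignalTrack
from .metagene import metagene_profile
from .ratio_stats import peak_nadir_ratio

__all__ = [
    "SimConfig",
    "SimGenome",
    "make_genome",
    "simulate_track",
    "simulate_expression",
    "promoter_sequences",
    "expected_ratio",
    "calibrate_amplitude",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the emulated tiling-array study.

    Signal shape: expected probe value near a marked gene is
    ``baseline + A * exp(-(d - bump_center)^2 / (2 bump_sd^2))
    + body_slope * d / 1000`` (body term for d >= 0 only), where ``d`` is
    the strand-oriented distance in bp from the translational start
    (negative upstream). Observed values add Gaussian noise with SD
    ``noise_sd`` and are floored at ``value_floor`` to stay positive.
    """

    n_genes: int = 827
    gene_length: tuple[int, int] = (1000, 3000)
    intergenic: tuple[int, int] = (3000, 5000)
    probe_spacing: int = 50
    probe_length: int = 50
    baseline: float = 1.0
    bump_amplitude: float | Mapping[tuple[str, str], float] = 1.3
    bump_center: float = -150.0
    bump_sd: float = 400.0
    amplitude_cv: float = 0.0  # per-gene lognormal dispersion of bump amplitude
    body_slope: float = 0.0
    noise_sd: float = 0.2
    frac_marked: float = 1.0
    upstream_clearance: float = 3000.0
    edge_fraction: float = 0.0
    chrom: str = "chrI"
    chrom_length: int | None = None
    value_floor: float = 0.01
    # promoter sequence / motif planting
    promoter_len: int = 500
    repeat_frac: float = 0.3
    repeat_unit_len: int = 15  # (GA)_15 / (AC)_15 runs
    repeat_units: tuple[str, ...] = ("GA", "AC")
    # expression simulation
    planted_log2fc: Mapping[str, float] = field(
        default_factory=lambda: {"up_in_b": 2.0, "up_in_a": -2.0, "neutral": 0.0}
    )
    expr_noise_sd: float = 0.2
    expr_frac_up_b: float = 0.1
    expr_frac_up_a: float = 0.05
    expr_base_log2: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ConfigError("baseline must be positive")
        if self.noise_sd < 0 or self.expr_noise_sd < 0:
            raise ConfigError("noise SDs must be non-negative")
        if not (0.0 <= self.frac_marked <= 1.0):
            raise ConfigError("frac_marked must lie in [0, 1]")
        if self.n_genes < 1 or self.probe_spacing < 1 or self.probe_length < 1:
            raise ConfigError("counts and probe geometry must be positive")

    def amplitude(self, condition: str, genotype: str) -> float:
        if isinstance(self.bump_amplitude, Mapping):
            try:
                return float(self.bump_amplitude[(genotype, condition)])
            except KeyError as exc:
                raise ConfigError(
                    f"no bump amplitude configured for ({genotype!r}, {condition!r})"
                ) from exc
        return float(self.bump_amplitude)


@dataclass
class SimGenome:
    genes: list[GeneModel]
    chrom_lengths: dict[str, int]
    sequences: dict[str, str]
    marked: frozenset[str]
    repeat_genes: frozenset[str]
    # per-gene enrichment propensity multiplying the bump amplitude; shared
    # across conditions/genotypes so the same genes run hot in every track
    enrichment: dict[str, float] = field(default_factory=dict)

    def gene_multiplier(self, gene_id: str) -> float:
        return self.enrichment.get(gene_id, 1.0)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def make_genome(cfg: SimConfig, with_sequence: bool = True) -> SimGenome:
    """Lay out non-overlapping genes on alternating strands.

    Intergenic gaps are widened where needed so every non-edge gene keeps
    ``upstream_clearance`` bp free of neighbouring genes upstream of its
    translational start. A ``frac_marked`` subset of genes is flagged to
    receive the promoter bump; a ``repeat_frac`` subset of those carries a
    planted (GA)_n or (AC)_n run in its promoter sequence.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.gene_length
    glo, ghi = cfg.intergenic
    genes: list[GeneModel] = []
    n_edge = int(round(cfg.edge_fraction * cfg.n_genes))
    pos = int(rng.integers(0, max(int(cfg.upstream_clearance), 1))) if n_edge else int(
        cfg.upstream_clearance + rng.integers(0, 1000)
    )
    for i in range(cfg.n_genes):
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if i % 2 == 0 else "-"
        gap = int(rng.integers(glo, ghi + 1))
        if i >= n_edge:
            # widen the gap so the upstream flank of whichever neighbour
            # points into it stays free of genes
            gap = max(gap, int(cfg.upstream_clearance))
        if i > 0:
            pos += gap
        genes.append(GeneModel(f"g{i:05d}", cfg.chrom, pos, pos + length, strand))
        pos += length
    chrom_length = pos + int(cfg.upstream_clearance) + cfg.probe_spacing
    if cfg.chrom_length is not None:
        if cfg.chrom_length < chrom_length:
            raise ConfigError(
                f"gene layout needs {chrom_length} bp but chrom_length is {cfg.chrom_length}"
            )
        chrom_length = cfg.chrom_length
    n_marked = int(round(cfg.frac_marked * cfg.n_genes))
    marked_idx = rng.choice(cfg.n_genes, size=n_marked, replace=False)
    marked = frozenset(genes[i].gene_id for i in marked_idx)
    n_repeat = int(round(cfg.repeat_frac * n_marked))
    repeat_idx = rng.choice(marked_idx, size=n_repeat, replace=False) if n_repeat else []
    repeat_genes = frozenset(genes[i].gene_id for i in repeat_idx)
    if cfg.amplitude_cv > 0:
        # lognormal with unit mean: mu = -sigma^2/2, cv^2 = exp(sigma^2) - 1
        sigma = float(np.sqrt(np.log1p(cfg.amplitude_cv**2)))
        draws = rng.lognormal(-0.5 * sigma**2, sigma, size=cfg.n_genes)
        enrichment = {g.gene_id: float(m) for g, m in zip(genes, draws)}
    else:
        enrichment = {}
    sequences: dict[str, str] = {}
    if with_sequence:
        seq = _random_sequence(rng, chrom_length)
        for i in repeat_idx:
            _plant_repeat(seq, genes[i], cfg, rng)
        sequences[cfg.chrom] = seq.tobytes().decode("ascii")
    return SimGenome(genes, {cfg.chrom: chrom_length}, sequences, marked, repeat_genes, enrichment)


def _plant_repeat(seq: np.ndarray, gene: GeneModel, cfg: SimConfig, rng: np.random.Generator) -> None:
    unit = cfg.repeat_units[int(rng.integers(0, len(cfg.repeat_units)))]
    run = np.frombuffer((unit * cfg.repeat_unit_len).encode(), dtype="S1")
    if gene.strand == "+":
        lo, hi = gene.start - cfg.promoter_len, gene.start
    else:
        lo, hi = gene.end, gene.end + cfg.promoter_len
    lo = max(lo, 0)
    hi = min(hi, len(seq))
    if hi - lo < len(run):
        return
    off = int(rng.integers(lo, hi - len(run) + 1))
    seq[off : off + len(run)] = run


def _probe_grid(cfg: SimConfig, chrom_length: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, chrom_length - cfg.probe_length + 1, cfg.probe_spacing, dtype=np.int64)
    return starts, starts + cfg.probe_length


def expected_values(genome: SimGenome, cfg: SimConfig, amplitude: float, midpoints: np.ndarray) -> np.ndarray:
    """Noise-free expected probe values at the given midpoints."""
    exp = np.full(len(midpoints), cfg.baseline, dtype=float)
    flank = cfg.upstream_clearance
    for gene in genome.genes:
        if gene.gene_id not in genome.marked:
            continue
        if gene.strand == "+":
            lo, hi = gene.start - flank, gene.end
        else:
            lo, hi = gene.start, gene.end + flank
        i0, i1 = np.searchsorted(midpoints, [lo, hi])
        if i1 <= i0:
            continue
        mid = midpoints[i0:i1]
        d = mid - gene.start if gene.strand == "+" else gene.end - mid
        gene_amp = amplitude * genome.gene_multiplier(gene.gene_id)
        bump = gene_amp * np.exp(-((d - cfg.bump_center) ** 2) / (2.0 * cfg.bump_sd**2))
        body = np.where(d >= 0, cfg.body_slope * d / 1000.0, 0.0)
        exp[i0:i1] += bump + body
    return exp


def _track_rng(cfg: SimConfig, condition: str, genotype: str, seed: int | None) -> np.random.Generator:
    base = cfg.seed if seed is None else seed
    return np.random.default_rng(
        [base, zlib.crc32(condition.encode()), zlib.crc32(genotype.encode())]
    )


def simulate_track(
    genome: SimGenome,
    cfg: SimConfig,
    condition: str = "starved",
    genotype: str = "wt",
    seed: int | None = None,
) -> SignalTrack:
    """Simulate one tiling-array fold-enrichment track.

    Probes tile every ``probe_spacing`` bp genome-wide. Marked genes add a
    Gaussian promoter bump with the configured amplitude for this
    (genotype, condition); unmarked genes see the flat baseline. Noise is
    additive Gaussian with SD ``noise_sd``, floored at ``value_floor``.
    """
    chrom = cfg.chrom
    chrom_length = genome.chrom_lengths[chrom]
    starts, ends = _probe_grid(cfg, chrom_length)
    mid = (starts + ends) / 2.0
    amplitude = cfg.amplitude(condition, genotype)
    values = expected_values(genome, cfg, amplitude, mid)
    if cfg.noise_sd > 0:
        rng = _track_rng(cfg, condition, genotype, seed)
        values = values + rng.normal(0.0, cfg.noise_sd, size=len(values))
    values = np.maximum(values, cfg.value_floor)
    return SignalTrack(f"{genotype}_{condition}", {chrom: (starts, ends, values)})


def promoter_sequences(
    genome: SimGenome, genes: Sequence[GeneModel] | None = None, length: int | None = None
) -> dict[str, str]:
    """Strand-oriented 5'->3' promoter sequences upstream of each start."""
    genes = genes if genes is not None else genome.genes
    out: dict[str, str] = {}
    for gene in genes:
        seq = genome.sequences[gene.chrom]
        n = length if length is not None else 500
        if gene.strand == "+":
            s = seq[max(gene.start - n, 0) : gene.start]
        else:
            raw = seq[gene.end : gene.end + n]
            s = raw.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
        out[gene.gene_id] = s
    return out


def simulate_expression(
    genes: Sequence[GeneModel],
    cfg: SimConfig,
    conditions: tuple[str, str] = ("starved", "fed"),
    classes: Mapping[str, str] | None = None,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Expression matrix with planted per-class log2 fold changes.

    Each gene draws a base log2 level, splits the planted effect
    symmetrically across the two conditions, and adds Gaussian log2 noise
    per sample. Values are returned on the linear scale. Also returns the
    true class assignment for recovery checks.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    gene_ids = [g.gene_id for g in genes]
    if classes is None:
        n = len(gene_ids)
        n_b = int(round(cfg.expr_frac_up_b * n))
        n_a = int(round(cfg.expr_frac_up_a * n))
        perm = rng.permutation(n)
        classes = {}
        for j, i in enumerate(perm):
            if j < n_b:
                classes[gene_ids[i]] = "up_in_b"
            elif j < n_b + n_a:
                classes[gene_ids[i]] = "up_in_a"
            else:
                classes[gene_ids[i]] = "neutral"
    effects = []
    for gid in gene_ids:
        cls = classes.get(gid, "neutral")
        if cls not in cfg.planted_log2fc:
            raise DataError(f"unknown expression class {cls!r} for gene {gid!r}")
        effects.append(cfg.planted_log2fc[cls])
    effects = np.asarray(effects, dtype=float)
    base = rng.normal(cfg.expr_base_log2, 1.0, size=len(gene_ids))
    log2_a = base - effects / 2.0 + rng.normal(0.0, cfg.expr_noise_sd, size=len(gene_ids))
    log2_b = base + effects / 2.0 + rng.normal(0.0, cfg.expr_noise_sd, size=len(gene_ids))
    df = pd.DataFrame(
        {conditions[0]: 2.0**log2_a, conditions[1]: 2.0**log2_b}, index=pd.Index(gene_ids, name="gene_id")
    )
    return ExpressionMatrix(df), dict(classes)


def expected_ratio(
    genome: SimGenome,
    cfg: SimConfig,
    amplitude: float,
    scheme: BinScheme | None = None,
    min_probes: int = 5,
) -> float:
    """Aggregate smoothed peak/nadir ratio of the noise-free expected profile.

    This pushes the generator's mean function through the identical
    binning + smoothing + ratio code path used for observed tracks, so it
    serves as the deterministic oracle for parameter-recovery checks.
    """
    scheme = scheme or BinScheme()
    marked = [g for g in genome.genes if g.gene_id in genome.marked]
    noise_free = replace(cfg, noise_sd=0.0, bump_amplitude=amplitude)
    track = simulate_track(genome, noise_free, "oracle", "oracle")
    profile = metagene_profile(track, marked, scheme, min_probes=min_probes)
    return peak_nadir_ratio(profile).ratio


def calibrate_amplitude(
    genome: SimGenome,
    cfg: SimConfig,
    target_ratio: float,
    scheme: BinScheme | None = None,
    a_max: float = 20.0,
) -> float:
    """Bump amplitude whose noise-free aggregate ratio equals ``target_ratio``.

    The whole binning/averaging/smoothing path is linear in probe values,
    so the expected profile at amplitude A is an affine combination of the
    A=0 and A=1 profiles; the ratio is then solved by root finding.
    """
    scheme = scheme or BinScheme()
    marked = [g for g in genome.genes if g.gene_id in genome.marked]
    base_cfg = replace(cfg, noise_sd=0.0)
    p0 = metagene_profile(
        simulate_track(genome, replace(base_cfg, bump_amplitude=0.0), "cal", "cal"), marked, scheme
    )
    p1 = metagene_profile(
        simulate_track(genome, replace(base_cfg, bump_amplitude=1.0), "cal", "cal"), marked, scheme
    )
    dm = p1.smoothed_mean - p0.smoothed_mean
    from .ratio_stats import default_body_bins, default_promoter_bins

    prom = list(default_promoter_bins(scheme))
    body = list(default_body_bins(scheme))

    def ratio_at(a: float) -> float:
        m = p0.smoothed_mean + a * dm
        return float(np.max(m[prom]) / np.min(m[body]))

    if target_ratio <= ratio_at(0.0):
        raise ConfigError(f"target ratio {target_ratio} not reachable with non-negative amplitude")
    return float(brentq(lambda a: ratio_at(a) - target_ratio, 0.0, a_max, xtol=1e-10))
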