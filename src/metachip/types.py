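"""Core domain containers shared by every stage of the pipeline.

Coordinates are 0-based half-open throughout (BED convention); formats
that use 1-based inclusive coordinates (GFF3, WIG) are converted at the
I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "SignalTrack",
    "GeneSet",
    "ExpressionMatrix",
    "BinScheme",
    "GeneProfile",
    "MetageneProfile",
    "ConfigError",
    "DataError",
]


class ConfigError(ValueError):
    """Invalid configuration; the CLI maps this to exit code 2."""


class DataError(ValueError):
    """Malformed or inconsistent input data; the CLI maps this to exit code 3."""


@dataclass(frozen=True)
class GeneModel:
    """One gene span (translational start to stop codon) with strand.

    ``start``/``end`` are 0-based half-open genomic coordinates; the
    translational start sits at ``start`` on the plus strand and at
    ``end`` on the minus strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError(
                f"gene {self.gene_id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tls(self) -> int:
        """Genomic coordinate of the translational start."""
        return self.start if self.strand == "+" else self.end


@dataclass
class SignalTrack:
    """Sorted, non-overlapping genomic intervals carrying one fold-enrichment value each.

    ``data`` maps chromosome name to ``(starts, ends, values)`` numpy arrays,
    sorted by start within each chromosome.
    """

    sample_id: str
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.data[chrom]

    def validate(self) -> None:
        for chrom, (starts, ends, values) in self.data.items():
            if not (len(starts) == len(ends) == len(values)):
                raise DataError(f"{chrom}: ragged interval arrays")
            if np.any(ends <= starts):
                i = int(np.argmax(ends <= starts))
                raise DataError(f"{chrom}: empty/inverted interval at [{starts[i]}, {ends[i]})")
            if np.any(np.diff(starts) < 0):
                raise DataError(f"{chrom}: intervals not sorted by start")
            if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise DataError(
                    f"{chrom}: overlapping intervals [{starts[i]}, {ends[i]}) and "
                    f"[{starts[i + 1]}, {ends[i + 1]})"
                )
            if not np.all(np.isfinite(values)):
                raise DataError(f"{chrom}: non-finite signal value")


@dataclass(frozen=True)
class GeneSet:
    """Named collection of gene identifiers within a defined universe."""

    name: str
    members: frozenset[str]
    universe_size: int

    def __post_init__(self) -> None:
        if len(self.members) > self.universe_size:
            raise DataError(
                f"gene set {self.name!r}: {len(self.members)} members exceed "
                f"universe of {self.universe_size}"
            )

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression levels on the linear scale.

    ``data`` is a rectangular DataFrame indexed by gene_id with one column
    per sample label (e.g. ``"wt:fed"``). No missing values are allowed
    after loading.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise DataError("expression matrix contains missing values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class BinScheme:
    """Metagene binning: upstream flank bins plus gene-body deciles.

    Defaults follow the tiling-array analysis this package reproduces:
    a 3 kb upstream flank in 20 bins, the gene body in 10 equal segments,
    and a centered 5-bin moving average for display/ratio curves.
    """

    n_body_bins: int = 10
    flank_bp: float = 3000.0
    n_flank_bins: int = 20
    smooth_window: int = 5

    def __post_init__(self) -> None:
        if min(self.n_body_bins, self.n_flank_bins, self.smooth_window) < 1 or self.flank_bp <= 0:
            raise ConfigError("all BinScheme parameters must be positive")
        if self.smooth_window % 2 == 0:
            raise ConfigError("smooth_window must be odd")

    @property
    def n_bins(self) -> int:
        return self.n_flank_bins + self.n_body_bins

    @property
    def bin_labels(self) -> list[str]:
        return [f"F{i + 1}" for i in range(self.n_flank_bins)] + [
            f"B{i + 1}" for i in range(self.n_body_bins)
        ]


@dataclass
class GeneProfile:
    """Per-gene binned signal: mean probe value and probe count per bin.

    Bins with no contributing probe have NaN mean and count 0.
    """

    gene_id: str
    bin_means: np.ndarray
    probe_counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_means = np.asarray(self.bin_means, dtype=float)
        self.probe_counts = np.asarray(self.probe_counts, dtype=int)
        if self.bin_means.shape != self.probe_counts.shape:
            raise DataError(f"gene {self.gene_id!r}: mean/count length mismatch")

    @property
    def n_bins(self) -> int:
        return len(self.bin_means)


@dataclass
class MetageneProfile:
    """Cross-gene aggregate profile: mean, SD, SE and gene count per bin.

    ``se = sd / sqrt(n_genes)`` wherever at least one gene contributes;
    the smoothed vectors are centered moving averages of mean and SE.
    """

    bin_labels: list[str]
    mean: np.ndarray
    sd: np.ndarray
    se: np.ndarray
    n_genes: np.ndarray
    smoothed_mean: np.ndarray
    smoothed_se: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_index": np.arange(self.n_bins),
                "bin_label": self.bin_labels,
                "mean": self.mean,
                "sd": self.sd,
                "se": self.se,
                "n_genes": self.n_genes,
                "smoothed_mean": self.smoothed_mean,
                "smoothed_se": self.smoothed_se,
            }
        )


def check_same_universe(sets: Mapping[str, GeneSet] | list[GeneSet]) -> int:
    """Return the shared universe size, raising if the sets disagree."""
    items = list(sets.values()) if isinstance(sets, Mapping) else list(sets)
    sizes = {s.universe_size for s in items}
    if len(sizes) != 1:
        raise DataError(f"gene sets drawn from different universes: sizes {sorted(sizes)}")
    return sizes.pop()
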