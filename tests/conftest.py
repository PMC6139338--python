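import numpy as np
import pytest

from metachip import BinScheme, GeneModel, SignalTrack


@pytest.fixture
def scheme():
    return BinScheme()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_track(chrom, triples, sample_id="t"):
    """Build a SignalTrack from (start, end, value) triples on one chromosome."""
    triples = sorted(triples)
    starts = np.array([t[0] for t in triples], dtype=np.int64)
    ends = np.array([t[1] for t in triples], dtype=np.int64)
    values = np.array([t[2] for t in triples], dtype=float)
    track = SignalTrack(sample_id, {chrom: (starts, ends, values)})
    track.validate()
    return track


def mirror_gene(gene: GeneModel, chrom_length: int) -> GeneModel:
    return GeneModel(
        gene.gene_id,
        gene.chrom,
        chrom_length - gene.end,
        chrom_length - gene.start,
        "-" if gene.strand == "+" else "+",
    )


def mirror_track(track: SignalTrack, chrom_length: int) -> SignalTrack:
    data = {}
    for chrom, (starts, ends, values) in track.data.items():
        data[chrom] = (
            (chrom_length - ends)[::-1].copy(),
            (chrom_length - starts)[::-1].copy(),
            values[::-1].copy(),
        )
    out = SignalTrack(track.sample_id, data)
    out.validate()
    return out


def brute_force_smooth(values, window):
    """Reference centered truncated moving average, skipping NaNs."""
    values = np.asarray(values, dtype=float)
    half = window // 2
    out = np.full(len(values), np.nan)
    for i in range(len(values)):
        acc = []
        for j in range(i - half, i + half + 1):
            if 0 <= j < len(values) and np.isfinite(values[j]):
                acc.append(values[j])
        if acc:
            out[i] = sum(acc) / len(acc)
    return out
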