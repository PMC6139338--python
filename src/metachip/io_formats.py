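"""Readers and writers for the standard text formats the pipeline touches.

BED, GFF3, bedGraph and WIG are line formats with fixed coordinate
conventions; everything is normalised to 0-based half-open coordinates on
the way in. Profile tables round-trip losslessly at 9 significant digits,
with missing values serialised as ``NA``.
"""
from __future__ import annotations

import logging
import math
import re
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    BinScheme,
    DataError,
    ExpressionMatrix,
    GeneModel,
    GeneSet,
    MetageneProfile,
    SignalTrack,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_gene_models",
    "read_signal_track",
    "read_gene_set",
    "write_gene_set",
    "write_profile_table",
    "read_profile_table",
    "read_fasta",
    "write_fasta",
    "write_gene_models_bed",
    "write_signal_track_bedgraph",
    "read_expression_tsv",
    "write_expression_tsv",
]

_GFF3_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def _detect_annotation_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        return "GFF3"
    if suffix == ".bed":
        return "BED"
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gff-version"):
                return "GFF3"
            break
    return "BED"


def read_gene_models(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Read gene models from BED6+ or GFF3 into 0-based half-open spans.

    GFF3 records (1-based, inclusive) are converted; multiple GFF3 features
    sharing one ID (mRNA/CDS structure) are collapsed to the min-start /
    max-end span of that ID. Input order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"annotation file not found: {path}")
    fmt = (format or _detect_annotation_format(path)).upper()
    if fmt == "BED":
        genes = _read_bed(path)
    elif fmt == "GFF3":
        genes = _read_gff3(path)
    else:
        raise DataError(f"unknown annotation format {format!r} (expected BED or GFF3)")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise DataError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def _read_bed(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise DataError(
                    f"{path}:{lineno}: BED needs >= 6 columns (strand required), got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer coordinates") from exc
            if e <= s:
                raise DataError(f"{path}:{lineno}: end ({e}) <= start ({s})")
            if strand not in ("+", "-"):
                raise DataError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            genes.append(GeneModel(name, chrom, s, e, strand))
    return genes


def _read_gff3(path: Path) -> list[GeneModel]:
    # Collapse features by ID: min start / max end defines the gene span.
    spans: dict[str, list] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise DataError(f"{path}:{lineno}: GFF3 needs 9 tab-separated columns")
            chrom, _src, _type, start, end, _score, strand, _phase, attrs = fields
            m = _GFF3_ID.search(attrs)
            if not m:
                raise DataError(f"{path}:{lineno}: GFF3 record lacks an ID attribute")
            gene_id = m.group(1)
            try:
                s1, e1 = int(start), int(end)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer coordinates") from exc
            s, e = s1 - 1, e1  # 1-based inclusive -> 0-based half-open
            if e <= s:
                raise DataError(f"{path}:{lineno}: end ({e1}) <= start ({s1}) after conversion")
            if strand not in ("+", "-"):
                raise DataError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            if gene_id not in spans:
                spans[gene_id] = [chrom, s, e, strand]
                order.append(gene_id)
            else:
                rec = spans[gene_id]
                if rec[0] != chrom or rec[3] != strand:
                    raise DataError(f"{path}:{lineno}: ID {gene_id!r} spans chromosomes/strands")
                rec[1] = min(rec[1], s)
                rec[2] = max(rec[2], e)
    return [GeneModel(gid, *spans[gid][:3], spans[gid][3]) for gid in order]


def _detect_signal_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                return "wig-fixed"
            if line.startswith("variableStep"):
                return "wig-variable"
            return "bedgraph"
    return "bedgraph"


def read_signal_track(
    path: str | Path, format: str | None = None, sample_id: str | None = None
) -> SignalTrack:
    """Read a bedGraph or WIG (fixedStep/variableStep) track.

    WIG 1-based starts are converted to 0-based. Intervals are sorted per
    chromosome; overlapping input intervals are an error because a track
    is single-valued.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"signal file not found: {path}")
    fmt = (format or _detect_signal_format(path)).lower()
    if fmt == "bedgraph":
        raw = _read_bedgraph(path)
    elif fmt in ("wig", "wig-fixed", "wig-variable"):
        raw = _read_wig(path)
    else:
        raise DataError(f"unknown signal format {format!r}")
    data = {}
    for chrom, rows in raw.items():
        rows.sort(key=lambda r: r[0])
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        values = np.array([r[2] for r in rows], dtype=float)
        data[chrom] = (starts, ends, values)
    track = SignalTrack(sample_id or path.stem, data)
    track.validate()
    return track


def _read_bedgraph(path: Path) -> dict[str, list]:
    raw: dict[str, list] = defaultdict(list)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise DataError(f"{path}:{lineno}: bedGraph needs 4 columns")
            chrom, start, end, value = fields[:4]
            try:
                s, e, v = int(start), int(end), float(value)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-numeric field") from exc
            if not math.isfinite(v):
                raise DataError(f"{path}:{lineno}: non-finite value")
            raw[chrom].append((s, e, v))
    return raw


def _parse_step_header(fields: Sequence[str], path: Path, lineno: int) -> dict[str, str]:
    out = {}
    for kv in fields[1:]:
        if "=" not in kv:
            raise DataError(f"{path}:{lineno}: malformed WIG declaration field {kv!r}")
        k, v = kv.split("=", 1)
        out[k] = v
    return out


def _read_wig(path: Path) -> dict[str, list]:
    raw: dict[str, list] = defaultdict(list)
    mode = None  # ("fixed", chrom, next_start0, step, span) | ("variable", chrom, span)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                h = _parse_step_header(line.split(), path, lineno)
                try:
                    start0 = int(h["start"]) - 1
                    step = int(h["step"])
                    span = int(h.get("span", 1))
                except (KeyError, ValueError) as exc:
                    raise DataError(f"{path}:{lineno}: bad fixedStep declaration") from exc
                mode = ["fixed", h["chrom"], start0, step, span]
                continue
            if line.startswith("variableStep"):
                h = _parse_step_header(line.split(), path, lineno)
                try:
                    span = int(h.get("span", 1))
                except ValueError as exc:
                    raise DataError(f"{path}:{lineno}: bad variableStep declaration") from exc
                mode = ["variable", h["chrom"], span]
                continue
            if mode is None:
                raise DataError(f"{path}:{lineno}: WIG data before any step declaration")
            if mode[0] == "fixed":
                try:
                    v = float(line)
                except ValueError as exc:
                    raise DataError(f"{path}:{lineno}: non-numeric WIG value") from exc
                _, chrom, start0, step, span = mode
                raw[chrom].append((start0, start0 + span, v))
                mode[2] = start0 + step
            else:
                fields = line.split()
                if len(fields) != 2:
                    raise DataError(f"{path}:{lineno}: variableStep lines need 2 columns")
                try:
                    pos0 = int(fields[0]) - 1
                    v = float(fields[1])
                except ValueError as exc:
                    raise DataError(f"{path}:{lineno}: non-numeric WIG value") from exc
                raw[mode[1]].append((pos0, pos0 + mode[2], v))
    return raw


def read_gene_set(
    path: str | Path, universe: Sequence[GeneModel] | Sequence[str], name: str | None = None
) -> GeneSet:
    """Read a one-id-per-line gene list, dropping ids absent from the universe.

    Unknown ids are logged and dropped; an empty file yields an empty set
    with a warning rather than an error.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"gene list not found: {path}")
    universe_ids = {g.gene_id if isinstance(g, GeneModel) else str(g) for g in universe}
    if not universe_ids:
        raise DataError("gene universe is empty")
    members, dropped = set(), []
    with open(path) as fh:
        for line in fh:
            gid = line.split("\t")[0].strip()
            if not gid or gid.startswith("#"):
                continue
            if gid in universe_ids:
                members.add(gid)
            else:
                dropped.append(gid)
    if dropped:
        logger.warning("%s: dropped %d ids absent from the universe", path, len(dropped))
    if not members:
        logger.warning("%s: empty gene set", path)
    return GeneSet(name or path.stem, frozenset(members), len(universe_ids))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(gene_set.members):
            fh.write(gid + "\n")


def _fmt(x: float) -> str:
    return "NA" if (x is None or not np.isfinite(x)) else format(float(x), ".9g")


def write_profile_table(profile: MetageneProfile, path: str | Path) -> None:
    """Write one row per bin; values at 9 significant digits, missing as NA."""
    df = profile.to_frame()
    with open(path, "w") as fh:
        fh.write("bin_index\tbin_label\tmean\tsd\tse\tn_genes\tsmoothed_mean\tsmoothed_se\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.bin_index}\t{row.bin_label}\t{_fmt(row.mean)}\t{_fmt(row.sd)}\t"
                f"{_fmt(row.se)}\t{row.n_genes}\t{_fmt(row.smoothed_mean)}\t{_fmt(row.smoothed_se)}\n"
            )


def read_profile_table(path: str | Path) -> MetageneProfile:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    return MetageneProfile(
        bin_labels=[str(x) for x in df["bin_label"]],
        mean=df["mean"].to_numpy(float),
        sd=df["sd"].to_numpy(float),
        se=df["se"].to_numpy(float),
        n_genes=df["n_genes"].to_numpy(int),
        smoothed_mean=df["smoothed_mean"].to_numpy(float),
        smoothed_se=df["smoothed_se"].to_numpy(float),
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gene_models_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_signal_track_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.intervals(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{format(v, '.9g')}\n")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", float_format="%.9g", index_label="gene_id")


def bin_scheme_from_config(cfg: dict) -> BinScheme:
    """Build a BinScheme from a ``binning:`` config mapping."""
    return BinScheme(
        n_body_bins=int(cfg.get("n_body_bins", 10)),
        flank_bp=float(cfg.get("flank_bp", 3000)),
        n_flank_bins=int(cfg.get("n_flank_bins", 20)),
        smooth_window=int(cfg.get("smooth_window", 5)),
    )
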