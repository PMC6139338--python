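"""Simulate the study's raw data: gene models, six ChIP tracks
(O-GlcNAc in wild type and the oga-1 cycling mutant, Pol II in ogt-1,
each starved and fed), promoter FASTA with planted repeat runs, and an
expression matrix — written as standard files under results/fixtures/."""
import json
from dataclasses import replace

from metachip import io_formats
from metachip.simulate import calibrate_amplitude, make_genome, promoter_sequences, simulate_expression, simulate_track
from metachip.types import GeneSet

from common import CHIP_CFG, FIXTURES, OGLCNAC_RATIOS, POLII_RATIOS, TRACKS, track_path


def main() -> None:
    FIXTURES.mkdir(parents=True, exist_ok=True)
    genome = make_genome(CHIP_CFG)
    io_formats.write_gene_models_bed(genome.genes, FIXTURES / "genes.bed")
    io_formats.write_gene_set(
        GeneSet("marked", genome.marked, len(genome.genes)), FIXTURES / "marked_genes.txt"
    )

    targets = {**OGLCNAC_RATIOS, **POLII_RATIOS}
    amplitudes = {key: calibrate_amplitude(genome, CHIP_CFG, r) for key, r in targets.items()}
    with open(FIXTURES / "amplitudes.json", "w") as fh:
        json.dump({f"{g}:{c}": a for (g, c), a in amplitudes.items()}, fh, indent=2)
    cfg = replace(CHIP_CFG, bump_amplitude=amplitudes)
    for sample, (genotype, condition) in TRACKS.items():
        track = simulate_track(genome, cfg, condition, genotype)
        io_formats.write_signal_track_bedgraph(track, track_path(sample))
        print(f"wrote {sample}: amplitude {amplitudes[(genotype, condition)]:.3f} "
              f"(nominal ratio {targets[(genotype, condition)]})")

    promoters = promoter_sequences(genome, length=CHIP_CFG.promoter_len)
    io_formats.write_fasta(promoters, FIXTURES / "promoters.fasta")
    expr, classes = simulate_expression(genome.genes, CHIP_CFG)
    io_formats.write_expression_tsv(expr, FIXTURES / "expression.tsv")
    print(f"simulated {len(genome.genes)} genes, {len(genome.repeat_genes)} promoters "
          f"with planted repeats, expression for {len(expr.genes)} genes")


if __name__ == "__main__":
    main()
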