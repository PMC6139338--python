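"""Gene-set overlap: Venn-region counts among the delta-ranked bins and
the marked cohort, and a one-sided Fisher test of the marked set against
an independently drawn 'paused Pol II' set. The Fisher universe is the
genome-wide gene count, not the profiled cohort: the marked genes are a
small thresholded subset of the annotation."""
import json

import numpy as np

from metachip import GeneSet, fisher_overlap, io_formats, overlap_counts

from common import RESULTS, FIXTURES, SEED

GENOME_WIDE_N = 17000  # annotation-scale universe for the Fisher tests
N_PAUSED = 358


def main() -> None:
    genes = io_formats.read_gene_models(FIXTURES / "genes.bed")
    cohort = [g.gene_id for g in genes]
    top = io_formats.read_gene_set(RESULTS / "delta_top.txt", cohort)
    bottom = io_formats.read_gene_set(RESULTS / "delta_bottom.txt", cohort)
    marked = io_formats.read_gene_set(FIXTURES / "marked_genes.txt", cohort)

    venn = overlap_counts([top, bottom, marked])
    with open(RESULTS / "overlap_counts.tsv", "w") as fh:
        fh.write("region\tcount\n")
        for key in sorted(venn.region_counts):
            fh.write("&".join(key) + f"\t{venn.region_counts[key]}\n")

    # embed the cohort in a genome-scale universe and draw an unrelated
    # 'paused' set of the size of published promoter-proximal Pol II lists
    universe = cohort + [f"x{i:05d}" for i in range(GENOME_WIDE_N - len(cohort))]
    rng = np.random.default_rng(SEED + 40)
    paused = GeneSet(
        "paused", frozenset(rng.choice(universe, N_PAUSED, replace=False)), GENOME_WIDE_N
    )
    wide = {
        gs.name: GeneSet(gs.name, gs.members, GENOME_WIDE_N) for gs in (top, bottom, marked)
    }
    tests = []
    pairs = [
        (wide["delta_top"], wide["delta_bottom"]),
        (wide["delta_top"], wide["marked_genes"]),
        (wide["marked_genes"], paused),
    ]
    for a, b in pairs:
        res = fisher_overlap(a, b)
        tests.append({"set_a": a.name, "set_b": b.name, "k": res.k, "p": res.p_value,
                      "universe": GENOME_WIDE_N})
        verdict = "enriched" if res.p_value < 0.05 else "consistent with chance"
        print(f"{a.name} vs {b.name}: k={res.k}, one-sided Fisher p={res.p_value:.3g} ({verdict})")
    with open(RESULTS / "overlap_fisher.json", "w") as fh:
        json.dump(tests, fh, indent=2)


if __name__ == "__main__":
    main()
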