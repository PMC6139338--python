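"""Nutrient-responsiveness of promoter O-GlcNAc and of expression.

Ranks genes by the fed-minus-starved promoter signal difference in the
O-GlcNAcase mutant (delta signal), selects 100-gene bins from the top,
middle and bottom of the ranking, and classifies expression responsiveness
at the inclusive |log2FC| >= 1.5 (2.8-fold) threshold."""
from collections import Counter

from metachip import (
    BinScheme,
    classify_responsive,
    delta_signal,
    io_formats,
    profile_genes,
    select_rank_bins,
)

from common import RESULTS, FIXTURES, track_path


def main() -> None:
    scheme = BinScheme()
    genes = io_formats.read_gene_models(FIXTURES / "genes.bed")
    fed = io_formats.read_signal_track(track_path("oga1_fed"))
    starved = io_formats.read_signal_track(track_path("oga1_starved"))
    pf, _ = profile_genes(fed, genes, scheme)
    ps, _ = profile_genes(starved, genes, scheme)
    records, n_excl = delta_signal(pf, ps)

    with open(RESULTS / "delta_rank.tsv", "w") as fh:
        fh.write("gene_id\tfed\tstarved\tdelta\trank\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.signal_fed:.6g}\t{r.signal_starved:.6g}\t{r.delta:.6g}\t{r.rank}\n")
    top, middle, bottom = select_rank_bins(records, bin_size=100)
    for gs in (top, middle, bottom):
        io_formats.write_gene_set(gs, RESULTS / f"{gs.name}.txt")
    by_rank = {r.gene_id: r.delta for r in records}
    print(f"ranked {len(records)} genes ({n_excl} excluded)")
    for gs in (top, middle, bottom):
        mean = sum(by_rank[g] for g in gs.members) / len(gs)
        print(f"  {gs.name}: mean delta {mean:+.3f}")

    expr = io_formats.read_expression_tsv(FIXTURES / "expression.tsv")
    calls = classify_responsive(expr, "starved", "fed", threshold_log2=1.5)
    counts = Counter(c.call for c in calls)
    with open(RESULTS / "responsive_calls.tsv", "w") as fh:
        fh.write("gene_id\tlog2fc\tcall\n")
        for c in calls:
            fh.write(f"{c.gene_id}\t{c.log2fc:.6g}\t{c.call}\n")
    print(
        f"expression calls at |log2FC|>=1.5: {counts['up_in_b']} up in fed, "
        f"{counts['up_in_a']} up in starved, {counts['unresponsive']} unresponsive"
    )


if __name__ == "__main__":
    main()
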