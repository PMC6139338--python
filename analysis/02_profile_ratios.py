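"""Metagene profiles and promoter-peak/body-nadir ratio statistics.

Reads the simulated tracks from results/fixtures/, bins each gene onto
the 20-flank-bin + 10-decile metagene, aggregates across the cohort and
compares starved vs fed ratios per genotype with both the propagated-SE
z test and the per-gene Welch t test. Writes one profile TSV per track
and a ratios.json summary."""
import json

from metachip import (
    BinScheme,
    aggregate,
    compare_ratios,
    io_formats,
    peak_nadir_ratio,
    per_gene_ratios,
    profile_genes,
)

from common import RESULTS, FIXTURES, TRACKS, track_path


def main() -> None:
    scheme = BinScheme()
    genes = io_formats.read_gene_models(FIXTURES / "genes.bed")
    outdir = RESULTS / "profiles"
    outdir.mkdir(parents=True, exist_ok=True)

    stats, per_gene = {}, {}
    for sample, (genotype, condition) in TRACKS.items():
        track = io_formats.read_signal_track(track_path(sample))
        profiles, _ = profile_genes(track, genes, scheme)
        agg = aggregate(profiles, scheme.smooth_window)
        io_formats.write_profile_table(agg, outdir / f"{sample}.tsv")
        stats[(genotype, condition)] = peak_nadir_ratio(agg)
        ratios, _ = per_gene_ratios(profiles, scheme=scheme)
        per_gene[(genotype, condition)] = [r for _, r in ratios]

    report = []
    for genotype in ("wt", "oga-1", "ogt-1"):
        st, fd = stats[(genotype, "starved")], stats[(genotype, "fed")]
        cmp_z = compare_ratios(st, fd, "z_propagated")
        cmp_w = compare_ratios(
            st, fd, "welch_per_gene", per_gene[(genotype, "starved")], per_gene[(genotype, "fed")]
        )
        report.append(
            {
                "genotype": genotype,
                "ratio_starved": st.ratio,
                "se_starved": st.se_ratio,
                "ratio_fed": fd.ratio,
                "se_fed": fd.se_ratio,
                "p_z": cmp_z.p_value,
                "p_welch": cmp_w.p_value,
            }
        )
        verdict = "differs" if cmp_z.p_value < 0.05 else "no significant change"
        print(
            f"{genotype}: starved {st.ratio:.2f}±{st.se_ratio:.2f} vs "
            f"fed {fd.ratio:.2f}±{fd.se_ratio:.2f} -> p_z={cmp_z.p_value:.3g} ({verdict})"
        )
    with open(RESULTS / "ratios.json", "w") as fh:
        json.dump(report, fh, indent=2)


if __name__ == "__main__":
    main()
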