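# metachip

Metagene analysis of promoter-biased ChIP signal on whole-genome tiling
arrays, built around the question of how promoter *O*-GlcNAc marks and RNA
polymerase II occupancy respond to nutrient flux in *C. elegans* L1 larvae.
The package is aimed at analysts working with normalized tiling-array (or
tiling-array-like) fold-enrichment tracks who want promoter-bias statistics
with honest error bars, plus the downstream comparisons such studies lean
on: nutrient-responsiveness ranking, gene-set overlap testing and promoter
repeat-motif enrichment.

## The statistics at the core

**Metagene binning.** Each gene (translational start → stop) is projected
onto a common model: 20 bins covering a 3 kb upstream flank (F1 most
distal) followed by 10 equal gene-body segments (B1..B10). Each tiling
probe contributes its fold-enrichment value to the bin containing its
midpoint; per-gene bin means are then averaged across the cohort, so for
bin *j* over *n* genes

    SE_j = SD_j / sqrt(n)

with SD the cross-gene sample standard deviation. Display and ratio curves
are smoothed with a centered 5-bin moving average.

**Promoter-peak / body-nadir ratio.** The promoter-bias statistic is

    R = max_{j in promoter} m_j  /  min_{j in body} m_j

with the delta-method standard error under independence

    SE_R = R * sqrt( (SE_peak/peak)^2 + (SE_nadir/nadir)^2 ).

Two conditions are compared either by a normal z test on the propagated
SEs or by a Welch unequal-variance t test on per-gene ratios.

**Downstream stages.** Delta signal (fed − starved promoter mean) ranks
nutrient responsiveness, with 100-gene bins drawn from the top, middle and
bottom of the ranking; expression responsiveness uses an inclusive
|log2 FC| ≥ 1.5 (2.8-fold) threshold; gene-set overlaps get one-sided
Fisher exact (hypergeometric upper-tail) tests against an explicit,
genome-wide universe; promoter 8-mers (reverse-complement collapsed) are
scored against background sequence with upper-tail binomial tests and
Benjamini–Hochberg correction.

A seeded synthetic-data generator (`metachip.simulate`) produces toy
genomes, tiling tracks with a Gaussian promoter enrichment bump of
condition/genotype-dependent amplitude, promoter FASTA with optional
planted (GA)/(AC) repeat runs, and expression matrices with planted fold
changes — the known-truth substrate for every test in the suite.

## Worked example

```python
from metachip import BinScheme, aggregate, compare_ratios, peak_nadir_ratio, profile_genes
from metachip.simulate import SimConfig, make_genome, simulate_track

cfg = SimConfig(n_genes=827, seed=1, noise_sd=0.2,
                bump_amplitude={("wt", "starved"): 1.60, ("wt", "fed"): 1.48})
genome = make_genome(cfg, with_sequence=False)
stats = {}
for cond in ("starved", "fed"):
    track = simulate_track(genome, cfg, cond, "wt")
    profiles, _ = profile_genes(track, genome.genes, BinScheme())
    stats[cond] = peak_nadir_ratio(aggregate(profiles))
cmp = compare_ratios(stats["starved"], stats["fed"])
print(f"starved {stats['starved'].ratio:.2f}±{stats['starved'].se_ratio:.2f}  "
      f"fed {stats['fed'].ratio:.2f}±{stats['fed'].se_ratio:.2f}  p={cmp.p_value:.3f}")
```

prints

```
starved 2.34±0.01  fed 2.24±0.01  p=0.000
```

i.e. the starved-condition promoter peak sits 2.34-fold above the gene-body
nadir, the fed track 2.24-fold, and with homogeneous per-gene amplitudes the
cohort SEs are so tight that the 0.1 difference registers overwhelmingly.
With realistic per-gene amplitude dispersion (`amplitude_cv=2.5`, the
emulated-study default in `analysis/`) the same comparison yields SEs near
±0.09 and p ≈ 0.44 — no detectable change, the buffered-promoter picture.

## The analysis, step by step

Numbered drivers under `analysis/` run the whole study on simulated data
and write their tables under `results/`:

```sh
cd analysis
python 01_simulate.py          # genome, 6 ChIP tracks, promoters, expression
python 02_profile_ratios.py    # metagene profiles + ratio statistics per genotype
python 03_rank_responsiveness.py  # delta-signal ranking + expression calls
python 04_overlap.py           # Venn counts + Fisher overlap tests
python 05_motifs.py            # promoter 8-mer enrichment
```

The same stages are available behind one CLI (`metachip simulate|profile|
rank|overlap|motif --config <yaml> --outdir <dir>`); a packaged demo config
lives at `src/metachip/data/demo_config.yaml`.

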