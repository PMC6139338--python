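"""Shared configuration of the simulated tiling-array study driven by the
numbered analysis scripts. Amplitudes are calibrated at simulation time so
the noise-free aggregate ratios hit the study's nominal peak/nadir ratios;
the per-gene amplitude dispersion puts the propagated SEs on a realistic
scale for an 827-gene cohort (see docs/methods.md)."""
from pathlib import Path

from metachip.simulate import SimConfig

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"
FIXTURES = RESULTS / "fixtures"

# nominal aggregate peak/nadir ratios per (genotype, condition)
OGLCNAC_RATIOS = {
    ("wt", "starved"): 2.30,
    ("wt", "fed"): 2.20,
    ("oga-1", "starved"): 2.11,
    ("oga-1", "fed"): 2.62,
}
POLII_RATIOS = {("ogt-1", "starved"): 1.81, ("ogt-1", "fed"): 1.57}

CHIP_CFG = SimConfig(
    n_genes=827,
    seed=SEED,
    noise_sd=0.2,
    amplitude_cv=2.5,
    frac_marked=1.0,
    repeat_frac=0.3,
)

TRACKS = {
    f"{g}_{c}".replace("-", ""): (g, c) for (g, c) in {**OGLCNAC_RATIOS, **POLII_RATIOS}
}


def track_path(sample: str) -> Path:
    return FIXTURES / f"{sample}.bedgraph"
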