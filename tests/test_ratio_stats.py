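import numpy as np
import pytest
from scipy import stats as sps

from metachip import (
    BinScheme,
    DataError,
    GeneProfile,
    MetageneProfile,
    aggregate,
    compare_ratios,
    peak_nadir_ratio,
    per_gene_ratios,
    smooth,
)
from metachip.ratio_stats import RatioStat, propagate_ratio_se
from metachip.simulate import SimConfig, make_genome, simulate_track
from metachip.metagene import profile_genes


def make_aggregate(mean, se=None, n=100):
    mean = np.asarray(mean, dtype=float)
    se = np.zeros_like(mean) if se is None else np.asarray(se, dtype=float)
    sd = se * np.sqrt(n)
    labels = BinScheme().bin_labels[: len(mean)]
    return MetageneProfile(labels, mean, sd, se, np.full(len(mean), n), mean.copy(), se.copy())


def stat(ratio, se_ratio):
    return RatioStat(ratio, 0.0, 0, 1.0, 0.0, 21, ratio, se_ratio, 100, 100)


class TestPeakNadirRatio:
    def test_zero_error_limit(self):
        mean = np.ones(30)
        mean[18] = 2.0  # promoter peak
        prof = make_aggregate(mean)
        rs = peak_nadir_ratio(prof, use_smoothed=False)
        assert rs.ratio == 2.0 and rs.se_ratio == 0.0
        assert rs.peak_bin == 18

    def test_closed_form_error_propagation(self):
        mean = np.full(30, 1.5)
        mean[10] = 3.0
        se = np.full(30, 0.15)
        se[10] = 0.3
        rs = peak_nadir_ratio(make_aggregate(mean, se), use_smoothed=False)
        assert rs.ratio == pytest.approx(2.0)
        assert rs.se_ratio == pytest.approx(2.0 * np.sqrt(0.01 + 0.01))
        assert rs.se_ratio == pytest.approx(0.2828, abs=1e-4)

    def test_ties_break_to_lowest_bin_index(self):
        mean = np.ones(30)
        mean[[3, 7]] = 2.0
        mean[[22, 25]] = 0.5
        rs = peak_nadir_ratio(make_aggregate(mean), use_smoothed=False)
        assert rs.peak_bin == 3 and rs.nadir_bin == 22

    def test_nonpositive_nadir_rejected(self):
        mean = np.ones(30)
        mean[25] = 0.0
        with pytest.raises(DataError, match="nadir"):
            peak_nadir_ratio(make_aggregate(mean), use_smoothed=False)

    def test_overlapping_windows_rejected(self):
        prof = make_aggregate(np.ones(30))
        with pytest.raises(DataError, match="disjoint"):
            peak_nadir_ratio(prof, promoter_bins=range(0, 22), body_bins=range(21, 30))

    def test_se_ratio_identity_random_inputs(self, rng):
        for _ in range(200):
            peak, nadir = rng.uniform(0.5, 5.0, 2)
            se_p, se_n = rng.uniform(0.0, 0.5, 2)
            got = propagate_ratio_se(peak, se_p, nadir, se_n)
            want = (peak / nadir) * np.sqrt((se_p / peak) ** 2 + (se_n / nadir) ** 2)
            assert got == pytest.approx(want, abs=1e-14)

    def test_scale_invariance(self, rng):
        raw = rng.normal(2.0, 0.3, size=(50, 30)).clip(0.5)
        profiles = [GeneProfile(f"g{i}", raw[i], np.ones(30, int)) for i in range(50)]
        base = peak_nadir_ratio(aggregate(profiles))
        c = 3.7
        scaled = [GeneProfile(f"g{i}", c * raw[i], np.ones(30, int)) for i in range(50)]
        lift = peak_nadir_ratio(aggregate(scaled))
        assert lift.ratio == pytest.approx(base.ratio, rel=1e-12)
        assert lift.se_ratio / lift.ratio == pytest.approx(base.se_ratio / base.ratio, rel=1e-9)


class TestPerGeneRatios:
    def test_constant_profile_gives_unit_ratio(self):
        profiles = [GeneProfile("g", np.full(30, 4.2), np.ones(30, int))]
        ratios, n_excl = per_gene_ratios(profiles)
        assert ratios == [("g", 1.0)] and n_excl == 0

    def test_gene_missing_body_excluded_and_counted(self):
        vals = np.full(30, 2.0)
        vals[21:] = np.nan
        profiles = [
            GeneProfile("missing_body", vals, np.where(np.isfinite(vals), 1, 0)),
            GeneProfile("ok", np.full(30, 2.0), np.ones(30, int)),
        ]
        ratios, n_excl = per_gene_ratios(profiles)
        assert [g for g, _ in ratios] == ["ok"] and n_excl == 1

    def test_noise_free_cohort_matches_expected_profile_oracle(self, scheme):
        # With no noise every per-gene ratio equals the value obtained by
        # binning + smoothing the generator's mean function for that gene.
        cfg = SimConfig(n_genes=12, seed=2, noise_sd=0.0, bump_amplitude=1.5)
        genome = make_genome(cfg, with_sequence=False)
        track = simulate_track(genome, cfg, "starved", "wt")
        profiles, _ = profile_genes(track, genome.genes, scheme)
        ratios, n_excl = per_gene_ratios(profiles, scheme=scheme)
        assert n_excl == 0
        for gene, (gid, ratio) in zip(genome.genes, ratios):
            # independent oracle: evaluate the mean function on this gene's
            # probes, bin by brute force over d-space, smooth, take max/min
            starts, ends, values = track.intervals(gene.chrom)
            mids = (starts + ends) / 2.0
            d = mids - gene.start if gene.strand == "+" else gene.end - mids
            edges = np.concatenate(
                [
                    np.linspace(-scheme.flank_bp, 0, scheme.n_flank_bins + 1)[:-1],
                    np.linspace(0, gene.length, scheme.n_body_bins + 1),
                ]
            )
            means = np.full(scheme.n_bins, np.nan)
            for b in range(scheme.n_bins):
                lo, hi = edges[b], edges[b + 1]
                sel = (d > lo) & (d <= hi) if b else (d >= lo) & (d <= hi)
                if sel.any():
                    means[b] = values[sel].mean()
            sm = smooth(means, scheme.smooth_window)
            want = np.nanmax(sm[:21]) / np.nanmin(sm[21:])
            assert ratio == pytest.approx(want, rel=1e-12), gid


class TestCompareRatios:
    def test_identical_stats_give_p_one(self):
        a = stat(2.0, 0.1)
        cmp = compare_ratios(a, a)
        assert cmp.statistic == 0.0 and cmp.p_value == 1.0

    def test_z_example_against_normal_cdf(self):
        cmp = compare_ratios(stat(2.0, 0.1), stat(2.5, 0.1))
        assert cmp.statistic == pytest.approx(-3.5355, abs=1e-4)
        assert cmp.p_value == pytest.approx(4.07e-4, rel=5e-3)
        assert cmp.p_value == pytest.approx(2 * sps.norm.sf(3.53553), rel=1e-4)

    def test_zero_se_distinct_ratios_give_p_zero_with_warning(self):
        with pytest.warns(UserWarning):
            cmp = compare_ratios(stat(2.0, 0.0), stat(2.5, 0.0))
        assert cmp.p_value == 0.0

    def test_antisymmetry(self, rng):
        a, b = stat(2.3, 0.09), stat(2.62, 0.11)
        ab = compare_ratios(a, b)
        ba = compare_ratios(b, a)
        assert ab.p_value == pytest.approx(ba.p_value, rel=1e-12)
        assert ab.statistic == pytest.approx(-ba.statistic, rel=1e-12)

    def test_welch_matches_scipy_and_is_symmetric(self, rng):
        x = rng.normal(2.0, 0.4, 60)
        y = rng.normal(2.2, 0.5, 45)
        cmp = compare_ratios(stat(2.0, 0.1), stat(2.2, 0.1), "welch_per_gene", x, y)
        want = sps.ttest_ind(x, y, equal_var=False)
        assert cmp.statistic == pytest.approx(want.statistic)
        assert cmp.p_value == pytest.approx(want.pvalue)
        rev = compare_ratios(stat(2.2, 0.1), stat(2.0, 0.1), "welch_per_gene", y, x)
        assert rev.statistic == pytest.approx(-cmp.statistic)
        assert rev.p_value == pytest.approx(cmp.p_value)

    def test_welch_requires_samples(self):
        with pytest.raises(DataError):
            compare_ratios(stat(2.0, 0.1), stat(2.1, 0.1), "welch_per_gene")

    def test_unknown_method_rejected(self):
        with pytest.raises(DataError):
            compare_ratios(stat(2.0, 0.1), stat(2.1, 0.1), "anova")
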