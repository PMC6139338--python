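import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metachip import (
    BinScheme,
    DataError,
    GeneModel,
    GeneProfile,
    aggregate,
    assign_bins,
    gene_profile,
    metagene_profile,
    smooth,
)
from metachip.simulate import SimConfig, make_genome, simulate_track

from conftest import brute_force_smooth, make_track, mirror_gene, mirror_track


class TestAssignBins:
    def test_plus_strand_flank_and_first_body_bin(self, scheme):
        gene = GeneModel("g", "chrI", 3000, 4000, "+")
        bins = dict(assign_bins(gene, scheme, 10000))
        assert bins[19] == (2850.0, 3000.0)
        assert bins[20] == (3000.0, 3100.0)

    def test_minus_strand_is_mirrored(self, scheme):
        gene = GeneModel("g", "chrI", 3000, 4000, "-")
        bins = dict(assign_bins(gene, scheme, 8000))
        assert bins[0] == (6850.0, 7000.0)
        assert bins[20] == (3900.0, 4000.0)

    def test_flank_clipped_at_chromosome_start(self, scheme):
        gene = GeneModel("g", "chrI", 1000, 2000, "+")
        bins = dict(assign_bins(gene, scheme, 10000))
        # flank would span [-2000, 1000); bins wholly below position 0 are absent
        assert all(bins[i] is None for i in range(13))
        assert bins[13] == (0.0, 100.0)
        covered = [bins[i] for i in range(13, 20)]
        assert covered[0][0] == 0.0 and covered[-1][1] == 1000.0

    def test_bins_are_ordered_5prime_to_3prime(self, scheme):
        gene = GeneModel("g", "chrI", 50000, 52000, "-")
        bins = [iv for _, iv in assign_bins(gene, scheme, 100000)]
        # minus strand: genomic coordinates decrease along the metagene
        starts = [iv[0] for iv in bins]
        assert starts == sorted(starts, reverse=True)

    def test_gene_past_chromosome_end_errors(self, scheme):
        gene = GeneModel("g", "chrI", 3000, 4000, "+")
        with pytest.raises(DataError):
            assign_bins(gene, scheme, 3500)


class TestGeneProfile:
    def test_constant_track_gives_constant_bins(self, scheme):
        gene = GeneModel("g", "chrI", 3000, 4000, "+")
        track = make_track("chrI", [(s, s + 50, 2.5) for s in range(0, 5000, 50)])
        prof = gene_profile(track, gene, scheme)
        present = np.isfinite(prof.bin_means)
        assert present.all()
        np.testing.assert_allclose(prof.bin_means[present], 2.5)

    def test_probe_midpoint_decides_the_bin(self, scheme):
        gene = GeneModel("g", "chrI", 3000, 4000, "+")
        track = make_track("chrI", [(3000, 3050, 2.0)])  # midpoint 3025 -> B1 only
        prof = gene_profile(track, gene, scheme)
        assert prof.probe_counts[20] == 1 and prof.bin_means[20] == 2.0
        assert prof.probe_counts.sum() == 1

    def test_two_probes_in_one_bin_average_unweighted(self, scheme):
        gene = GeneModel("g", "chrI", 3000, 4000, "+")
        track = make_track("chrI", [(3000, 3020, 1.0), (3040, 3060, 3.0)])
        prof = gene_profile(track, gene, scheme)
        assert prof.bin_means[20] == 2.0 and prof.probe_counts[20] == 2

    def test_missing_chromosome_gives_all_missing_profile(self, scheme, caplog):
        gene = GeneModel("g", "chrX", 3000, 4000, "+")
        track = make_track("chrI", [(0, 50, 1.0)])
        with caplog.at_level("WARNING"):
            prof = gene_profile(track, gene, scheme)
        assert np.isnan(prof.bin_means).all()
        assert "chrX" in caplog.text

    def test_mass_conservation_per_gene(self, scheme, rng):
        # total probe mass assigned to bins equals the sum of assigned values
        gene = GeneModel("g", "chrI", 5000, 7000, "-")
        probes = [(s, s + 50, float(rng.lognormal(0, 0.5))) for s in range(0, 12000, 50)]
        track = make_track("chrI", probes)
        prof = gene_profile(track, gene, scheme)
        binned_mass = np.nansum(prof.bin_means * prof.probe_counts)
        mids = np.array([(s + e) / 2 for s, e, _ in probes])
        vals = np.array([v for _, _, v in probes])
        d = gene.end - mids
        inside = (d >= -scheme.flank_bp) & (d <= gene.length)
        assert binned_mass == pytest.approx(vals[inside].sum())

    def test_affine_track_recovers_function_at_bin_midpoints(self, scheme):
        # probes aligned with bin edges: bin mean == affine function at bin center
        a, b = 2.0, 1e-3
        gene = GeneModel("g", "chrI", 3000, 4000, "+")
        probes = [(s, s + 50, a + b * (s + 25.0)) for s in range(0, 6000, 50)]
        prof = gene_profile(make_track("chrI", probes), gene, scheme)
        edges = np.concatenate([np.linspace(0.0, 3000.0, 21)[:-1] + 75.0, 3000 + np.linspace(0.0, 1000.0, 11)[:-1] + 50.0])
        np.testing.assert_allclose(prof.bin_means, a + b * edges)


class TestStrandSymmetry:
    def test_mirrored_genome_gives_identical_profiles(self, scheme):
        cfg = SimConfig(n_genes=30, seed=11, noise_sd=0.3)
        genome = make_genome(cfg, with_sequence=False)
        track = simulate_track(genome, cfg, "starved", "wt")
        L = genome.chrom_lengths[cfg.chrom]
        m_track = mirror_track(track, L)
        for gene in genome.genes:
            fwd = gene_profile(track, gene, scheme)
            rev = gene_profile(m_track, mirror_gene(gene, L), scheme)
            np.testing.assert_array_equal(fwd.probe_counts, rev.probe_counts)
            np.testing.assert_allclose(fwd.bin_means, rev.bin_means, equal_nan=True)


class TestAggregate:
    def p(self, gid, values):
        values = np.asarray(values, dtype=float)
        return GeneProfile(gid, values, np.where(np.isfinite(values), 1, 0))

    def test_identical_profiles_have_zero_sd_and_se(self):
        prof = aggregate([self.p(f"g{i}", [1.0, 2.0, 3.0]) for i in range(5)], smooth_window=1)
        np.testing.assert_allclose(prof.mean, [1, 2, 3])
        np.testing.assert_allclose(prof.sd, 0)
        np.testing.assert_allclose(prof.se, 0)
        assert prof.n_genes.tolist() == [5, 5, 5]

    def test_two_gene_closed_form(self):
        prof = aggregate([self.p("a", [1.0]), self.p("b", [3.0])], smooth_window=1)
        assert prof.mean[0] == 2.0
        assert prof.sd[0] == pytest.approx(np.sqrt(2))
        assert prof.se[0] == pytest.approx(1.0)

    def test_single_contributor_bin_has_missing_sd_se(self):
        prof = aggregate([self.p("a", [1.0, np.nan]), self.p("b", [3.0, 5.0])], smooth_window=1)
        assert prof.n_genes.tolist() == [2, 1]
        assert prof.mean[1] == 5.0
        assert np.isnan(prof.sd[1]) and np.isnan(prof.se[1])

    def test_se_identity_against_sd(self, rng):
        profiles = [self.p(f"g{i}", rng.normal(2, 0.5, 30)) for i in range(40)]
        prof = aggregate(profiles)
        np.testing.assert_allclose(prof.se, prof.sd / np.sqrt(prof.n_genes))

    def test_empty_input_errors(self):
        with pytest.raises(DataError):
            aggregate([])


class TestSmooth:
    def test_constant_vector_unchanged(self):
        np.testing.assert_allclose(smooth(np.full(30, 1.7), 5), 1.7)

    def test_impulse_example(self):
        v = np.array([0, 0, 0, 0, 5, 0, 0, 0, 0], dtype=float)
        out = smooth(v, 5)
        np.testing.assert_allclose(out[2:7], 1.0)
        np.testing.assert_allclose(out[[0, 1, 7, 8]], 0.0)

    def test_even_window_rejected(self):
        with pytest.raises(DataError):
            smooth(np.ones(10), 4)

    @settings(max_examples=50, derandomize=True)
    @given(
        values=st.lists(
            st.one_of(st.floats(-10, 10), st.just(float("nan"))), min_size=1, max_size=60
        ),
        window=st.sampled_from([1, 3, 5, 7]),
    )
    def test_matches_brute_force_windowed_mean(self, values, window):
        got = smooth(np.array(values), window)
        want = brute_force_smooth(values, window)
        np.testing.assert_allclose(got, want, equal_nan=True)


def test_metagene_profile_excludes_sparse_genes(scheme):
    cfg = SimConfig(n_genes=10, seed=5, noise_sd=0.0)
    genome = make_genome(cfg, with_sequence=False)
    track = simulate_track(genome, cfg, "starved", "wt")
    # a gene on a chromosome with no probes contributes nothing and is dropped
    genes = genome.genes + [GeneModel("orphan", "chrZ", 100, 900, "+")]
    prof = metagene_profile(track, genes, scheme, min_probes=5)
    assert prof.n_genes.max() == 10
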