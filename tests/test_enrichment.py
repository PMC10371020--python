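"""Per-bin enrichment inference: recovery, calibration, spike-in size
factors, contrasts, and qPCR quantitation."""

import numpy as np
import pandas as pd
import pytest

from rloopscape.counts import StrandedCountMatrix, size_factors_from_spike
from rloopscape.enrich import (
    EnrichmentOptions,
    contrast,
    ddcq,
    fit_enrichment,
)


def toy_counts(
    beta,
    depth=100.0,
    replicates=2,
    seed=0,
    size_factors=None,
    extracted=None,
    phi=None,
):
    """Minimal one-genotype count container from a per-bin truth vector."""
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    n = len(beta)
    bins = pd.DataFrame(
        {"contig": "chr", "start": np.arange(n) * 100, "end": (np.arange(n) + 1) * 100}
    )
    libs, cols = [], []
    for r in range(1, replicates + 1):
        libs.append((f"in{r}", "WT", r, "input", "."))
        cols.append(rng.poisson(depth, n) if phi is None
                    else rng.negative_binomial(phi, phi / (phi + depth), n))
    for r in range(1, replicates + 1):
        libs.append((f"ex{r}", "WT", r, "extracted", "+"))
        mu = depth * 2.0**beta
        cols.append(rng.poisson(mu) if phi is None
                    else rng.negative_binomial(phi, phi / (phi + mu)))
    counts = np.column_stack(cols)
    if extracted is not None:  # override extracted columns deterministically
        counts[:, replicates:] = extracted
    return StrandedCountMatrix(
        bins=bins,
        libraries=pd.DataFrame(
            libs, columns=["library", "genotype", "replicate", "sample_type", "strand"]
        ),
        counts=counts,
        size_factors=size_factors,
    )


class TestFitEnrichment:
    def test_flat_beta_two_recovered(self):
        counts = toy_counts(np.full(2000, 2.0), seed=1)
        post = fit_enrichment(counts, "WT", "+", EnrichmentOptions(seed=2))
        err = post.mean - 2.0
        assert np.mean(np.abs(err) < 0.25) >= 0.90

    def test_grid_recovery_coverage(self):
        """90% intervals cover the truth for >= 80% of bins across a grid of
        planted enrichments (simulation-based calibration)."""
        for i, b in enumerate([-2.0, 0.0, 1.0, 2.0, 4.0]):
            counts = toy_counts(np.full(400, b), seed=10 + i)
            post = fit_enrichment(counts, "WT", "+", EnrichmentOptions(seed=20 + i))
            cover = (post.q05 <= b) & (b <= post.q95)
            assert cover.mean() >= 0.80, f"beta={b}: coverage {cover.mean():.3f}"

    def test_identical_extracted_and_input_covers_zero(self):
        rng = np.random.default_rng(3)
        shared = rng.poisson(100, (1000, 2))
        counts = toy_counts(np.zeros(1000), seed=3, extracted=shared)
        counts.counts[:, :2] = shared
        post = fit_enrichment(counts, "WT", "+", EnrichmentOptions(seed=4))
        assert np.mean((post.q05 <= 0) & (0 <= post.q95)) >= 0.85

    def test_doubling_extracted_size_factor_shifts_beta_by_minus_one(self):
        counts = toy_counts(np.full(500, 1.0), seed=5)
        post1 = fit_enrichment(counts, "WT", "+", EnrichmentOptions(seed=6))
        sf = counts.size_factors.copy()
        sf[2:] = 2.0  # extracted libraries claimed twice as deep
        counts2 = toy_counts(np.full(500, 1.0), seed=5, size_factors=sf)
        post2 = fit_enrichment(counts2, "WT", "+", EnrichmentOptions(seed=6))
        shift = post2.mean - post1.mean
        assert np.median(shift) == pytest.approx(-1.0, abs=0.02)

    def test_scaling_library_and_size_factor_leaves_posterior_unchanged(self):
        from scipy.stats import ks_2samp

        counts = toy_counts(np.full(300, 0.5), seed=7)
        post1 = fit_enrichment(counts, "WT", "+", EnrichmentOptions(seed=8))
        scaled = toy_counts(np.full(300, 0.5), seed=7)
        scaled.counts[:, 2] *= 3
        sf = scaled.size_factors.copy()
        sf[2] = 3.0
        scaled.size_factors = sf
        post2 = fit_enrichment(scaled, "WT", "+", EnrichmentOptions(seed=8))
        ks = ks_2samp(post1.draws.ravel(), post2.draws.ravel())
        assert ks.pvalue > 0.01

    def test_equal_data_beta_shrinks_with_depth(self):
        mags = []
        for depth in (10, 100, 1000):
            rng = np.random.default_rng(9)
            shared = rng.poisson(depth, (500, 2))
            counts = toy_counts(np.zeros(500), depth=depth, seed=9, extracted=shared)
            counts.counts[:, :2] = shared
            post = fit_enrichment(counts, "WT", "+", EnrichmentOptions(seed=10))
            mags.append(np.mean(np.abs(post.mean)))
        assert mags[0] > mags[1] > mags[2]

    def test_independent_seeds_agree(self):
        counts = toy_counts(np.linspace(-1, 3, 400), seed=11)
        opts = dict(engine="mcmc", draws=300)
        p1 = fit_enrichment(counts, "WT", "+", EnrichmentOptions(seed=1, **opts))
        p2 = fit_enrichment(counts, "WT", "+", EnrichmentOptions(seed=99, **opts))
        r = np.corrcoef(p1.mean, p2.mean)[0, 1]
        assert r >= 0.99

    def test_vi_and_mcmc_engines_agree(self):
        counts = toy_counts(np.linspace(-1, 3, 300), seed=12)
        pv = fit_enrichment(counts, "WT", "+", EnrichmentOptions(seed=1))
        pm = fit_enrichment(counts, "WT", "+", EnrichmentOptions(engine="mcmc", seed=1))
        np.testing.assert_allclose(pv.mean, pm.mean, atol=0.15)

    def test_missing_library_class_rejected(self):
        counts = toy_counts(np.zeros(50), seed=13)
        with pytest.raises(ValueError, match="extracted"):
            fit_enrichment(counts, "WT", "-", EnrichmentOptions())

    def test_all_zero_library_named(self):
        counts = toy_counts(np.zeros(50), seed=14)
        counts.counts[:, 2] = 0
        with pytest.raises(ValueError, match="ex1"):
            fit_enrichment(counts, "WT", "+", EnrichmentOptions())

    def test_masked_bins_become_flagged_null_records(self):
        counts = toy_counts(np.zeros(100), seed=15)
        counts.mask[10:20] = True
        post = fit_enrichment(counts, "WT", "+", EnrichmentOptions(seed=16))
        assert post.masked[10:20].all()
        assert np.isnan(post.draws[10:20]).all()
        assert not np.isnan(post.draws[~post.masked]).any()

    def test_draws_deterministic_given_seed(self):
        counts = toy_counts(np.zeros(100), seed=17)
        p1 = fit_enrichment(counts, "WT", "+", EnrichmentOptions(seed=18))
        p2 = fit_enrichment(counts, "WT", "+", EnrichmentOptions(seed=18))
        np.testing.assert_array_equal(p1.draws, p2.draws)

    def test_quantiles_bracket_mean(self, recovery_posteriors):
        post = recovery_posteriors["+"]
        ok = ~post.masked
        assert (post.q05[ok] <= post.mean[ok] + 1e-9).all()
        assert (post.mean[ok] <= post.q95[ok] + 1e-9).all()
        assert post.draws.shape[1] == 500


class TestSizeFactors:
    def _with_spike(self, spike_sums):
        n_spike = 10
        n = 50
        L = len(spike_sums)
        bins = pd.DataFrame(
            {"contig": ["chr"] * n + ["spike"] * n_spike,
             "start": list(range(0, n * 100, 100)) + list(range(0, n_spike * 100, 100)),
             "end": list(range(100, n * 100 + 100, 100))
             + list(range(100, n_spike * 100 + 100, 100))}
        )
        libs = pd.DataFrame(
            {"library": [f"l{i}" for i in range(L)],
             "genotype": "WT",
             "replicate": 1,
             "sample_type": ["input"] + ["extracted"] * (L - 1),
             "strand": ["."] + ["+"] * (L - 1)}
        )
        counts = np.ones((n + n_spike, L), dtype=int)
        for j, s in enumerate(spike_sums):
            counts[n:, j] = s // n_spike
        spike = np.zeros(n + n_spike, dtype=bool)
        spike[n:] = True
        return StrandedCountMatrix(bins=bins, libraries=libs, counts=counts,
                                   spike_mask=spike)

    def test_identical_spike_counts_give_unit_factors(self):
        sf = size_factors_from_spike(self._with_spike([100, 100, 100]))
        np.testing.assert_allclose(sf, 1.0)

    def test_two_library_example(self):
        sf = size_factors_from_spike(self._with_spike([100, 400]))
        np.testing.assert_allclose(sf, [0.5, 2.0])

    def test_doubling_one_library_follows_geometric_mean_arithmetic(self):
        base = [120, 120, 120]
        sf0 = size_factors_from_spike(self._with_spike(base))
        doubled = [240, 120, 120]
        sf1 = size_factors_from_spike(self._with_spike(doubled))
        L = 3
        np.testing.assert_allclose(sf1[0], sf0[0] * 2 ** (1 - 1 / L))
        np.testing.assert_allclose(sf1[1:], sf0[1:] * 2 ** (-1 / L))

    def test_zero_spike_library_rejected(self):
        with pytest.raises(ValueError, match="l1"):
            size_factors_from_spike(self._with_spike([100, 0]))


class TestContrast:
    def test_self_contrast_is_zero(self):
        counts = toy_counts(np.zeros(100), seed=20)
        p = fit_enrichment(counts, "WT", "+", EnrichmentOptions(seed=21))
        ct = contrast(p, p)
        np.testing.assert_allclose(ct.mean, 0.0)

    def test_translation_shows_in_contrast_mean(self):
        counts = toy_counts(np.zeros(800), seed=22)
        shifted = toy_counts(np.ones(800), seed=23)
        pa = fit_enrichment(shifted, "WT", "+", EnrichmentOptions(seed=24))
        pb = fit_enrichment(counts, "WT", "+", EnrichmentOptions(seed=25))
        ct = contrast(pa, pb)
        assert np.median(ct.mean) == pytest.approx(1.0, abs=0.05)

    def test_planted_differential_region_stands_out(self):
        beta_b = np.zeros(600)
        beta_a = beta_b.copy()
        beta_a[250:300] = 1.5
        pa = fit_enrichment(toy_counts(beta_a, seed=26), "WT", "+", EnrichmentOptions(seed=27))
        pb = fit_enrichment(toy_counts(beta_b, seed=28), "WT", "+", EnrichmentOptions(seed=29))
        z = contrast(pa, pb).z_track().values
        assert np.median(np.abs(z[250:300])) > 3 * np.median(np.abs(z[:250]))

    def test_bin_mismatch_reported(self):
        pa = fit_enrichment(toy_counts(np.zeros(100), seed=30), "WT", "+",
                            EnrichmentOptions(seed=31))
        pb = fit_enrichment(toy_counts(np.zeros(99), seed=32), "WT", "+",
                            EnrichmentOptions(seed=33))
        with pytest.raises(ValueError, match="mismatch"):
            contrast(pa, pb)


class TestDdcq:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["locus", "genotype", "fraction",
                                           "replicate", "cq"])

    def test_worked_example(self):
        t = self.table([
            ("gene", "WT", "pulldown", 1, 20.0),
            ("gene", "WT", "input", 1, 18.0),
            ("ref", "WT", "pulldown", 1, 22.0),
            ("ref", "WT", "input", 1, 21.0),
        ])
        assert ddcq(t, "gene", "WT", "ref").ddcq == pytest.approx(1.0)

    def test_locus_vs_itself_is_zero(self):
        t = self.table([
            ("ref", "WT", "pulldown", 1, 22.0),
            ("ref", "WT", "input", 1, 21.0),
        ])
        assert ddcq(t, "ref", "WT", "ref").ddcq == 0.0

    def test_replicate_means_match_hand_computation(self):
        rows = []
        for i, cq in enumerate([20.0, 20.4, 20.6]):
            rows.append(("gene", "WT", "pulldown", i, cq))
        for i, cq in enumerate([18.0, 18.2, 18.1]):
            rows.append(("gene", "WT", "input", i, cq))
        rows += [("ref", "WT", "pulldown", 1, 22.0), ("ref", "WT", "input", 1, 21.0)]
        res = ddcq(self.table(rows), "gene", "WT", "ref")
        hand = (np.mean([20.0, 20.4, 20.6]) - np.mean([18.0, 18.2, 18.1])) - 1.0
        assert res.ddcq == pytest.approx(hand)
        assert res.se > 0

    def test_missing_fraction_rejected(self):
        t = self.table([("gene", "WT", "pulldown", 1, 20.0),
                        ("ref", "WT", "pulldown", 1, 22.0),
                        ("ref", "WT", "input", 1, 21.0)])
        with pytest.raises(ValueError, match="fraction"):
            ddcq(t, "gene", "WT", "ref")
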