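"""Feature aggregation, group-comparison battery, and the orientation x
expression regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rloopscape.featstats import (
    aggregate_features,
    adjust_battery,
    compare_groups,
    fit_orientation_regression,
    run_battery,
    stars_from_fdr,
    top_expression_ids,
)
from rloopscape.genome import FeatureType, GenomeFeature, Orientation
from rloopscape.trackio import GenomicTrack


def z_tracks_from(values_plus, values_minus=None, bin_width=100):
    n = len(values_plus)
    starts = np.arange(n) * bin_width
    mk = lambda v: GenomicTrack("chr", starts, starts + bin_width, np.asarray(v, float))
    return {"+": mk(values_plus), "-": mk(values_minus if values_minus is not None else values_plus)}


def feature(fid, start, end, strand="+", ftype=FeatureType.CDS, orientation=Orientation.codirectional):
    from dataclasses import replace

    f = GenomeFeature(fid, ftype, "chr", start, end, strand)
    return replace(f, orientation=orientation)


class TestAggregate:
    def test_median_of_covered_bins(self):
        tr = z_tracks_from([0.1, 0.5, 0.9, 7.0])
        t = aggregate_features(tr, [feature("f", 0, 300)])
        assert t["score"].iloc[0] == 0.5

    def test_fully_masked_feature_is_missing(self):
        tr = z_tracks_from([1.0, 2.0, 3.0, 4.0])
        mask = np.array([True, True, False, False])
        t = aggregate_features(tr, [feature("f", 0, 200)], mask_flags=mask)
        assert np.isnan(t["score"].iloc[0])
        assert t["n_bins"].iloc[0] == 0

    def test_matches_brute_force_oracle(self, rng):
        n_bins = 2000
        vals_p = rng.normal(size=n_bins)
        vals_m = rng.normal(size=n_bins)
        tr = z_tracks_from(vals_p, vals_m)
        feats = []
        for i in range(1000):
            s = int(rng.integers(0, n_bins * 100 - 600))
            feats.append(feature(f"f{i}", s, s + int(rng.integers(80, 600)),
                                 strand=str(rng.choice(["+", "-"]))))
        table = aggregate_features(tr, feats)
        mids = np.arange(n_bins) * 100 + 50
        for f, score in zip(feats, table["score"]):
            src = vals_p if f.strand == "+" else vals_m
            inside = src[(mids >= f.start) & (mids < f.end)]
            if inside.size == 0:
                assert np.isnan(score)
            else:
                assert score == np.median(inside)

    def test_first_100_bp_is_strand_aware(self):
        vals = np.arange(10, dtype=float)
        tr = z_tracks_from(vals, vals[::-1])
        plus = feature("p", 0, 500, "+")
        minus = feature("m", 0, 500, "-")
        t = aggregate_features(tr, [plus, minus], first_bp=100)
        assert t["score"].iloc[0] == 0.0  # + strand: first bin
        assert t["score"].iloc[1] == vals[::-1][4]  # - strand: last bin of feature


class TestCompareGroups:
    def test_shifted_group_has_unit_median_difference(self, rng):
        a = rng.normal(size=20)
        b = a + 1.0
        c = compare_groups(b, a, label="shift")
        assert c.estimate == pytest.approx(1.0, abs=1e-12)
        assert c.ci_low <= 1.0 <= c.ci_high

    def test_identical_groups(self, rng):
        a = rng.normal(size=15)
        c = compare_groups(a, a.copy())
        assert c.estimate == 0.0
        assert c.p_value > 0.9

    @pytest.mark.parametrize("n1,n2", [(4, 4), (5, 6), (8, 7)])
    def test_rank_sum_p_matches_permutation_enumeration(self, n1, n2, rng):
        """Exact Wilcoxon p equals brute-force enumeration over all
        assignments of the pooled values to groups (tie-free data)."""
        pooled = rng.normal(size=n1 + n2)
        a, b = pooled[:n1], pooled[n1:]
        p_impl = compare_groups(a, b, n_boot=100).p_value

        def ustat(x, y):
            return sum(xi > yi for xi in x for yi in y) + 0.5 * sum(
                xi == yi for xi in x for yi in y
            )

        obs = ustat(a, b)
        m = 0
        total = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            x = pooled[list(comb)]
            y = np.delete(pooled, list(comb))
            u = ustat(x, y)
            # two-sided: as or more extreme in either direction
            if min(u, n1 * n2 - u) <= min(obs, n1 * n2 - obs):
                m += 1
            total += 1
        assert p_impl == pytest.approx(m / total, abs=1e-12)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=12), rng.normal(1.0, 1, 15)
        c1 = compare_groups(a, b, seed=1)
        c2 = compare_groups(b, a, seed=1)
        assert c1.estimate == pytest.approx(-c2.estimate)
        assert c1.p_value == pytest.approx(c2.p_value)

    def test_paired_difference_and_signed_rank(self, rng):
        a = rng.normal(size=30)
        b = a - 0.8 + rng.normal(0, 0.05, 30)
        c = compare_groups(a, b, paired=True)
        assert c.estimate == pytest.approx(0.8, abs=0.1)
        assert c.p_value == pytest.approx(
            stats.wilcoxon(a - b, zero_method="wilcox").pvalue
        )
        assert c.ci_low <= c.estimate <= c.ci_high

    def test_too_small_group_is_an_error(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            compare_groups(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]))


class TestFdr:
    def test_bh_worked_example(self):
        _, fdr, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        np.testing.assert_allclose(fdr, 0.04)

    def test_star_map(self):
        assert stars_from_fdr(0.0005) == "***"
        assert stars_from_fdr(0.001) == "**"
        assert stars_from_fdr(0.009) == "**"
        assert stars_from_fdr(0.01) == "*"
        assert stars_from_fdr(0.049) == "*"
        assert stars_from_fdr(0.05) == ""

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_bh_monotone_and_bounded(self, ps):
        _, fdr, _, _ = multipletests(ps, method="fdr_bh")
        order = np.argsort(ps)
        assert (np.diff(np.asarray(fdr)[order]) >= -1e-12).all()
        assert (np.asarray(fdr) <= 1.0 + 1e-12).all()

    def test_battery_applies_fdr_and_stars(self, rng):
        comps = [
            compare_groups(rng.normal(3, 1, 30), rng.normal(0, 1, 30), label=f"c{i}")
            for i in range(3)
        ]
        df = adjust_battery(comps)
        assert (df["fdr"] >= df["p_value"] - 1e-15).all()
        assert set(df["stars"]) <= {"", "*", "**", "***"}


class TestBatteryFilters:
    def make_tables(self, rng):
        rows = []
        for i in range(60):
            rows.append({
                "id": f"f{i}", "type": "CDS",
                "orientation": "head_on" if i % 4 == 0 else "codirectional",
                "score": rng.normal(), "score_first100": rng.normal(),
                "expr_z": rng.normal(),
            })
        t = pd.DataFrame(rows)
        return {"WT": t, "mut": t.assign(score=t["score"] + 0.5)}

    def test_top_expression_threshold_keeps_ties(self):
        t = pd.DataFrame({"id": list("abcde"), "expr_z": [0, 1, 2, 2, -1]})
        ids = top_expression_ids(t, 0.2)
        assert ids == {"c", "d"}  # both tied values kept

    def test_genotype_comparison_is_paired_by_feature(self, rng):
        tables = self.make_tables(rng)
        df = run_battery(
            tables,
            [{"feature_type": "CDS", "comparison": "genotype",
              "genotypes": ("mut", "WT")}],
            n_boot=200,
        )
        assert df["paired"].iloc[0]
        assert df["estimate"].iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_empty_filter_reports_the_filter(self, rng):
        tables = self.make_tables(rng)
        with pytest.raises(ValueError, match="empty group"):
            run_battery(
                tables,
                [{"feature_type": "rRNA", "comparison": "genotype",
                  "genotypes": ("mut", "WT")}],
            )


class TestOrientationRegression:
    @staticmethod
    def synth_table(n, slope, interaction, sigma=0.5, seed=0, ho_effect=0.2):
        rng = np.random.default_rng(seed)
        ho = rng.random(n) < 0.3
        expr = rng.normal(0, 1, n)
        score = (
            0.1 + ho_effect * ho + slope * expr + interaction * ho * expr
            + rng.normal(0, sigma, n)
        )
        return pd.DataFrame({
            "id": [f"c{i}" for i in range(n)],
            "type": "CDS",
            "orientation": np.where(ho, "head_on", "codirectional"),
            "score": score,
            "expr_z": expr,
        })

    def test_planted_expression_slope_recovered(self):
        t = self.synth_table(500, slope=0.8, interaction=0.0, seed=1)
        fit = fit_orientation_regression(t, draws=2000, seed=2)
        assert fit.coef_draws("expr_z").mean() == pytest.approx(0.8, abs=0.1)

    def test_negative_interaction_detected(self):
        # head-on genes gain less hybrid signal with expression
        t = self.synth_table(500, slope=0.8, interaction=-0.5, seed=3)
        fit = fit_orientation_regression(t, draws=2000, seed=4)
        draws = fit.coef_draws("head_on:expr_z")
        assert np.mean(draws < 0) > 0.95

    def test_zero_response_intervals_cover_zero(self):
        t = self.synth_table(200, slope=0.0, interaction=0.0, sigma=1.0,
                             seed=5, ho_effect=0.0)
        t["score"] = np.random.default_rng(6).normal(0, 1, len(t))
        fit = fit_orientation_regression(t, draws=2000, seed=7)
        s = fit.summary().set_index("coef")
        for coef in ("head_on", "expr_z", "head_on:expr_z"):
            assert s.loc[coef, "q05"] <= 0 <= s.loc[coef, "q95"]

    def test_too_few_cds_rejected(self):
        t = self.synth_table(10, 0.5, 0.0)
        with pytest.raises(ValueError, match=">= 20"):
            fit_orientation_regression(t)

    def test_interval_calibration_over_replicates(self):
        """95% intervals cover planted coefficients in >= 85% of simulated
        datasets."""
        true = {"head_on": 0.2, "expr_z": 0.8, "head_on:expr_z": -0.3}
        covered = total = 0
        n_rep = 20
        for r in range(n_rep):
            t = self.synth_table(150, slope=0.8, interaction=-0.3, seed=100 + r)
            fit = fit_orientation_regression(t, draws=1000, seed=200 + r)
            for k, v in true.items():
                d = fit.coef_draws(k)
                lo, hi = np.quantile(d, [0.025, 0.975])
                covered += lo <= v <= hi
                total += 1
        assert covered / total >= 0.85, f"covered {covered}/{total}"
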