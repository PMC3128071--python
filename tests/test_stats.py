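"""Length-distribution statistics: lower limits, mixture fits, summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from intercds.io_formats import GeneRecord
from intercds.regions import build_neighbor_pairs
from intercds.stats import (
    compare_fits,
    correlate,
    cv_across_species,
    estimate_lower_limit,
    fit_gaussians,
    optimized_space,
    orientation_composition_test,
    summarize_lengths,
)


class TestEstimateLowerLimit:
    def test_degenerate_sample(self):
        for method in ("min", "quantile"):
            assert estimate_lower_limit([100] * 30, method=method).value == 100

    def test_small_sample_falls_back_to_min(self, caplog):
        with caplog.at_level("WARNING"):
            est = estimate_lower_limit([7, 9, 11, 13, 20], method="quantile")
        assert est.method == "min" and est.value == 7
        assert "falling back" in caplog.text

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            estimate_lower_limit([])

    @given(st.lists(st.integers(1, 10_000), min_size=20, max_size=200))
    def test_monotone_in_q_and_below_median(self, lengths):
        qs = [0.0, 0.01, 0.03, 0.05]
        values = [estimate_lower_limit(lengths, q=q).value for q in qs]
        assert values == sorted(values)
        assert all(v <= np.median(lengths) for v in values)


class TestFitGaussians:
    def test_single_gaussian_parameter_recovery(self):
        rng = np.random.default_rng(5)
        lengths = np.maximum(np.round(10 ** rng.normal(2.5, 0.15, 2000)), 1)
        fit = fit_gaussians(lengths, 1, seed=0)
        (comp,) = fit.components
        assert comp.mean == pytest.approx(2.5, abs=0.02)
        assert comp.sd == pytest.approx(0.15, abs=0.02)
        assert comp.weight == 1.0

    def test_bimodal_point_masses(self):
        lengths = [int(10**2.2)] * 400 + [int(10**2.8)] * 400
        f1 = fit_gaussians(lengths, 1, seed=0)
        f2 = fit_gaussians(lengths, 2, seed=0)
        means = [c.mean for c in f2.components]
        assert means[0] == pytest.approx(2.2, abs=0.1)
        assert means[1] == pytest.approx(2.8, abs=0.1)
        assert f2.rss < f1.rss

    def test_nesting_rss2_never_exceeds_rss1(self):
        rng = np.random.default_rng(17)
        for seed in range(5):
            lengths = np.maximum(
                np.round(10 ** rng.normal(2.6, 0.3, 500)), 1
            )
            f1 = fit_gaussians(lengths, 1, seed=seed)
            f2 = fit_gaussians(lengths, 2, seed=seed)
            assert f2.rss <= f1.rss * (1 + 1e-9)

    def test_components_sorted_by_mean(self):
        rng = np.random.default_rng(3)
        comp = rng.choice(2, size=1000)
        lengths = np.maximum(
            np.round(10 ** rng.normal(np.where(comp, 2.9, 2.3), 0.12)), 1
        )
        f2 = fit_gaussians(lengths, 2, seed=0)
        assert f2.components[0].mean <= f2.components[1].mean
        assert sum(c.weight for c in f2.components) == pytest.approx(1.0)

    def test_too_small_sample_errors(self):
        with pytest.raises(ValueError, match="n >= 50"):
            fit_gaussians([100] * 49, 1)


class TestCompareFits:
    def test_equal_rss_gives_f_zero_p_one(self):
        lengths = list(np.maximum(np.round(10 ** np.random.default_rng(0).normal(2.5, 0.2, 300)), 1))
        f1 = fit_gaussians(lengths, 1, seed=0)
        f2 = fit_gaussians(lengths, 2, seed=0)
        from dataclasses import replace

        f2_forced = replace(f2, rss=f1.rss)
        cmp_ = compare_fits(f1, f2_forced)
        assert cmp_.f_statistic == 0.0 and cmp_.p_value == 1.0

    def test_strong_bimodality_detected(self):
        rng = np.random.default_rng(42)
        comp = rng.choice(2, size=2000)
        lengths = np.maximum(
            np.round(10 ** rng.normal(np.where(comp, 2.8, 2.2), 0.12)), 1
        )
        f1 = fit_gaussians(lengths, 1, seed=0)
        f2 = fit_gaussians(lengths, 2, seed=0)
        assert compare_fits(f1, f2).p_value < 1e-6

    def test_optimizer_failure_detected(self):
        lengths = list(
            np.maximum(np.round(10 ** np.random.default_rng(1).normal(2.5, 0.2, 300)), 1)
        )
        f1 = fit_gaussians(lengths, 1, seed=0)
        f2 = fit_gaussians(lengths, 2, seed=0)
        from dataclasses import replace

        bad = replace(f2, rss=f1.rss * 2 + 1)
        with pytest.raises(RuntimeError, match="refit"):
            compare_fits(f1, bad)

    def test_model_selection_rate_on_known_strata(self):
        """Bimodal strata reject k=1 and unimodal strata retain it (alpha=0.01)
        in >= 90% of seeded replicates."""
        rng = np.random.default_rng(99)
        correct_uni = correct_bi = 0
        n_rep = 20
        for i in range(n_rep):
            uni = np.maximum(np.round(10 ** rng.normal(2.6, 0.3, 800)), 1)
            p_uni = compare_fits(
                fit_gaussians(uni, 1, seed=i), fit_gaussians(uni, 2, seed=i)
            ).p_value
            correct_uni += p_uni >= 0.01
            # clearly bimodal divergent-like stratum: components 3+ sd apart
            comp = rng.choice(2, size=800, p=[0.55, 0.45])
            bi = np.maximum(
                np.round(10 ** rng.normal(np.where(comp, 2.95, 2.45),
                                          np.where(comp, 0.16, 0.13))), 1
            )
            p_bi = compare_fits(
                fit_gaussians(bi, 1, seed=i), fit_gaussians(bi, 2, seed=i)
            ).p_value
            correct_bi += p_bi < 0.01
        assert correct_uni >= 0.9 * n_rep
        assert correct_bi >= 0.9 * n_rep


def _regions_with(lengths_by_stratum):
    """Build synthetic regions with given (species, age, orientation) lengths."""
    from dataclasses import replace

    out = []
    i = 0
    for (sp, age, orientation), lengths in lengths_by_stratum.items():
        strands = {
            "convergent": ("+", "-"), "divergent": ("-", "+"),
            "unidirectional": ("+", "+"),
        }[orientation]
        for L in lengths:
            start = 1000 * i + 1
            genes = [
                GeneRecord(gene_id=f"a{i}", species=sp, chromosome=f"c{i}",
                           strand=strands[0], cds_start=start, cds_end=start + 9),
                GeneRecord(gene_id=f"b{i}", species=sp, chromosome=f"c{i}",
                           strand=strands[1], cds_start=start + 10 + L,
                           cds_end=start + 19 + L),
            ]
            (r,) = build_neighbor_pairs(genes)
            out.append(replace(r, age_label=age))
            i += 1
    return out


class TestSummarizeLengths:
    def test_known_mean(self):
        regions = _regions_with({("sce", "old", "convergent"): [100, 200, 300]})
        df = summarize_lengths(regions)
        row = df[(df.age == "old") & (df.orientation == "convergent")].iloc[0]
        assert row.mean_bp == 200 and row.n == 3

    def test_ages_make_distinct_rows(self):
        regions = _regions_with(
            {("sce", "old", "convergent"): [100] * 3,
             ("sce", "young", "convergent"): [900] * 3}
        )
        df = summarize_lengths(regions)
        kept = df[df.n > 0]
        assert len(kept) == 2
        assert set(kept.age) == {"old", "young"}

    def test_counts_conserve_regions(self):
        strata = {
            ("sce", "old", "convergent"): [100] * 5,
            ("sce", "old", "divergent"): [300] * 7,
            ("sce", "young", "unidirectional"): [400] * 2,
        }
        df = summarize_lengths(_regions_with(strata))
        assert df.n.sum() == sum(len(v) for v in strata.values())

    def test_empty_stratum_has_missing_markers(self):
        df = summarize_lengths(_regions_with({("sce", "old", "convergent"): [100] * 3}))
        empty = df[(df.age == "young") & (df.orientation == "divergent")]
        assert empty.n.iloc[0] == 0 and pd.isna(empty.mean_bp.iloc[0])


class TestCvAcrossSpecies:
    def test_published_convergent_means(self):
        means = [205, 106, 248, 172, 213, 103, 88, 217, 158, 155, 96]
        assert cv_across_species(means) == pytest.approx(0.35, abs=0.005)

    def test_identical_values(self):
        assert cv_across_species([5.0, 5.0, 5.0]) == 0.0

    def test_hand_arithmetic(self):
        assert cv_across_species([1, 3]) == pytest.approx(np.sqrt(2) / 2)

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError):
            cv_across_species([-1.0, 1.0])


class TestOrientationComposition:
    def test_null_proportions_give_zero_chi2(self):
        regions = _regions_with(
            {("s", "old", "divergent"): [100] * 25,
             ("s", "old", "unidirectional"): [100] * 50,
             ("s", "old", "convergent"): [100] * 25}
        )
        t = orientation_composition_test(regions, (1, 1000))
        assert t.chi2 == pytest.approx(0.0) and t.p_value == pytest.approx(1.0)

    def test_hand_computed_chi2(self):
        regions = _regions_with(
            {("s", "old", "unidirectional"): [100] * 50,
             ("s", "old", "convergent"): [100] * 50}
        )
        t = orientation_composition_test(regions, (1, 1000))
        assert t.chi2 == pytest.approx(50.0)
        assert t.observed == (0, 50, 50)

    def test_null_calibration_by_simulation(self):
        rng = np.random.default_rng(8)
        from scipy.stats import chisquare

        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            counts = rng.multinomial(120, [0.25, 0.50, 0.25])
            _, p = chisquare(counts, [30, 60, 30])
            rejections += p < 0.05
        # our test statistic is the same goodness-of-fit chi-square, so its
        # rejection rate under the null must sit near alpha
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_window_restricts_counts(self):
        regions = _regions_with(
            {("s", "old", "convergent"): [100] * 5 + [900] * 3}
        )
        t = orientation_composition_test(regions, (50, 500))
        assert sum(t.observed) == 5


class TestCorrelate:
    def test_exact_linear_relation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = correlate(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)

    def test_independent_draws_rarely_correlate(self):
        rng = np.random.default_rng(21)
        big = 0
        rs = []
        for _ in range(500):
            r, _ = correlate(rng.normal(size=11), rng.normal(size=11))
            rs.append(r)
            big += abs(r) > 0.6
        # sd(r) ~ 1/sqrt(n-1) ~ 0.32 at n=11, so "mean ~ 0" is a coarse claim
        assert abs(np.mean(rs)) < 0.1
        assert big / 500 < 0.1

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [3.0, 4.0])

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@pytest.mark.parametrize(
    "promoter,utr,expected", [(140, 68, 276), (140, 0, 140), (0, 0, 0)]
)
def test_optimized_space(promoter, utr, expected):
    assert optimized_space(promoter, utr) == expected


def test_optimized_space_rejects_negative():
    with pytest.raises(ValueError):
        optimized_space(-1, 68)
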