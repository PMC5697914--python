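"""Spine census statistics: normalization, classification, nulls, co-localization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dendroscale.spines import (
    ClassificationCriteria,
    SpineDataset,
    chance_increasing_fraction,
    classify_branch,
    cluster_profile,
    colocalized_glua2,
    density_size_relation,
    derive_thresholds,
    lost_spine_nn,
    normalize_sizes,
    size_from_intensity,
)
from dendroscale.synthetic import gen_intensity_profiles
from conftest import make_spine_df


def tiny_dataset(sizes_by_tp: dict[float, float], extra=None) -> SpineDataset:
    spines = [(1.0, sizes_by_tp, "stable")]
    if extra:
        spines += extra
    return SpineDataset(make_spine_df({"b0": spines}))


class TestNormalizeSizes:
    @pytest.mark.parametrize("sizes, expected", [
        ({-24.0: 10.0, 0.0: 10.0, 48.0: 12.0}, 1.2),
        ({-24.0: 7.0, 0.0: 7.0, 48.0: 7.0}, 1.0),
        ({-24.0: 8.0, 0.0: 12.0, 48.0: 11.0}, 1.1),
    ])
    def test_baseline_mean_normalization(self, sizes, expected):
        ds = normalize_sizes(tiny_dataset(sizes))
        got = ds.at_timepoint(48.0)["size_norm"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_baseline_excluded(self):
        ds = normalize_sizes(tiny_dataset({-24.0: 0.0, 0.0: 0.0, 48.0: 5.0}))
        assert np.isnan(ds.at_timepoint(48.0)["size_norm"].iloc[0])

    def test_log10_flag(self):
        ds = normalize_sizes(tiny_dataset({-24.0: 10.0, 0.0: 10.0, 48.0: 10.0}),
                             log10=True)
        assert ds.df["size_norm_log10"].iloc[-1] == pytest.approx(0.0)


class TestSizeFromIntensity:
    @pytest.mark.parametrize("args, expected", [
        ((110.0, 10.0, 50.0), 2.0),
        ((10.0, 10.0, 50.0), 0.0),
        ((60.0, 10.0, 100.0), 0.5),
    ])
    def test_arithmetic(self, args, expected):
        assert size_from_intensity(*args) == pytest.approx(expected)

    def test_nonpositive_dendrite_rejected(self):
        with pytest.raises(ValueError):
            size_from_intensity(10.0, 1.0, 0.0)


class TestClassifyBranch:
    def test_joint_criteria_increasing(self):
        sizes = [1.3, 1.2, 1.25, 1.15, 0.9, 1.0, 1.2, 1.3, 1.18, 1.22]
        assert classify_branch(sizes) == "increasing"

    def test_single_outlier_guard(self):
        sizes = [3.0] + [1.0] * 9  # mean 1.2 but only 1/10 spines above threshold
        assert classify_branch(sizes) != "increasing"

    def test_unchanged_branch_same(self):
        assert classify_branch([1.0] * 8) == "same"

    def test_decreasing(self):
        assert classify_branch([0.8, 0.85, 0.7, 0.9]) == "decreasing"

    def test_empty_branch_unclassifiable(self):
        with pytest.raises(ValueError, match="empty"):
            classify_branch([])

    @given(st.lists(st.floats(0.3, 2.5), min_size=2, max_size=30),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_spine_ordering(self, sizes, rnd):
        shuffled = list(sizes)
        rnd.shuffle(shuffled)
        assert classify_branch(sizes) == classify_branch(shuffled)


class TestDeriveThresholds:
    def test_ten_percent_population_gives_1p1(self):
        # continuous control spread with exactly 10% of spines above 1.1
        rng = np.random.default_rng(0)
        spines = []
        for i in range(200):
            v = rng.uniform(0.9, 1.1) if i < 180 else rng.uniform(1.1, 1.3)
            spines.append((float(i + 1), {0.0: 1.0, 48.0: v}, "stable"))
        branches = {f"b{k}": spines[k * 20:(k + 1) * 20] for k in range(10)}
        ds = SpineDataset(make_spine_df(branches))
        ds = normalize_sizes(ds, baseline_timepoints=[0.0])
        crit = derive_thresholds(ds, 48.0)
        assert crit.size_threshold == pytest.approx(1.1, abs=0.02)

    def test_generator_control_calibration(self):
        """Thresholds derived from a generated control land near the canonical
        size threshold of 1.1; the branch-fraction threshold is overdispersed
        above the pure-binomial value by the branch-level noise component."""
        from dendroscale.synthetic import SpineGenParams, gen_spine_dataset
        ds, _ = gen_spine_dataset(SpineGenParams(deprived=False, n_cells=20, seed=31))
        ds = normalize_sizes(ds)
        crit = derive_thresholds(ds, 48.0)
        assert crit.size_threshold == pytest.approx(1.1, abs=0.05)
        assert 0.15 < crit.fraction_threshold < 0.55

    def test_degenerate_control_warns(self, caplog):
        spines = [(float(i + 1), {0.0: 1.0, 48.0: 1.0}, "stable") for i in range(20)]
        ds = normalize_sizes(SpineDataset(make_spine_df({"b0": spines})),
                             baseline_timepoints=[0.0])
        with caplog.at_level("WARNING"):
            crit = derive_thresholds(ds, 48.0)
        assert crit.size_threshold == pytest.approx(1.0)
        assert "degenerate" in caplog.text

    def test_too_few_spines_rejected(self):
        spines = [(float(i + 1), {0.0: 1.0, 48.0: 1.2}, "stable") for i in range(5)]
        ds = normalize_sizes(SpineDataset(make_spine_df({"b0": spines})),
                             baseline_timepoints=[0.0])
        with pytest.raises(ValueError, match="10 control spines"):
            derive_thresholds(ds, 48.0)


class TestChanceIncreasingFraction:
    def test_population_below_threshold_zero(self):
        m, s, _ = chance_increasing_fraction(np.full(100, 0.95),
                                             rng=np.random.default_rng(0))
        assert m == 0.0

    def test_population_above_threshold_all(self):
        m, s, _ = chance_increasing_fraction(np.full(100, 1.5),
                                             rng=np.random.default_rng(0))
        assert m == 1.0

    def test_monotone_in_above_threshold_fraction(self):
        """More above-threshold spines in the population -> higher chance level."""
        prev = -1.0
        for frac in (0.2, 0.4, 0.6, 0.8):
            n_hi = int(1000 * frac)
            pop = np.r_[np.full(n_hi, 1.3), np.full(1000 - n_hi, 0.95)]
            m, _, _ = chance_increasing_fraction(pop, rng=np.random.default_rng(7))
            assert m >= prev
            prev = m

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            chance_increasing_fraction([], rng=np.random.default_rng(0))


class TestClusterProfile:
    def _flat_dataset(self, value: float) -> SpineDataset:
        spines = [(float(4 * i + 1), {0.0: 1.0, 48.0: value}, "stable")
                  for i in range(12)]
        ds = SpineDataset(make_spine_df({"b0": spines, "b1": spines}))
        return normalize_sizes(ds, baseline_timepoints=[0.0])

    def test_all_increasing_gives_unit_fractions(self):
        ds = self._flat_dataset(1.5)
        prof = cluster_profile(ds, 48.0, rng=np.random.default_rng(0), n_shuffles=10)
        occupied = prof.observed_counts > 0
        assert np.all(prof.observed_fraction[occupied] == 1.0)
        assert prof.db_probability == 1.0

    def test_none_increasing_population_zero(self):
        ds = self._flat_dataset(1.0)
        prof = cluster_profile(ds, 48.0, seed_type="all",
                               rng=np.random.default_rng(0), n_shuffles=10)
        occupied = prof.observed_counts > 0
        assert np.all(prof.observed_fraction[occupied] == 0.0)

    def test_shuffled_null_matches_hypergeometric_expectation(self):
        """Permuting positions on one branch makes every distance bin an
        exchangeable draw: the mean shuffled fraction equals (m-1)/(n-1)
        for m increased spines out of n."""
        rng = np.random.default_rng(1)
        n, m = 16, 6
        flags = np.zeros(n)
        flags[:m] = 1
        rng.shuffle(flags)
        spines = [(float(p), {0.0: 1.0, 48.0: 1.3 if f else 1.0}, "stable")
                  for p, f in zip(np.cumsum(rng.uniform(2, 6, n)), flags)]
        ds = normalize_sizes(SpineDataset(make_spine_df({"b0": spines})),
                             baseline_timepoints=[0.0])
        prof = cluster_profile(ds, 48.0, rng=np.random.default_rng(2),
                               n_shuffles=3000)
        # ratio-of-counts estimator is only unbiased where bins are well
        # populated; sparse far bins are excluded
        well_filled = prof.observed_counts >= 8
        assert well_filled.any()
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            mean_sh = np.nanmean(prof.shuffled_fractions, axis=0)[well_filled]
        assert mean_sh == pytest.approx((m - 1) / (n - 1), abs=0.04)

    def test_position_independent_sizes_stay_within_band(self, clustered_branch_dataset):
        rng = np.random.default_rng(3)
        spines = []
        for p in np.cumsum(rng.uniform(2, 6, 200)):
            v = 1.3 if rng.random() < 0.3 else 1.0
            spines.append((float(p), {0.0: 1.0, 48.0: v}, "stable"))
        branches = {f"b{k}": spines[k * 20:(k + 1) * 20] for k in range(10)}
        # re-anchor positions per branch
        fixed = {b: [(pos - sp[0][0] + 1.0, sz, f) for (pos, sz, f) in sp]
                 for b, sp in ((b, sp) for b, sp in branches.items())}
        ds = normalize_sizes(SpineDataset(make_spine_df(fixed)),
                             baseline_timepoints=[0.0])
        prof = cluster_profile(ds, 48.0, rng=np.random.default_rng(4), n_shuffles=300)
        lo, hi = prof.shuffled_band()
        ok = prof.observed_counts >= 5
        inside = (prof.observed_fraction[ok] >= lo[ok]) & (prof.observed_fraction[ok] <= hi[ok])
        assert inside.mean() >= 0.9

    def test_injected_clustering_detected(self, clustered_branch_dataset):
        ds = clustered_branch_dataset(seed=11)
        prof = cluster_profile(ds, 48.0, rng=np.random.default_rng(5), n_shuffles=300)
        lo, hi = prof.shuffled_band()
        assert prof.observed_fraction[0] > hi[0]


class TestLostSpineNN:
    def test_two_lost_spines_mutual_neighbors(self):
        spines = [(3.0, {0.0: 1.0}, "lost"), (7.0, {0.0: 1.0}, "stable"),
                  (11.0, {0.0: 1.0}, "lost")]
        ds = SpineDataset(make_spine_df({"b0": spines}))
        res = lost_spine_nn(ds, np.random.default_rng(0), n_shuffles=10)
        assert sorted(res.observed.tolist()) == [8.0, 8.0]

    def test_single_lost_spine_contributes_nothing(self):
        spines = [(3.0, {0.0: 1.0}, "lost"), (7.0, {0.0: 1.0}, "stable")]
        ds = SpineDataset(make_spine_df({"b0": spines}))
        res = lost_spine_nn(ds, np.random.default_rng(0), n_shuffles=10)
        assert res.observed.size == 0

    def test_random_loss_within_null_band(self):
        from dendroscale.synthetic import SpineGenParams, gen_spine_dataset
        ds, _ = gen_spine_dataset(SpineGenParams(deprived=True, n_cells=15, seed=21))
        res = lost_spine_nn(ds, np.random.default_rng(1), n_shuffles=300)
        lo, hi = np.percentile(res.shuffled_means, [2.5, 97.5])
        assert lo <= res.observed_mean <= hi


class TestDensitySizeRelation:
    def test_exact_inverse_relation(self):
        branches = {}
        for k, keep in enumerate([10, 8, 6, 4]):
            ratio = keep / 10
            size = 2.0 - ratio
            spines = [(float(i + 1), {0.0: 1.0, 48.0: size}, "stable")
                      for i in range(keep)]
            spines += [(float(i + 1), {0.0: 1.0}, "lost") for i in range(keep, 10)]
            branches[f"b{k}"] = spines
        ds = normalize_sizes(SpineDataset(make_spine_df(branches)),
                             baseline_timepoints=[0.0])
        rel = density_size_relation(ds, 48.0)
        assert rel["rho"] == pytest.approx(-1.0)

    def test_identical_branches_undefined(self):
        spines = [(float(i + 1), {0.0: 1.0, 48.0: 1.0}, "stable") for i in range(5)]
        ds = normalize_sizes(SpineDataset(make_spine_df(
            {f"b{k}": spines for k in range(4)})), baseline_timepoints=[0.0])
        rel = density_size_relation(ds, 48.0)
        assert np.isnan(rel["rho"])

    def test_too_few_branches_undefined(self):
        spines = [(1.0, {0.0: 1.0, 48.0: 1.1}, "stable")]
        ds = normalize_sizes(SpineDataset(make_spine_df({"b0": spines})),
                             baseline_timepoints=[0.0])
        assert np.isnan(density_size_relation(ds, 48.0)["rho"])


class TestColocalization:
    def _profiles(self, glua2_sds: float, grip1_sds: float):
        """One spine whose channel peaks sit a given number of SDs above background."""
        rng = np.random.default_rng(0)
        L = 21
        bg = rng.normal(100.0, 10.0, (1, L))
        m, s = bg.mean(), bg.std()
        gfp = np.zeros((1, L))
        gfp[0, 10] = 500.0
        glua2 = np.full((1, L), m)
        glua2[0, 10] = m + glua2_sds * s
        grip1 = np.full((1, L), m)
        grip1[0, 10] = m + grip1_sds * s
        from dendroscale.spines import IntensityProfileSet
        return IntensityProfileSet(gfp=gfp, glua2=glua2, grip1=grip1,
                                   glua2_background=bg.copy(),
                                   grip1_background=bg.copy(),
                                   spine_sizes=np.array([2.0]))

    def test_three_sd_peaks_colocalize(self):
        assert colocalized_glua2(self._profiles(3.0, 3.0))["coloc"].iloc[0]

    def test_one_sd_peak_does_not(self):
        assert not colocalized_glua2(self._profiles(1.0, 3.0))["coloc"].iloc[0]

    def test_normalized_intensity(self):
        prof = self._profiles(3.0, 3.0)
        prof.glua2[0, 10] = 200.0
        prof.glua2_background[:] = 50.0
        prof.glua2_background[0, 0] = 50.5  # keep SD nonzero
        table = colocalized_glua2(prof)
        assert table["glua2_normalized"].iloc[0] == pytest.approx(4.0, abs=0.01)

    def test_flat_background_rejected(self):
        prof = self._profiles(3.0, 3.0)
        prof.glua2_background[:] = 100.0
        with pytest.raises(ValueError, match="flat"):
            colocalized_glua2(prof)
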