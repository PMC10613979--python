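"""CFS merit, correlation scores and the greedy stepwise search."""

from itertools import combinations

import numpy as np
import pytest

from hsin.band_selection import (
    cfs_merit,
    feature_class_correlation,
    greedy_stepwise_select,
)


def planted_design(n=400, n_bands=50, informative=(10, 25, 40), shift=3.0,
                   seed=123):
    """Four classes; each informative band carries a one-vs-rest mean shift
    for a different class; all other bands are pure noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(4), n // 4)
    X = rng.normal(0.0, 1.0, (n, n_bands))
    for k, band in enumerate(informative):
        X[:, band] += shift * (y == k)
    return X, y


def exhaustive_best_subset(X, y, k_max):
    """Oracle: best CFS merit over all subsets of size <= k_max."""
    from hsin.band_selection import _feature_correlation_matrix

    cc = feature_class_correlation(X, y)
    fc = _feature_correlation_matrix(X)
    best, best_merit = None, -np.inf
    for k in range(1, k_max + 1):
        for sub in combinations(range(X.shape[1]), k):
            m = cfs_merit(list(sub), cc, fc)
            if m > best_merit:
                best, best_merit = sub, m
    return set(best), best_merit


class TestClassCorrelation:
    def test_class_indicator_band_scores_high(self):
        y = np.repeat(["a", "b"], 50)
        X = np.column_stack([(y == "a").astype(float)])
        # the band IS the indicator of both classes (two-class case)
        assert feature_class_correlation(X, y)[0] == pytest.approx(1.0)

    def test_duplicated_band_scores_identically(self, rng):
        X = rng.normal(0, 1, (60, 3))
        X[:, 2] = X[:, 0]
        y = np.repeat(["a", "b", "c"], 20)
        s = feature_class_correlation(X, y)
        assert s[0] == pytest.approx(s[2])

    def test_noise_band_score_below_permutation_null(self, rng):
        """|r| of a pure-noise band falls below the 95th percentile of its
        permutation null distribution at large n."""
        n = 2000
        y = np.repeat(["a", "b", "c", "d"], n // 4)
        noise = rng.normal(0, 1, (n, 1))
        score = feature_class_correlation(noise, y)[0]
        null = []
        for _ in range(200):
            null.append(
                feature_class_correlation(noise, rng.permutation(y))[0]
            )
        assert score < np.quantile(null, 0.95) + 0.02

    def test_zero_variance_band_scores_zero_with_warning(self):
        y = np.repeat(["a", "b"], 10)
        X = np.column_stack([np.ones(20), (y == "a").astype(float)])
        with pytest.warns(UserWarning, match="zero-variance"):
            s = feature_class_correlation(X, y)
        assert s[0] == 0.0


class TestMerit:
    CC = np.array([0.8, 0.8, 0.5])

    def test_singleton_merit_is_class_correlation(self):
        fc = np.eye(3)
        assert cfs_merit([0], self.CC, fc) == pytest.approx(0.8)

    def test_two_uncorrelated_bands_beat_one(self):
        """merit({i,j}) = 2c/sqrt(2) > c for uncorrelated bands."""
        fc = np.eye(3)
        m2 = cfs_merit([0, 1], self.CC, fc)
        assert m2 == pytest.approx(2 * 0.8 / np.sqrt(2))
        assert m2 > cfs_merit([0], self.CC, fc)

    def test_adding_exact_duplicate_decreases_merit(self):
        """From a pair of uncorrelated bands, adding an exact duplicate of
        one of them lowers the merit (verified algebraically:
        3c/sqrt(5) < 2c/sqrt(2)).  From a single band the merit is exactly
        unchanged (k*c/sqrt(k^2) = c), so a duplicate is never selected."""
        fc = np.eye(3)
        fc[0, 2] = fc[2, 0] = 1.0  # band 2 duplicates band 0; band 1 independent
        cc = np.array([0.8, 0.8, 0.8])
        assert cfs_merit([0, 1, 2], cc, fc) < cfs_merit([0, 1], cc, fc)
        assert cfs_merit([0, 2], cc, fc) == pytest.approx(cfs_merit([0], cc, fc))


class TestGreedySearch:
    def test_recovers_planted_informative_bands(self):
        X, y = planted_design()
        res = greedy_stepwise_select(X, y, max_bands=3)
        assert set(res.selected_indices) == {10, 25, 40}

    def test_greedy_matches_exhaustive_on_planted_design(self):
        X, y = planted_design(n=200, n_bands=12, informative=(2, 7, 11))
        res = greedy_stepwise_select(X, y, max_bands=3)
        oracle_set, oracle_merit = exhaustive_best_subset(X, y, 3)
        assert set(res.selected_indices) == oracle_set
        assert res.merit_trace[-1] == pytest.approx(oracle_merit)

    def test_single_informative_band(self, rng):
        y = np.repeat(np.arange(2), 100)
        X = rng.normal(0, 1, (200, 6))
        X[:, 3] += 4.0 * (y == 1)
        res = greedy_stepwise_select(X, y)
        assert res.selected_indices[0] == 3
        # adding noise bands cannot improve merit at strict min_gain
        assert len(res.merit_trace) == len(res.selected_indices)
        assert all(
            b >= a for a, b in zip(res.merit_trace, res.merit_trace[1:])
        )

    def test_max_bands_zero_gives_empty_result(self):
        X, y = planted_design(n=100)
        res = greedy_stepwise_select(X, y, max_bands=0)
        assert len(res) == 0 and res.merit_trace == []

    def test_all_constant_input_warns_and_returns_empty(self):
        X = np.ones((40, 5))
        y = np.repeat(["a", "b"], 20)
        with pytest.warns(UserWarning):
            res = greedy_stepwise_select(X, y)
        assert len(res) == 0

    def test_affine_rescaling_invariance(self):
        """Per-band affine maps leave the Pearson-based selection unchanged."""
        X, y = planted_design(n=200)
        scale = np.linspace(0.5, 20.0, X.shape[1])
        offset = np.linspace(-3, 3, X.shape[1])
        r1 = greedy_stepwise_select(X, y, max_bands=5)
        r2 = greedy_stepwise_select(X * scale + offset, y, max_bands=5)
        assert r1.selected_indices == r2.selected_indices

    def test_deterministic_tie_break_lowest_index(self):
        y = np.repeat(np.arange(2), 30)
        base = np.repeat([0.0, 1.0], 30)
        X = np.column_stack([base, base])  # identical informative bands
        res = greedy_stepwise_select(X, y, max_bands=1)
        assert res.selected_indices == [0]

    def test_selected_wavelengths_cluster_in_discriminative_regions(
        self, tiny_dataset
    ):
        """On second-derivative synthetic patches the selected wavelengths
        fall where the treatment profiles actually differ (visible/red-edge/
        NIR/SWIR-dip regions), not in featureless parts of the grid."""
        from hsin.pipeline import (
            PipelineConfig,
            apply_transform,
            build_patch_library,
            select_bands,
        )
        from hsin.patches import SplitSpec, split_dataset

        cfg = PipelineConfig(
            n_scenes_per_treatment=2, patches_per_quadrant=3, sg_window=7,
            split=SplitSpec(seed=0),
        )
        lib = build_patch_library(tiny_dataset, cfg, seed=1)
        tr, va, te = split_dataset(lib, cfg.split)
        trT, _, _, _ = apply_transform(tr, va, te, "sderi", cfg)
        sel = select_bands(trT, max_bands=8)
        assert len(sel) >= 3
        # discriminative regions of the generator: green peak / red edge /
        # NIR plateau contrasts (500-1100 nm) and the ~1450 nm water dip
        informative = ((sel.selected_wavelengths >= 480)
                       & (sel.selected_wavelengths <= 1150)) | (
            (sel.selected_wavelengths >= 1250)
            & (sel.selected_wavelengths <= 1700)
        )
        assert informative.mean() >= 0.75
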