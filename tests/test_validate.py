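"""Cross-validation schemes, bias, outliers, and selection proportions."""

import numpy as np
import pandas as pd
import pytest

from cyclegs.markers import MarkerMatrix, compute_kinship, filter_markers, impute_missing
from cyclegs.simdata import GRAIN_YIELD, simulate_program, small_config
from cyclegs.validate import (
    GSData,
    _make_folds,
    across_cycle_cv,
    between_cycle_bias,
    bias_percent,
    identify_outlier_trials,
    identify_outliers,
    independent_validation,
    outlier_corrected_cv,
    pairwise_cycle_matrix,
    relatedness_accuracy_correlation,
    selection_proportion,
    within_cycle_cv,
)


@pytest.fixture(scope="module")
def marker_determined_data(rng):
    """Adjusted means that are an exact linear function of the markers.

    With fewer markers than training lines the model saturates: every
    fold's ridge solution recovers the generating effects exactly, so
    out-of-fold GEBVs equal the adjusted means.
    """
    n_per, n_cycles, m = 32, 3, 20
    ids, cycles, codes = [], [], []
    for c in range(n_cycles):
        block = rng.choice([-1.0, 1.0], size=(n_per, m))
        codes.append(block)
        ids += [f"C{c}_L{i}" for i in range(n_per)]
        cycles += [c] * n_per
    codes = np.vstack(codes)
    mm = MarkerMatrix(ids, [f"M{j}" for j in range(m)], codes)
    w = rng.normal(0, 0.5, m)
    blues = pd.DataFrame(
        {"cycle": cycles, "trait": GRAIN_YIELD, "line": ids, "blue": codes @ w}
    )
    return GSData(markers=mm, blues=blues)


class TestFolds:
    def test_partition_covers_every_line_once(self, rng):
        ids = np.array([f"L{i}" for i in range(23)], dtype=object)
        folds = _make_folds(rng, ids, 5)
        assert sorted(np.concatenate(folds)) == sorted(ids)
        sizes = sorted(len(f) for f in folds)
        assert sizes in ([4, 4, 5, 5, 5], [4, 5, 4, 5, 5])
        assert max(sizes) - min(sizes) <= 1


class TestWithinCycle:
    def test_same_seed_identical_replicates(self, sim_data):
        a = within_cycle_cv(sim_data, 0, GRAIN_YIELD, reps=3, seed=11)
        b = within_cycle_cv(sim_data, 0, GRAIN_YIELD, reps=3, seed=11)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_marker_determined_blues_predicted_near_perfectly(self, marker_determined_data):
        res = within_cycle_cv(marker_determined_data, 0, GRAIN_YIELD, n_folds=4, reps=3, seed=0)
        assert res.mean > 0.95

    def test_too_small_fold_errors(self, marker_determined_data):
        with pytest.raises(ValueError, match="3 lines"):
            within_cycle_cv(marker_determined_data, 0, GRAIN_YIELD, n_folds=14, reps=2, seed=0)

    def test_r_mt_reported_when_truth_available(self, sim_data):
        res = within_cycle_cv(sim_data, 1, GRAIN_YIELD, reps=2, seed=3)
        assert res.replicates_mt is not None
        assert np.all(np.abs(res.replicates_mt) <= 1.0)


class TestBias:
    def test_bias_percent_arithmetic(self):
        assert bias_percent(0.4, 0.2) == pytest.approx(100.0)
        assert bias_percent(0.3, 0.3) == pytest.approx(0.0)
        assert np.isnan(bias_percent(0.4, 0.0))
        assert np.isnan(bias_percent(0.4, -0.1))

    def test_reuses_within_cycle_folds_bit_exactly(self, sim_data):
        """Same master seed: the within-cycle accuracy computed by the
        between-cycle scheme equals the standalone within-cycle run."""
        within = within_cycle_cv(sim_data, 0, GRAIN_YIELD, reps=3, seed=21)
        res = between_cycle_bias(sim_data, 0, GRAIN_YIELD, reps=3, seed=21)
        np.testing.assert_array_equal(res.within.replicates, within.replicates)

    def test_needs_two_cycles(self, marker_determined_data):
        single = GSData(
            markers=marker_determined_data.markers,
            blues=marker_determined_data.blues[marker_determined_data.blues.cycle == 0],
        )
        with pytest.raises(ValueError, match=">= 2 cycles"):
            between_cycle_bias(single, 0, GRAIN_YIELD, reps=1, seed=0)


class TestAcrossCycle:
    def test_zero_train_size_errors(self, sim_data):
        with pytest.raises(ValueError, match="positive"):
            across_cycle_cv(sim_data, GRAIN_YIELD, 0, reps=1, seed=0)

    def test_indivisible_train_size_errors(self, sim_data):
        with pytest.raises(ValueError, match="divisible"):
            across_cycle_cv(sim_data, GRAIN_YIELD, 46, reps=1, seed=0)

    def test_quota_exceeding_cycle_names_it(self, sim_data):
        with pytest.raises(ValueError, match="cycle"):
            across_cycle_cv(sim_data, GRAIN_YIELD, 400, reps=1, seed=0)

    def test_deterministic(self, sim_data):
        a = across_cycle_cv(sim_data, GRAIN_YIELD, 48, reps=3, seed=5)
        b = across_cycle_cv(sim_data, GRAIN_YIELD, 48, reps=3, seed=5)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_excluding_nothing_equals_plain_scheme(self, sim_data):
        a = across_cycle_cv(sim_data, GRAIN_YIELD, 48, reps=3, seed=5)
        b = outlier_corrected_cv(sim_data, (), 48, GRAIN_YIELD, reps=3, seed=5)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_validation_cycle_not_a_fold(self, sim_data):
        res = across_cycle_cv(sim_data, GRAIN_YIELD, 48, reps=2, seed=5)
        assert sim_data.validation_cycle not in res.meta.get("exclude", ())
        assert len(sim_data.breeding_cycles) == 5


@pytest.fixture(scope="module")
def outlier_sim():
    """Five 64-line cycles, the third with every trial sign-flipped."""
    cfg = small_config(
        seed=31, missing_rate=0.0, n_validation_lines=0,
        lines_per_cycle=(64,) * 5,
        target_h2={GRAIN_YIELD: 0.6, "protein_content": 0.8},
        outlier_trial_spec=tuple((2, j, -1) for j in range(3)),
    )
    from cyclegs.validate import dataset_from_simulation

    pop, plots = simulate_program(cfg)
    return dataset_from_simulation(pop, plots)


class TestPairwiseAndOutliers:
    def test_sign_flipped_cycle_has_lowest_training_row(self, outlier_sim):
        M = pairwise_cycle_matrix(outlier_sim, GRAIN_YIELD, reps_diag=3, seed=2)
        vals = M.to_numpy().copy()
        np.fill_diagonal(vals, np.nan)
        row_means = np.nanmean(vals, axis=1)
        assert np.argmin(row_means) == 2
        assert identify_outliers(M) == [2]

    def test_deterministic(self, outlier_sim):
        a = pairwise_cycle_matrix(outlier_sim, GRAIN_YIELD, reps_diag=2, seed=2)
        b = pairwise_cycle_matrix(outlier_sim, GRAIN_YIELD, reps_diag=2, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_equal_row_means_no_outliers(self):
        M = pd.DataFrame(0.4 * np.ones((4, 4)), index=range(4), columns=range(4))
        assert identify_outliers(M) == []

    def test_fewer_than_three_units_errors(self):
        M = pd.DataFrame(np.ones((2, 2)))
        with pytest.raises(ValueError, match=">= 3"):
            identify_outliers(M)

    def test_trial_variant_flags_negative_training_row(self):
        M = pd.DataFrame(0.3 * np.ones((4, 4)), index=list("abcd"), columns=list("abcd"))
        M.loc["c"] = -0.1  # negative mean accuracy as training set
        flagged = identify_outlier_trials(M)
        assert "c" in flagged


class TestSelectionProportions:
    def test_perfect_gebv_full_recovery(self, rng):
        blue = pd.Series(rng.normal(size=50), index=[f"L{i}" for i in range(50)])
        for q in (0.1, 0.2, 0.3):
            assert selection_proportion(blue.copy(), blue, q, "best") == 1.0
            assert selection_proportion(blue.copy(), blue, q, "worst") == 1.0

    def test_anticorrelated_gebv_misses_top_fraction(self, rng):
        blue = pd.Series(rng.normal(size=50), index=[f"L{i}" for i in range(50)])
        assert selection_proportion(-blue, blue, 0.1, "best") == 0.0

    def test_invalid_arguments(self, rng):
        blue = pd.Series(rng.normal(size=10), index=[f"L{i}" for i in range(10)])
        with pytest.raises(ValueError):
            selection_proportion(blue, blue, 0.0)
        with pytest.raises(ValueError):
            selection_proportion(blue, blue, 0.2, "sideways")


class TestIndependentValidation:
    def test_full_and_corrected_arms_reported(self, sim_data):
        out = independent_validation(
            sim_data, sim_data.breeding_cycles, sim_data.validation_cycle, GRAIN_YIELD,
            corrections={"drop_c2": (2,)},
        )
        assert list(out["correction"]) == ["full", "drop_c2"]
        assert {"r_GS", "prop_best_q10", "prop_worst_q30"} <= set(out.columns)
        assert out["n_train"].iloc[0] > out["n_train"].iloc[1]

    def test_overlap_rejected(self, sim_data):
        with pytest.raises(ValueError, match="overlap"):
            independent_validation(sim_data, sim_data.breeding_cycles, 0, GRAIN_YIELD)


class TestRelatednessAccuracy:
    def test_curve_shape_and_truncation(self, sim_data):
        filtered, _ = filter_markers(sim_data.markers)
        K = compute_kinship(impute_missing(filtered))
        with pytest.warns(UserWarning, match="truncated"):
            out = relatedness_accuracy_correlation(
                sim_data, K, GRAIN_YIELD, k_values=(1, 10, 5000)
            )
        assert set(out["held_cycle"]) == set(sim_data.breeding_cycles)
        assert (out.loc[out.k == 5000, "k_used"] < 5000).all()
        assert out["pearson_r"].abs().max() <= 1.0

    def test_k_equal_to_training_size_means_over_all(self, sim_data):
        filtered, _ = filter_markers(sim_data.markers)
        K = compute_kinship(impute_missing(filtered))
        held = 0
        train = np.concatenate(
            [sim_data.lines(c, GRAIN_YIELD) for c in sim_data.breeding_cycles if c != held]
        )
        out = relatedness_accuracy_correlation(sim_data, K, GRAIN_YIELD, k_values=(train.size,))
        row = out[(out.held_cycle == held)].iloc[0]
        # oracle: correlation using the plain mean over all training kinships
        val = sim_data.lines(held, GRAIN_YIELD)
        K_vt = K.K[np.ix_(K.indexer(val), K.indexer(train))]
        assert row["k_used"] == train.size
        assert np.isfinite(row["pearson_r"])
        # mean of k largest over all k entries is the row mean
        np.testing.assert_allclose(
            np.sort(K_vt, axis=1).mean(axis=1), K_vt.mean(axis=1), atol=1e-12
        )
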