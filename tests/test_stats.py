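import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from oralresponder import (
    ResponderClassifier,
    ValidationError,
    analyze_counts,
    assign_bands,
    classify_responders,
    compute_changes,
    compute_tau,
    generate_dataset,
    mean_patterns,
    percentile_cutpoints,
    scenario_presets,
    summarize_tau,
)

from conftest import make_delta


def naive_tau(delta_arr, leave_one_out=True):
    """Triple-loop reference implementation of τ (the test oracle)."""
    I, P, B = delta_arr.shape
    tau = np.zeros((I, P))
    for i in range(I):
        for p in range(P):
            for b_idx in range(B):
                if leave_one_out:
                    others = [delta_arr[j, p, b_idx] for j in range(I) if j != i]
                    m = sum(others) / (I - 1)
                else:
                    m = sum(delta_arr[j, p, b_idx] for j in range(I)) / I
                tau[i, p] += (delta_arr[i, p, b_idx] - m) ** 2
            tau[i, p] /= B
    return tau


def naive_loo_mean(delta_arr):
    I, P, B = delta_arr.shape
    out = np.zeros((I, P, B))
    for i in range(I):
        others = np.delete(delta_arr, i, axis=0)
        out[i] = others.mean(axis=0)
    return out


class TestComputeChanges:
    def test_change_is_difference_to_reference(self):
        idx = pd.MultiIndex.from_product([["A"], ["I", "II"]],
                                         names=["participant_id", "phase"])
        f = pd.DataFrame([[0.25, 0.75], [0.30, 0.70]], index=idx, columns=["a", "b"])
        delta = compute_changes(f)
        assert delta.loc[("A", "II"), "a"] == pytest.approx(0.05, abs=1e-12)
        assert list(delta.index.get_level_values("phase")) == ["II"]

    def test_reference_slice_gives_zero_change(self):
        idx = pd.MultiIndex.from_product([["A", "B"], ["I", "II"]],
                                         names=["participant_id", "phase"])
        f = pd.DataFrame(np.tile([0.4, 0.6], (4, 1)), index=idx, columns=["a", "b"])
        assert np.allclose(compute_changes(f).to_numpy(), 0.0)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(7)
        raw = rng.dirichlet(np.ones(5), size=6)
        idx = pd.MultiIndex.from_product([["A", "B"], ["I", "II", "III"]],
                                         names=["participant_id", "phase"])
        f = pd.DataFrame(raw, index=idx, columns=[f"g{j}" for j in range(5)])
        delta = compute_changes(f)
        assert np.allclose(delta.sum(axis=1).to_numpy(), 0.0, atol=1e-9)

    def test_missing_reference_phase_names_participant(self):
        idx = pd.MultiIndex.from_tuples(
            [("A", "I"), ("A", "II"), ("B", "II")],
            names=["participant_id", "phase"])
        f = pd.DataFrame(np.full((3, 2), 0.5), index=idx, columns=["a", "b"])
        with pytest.raises(ValidationError, match="B"):
            compute_changes(f, reference_phase="I")


class TestMeanPatterns:
    def test_two_participants_loo_is_the_other_profile(self):
        delta = make_delta([[[0.1, -0.1]], [[0.3, 0.1]]])
        pat = mean_patterns(delta)
        assert np.allclose(pat.mu_loo.loc[("P1", "ph1")].to_numpy(), [0.3, 0.1])
        assert np.allclose(pat.mu_loo.loc[("P2", "ph1")].to_numpy(), [0.1, -0.1])

    def test_hand_computed_mean_and_loo(self):
        delta = make_delta([[[0.1]], [[0.2]], [[0.3]]])
        pat = mean_patterns(delta)
        assert pat.mu.loc["ph1", "B1"] == pytest.approx(0.2, abs=1e-12)
        assert pat.mu_loo.loc[("P1", "ph1"), "B1"] == pytest.approx(0.25, abs=1e-12)

    def test_identical_profiles_make_loo_equal_full_mean(self):
        delta = make_delta(np.tile([[0.2, -0.2]], (4, 1, 1)))
        pat = mean_patterns(delta)
        for i in ("P1", "P2", "P3", "P4"):
            assert np.allclose(pat.mu_loo.loc[(i, "ph1")].to_numpy(),
                               pat.mu.loc["ph1"].to_numpy(), atol=1e-12)

    def test_single_participant_rejected(self):
        with pytest.raises(ValidationError, match="two participants"):
            mean_patterns(make_delta([[[0.1]]]))

    def test_loo_matches_direct_omission(self):
        rng = np.random.default_rng(11)
        arr = rng.normal(size=(5, 3, 4))
        pat = mean_patterns(make_delta(arr))
        got = pat.mu_loo.to_numpy().reshape(5, 3, 4)
        assert np.allclose(got, naive_loo_mean(arr), atol=1e-12)


class TestComputeTau:
    def test_two_participant_hand_example(self):
        delta = make_delta([[[0.1, -0.1]], [[0.3, 0.1]]])
        tau = compute_tau(delta)
        # each profile is compared against the other's: ((0.2)^2 + (0.2)^2)/2
        assert tau.loc["P1", "ph1"] == pytest.approx(0.04, abs=1e-12)
        assert tau.loc["P2", "ph1"] == pytest.approx(0.04, abs=1e-12)

    def test_identical_cohort_gives_zero(self):
        delta = make_delta(np.tile([[0.3, -0.3, 0.0]], (5, 1, 1)))
        assert np.allclose(compute_tau(delta).to_numpy(), 0.0)

    def test_quadratic_scaling_of_deviations(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(4, 2, 5))
        centered = arr - arr.mean(axis=0, keepdims=True)
        for c in (2.0, 5.0):
            tau_c = compute_tau(make_delta(arr.mean(axis=0, keepdims=True)
                                           + c * centered))
            assert np.allclose(tau_c.to_numpy(),
                               c ** 2 * compute_tau(make_delta(arr)).to_numpy(),
                               rtol=1e-12)

    @pytest.mark.parametrize("leave_one_out", [True, False])
    def test_matches_naive_loop_oracle(self, leave_one_out):
        rng = np.random.default_rng(42)
        for _ in range(50):
            I = rng.integers(2, 7)
            P = rng.integers(1, 5)
            B = rng.integers(1, 9)
            arr = rng.normal(size=(I, P, B))
            tau = compute_tau(make_delta(arr), leave_one_out=leave_one_out)
            assert np.allclose(tau.to_numpy(), naive_tau(arr, leave_one_out),
                               atol=1e-12)

    def test_plugin_mean_underestimates_loo_on_average(self):
        # the plug-in mean contains participant i, pulling the distance down
        rng = np.random.default_rng(0)
        diffs = []
        for _ in range(200):
            arr = rng.normal(size=(5, 2, 4))
            delta = make_delta(arr)
            diffs.append(compute_tau(delta, leave_one_out=False).to_numpy().mean()
                         - compute_tau(delta, leave_one_out=True).to_numpy().mean())
        assert np.mean(diffs) < 0


class TestSummaries:
    def test_constant_matrix(self):
        tau = pd.DataFrame(0.02, index=["A", "B", "C"], columns=["II", "III"])
        tau.index.name = "participant_id"
        s = summarize_tau(tau, rounding=None)
        assert s.loc["II", "mean"] == pytest.approx(0.02)
        assert s.loc["II", "sd"] == pytest.approx(0.0)
        assert s.loc["all", "A"] == pytest.approx(0.02)

    def test_published_table_phase_means(self, table1_tau):
        s = summarize_tau(table1_tau)
        assert s.loc["II", "mean"] == 0.014 and s.loc["II", "sd"] == 0.004
        assert s.loc["III", "mean"] == 0.017
        assert s.loc["all", "P1"] == 0.012


class TestPercentilesAndBands:
    def test_median_of_odd_set(self):
        tau = pd.DataFrame([[1.0], [2.0], [3.0], [4.0], [5.0]],
                           index=list("abcde"), columns=["II"])
        q = percentile_cutpoints(tau, probs=[0.5])
        assert q.iloc[0] == pytest.approx(3.0)

    def test_pooled_q40_matches_order_statistic_oracle(self, table1_tau):
        values = np.sort(table1_tau.to_numpy().ravel())
        h = 1 + (len(values) - 1) * 0.4  # linear interpolation rule
        lo, frac = int(np.floor(h)) - 1, h % 1
        expected = values[lo] + frac * (values[lo + 1] - values[lo])
        q = percentile_cutpoints(table1_tau, probs=[0.4])
        assert q.iloc[0] == pytest.approx(expected, abs=1e-15)
        assert 0.014 < q.iloc[0] < 0.015

    def test_degenerate_distribution(self):
        tau = pd.DataFrame(0.5, index=["a", "b"], columns=["II"])
        q = percentile_cutpoints(tau)
        assert np.allclose(q.to_numpy(), 0.5)

    def test_per_phase_layout(self, table1_tau):
        q = percentile_cutpoints(table1_tau, pooling="per_phase")
        assert list(q.index) == ["II", "III", "IV", "V"]
        assert (q.diff(axis=1).iloc[:, 1:].to_numpy() >= 0).all()

    def test_band_boundaries_right_closed(self):
        tau = pd.DataFrame([[0.1, 0.2, 0.3, 0.4, 0.5]],
                           index=["i"], columns=list("vwxyz"))
        bands = assign_bands(tau, [0.2, 0.3, 0.4, 0.45])
        assert bands.loc["i"].tolist() == [1, 1, 2, 3, 5]

    def test_largest_published_value_lands_in_top_band(self, table1_tau):
        report = classify_responders(table1_tau)
        assert report.bands.loc["P11", "V"] == 5
        assert report.bands.loc["P8", "V"] == 5


class TestClassification:
    def test_published_responders_recovered(self, table1_tau):
        report = classify_responders(table1_tau)
        assert report.typical == ["P1", "P2"]
        assert report.atypical == ["P11", "P6", "P8"]

    def test_all_equal_tau_means_everyone_intermediate(self):
        tau = pd.DataFrame(0.01, index=["a", "b", "c"], columns=["II", "III"])
        report = classify_responders(tau)
        assert (report.labels == "intermediate").all()

    def test_well_separated_three_participants(self):
        tau = pd.DataFrame([[0.001, 0.001], [0.01, 0.01], [0.1, 0.1]],
                           index=["lo", "mid", "hi"], columns=["II", "III"])
        report = classify_responders(tau)
        assert report.typical == ["lo"]
        assert report.atypical == ["hi"]
        # brute-force check of the percentile rule itself
        pooled = np.sort(tau.to_numpy().ravel())
        q40 = np.quantile(pooled, 0.4)
        q60 = np.quantile(pooled, 0.6)
        assert (tau.loc["lo"] < q40).all() and (tau.loc["hi"] > q60).all()

    def test_labels_invariant_under_increasing_affine_maps(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            tau = pd.DataFrame(rng.uniform(0.001, 0.05, size=(8, 4)),
                               index=[f"P{i}" for i in range(8)],
                               columns=["II", "III", "IV", "V"])
            base = classify_responders(tau).labels
            for a, b in ((3.0, 0.0), (0.5, 0.01), (10.0, 1.0)):
                mapped = classify_responders(a * tau + b).labels
                assert (mapped == base).all()

    def test_low_above_high_rejected(self, table1_tau):
        with pytest.raises(ValidationError):
            classify_responders(table1_tau, low=0.7, high=0.3)


@pytest.fixture(scope="module")
def fractions():
    table, _ = generate_dataset(scenario_presets("extreme"), seed=2)
    return analyze_counts(table).fractions


class TestResponderClassifierEstimator:
    def test_fitted_attributes_and_consistency(self, fractions):
        est = ResponderClassifier().fit(fractions)
        assert set(est.labels_.unique()) <= {"typical", "atypical", "intermediate"}
        report = classify_responders(est.tau_)
        assert (est.labels_ == report.labels).all()
        assert est.tau_.shape == (11, 4)
        assert np.allclose(est.summary_.loc["all", "mean"],
                           round(est.tau_.to_numpy().mean(), 3))

    def test_fit_predict_equals_labels(self, fractions):
        est = ResponderClassifier()
        assert (est.fit_predict(fractions) == est.labels_).all()

    def test_plugin_variant_changes_tau_not_contract(self, fractions):
        loo = ResponderClassifier().fit(fractions).tau_
        plugin = ResponderClassifier(leave_one_out=False).fit(fractions).tau_
        assert (plugin.to_numpy() <= loo.to_numpy() + 1e-15).all() or \
               not np.allclose(plugin.to_numpy(), loo.to_numpy())

    def test_clone_round_trips_params(self):
        est = ResponderClassifier(low=0.3, high=0.7, pooling="per_phase",
                                  leave_one_out=False)
        params = clone(est).get_params()
        assert params["low"] == 0.3 and params["pooling"] == "per_phase"
        assert params["leave_one_out"] is False
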