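"""Rates, signal-detection indices, thresholds, binning, HR averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from olfex import DogModel, make_block_design, randomize_session, run_session
from olfex.io import sessions_to_frame
from olfex.psychometrics import (
    a_prime,
    adjust_extreme_rates,
    b_double_prime,
    bin_results,
    determine_threshold,
    dilution_steps,
    hr_per_trial,
    latency_summary,
    outcome_rates,
)

from oracles import a_prime_roc_area

rates = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def make_trials(rows):
    """rows: (stimulus_class, conc, intensity, outcome, latency)"""
    return pd.DataFrame(
        rows,
        columns=["stimulus_class", "concentration_vv", "intensity_kmh", "outcome", "latency_s"],
    )


def cell_rows(conc, intensity, hits, misses):
    rows = [("target", conc, intensity, "hit", 2.0)] * hits
    rows += [("target", conc, intensity, "miss", 10.0)] * misses
    return rows


def noise_rows(intensity, fas, crs):
    rows = [("diluent", np.nan, intensity, "false_alert", 1.5)] * fas
    rows += [("diluent", np.nan, intensity, "correct_rejection", 10.0)] * crs
    return rows


class TestAPrime:
    @pytest.mark.parametrize(
        "h,f,expected",
        [
            (0.5, 0.5, 0.5),  # no discrimination
            (1.0, 0.0, 1.0),  # perfect performance
            (0.75, 0.25, 5.0 / 6.0),  # direct evaluation of the index
            (0.0, 0.0, 0.5),
            (1.0, 1.0, 0.5),
        ],
    )
    def test_reference_values(self, h, f, expected):
        assert a_prime(h, f) == pytest.approx(expected, abs=1e-12)
        assert a_prime(h, f) == pytest.approx(a_prime_roc_area(h, f), abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(h=rates, f=rates)
    def test_matches_geometric_roc_oracle(self, h, f):
        assert a_prime(h, f) == pytest.approx(a_prime_roc_area(h, f), abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(h=rates, f=rates)
    def test_swap_symmetry(self, h, f):
        assert a_prime(f, h) == pytest.approx(1.0 - a_prime(h, f), abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            a_prime(1.2, 0.5)


class TestBDoublePrime:
    @pytest.mark.parametrize(
        "h,f,expected",
        [
            (0.75, 0.25, 0.0),  # H(1-H) = F(1-F): numerator vanishes
            (0.9, 0.3, -0.4),  # go bias
            (0.3, 0.9, -0.4),  # sgn prefactor: swap leaves B'' unchanged
        ],
    )
    def test_reference_values(self, h, f, expected):
        assert b_double_prime(h, f) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("h", np.linspace(0.05, 0.95, 10))
    def test_unbiased_when_rates_mirror(self, h):
        assert b_double_prime(h, 1.0 - h) == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(h=st.floats(0.01, 0.99), f=st.floats(0.01, 0.99))
    def test_swap_symmetry(self, h, f):
        # the sgn(H-F) prefactor makes the index invariant under swapping
        # H and F: the magnitude measures bias, the sign the direction
        assert b_double_prime(f, h) == pytest.approx(b_double_prime(h, f), abs=1e-12)

    def test_degenerate_needs_counts(self):
        with pytest.raises(ValueError):
            b_double_prime(1.0, 0.0)
        # with counts the 1/(2N) adjustment applies first
        val = b_double_prime(1.0, 0.0, n_signal=25, n_noise=50)
        h, f = 1 - 1 / 50, 1 / 100
        expected = (h * (1 - h) - f * (1 - f)) / (h * (1 - h) + f * (1 - f))
        assert val == pytest.approx(expected)

    def test_extreme_rate_adjustment(self):
        h, f = adjust_extreme_rates(0.0, 1.0, 25, 50)
        assert h == pytest.approx(1 / 50)
        assert f == pytest.approx(1 - 1 / 100)
        # interior rates untouched
        assert adjust_extreme_rates(0.6, 0.1, 25, 50) == (0.6, 0.1)


class TestOutcomeRates:
    def test_hit_rate_arithmetic(self):
        trials = make_trials(cell_rows(1e-3, 8, 45, 5) + noise_rows(8, 0, 50))
        summary, sdt = outcome_rates(trials)
        assert summary.loc[0, "hit_rate"] == pytest.approx(0.9)
        assert summary.loc[0, "n_trials"] == 50
        assert sdt.loc[0, "F"] == 0.0

    def test_false_alert_pool_shared_across_concentrations(self):
        trials = make_trials(
            cell_rows(1e-3, 8, 10, 3) + cell_rows(1e-4, 8, 6, 7) + noise_rows(8, 2, 23)
        )
        _, sdt = outcome_rates(trials)
        assert (sdt["F"] == 2 / 25).all()
        assert (sdt["n_noise"] == 25).all()

    def test_empty_cells_absent_not_zero(self):
        trials = make_trials(cell_rows(1e-3, 8, 13, 0) + noise_rows(8, 1, 24))
        summary, _ = outcome_rates(trials)
        assert len(summary) == 1
        assert summary.loc[0, "hit_rate"] == 1.0

    def test_correction_bounds_extreme_cells(self):
        trials = make_trials(cell_rows(1e-3, 8, 13, 0) + noise_rows(8, 0, 25))
        _, sdt = outcome_rates(trials, correction=True)
        assert sdt.loc[0, "H"] == 1.0  # raw rate reported
        assert sdt.loc[0, "a_prime"] < 1.0  # index computed from adjusted rates
        _, raw = outcome_rates(trials, correction=False)
        assert raw.loc[0, "a_prime"] == 1.0


class TestDetermineThreshold:
    concs = [1e-2, 10**-2.5, 1e-3, 10**-3.5]

    def summary(self, rates, intensity=8):
        return pd.DataFrame(
            {
                "concentration_vv": self.concs,
                "intensity_kmh": intensity,
                "hit_rate": rates,
            }
        )

    def test_first_concentration_at_or_below_half(self):
        thr = determine_threshold(self.summary([1.0, 0.9, 0.8, 0.45]))
        assert thr.reached
        assert thr.threshold_concentration == pytest.approx(10**-3.5)
        assert thr.dilution_steps[1e-2] == pytest.approx(1.5)

    def test_all_above_half_not_reached(self):
        thr = determine_threshold(self.summary([1.0, 0.9, 0.8, 0.6]))
        assert not thr.reached
        assert thr.threshold_concentration is None
        assert thr.dilution_steps is None

    def test_inclusive_rule_at_exactly_half(self):
        thr = determine_threshold(self.summary([0.9, 0.5, 0.2, 0.1]))
        assert thr.threshold_concentration == pytest.approx(10**-2.5)

    def test_descending_first_wins_over_lower_qualifiers(self):
        thr = determine_threshold(self.summary([0.9, 0.4, 0.9, 0.2]))
        assert thr.threshold_concentration == pytest.approx(10**-2.5)

    def test_specific_intensity_filter(self):
        df = pd.concat(
            [self.summary([1.0, 0.9, 0.8, 0.4], 8), self.summary([1.0, 1.0, 0.9, 0.8], 4)],
            ignore_index=True,
        )
        assert determine_threshold(df, intensity=8).reached
        assert not determine_threshold(df, intensity=4).reached
        either = determine_threshold(df, intensity="either")
        assert either.intensity == 8


class TestDilutionSteps:
    @pytest.mark.parametrize(
        "conc,thr,expected,tol",
        [
            (0.00316, 0.001, 0.5, 5e-4),  # the printed concentration is rounded
            (10**-2.5, 10**-3, 0.5, 1e-12),
            (0.01, 0.001, 1.0, 1e-12),
            (0.001, 0.001, 0.0, 1e-12),
        ],
    )
    def test_worked_examples(self, conc, thr, expected, tol):
        assert dilution_steps(conc, thr) == pytest.approx(expected, abs=tol)

    @settings(derandomize=True, max_examples=100)
    @given(
        c=st.floats(1e-8, 1e-1), t=st.floats(1e-8, 1e-1)
    )
    def test_linear_in_log_concentration(self, c, t):
        step = dilution_steps(c, t)
        assert dilution_steps(c * 10**0.5, t) - step == pytest.approx(0.5, abs=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dilution_steps(0.0, 0.001)


class TestBinResults:
    def trials_at(self, indices_starts):
        rows = []
        for idx, start in indices_starts:
            rows.append(
                {
                    "trial_index": idx,
                    "stimulus_class": "target",
                    "concentration_vv": 1e-3,
                    "intensity_kmh": 8,
                    "outcome": "hit",
                    "latency_s": 1.0,
                    "start_s": start,
                }
            )
        return pd.DataFrame(rows)

    def test_trial_block_boundaries(self):
        out = bin_results(self.trials_at([(75, 0.0), (76, 0.0)]), "trial_block_25")
        assert sorted(out["bin_index"]) == [3, 4]

    def test_time_bins_half_open(self):
        out = bin_results(
            self.trials_at([(1, 599.9), (2, 600.0), (3, 1250.0), (4, 2400.0)]),
            "time_bin_10min",
        )
        assert sorted(out["bin_index"]) == [1, 2, 3]
        # 600.0 s falls in the second bin; everything past 20 min pools in
        # the open-ended third bin
        assert out.set_index("bin_index")["n_trials"].to_dict() == {1: 1, 2: 1, 3: 2}

    def test_strong_decay_silences_final_block(self):
        design = make_block_design(2, 10**-3.5)
        # resting threshold well below the block's lowest concentration, so
        # early blocks sit at ceiling and the collapse is purely duration
        dog = DogModel(mu0=-5.9, decay_rate=0.3, lapse=0.0,
                       fa_rate_low=0.0, fa_rate_mod=0.0)
        plan = randomize_session(design, 8, seed=2)
        frame = sessions_to_frame([run_session(plan, dog, seed=2)])
        out = bin_results(frame, "trial_block_25")
        lowest = out[np.isclose(out.concentration_vv, design.concentrations[-1])]
        assert lowest[lowest.bin_index == 4]["hit_rate"].iloc[0] == 0.0
        assert lowest[lowest.bin_index == 1]["hit_rate"].iloc[0] > 0.5


class TestLatencySummary:
    def test_censored_mean(self):
        trials = make_trials(
            [
                ("target", 1e-3, 8, "hit", 2.0),
                ("target", 1e-3, 8, "hit", 4.0),
                ("target", 1e-3, 8, "miss", 10.0),
            ]
        )
        out = latency_summary(trials)
        assert out.loc[0, "mean_latency_s"] == pytest.approx(16.0 / 3.0)

    def test_all_misses_average_the_censor_value(self):
        trials = make_trials([("target", 1e-3, 8, "miss", 10.0)] * 7)
        assert latency_summary(trials).loc[0, "mean_latency_s"] == 10.0


class TestHrPerTrial:
    def trials(self):
        return pd.DataFrame(
            {"trial_index": [1, 2], "start_s": [99.5, 200.0], "end_s": [104.5, 200.4]}
        )

    def test_window_average(self):
        hr = pd.DataFrame({"timestamp_s": [100.0, 102.0, 104.0, 200.9], "bpm": [100, 102, 104, 90]})
        out = hr_per_trial(hr, self.trials())
        assert out.loc[0, "mean_bpm"] == pytest.approx(102.0)
        assert out.loc[0, "n_samples"] == 3

    def test_trial_without_samples_flagged_missing(self):
        hr = pd.DataFrame({"timestamp_s": [100.0, 102.0], "bpm": [100, 102]})
        out = hr_per_trial(hr, self.trials())
        assert np.isnan(out.loc[1, "mean_bpm"])
        assert out.loc[1, "n_samples"] == 0

    def test_constant_series(self):
        hr = pd.DataFrame({"timestamp_s": np.arange(300.0), "bpm": 97.0})
        out = hr_per_trial(hr, self.trials())
        assert (out["mean_bpm"].dropna() == 97.0).all()

    def test_unordered_timestamps_rejected(self):
        hr = pd.DataFrame({"timestamp_s": [5.0, 1.0], "bpm": [100, 100]})
        with pytest.raises(ValueError):
            hr_per_trial(hr, self.trials())
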