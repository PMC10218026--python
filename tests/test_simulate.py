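"""Generator correctness: design balance, observer model, epoch structure."""

import numpy as np
import pandas as pd
import pytest

import serialdep as sd
from serialdep.params import (
    CATCH_CONTRAST,
    CouplingParams,
    EEGSimParams,
    EXP1_INDUCER_LEVELS,
    ObserverParams,
    PROBE_LEVELS,
)


class TestExp1Design:
    def test_total_and_cell_counts(self):
        table = sd.generate_design_exp1("numerosity", n_reps_per_cell=10, seed=1)
        assert len(table) == 400
        cells = table.groupby(["inducer_numerosity", "inducer_duration",
                               "inducer_size", "probe"]).size()
        assert len(cells) == 40 and (cells == 10).all()

    def test_inducer_combination_balance(self):
        table = sd.generate_design_exp1("size", n_reps_per_cell=10, seed=1)
        combos = table.groupby(["inducer_numerosity", "inducer_duration",
                                "inducer_size"]).size()
        assert (combos == 50).all()

    @pytest.mark.parametrize("task", ["numerosity", "duration", "size"])
    def test_probe_levels_match_task(self, task):
        table = sd.generate_design_exp1(task, n_reps_per_cell=1, seed=0)
        assert set(table["probe"]) == set(PROBE_LEVELS[task])

    def test_seeded_reproducibility(self):
        a = sd.generate_design_exp1("duration", 10, seed=5)
        b = sd.generate_design_exp1("duration", 10, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError, match="task"):
            sd.generate_design_exp1("orientation", 10, seed=0)


class TestExp2Design:
    def test_full_stream_counts(self):
        table = sd.generate_design_exp2(n_blocks=8, reps_per_combo=80,
                                        catch_per_block=10, seed=2)
        assert len(table) == 2160
        combos = table.groupby(["numerosity", "duration", "size"]).size()
        assert len(combos) == 27 and (combos == 80).all()
        assert np.isclose(table.is_catch.mean(), 10 / 270)
        assert (table.loc[table.is_catch, "contrast"] == CATCH_CONTRAST).all()

    def test_minimal_factorial(self):
        table = sd.generate_design_exp2(n_blocks=1, reps_per_combo=1,
                                        catch_per_block=0, seed=3)
        assert len(table) == 27
        assert table.groupby(["numerosity", "duration", "size"]).size().eq(1).all()

    def test_past_labels_shift_and_first_trial_unusable(self):
        table = sd.generate_design_exp2(n_blocks=1, reps_per_combo=2,
                                        catch_per_block=0, seed=4)
        assert not table["usable"].iloc[0]
        assert np.isnan(table["past_numerosity"].iloc[0])
        assert (table["past_duration"].iloc[1:].to_numpy()
                == table["duration"].iloc[:-1].to_numpy()).all()

    def test_indivisible_blocks_rejected(self):
        with pytest.raises(ValueError, match="block"):
            sd.generate_design_exp2(n_blocks=7, reps_per_combo=80,
                                    catch_per_block=10, seed=0)


class TestObserver:
    def test_degenerate_slope_is_step_function(self):
        table = sd.generate_design_exp1("numerosity", 5, seed=6)
        obs = ObserverParams(pse_base=16.0, sigma=1e-9, lapse=0.0)
        out = sd.simulate_responses(table, obs, seed=7)
        # at probe == PSE the choice probability is 1/2 even in the limit
        off = out[out["probe"] != 16.0]
        assert (off["response"] == (off["probe"] > 16).astype(float)).all()

    def test_unbiased_observer_null_effect(self):
        table = sd.generate_design_exp1("numerosity", 10, seed=8)
        obs = ObserverParams(pse_base=16.0, sigma=2.7, lapse=0.05)
        out = sd.simulate_responses(table, obs, seed=9)
        _, _, eff = sd.effects_by_inducer(out, "numerosity")
        assert abs(eff.eff) < 6.0  # Monte-Carlo tolerance at n=400

    def test_passive_table_rejected(self):
        passive = sd.generate_design_exp2(1, 1, 0, seed=0)
        with pytest.raises(ValueError, match="probe"):
            sd.simulate_responses(passive, ObserverParams(), seed=0)

    def test_bias_shifts_response_rates(self):
        # An attractive numerosity bias makes "probe greater" responses rarer
        # after a high-numerosity inducer.
        table = sd.generate_design_exp1("numerosity", 25, seed=10)
        obs = ObserverParams(bias_per_dimension={"numerosity": 3.0})
        out = sd.simulate_responses(table, obs, seed=11)
        lo, hi = EXP1_INDUCER_LEVELS["numerosity"]
        p_lo = out[out.inducer_numerosity == lo]["response"].mean()
        p_hi = out[out.inducer_numerosity == hi]["response"].mean()
        assert p_hi < p_lo


class TestEpochs:
    def test_epoch_grid_spans_stated_window(self):
        eeg = EEGSimParams(n_channels=4, sampling_rate=250.0,
                           epoch_start=-200.0, epoch_end=700.0, noise_sd=0.5)
        table = sd.generate_design_exp1("numerosity", 1, seed=12)
        ep = sd.simulate_epochs(table, eeg, subject_amplitude=0.0)
        assert ep.time_ms[0] == -200.0 and ep.time_ms[-1] == 700.0
        assert ep.data.shape == (40, 4, 226)

    def test_zero_amplitude_classes_identical_in_expectation(self, null_epochs):
        ep0, ep1 = sd.sort_epochs_by_past(null_epochs, "numerosity")
        diff = ep0.data.mean(axis=0) - ep1.data.mean(axis=0)
        # standardize by the sampling SD of a mean difference; the bound
        # accounts for taking the max over ~1400 (correlated) samples
        noise_sd = (null_epochs.data - null_epochs.data.mean(axis=0)).std()
        z = diff / (noise_sd * np.sqrt(2.0 / ep0.n_trials))
        assert np.abs(z).max() < 5.5
        assert abs(z.mean()) < 0.5

    def test_signal_window_outside_span_rejected(self):
        eeg = EEGSimParams(n_channels=4, epoch_start=-100.0, epoch_end=300.0,
                           signal_windows=((500.0, 650.0, {"numerosity": 1.0}),))
        table = sd.generate_design_exp1("numerosity", 1, seed=13)
        with pytest.raises(ValueError, match="outside"):
            sd.simulate_epochs(table, eeg)

    def test_hdf5_round_trip(self, tmp_path, signal_epochs):
        path = tmp_path / "ep.h5"
        signal_epochs.save_h5(path)
        back = sd.EpochSet.load_h5(path)
        np.testing.assert_array_equal(back.data, signal_epochs.data)
        np.testing.assert_array_equal(back.time_ms, signal_epochs.time_ms)
        pd.testing.assert_frame_equal(back.trial_meta, signal_epochs.trial_meta,
                                      check_dtype=False)


class TestCohort:
    def test_cardinality_and_determinism(self, short_eeg):
        coup = CouplingParams(slope=10.0, intercept=2.0, noise_sd=1.0)
        a = sd.simulate_cohort(2, ObserverParams(), short_eeg, coup, seed=30,
                               n_reps_per_cell=1)
        b = sd.simulate_cohort(2, ObserverParams(), short_eeg, coup, seed=30,
                               n_reps_per_cell=1)
        assert len(a) == 2
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.table, y.table)
            np.testing.assert_array_equal(x.epochs.data, y.epochs.data)
            assert x.true_effect == y.true_effect

    def test_effect_follows_coupling(self, short_eeg):
        coup = CouplingParams(slope=20.0, intercept=1.0, noise_sd=0.0,
                              amplitude_mean=1.0, amplitude_sd=0.3)
        cohort = sd.simulate_cohort(6, ObserverParams(), short_eeg, coup,
                                    seed=31, n_reps_per_cell=1)
        for sub in cohort:
            assert np.isclose(sub.true_effect, 1.0 + 20.0 * sub.amplitude)

    def test_too_small_cohort_rejected(self, short_eeg):
        with pytest.raises(ValueError, match="subjects"):
            sd.simulate_cohort(1, ObserverParams(), short_eeg, CouplingParams(),
                               seed=0)
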