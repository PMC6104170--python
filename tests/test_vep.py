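"""Peri-stimulus extraction, state sorting, averaging and magnitude scoring."""
import numpy as np
import pytest

import stabvep as sv
from stabvep.errors import GridError
from stabvep.vep import VEPWaveform, _interval_of, peristimulus_time_axis

from conftest import make_features, make_recording

FS = 400.0


def waveform(values, pre_s=0.5):
    values = np.asarray(values, float)
    t = np.arange(len(values)) / FS - pre_s
    return VEPWaveform(time_s=t, mean_uv=values, n_trials=1)


class TestExtraction:
    def test_window_index_arithmetic(self):
        rec = make_recording(eeg=np.arange(1600.0))
        train = sv.StimulusTrain([1.0])
        segments, onsets, dropped = sv.extract_peristimulus(rec, train)
        assert segments.shape == (1, 401)
        assert onsets[0] == 400
        assert np.array_equal(segments[0], np.arange(200.0, 601.0))
        assert dropped == 0

    def test_onset_too_close_to_start_is_dropped_and_tallied(self):
        rec = make_recording(n=1600)
        segments, _, dropped = sv.extract_peristimulus(rec, sv.StimulusTrain([0.2, 2.0]))
        assert len(segments) == 1
        assert dropped == 1

    def test_empty_train_yields_empty_list(self):
        segments, _, dropped = sv.extract_peristimulus(
            make_recording(n=800), sv.StimulusTrain([]))
        assert len(segments) == 0 and dropped == 0


class TestTrialState:
    def test_onset_labeled_by_containing_epoch(self):
        hyp = sv.Hypnogram(["WAKE", "SWS", "REMS"],
                           wake_substates=["QW", "NOT_WAKE", "NOT_WAKE"])
        labels = sv.assign_trial_state(sv.StimulusTrain([15.0]), hyp)
        assert labels[0] == "SWS"

    def test_onset_on_boundary_belongs_to_later_epoch(self):
        hyp = sv.Hypnogram(["SWS", "SWS", "REMS"])
        labels = sv.assign_trial_state(sv.StimulusTrain([20.0]), hyp)
        assert labels[0] == "REMS"

    def test_unscored_epoch_trials_excluded(self):
        hyp = sv.Hypnogram(["SWS", "UNSCORED"])
        labels = sv.assign_trial_state(sv.StimulusTrain([5.0, 15.0]), hyp)
        assert list(labels) == ["SWS", "EXCLUDED"]


class TestAveraging:
    def test_mean_of_identical_copies_is_the_template(self, rng):
        template = rng.normal(0, 10, 401)
        segments = np.tile(template, (12, 1))
        wfs = sv.average_vep(segments, ["SWS"] * 12, FS)
        assert np.allclose(wfs["SWS"].mean_uv, template, rtol=1e-12, atol=1e-12)
        assert wfs["SWS"].n_trials == 12

    def test_opposite_trials_cancel(self, rng):
        v = rng.normal(0, 5, 401)
        wfs = sv.average_vep(np.stack([v, -v] * 5), ["QW"] * 10, FS)
        assert np.allclose(wfs["QW"].mean_uv, 0.0)

    def test_small_groups_omitted_with_warning(self, rng):
        segments = rng.normal(0, 1, (4, 401))
        with pytest.warns(UserWarning, match="min_trials"):
            wfs = sv.average_vep(segments, ["AW"] * 4, FS, min_trials=10)
        assert wfs == {}

    def test_noisy_average_converges_to_template(self, rng):
        template = 50.0 * sv.vep_template(FS)
        template = np.concatenate([np.zeros(200), template])[:401]
        sigma, n_trials = 20.0, 40
        trials = template + rng.normal(0, sigma, (n_trials, len(template)))
        wfs = sv.average_vep(trials, ["QW"] * n_trials, FS)
        assert np.abs(wfs["QW"].mean_uv - template).max() <= 5 * sigma / np.sqrt(n_trials)


class TestMagnitude:
    def test_quoted_definition(self):
        values = np.zeros(401)
        values[260] = -80.0   # +150 ms (onset at index 200)
        values[300] = +20.0   # +250 ms
        assert sv.vep_magnitude(waveform(values)) == pytest.approx(100.0)

    def test_zero_waveform_scores_zero(self):
        assert sv.vep_magnitude(waveform(np.zeros(401))) == 0.0

    def test_constant_offset_invariance(self, rng):
        values = rng.normal(0, 10, 401)
        m0 = sv.vep_magnitude(waveform(values))
        m1 = sv.vep_magnitude(waveform(values + 37.5))
        assert m1 == pytest.approx(m0)

    def test_grid_not_covering_latency_raises(self):
        with pytest.raises(GridError):
            sv.vep_magnitude(waveform(np.zeros(250)))  # ends at +0.12 s

    def test_linearity_mean_of_scores_equals_score_of_mean(self, rng):
        trials = rng.normal(0, 30, (25, 401))
        per_trial = [
            sv.vep_magnitude(waveform(trial)) for trial in trials
        ]
        pooled = sv.vep_magnitude(waveform(trials.mean(axis=0)))
        assert pooled == pytest.approx(np.mean(per_trial), rel=1e-9)

    def test_local_extremum_search_at_least_fixed_readout(self):
        tpl = 60.0 * sv.vep_template(FS)
        values = np.concatenate([np.zeros(200), tpl])[:401]
        w = waveform(values)
        fixed = sv.vep_magnitude(w)
        searched = sv.vep_magnitude(w, search_halfwidth_s=0.0125)
        assert searched >= fixed


class TestGroupedTables:
    def make_session(self):
        """Tiny deterministic session: 8 epochs, one trial per epoch, template
        amplitude fixed per effective state, no background EEG."""
        states = ["QW", "QW", "AW", "AW", "SWS", "SWS", "REMS", "QW"]
        base = ["WAKE" if s in ("QW", "AW") else s for s in states]
        subs = [s if s in ("QW", "AW") else "NOT_WAKE" for s in states]
        hyp = sv.Hypnogram(base, wake_substates=subs)
        scale = {"QW": 90.0, "AW": 60.0, "SWS": 100.0, "REMS": 70.0}
        fs = FS
        n = int(len(states) * 10 * fs)
        eeg = np.zeros(n)
        tpl = sv.vep_template(fs)
        onsets = np.arange(2.0, 80.0, 10.0)  # one mid-epoch trial each
        for t0, s in zip(onsets, states):
            i = int(t0 * fs)
            eeg[i : i + len(tpl)] += scale[s] * tpl
        rec = make_recording(eeg=eeg, n=n)
        return rec, sv.StimulusTrain(onsets), hyp, scale

    def test_state_sorted_magnitudes_recover_injected_scales(self):
        rec, train, hyp, scale = self.make_session()
        table = sv.vep_table(rec, train, hyp, group_by=("state",), min_trials=1)
        for _, row in table.iterrows():
            assert row["magnitude_uv"] == pytest.approx(scale[row["state"]], rel=1e-9)

    def test_substate_by_beta_grouping_produces_crossed_rows(self):
        rec, train, hyp, _ = self.make_session()
        features = make_features(
            hyp.base_labels, substates=hyp.wake_substates,
            beta=[1.0, 100.0, 1.0, 100.0, 5.0, 5.0, 5.0, 50.0])
        features["beta_class"] = ["LOW", "HIGH", "LOW", "HIGH",
                                  "UNASSIGNED", "UNASSIGNED", "UNASSIGNED", "MID"]
        table = sv.vep_table(rec, train, hyp, features=features,
                             group_by=("state", "beta_class"), min_trials=1)
        got = set(map(tuple, table[["state", "beta_class"]].to_numpy()))
        assert {("QW", "LOW"), ("QW", "HIGH"), ("AW", "LOW"), ("AW", "HIGH")} <= got

    def test_trial_count_conservation(self):
        cfg = sv.SimulationConfig(duration_h=0.2)
        hyp = sv.generate_hypnogram(cfg, 11)
        rec, _ = sv.generate_signals(hyp, cfg, 11)
        train = sv.extract_stimulus_train(rec)
        wfs, excl = sv.sort_and_average(rec, train, hyp, group_by=("state",), min_trials=10)
        kept = sum(w.n_trials for w in wfs.values())
        assert kept + sum(excl.values()) == train.n_stimuli

    def test_interval_boundary_is_half_open(self):
        assert list(_interval_of(np.array([7199.99, 7200.0, 14400.0, 21600.0]))) == \
            ["H12", "H34", "H56", "NONE"]


def test_time_axis_symmetric_around_onset():
    t = peristimulus_time_axis(FS)
    assert len(t) == 401
    assert t[0] == -0.5 and t[-1] == 0.5 and t[200] == 0.0
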