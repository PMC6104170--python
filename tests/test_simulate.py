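"""Synthetic polysomnography generator: architecture, determinism, and
recoverability of the injected ground truth."""
import numpy as np
import pytest
from scipy.stats import spearmanr

import stabvep as sv
from stabvep.simulate import epoch_transition_matrix


def wake_only_config(**overrides):
    # a dwell far longer than any session keeps the chain in WAKE throughout
    params = dict(duration_h=1.0, stimulus_rate_hz=0.0,
                  mean_dwell_epochs={"WAKE": 1e9, "SWS": 12.0, "REMS": 5.0})
    params.update(overrides)
    return sv.SimulationConfig(**params)


class TestHypnogram:
    def test_forcing_wake_yields_all_wake(self):
        hyp = sv.generate_hypnogram(wake_only_config(), 0)
        assert (hyp.base_labels == "WAKE").all()
        assert set(hyp.wake_substates) <= {"AW", "IW", "QW"}

    def test_same_seed_reproduces_labels(self):
        cfg = sv.SimulationConfig(duration_h=2.0)
        a = sv.generate_hypnogram(cfg, 42)
        b = sv.generate_hypnogram(cfg, 42)
        assert np.array_equal(a.base_labels, b.base_labels)
        assert np.array_equal(a.wake_substates, b.wake_substates)

    def test_rems_never_follows_wake(self):
        hyp = sv.generate_hypnogram(sv.SimulationConfig(duration_h=12.0), 5)
        prev, nxt = hyp.base_labels[:-1], hyp.base_labels[1:]
        assert not ((prev == "WAKE") & (nxt == "REMS")).any()

    def test_occupancy_matches_stationary_distribution(self):
        """Long-run state fractions agree with the eigen-analysis oracle of the
        equivalent per-epoch Markov chain (±3 percentage points, 10 seeds)."""
        cfg = sv.SimulationConfig(duration_h=48.0, stimulus_rate_hz=0.0)
        states, P = epoch_transition_matrix(cfg)
        w, v = np.linalg.eig(P.T)
        pi = np.real(v[:, np.argmax(np.real(w))])
        pi = pi / pi.sum()
        occ = np.zeros(3)
        n_seeds = 10
        for seed in range(n_seeds):
            labels = sv.generate_hypnogram(cfg, seed).base_labels
            occ += np.array([(labels == s).mean() for s in states]) / n_seeds
        assert np.abs(occ - pi).max() <= 0.03

    def test_sd_day_forces_wake_for_first_four_hours(self):
        cfg = sv.preset_config("sd_day", duration_h=6.0)
        hyp = sv.generate_hypnogram(cfg, 3)
        first_4h = hyp.base_labels[: int(4 * 360)]
        assert (first_4h == "WAKE").all()
        assert not (first_4h == "REMS").any()

    def test_wake_may_not_transition_to_rems_in_config(self):
        with pytest.raises(ValueError, match="REMS"):
            sv.SimulationConfig(transitions={
                "WAKE": {"SWS": 0.5, "REMS": 0.5},
                "SWS": {"WAKE": 1.0}, "REMS": {"WAKE": 1.0}})


class TestSignals:
    def test_deterministic_oscillator_gives_constant_band_power(self):
        """A pure 20-Hz tone (bandwidth 0), no noise, no jitter, no surges:
        epoch beta power is constant and the instability statistic is zero."""
        osc = {s: [sv.Oscillator(20.0, 10.0, 0.0)] for s in sv.EFFECTIVE_STATES}
        cfg = wake_only_config(
            duration_h=0.1, oscillators=osc, noise_sd_uv=0.0,
            amp_jitter_sigma={s: 0.0 for s in sv.EFFECTIVE_STATES},
            surge_rate=0.0, beta_buildup_per_h=0.0)
        hyp = sv.generate_hypnogram(cfg, 1)
        rec, _ = sv.generate_signals(hyp, cfg, 1)
        features = sv.build_epoch_features(rec, hyp)
        beta = features["power_beta"].to_numpy()
        assert np.ptp(beta) <= 1e-9 * beta.mean()
        summary = sv.stability_summary(features, hyp, bands=["beta"])
        with_pairs = summary[summary["n_pairs"] > 0]
        assert (with_pairs["p90_change_pct"] <= 1e-9).all()

    def test_surge_epochs_show_elevated_beta_power(self):
        """Surge epochs' measured beta power exceeds the same-substate
        non-surge median in ≥95% of surge epochs (10 seeds pooled)."""
        cfg = wake_only_config(surge_rate=0.2, surge_magnitude_mean=2.0,
                               surge_magnitude_sigma=0.3)
        hits = totals = 0
        for seed in range(10):
            hyp = sv.generate_hypnogram(cfg, seed)
            rec, truth = sv.generate_signals(hyp, cfg, seed)
            beta = sv.build_epoch_features(rec, hyp)["power_beta"].to_numpy()
            surged = truth.surge_multiplier > 1.0
            for s in ("AW", "IW", "QW"):
                in_state = truth.effective_labels == s
                ref = np.median(beta[in_state & ~surged])
                hits += int((beta[in_state & surged] > ref).sum())
                totals += int((in_state & surged).sum())
        assert totals > 50
        assert hits / totals >= 0.95

    def test_beta_power_tracks_surge_multiplier(self):
        """Spearman ρ > 0.9 between the true surge multiplier and measured
        beta power across wake epochs (every epoch surged so the multiplier
        varies continuously)."""
        osc = {s: [sv.Oscillator(25.0, 14.0, 4.0)] for s in sv.EFFECTIVE_STATES}
        cfg = wake_only_config(oscillators=osc, surge_rate=1.0,
                               surge_magnitude_sigma=0.4)
        for seed in range(10):
            hyp = sv.generate_hypnogram(cfg, seed)
            rec, truth = sv.generate_signals(hyp, cfg, seed)
            beta = sv.build_epoch_features(rec, hyp)["power_beta"].to_numpy()
            rho = spearmanr(truth.surge_multiplier, beta).statistic
            assert rho > 0.9

    def test_emg_rms_recovered_within_5_percent(self):
        cfg = sv.SimulationConfig(duration_h=0.5, stimulus_rate_hz=0.0)
        hyp = sv.generate_hypnogram(cfg, 2)
        rec, truth = sv.generate_signals(hyp, cfg, 2)
        measured = sv.epoch_emg_rms(rec, hyp)
        rel_err = np.abs(measured - truth.true_emg_rms) / truth.true_emg_rms
        assert np.median(rel_err) < 0.02
        assert np.quantile(rel_err, 0.95) < 0.05

    def test_emg_classifier_recovers_latent_substates(self):
        """Generate → classify agreement ≥90% on wake epochs when the EMG
        levels are well separated. A percentile classifier can only match the
        latent chain when the three substates occupy ≈ a tertile each, so this
        uses a fast-mixing chain over enough epochs for occupancy to settle."""
        agree = total = 0
        for seed in range(5):
            cfg = sv.SimulationConfig(duration_h=1.0, stimulus_rate_hz=0.0,
                                      substate_self_stay=0.45)
            hyp = sv.generate_hypnogram(cfg, seed)
            rec, truth = sv.generate_signals(hyp, cfg, seed)
            features = sv.build_epoch_features(rec, hyp)
            blank = sv.Hypnogram(hyp.base_labels, epoch_length_s=cfg.epoch_length_s)
            classified = sv.classify_wake_substates(features, blank)
            wake = hyp.base_labels == "WAKE"
            agree += int((classified.wake_substates[wake] == hyp.wake_substates[wake]).sum())
            total += int(wake.sum())
        assert agree / total >= 0.90

    def test_vep_template_normalization_recovered_exactly(self):
        """With oscillators and noise off, the pipeline magnitude equals the
        injected per-state scale exactly: the template is built so that
        value(+250 ms) − value(+150 ms) = 1."""
        base = ["SWS"] * 6 + ["WAKE"] * 6
        subs = ["NOT_WAKE"] * 6 + ["AW"] * 6
        hyp = sv.Hypnogram(base, wake_substates=subs)
        cfg = sv.SimulationConfig(
            duration_h=len(base) * 10 / 3600.0, oscillators={}, noise_sd_uv=0.0,
            vep_scale_uv={"SWS": 100.0, "AW": 40.0, "QW": 95.0, "IW": 75.0, "REMS": 72.0})
        rec, truth = sv.generate_signals(hyp, cfg, 0)
        train = sv.extract_stimulus_train(rec)
        table = sv.vep_table(rec, train, hyp, group_by=("state",), min_trials=5)
        by_state = dict(zip(table["state"], table["magnitude_uv"]))
        assert by_state["SWS"] == pytest.approx(100.0, rel=1e-9)
        assert by_state["AW"] == pytest.approx(40.0, rel=1e-9)

    def test_qw_beta_builds_up_with_time_awake(self):
        truthful = wake_only_config(duration_h=2.0, beta_buildup_per_h=0.3,
                                    amp_jitter_sigma={s: 0.0 for s in sv.EFFECTIVE_STATES},
                                    surge_rate=0.0)
        hyp = sv.generate_hypnogram(truthful, 4)
        _, truth = sv.generate_signals(hyp, truthful, 4)
        qw = truth.effective_labels == "QW"
        gains = truth.qw_beta_gain[qw]
        assert (np.diff(gains) >= 0).all()
        assert gains[-1] > gains[0]


class TestSession:
    def test_stimulus_count_matches_rate_times_duration(self):
        cfg = sv.SimulationConfig(duration_h=0.1)
        hyp = sv.generate_hypnogram(cfg, 1)
        _, truth = sv.generate_signals(hyp, cfg, 1)
        assert len(truth.trial_onset_s) == 360

    @pytest.mark.parametrize("dialect", ["EDF", "DELIMITED"])
    def test_regenerated_session_is_byte_identical(self, tmp_path, dialect):
        cfg = sv.SimulationConfig(duration_h=0.1)
        a = sv.generate_session(cfg, tmp_path / "a", seed=9, dialect=dialect)
        b = sv.generate_session(cfg, tmp_path / "b", seed=9, dialect=dialect)
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes(), key

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            sv.preset_config("no_such_preset")

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = sv.preset_config("mutant_like", duration_h=1.5)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = sv.SimulationConfig.from_yaml(tmp_path / "c.yaml")
        assert back.to_dict() == cfg.to_dict()
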