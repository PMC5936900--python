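"""Scoring: cents math, F0 estimation, exclusion filters, and the
inaccuracy / imprecision statistics."""

import numpy as np
import pandas as pd
import pytest

import pitchmimic as pm
from pitchmimic.compose import WHISTLED
from pitchmimic.scoring import (estimate_f0, filter_trials, flag_large_errors,
                                hz_to_cents, imprecision, inaccuracy,
                                interval_errors, note_errors,
                                octave_correct_errors, score_participants)
from pitchmimic.synth import SynthConfig, Waveform, synthesize_melody
from conftest import make_profile


class TestHzToCents:
    @pytest.mark.parametrize("f,ref,expected", [
        (440.0, 440.0, 0.0),
        (880.0, 440.0, 1200.0),
        (440.0 * 2 ** (1 / 12), 440.0, 100.0),
    ])
    def test_printed_identities(self, f, ref, expected):
        assert hz_to_cents(f, ref) == pytest.approx(expected, abs=1e-9)

    def test_log_additivity(self):
        a, b, c = 391.0, 523.25, 660.0
        assert hz_to_cents(a, b) + hz_to_cents(b, c) == pytest.approx(
            hz_to_cents(a, c), abs=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            hz_to_cents(0.0, 440.0)
        with pytest.raises(ValueError):
            hz_to_cents(440.0, -1.0)


class TestEstimateF0:
    def test_clean_sine_within_one_cent(self):
        sr = 44100
        t = np.arange(int(0.75 * sr)) / sr
        w = Waveform(np.sin(2 * np.pi * 440.0 * t), sr)
        est = estimate_f0(w, (0.0, 0.75))
        assert est.voiced
        assert abs(hz_to_cents(est.hz, 440.0)) < 1.0

    def test_synthesized_note_frequencies_recovered(self):
        mel = pm.Melody((0, 4, 9), "m")
        cfg = SynthConfig()
        w = synthesize_melody(mel, WHISTLED, cfg)
        step = (750 + 50) / 1000.0
        for i, degree in enumerate(mel.notes):
            est = estimate_f0(w, (i * step, i * step + 0.75))
            target = pm.degree_to_hz(degree, WHISTLED)
            assert abs(hz_to_cents(est.hz, target)) < 1.0

    def test_silence_flagged_unvoiced(self):
        w = Waveform(np.zeros(44100), 44100)
        est = estimate_f0(w, (0.0, 1.0))
        assert not est.voiced and np.isnan(est.hz)

    def test_noise_only_flagged_unvoiced(self, rng):
        w = Waveform(rng.normal(0, 0.3, 44100), 44100)
        assert not estimate_f0(w, (0.0, 1.0)).voiced

    def test_mild_noise_within_five_cents(self, rng):
        sr = 44100
        t = np.arange(int(0.5 * sr)) / sr
        x = np.sin(2 * np.pi * 523.25 * t)
        x = x + rng.normal(0, 10 ** (-20 / 20) * np.sqrt(0.5), len(x))  # 20 dB SNR
        est = estimate_f0(Waveform(x, sr), (0.0, 0.5))
        assert est.voiced
        assert abs(hz_to_cents(est.hz, 523.25)) < 5.0


def _toy_trials():
    """10 trials for one participant: one 4-note, one 6-note, one whose
    target exceeds the producible range, seven clean."""
    rows = []

    def add_trial(trial, n_prod, tmin=0.0, tmax=1200.0):
        for pos in range(n_prod):
            rows.append({
                "participant_id": "p0", "modality": "sing",
                "melody_id": f"mel{trial}", "trial": trial,
                "position": pos, "n_notes_target": 5,
                "n_notes_produced": n_prod,
                "target_degree": pos, "target_cents": 100.0 * pos,
                "target_min_cents": tmin, "target_max_cents": tmax,
                "produced_hz": 220.0 * 2 ** (pos / 12)})

    add_trial(0, 4)
    add_trial(1, 6)
    add_trial(2, 5, tmax=2400.0)  # above the participant's range
    for t in range(3, 10):
        add_trial(t, 5)
    return pd.DataFrame(rows)


def _toy_profiles():
    return pd.DataFrame([{
        "participant_id": "p0", "mbea_percent": 90.0,
        "sing_root_hz": 220.0, "whistle_root_hz": 880.0,
        "sing_range_low_cents": -600.0, "sing_range_high_cents": 1800.0,
        "whistle_range_low_cents": -600.0, "whistle_range_high_cents": 1800.0,
    }])


class TestFilterTrials:
    def test_constructed_fixture_keeps_seven(self):
        kept, excluded = filter_trials(_toy_trials(), _toy_profiles())
        assert kept[["melody_id", "trial"]].drop_duplicates().shape[0] == 7
        assert len(excluded) == 3
        reasons = dict(zip(excluded["trial"], excluded["reason"]))
        assert reasons[0] == "wrong_note_count"
        assert reasons[1] == "wrong_note_count"
        assert reasons[2] == "target_out_of_range"

    def test_all_well_formed_keeps_everything(self):
        trials = _toy_trials()
        trials = trials[~trials["trial"].isin([0, 1, 2])]
        kept, excluded = filter_trials(trials, _toy_profiles())
        assert len(excluded) == 0
        assert len(kept) == len(trials)

    def test_missing_profile_errors(self):
        trials = _toy_trials()
        profiles = _toy_profiles()
        profiles["participant_id"] = "other"
        with pytest.raises(ValueError, match="producible range"):
            filter_trials(trials, profiles)

    def test_exclusion_rate_matches_per_note_probability(self, melody_sets):
        # total per-note count-changing probability 0.0074 implies
        # 1 - (1-0.0074)^5 = 3.6% of trials excluded
        cohort = pm.CohortConfig(n_participants=25, p_omit=0.0037,
                                 p_duplicate=0.0037, p_octave_error=0.0)
        big_sets = {m: melody_sets[m] * 17 for m in melody_sets}  # 204 trials
        trials, profiles = pm.simulate_study(cohort, big_sets, seed=21)
        # disable range exclusions to isolate the note-count rule
        for m in ("sing", "whistle"):
            profiles[f"{m}_range_low_cents"] = -1e6
            profiles[f"{m}_range_high_cents"] = 1e6
        kept, excluded = filter_trials(trials, profiles)
        n_trials = trials[["participant_id", "modality", "trial"]] \
            .drop_duplicates().shape[0]
        frac = len(excluded) / n_trials
        expected = 1 - (1 - 0.0074) ** 5
        assert abs(frac - expected) < 3 * np.sqrt(expected * (1 - expected)
                                                  / n_trials)


class TestErrorsAndFlags:
    def test_note_errors_zero_for_perfect_imitation(self):
        trials = _toy_trials()
        kept, _ = filter_trials(trials, _toy_profiles())
        errs = note_errors(kept, _toy_profiles())
        assert np.allclose(errs["error_cents"], 0.0, atol=1e-9)
        assert set(errs["pitch_class"]) == {0, 1, 2, 3, 4}

    def test_flagging_and_octave_correction(self):
        errs = pd.DataFrame({
            "participant_id": "p0", "modality": "sing", "melody_id": "m",
            "trial": [0, 0, 0], "position": [0, 1, 2],
            "pitch_class": [0, 1, 2], "target_cents": [0.0, 100.0, 200.0],
            "produced_cents": [1250.0, 1099.0, 210.0],
            "error_cents": [1250.0, 999.0, 10.0]})
        flagged = flag_large_errors(errs)
        assert list(flagged["position"]) == [0]
        assert flagged["octave_corrected_cents"].iloc[0] == pytest.approx(50.0)
        corrected = octave_correct_errors(errs)
        assert corrected["error_cents"].tolist() == pytest.approx(
            [50.0, 999.0, 10.0])

    def test_injected_octave_errors_are_flagged(self, melody_sets):
        cohort = pm.CohortConfig(n_participants=20, p_omit=0.0,
                                 p_duplicate=0.0, p_octave_error=0.01)
        trials, profiles = pm.simulate_study(cohort, melody_sets, seed=8)
        for m in ("sing", "whistle"):
            profiles[f"{m}_range_low_cents"] = -1e6
            profiles[f"{m}_range_high_cents"] = 1e6
        kept, _ = filter_trials(trials, profiles)
        errs = note_errors(kept, profiles)
        frac = len(flag_large_errors(errs)) / len(errs)
        # noise can push a jumped note back under threshold, so allow slack
        assert abs(frac - 0.01) < 3 * np.sqrt(0.01 * 0.99 / len(errs)) + 0.003


class TestScoreStatistics:
    def test_inaccuracy_examples(self):
        assert inaccuracy([-50.0, 50.0]) == 0.0
        assert inaccuracy([-30.0, -10.0, -20.0]) == pytest.approx(-20.0)
        base = np.array([-30.0, -10.0, -20.0])
        assert inaccuracy(base + 7.5) == pytest.approx(-20.0 + 7.5)
        with pytest.raises(ValueError):
            inaccuracy([])

    def test_imprecision_against_two_pass_sd_oracle(self):
        errors = [0.0, 10.0, 0.0, 30.0]
        classes = ["a", "a", "b", "b"]

        def sample_sd(xs):  # brute-force two-pass, denominator n-1
            m = sum(xs) / len(xs)
            return (sum((x - m) ** 2 for x in xs) / (len(xs) - 1)) ** 0.5

        expected = (sample_sd([0, 10]) + sample_sd([0, 30])) / 2
        assert imprecision(errors, classes) == pytest.approx(expected)

    def test_imprecision_constant_errors_and_shift_invariance(self):
        assert imprecision([5.0] * 6, [0, 0, 0, 1, 1, 1]) == 0.0
        e = [1.0, 4.0, -2.0, 8.0, 3.0, 5.0]
        c = [0, 0, 0, 1, 1, 1]
        assert imprecision(e, c) == pytest.approx(
            imprecision([x + 123.4 for x in e], c))

    def test_imprecision_drops_singleton_classes(self):
        # class 'b' has one observation: only class 'a' contributes
        assert imprecision([0.0, 10.0, 99.0], ["a", "a", "b"]) == \
            pytest.approx(np.std([0, 10], ddof=1))
        with pytest.raises(ValueError):
            imprecision([1.0, 2.0], ["a", "b"])


class TestScoreParticipants:
    def _run(self, **profile_kw):
        melodies = {m: [pm.Melody((0, 4, 2, 7, 4), f"{m}-0"),
                        pm.Melody((2, 5, 1, 0, 3), f"{m}-1")]
                    for m in ("sing", "whistle")}
        prof = make_profile(**profile_kw)
        rng = np.random.default_rng(0)
        rows = []
        for m in ("sing", "whistle"):
            for t, mel in enumerate(melodies[m]):
                tr = pm.simulate_trial(mel, prof, m, rng)
                for pos, hz in enumerate(tr.produced_hz):
                    rows.append({
                        "participant_id": "p000", "modality": m,
                        "melody_id": mel.id, "trial": t, "position": pos,
                        "n_notes_target": 5, "n_notes_produced": 5,
                        "target_degree": mel.notes[pos],
                        "target_cents": 100.0 * mel.notes[pos],
                        "target_min_cents": 100.0 * min(mel.notes),
                        "target_max_cents": 100.0 * max(mel.notes),
                        "produced_hz": hz})
        trials = pd.DataFrame(rows)
        profiles = pd.DataFrame([{
            "participant_id": "p000", "mbea_percent": 95.0,
            "sing_root_hz": 220.0, "whistle_root_hz": 880.0,
            "sing_range_low_cents": -1e6, "sing_range_high_cents": 1e6,
            "whistle_range_low_cents": -1e6, "whistle_range_high_cents": 1e6}])
        kept, excl = filter_trials(trials, profiles)
        errs = note_errors(kept, profiles)
        return score_participants(errs, profiles, excl)

    def test_perfect_imitation_scores_all_zero(self):
        scores = self._run()
        for col in ("note_inaccuracy", "interval_inaccuracy",
                    "note_imprecision", "interval_imprecision"):
            assert np.allclose(scores[col], 0.0, atol=1e-9)

    def test_pure_bias_hits_note_inaccuracy_only(self):
        scores = self._run(bias=(-40.0, 25.0))
        by_mod = scores.set_index("modality")
        assert by_mod.at["sing", "note_inaccuracy"] == pytest.approx(-40.0)
        assert by_mod.at["whistle", "note_inaccuracy"] == pytest.approx(25.0)
        for col in ("interval_inaccuracy", "note_imprecision",
                    "interval_imprecision"):
            assert np.allclose(scores[col], 0.0, atol=1e-9)

    def test_transposition_leaves_interval_scores_zero(self):
        # a constant shift is a transposition: note inaccuracy moves
        # one-to-one, interval inaccuracy stays exactly 0
        scores = self._run(bias=(-300.0, 200.0))
        by_mod = scores.set_index("modality")
        assert by_mod.at["sing", "note_inaccuracy"] == pytest.approx(-300.0)
        assert np.allclose(scores["interval_inaccuracy"], 0.0, atol=1e-9)
        assert np.allclose(scores["interval_imprecision"], 0.0, atol=1e-9)

    def test_trial_bookkeeping(self, small_study):
        scores = small_study["scores"]
        trials = small_study["trials"]
        attempted = (trials[["participant_id", "modality", "trial"]]
                     .drop_duplicates().groupby(
                         ["participant_id", "modality"]).size())
        for _, row in scores.iterrows():
            key = (row["participant_id"], row["modality"])
            assert row["n_trials_used"] + row["n_excluded"] == attempted[key]
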