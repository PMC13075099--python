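import numpy as np
import pytest

from fecgx.eemd import EEMDConfig, eemd
from fecgx.extraction import (
    ExtractionConfig,
    auto_select_scores,
    build_maternal_template,
    detect_maternal_rpeaks,
    extract_fecg,
    oracle_select_scores,
    select_top_k,
    subtract_maternal,
)
from fecgx.preprocess import butter_bandpass_zerophase, preprocess_standard
from fecgx.evaluation import correlation_cc, match_rpeaks
from fecgx.study import simulated_grid_records


@pytest.fixture(scope="module")
def clean_grid():
    return simulated_grid_records(seed=5, duration_s=10.0, fs_gen=500.0, snr_db=None)


@pytest.fixture(scope="module")
def noisy_grid():
    return simulated_grid_records(seed=5, duration_s=10.0, fs_gen=500.0)


def periodic_beats(fs=1000.0, duration=10.0, rr=0.8, width=0.02, amp=1.0):
    n = int(duration * fs)
    t = np.arange(n)
    peaks = np.arange(int(0.5 * rr * fs), n - int(0.5 * rr * fs), int(rr * fs))
    x = np.zeros(n)
    for p in peaks:
        x += amp * np.exp(-0.5 * ((t - p) / (width * fs)) ** 2)
    return x, peaks


class TestMaternalDetection:
    def test_beat_count_and_timing_on_simulated_case(self, noisy_grid):
        rec = noisy_grid[0]  # 80 bpm maternal over 10 s -> ~13 beats
        pre = preprocess_standard(rec)
        det = detect_maternal_rpeaks(pre.signal, rec.fs)
        assert abs(det.size - rec.maternal_rpeaks.size) <= 1
        m = match_rpeaks(det, rec.maternal_rpeaks, rec.fs, tol_s=0.02)
        assert m.recall >= 0.9

    def test_flat_signal_yields_nothing(self):
        assert detect_maternal_rpeaks(np.zeros(5000), 1000.0).size == 0

    def test_fallback_refractory_keeps_larger_peak(self):
        from fecgx.extraction import _fallback_maternal

        x = np.zeros(3000)
        x[1000] = 1.0
        x[1400] = 2.0  # 400 ms later: inside the 500 ms refractory
        det = _fallback_maternal(x, 1000.0, min_rr_s=0.5)
        assert det.tolist() == [1400]


class TestTemplateSubtraction:
    def test_template_of_identical_beats_is_one_beat(self):
        x, peaks = periodic_beats()
        tpl = build_maternal_template(x, peaks, halfwidth=300)
        p = peaks[3]
        np.testing.assert_allclose(tpl, x[p - 300 : p + 301], atol=1e-10)

    def test_averaging_suppresses_independent_noise(self, rng):
        fs, rr, n_beats = 500.0, 1.0, 100
        n = int((n_beats + 1) * rr * fs)
        t = np.arange(n)
        peaks = np.arange(int(0.5 * fs), n - int(0.5 * fs), int(rr * fs))
        beat = lambda p: np.exp(-0.5 * ((t - p) / 10.0) ** 2)
        x = sum(beat(p) for p in peaks) + 0.5 * rng.standard_normal(n)
        tpl = build_maternal_template(x, peaks, halfwidth=100)
        clean = np.exp(-0.5 * ((np.arange(-100, 101)) / 10.0) ** 2)
        rms = np.sqrt(np.mean((tpl - clean) ** 2))
        assert rms < 0.15 * 0.5  # sqrt-N averaging law

    def test_edge_beat_excluded_from_average(self):
        x, peaks = periodic_beats()
        with_edge = np.concatenate([[10], peaks])  # beat at sample 10
        tpl = build_maternal_template(x, with_edge, halfwidth=300)
        ref = build_maternal_template(x, peaks, halfwidth=300)
        np.testing.assert_array_equal(tpl, ref)

    def test_too_few_beats_rejected(self):
        x, peaks = periodic_beats()
        with pytest.raises(ValueError, match="2 beats"):
            build_maternal_template(x, peaks[:1], halfwidth=300)

    def test_periodic_signal_self_cancels(self):
        x, peaks = periodic_beats()
        tpl = build_maternal_template(x, peaks, halfwidth=390)
        resid = subtract_maternal(x, tpl, peaks)
        assert np.sqrt(np.mean(resid**2)) < 0.05 * np.sqrt(np.mean(x**2))

    def test_empty_peaks_is_identity(self):
        x, _ = periodic_beats()
        np.testing.assert_array_equal(subtract_maternal(x, np.zeros(601), []), x)

    def test_subtraction_enhances_fetal_component(self, noisy_grid):
        rec = noisy_grid[1]
        pre = preprocess_standard(rec)
        det = detect_maternal_rpeaks(pre.signal, rec.fs)
        tpl = build_maternal_template(pre.signal, det, halfwidth=int(0.5 * rec.fs))
        resid = subtract_maternal(pre.signal, tpl, det)
        ref = butter_bandpass_zerophase(rec.fetal_clean, rec.fs, 10, 60, 4)
        cc_raw = abs(correlation_cc(pre.signal, ref, fs=rec.fs))
        cc_resid = abs(correlation_cc(resid, ref, fs=rec.fs))
        assert cc_resid > cc_raw


@pytest.fixture(scope="module")
def toy_imfset():
    from fecgx.eemd import IMFSet

    t = np.arange(5000) / 1000.0
    imfs = np.stack([
        np.sin(2 * np.pi * 30 * t),
        np.sin(2 * np.pi * 12 * t),
        np.sin(2 * np.pi * 2 * t),
        0.3 * np.sin(2 * np.pi * 0.5 * t),
    ])
    return IMFSet(imfs=imfs, residual=np.zeros(5000), fs=1000.0)


class TestSelection:
    def test_top_k_sums_highest_scoring(self, toy_imfset):
        out = select_top_k(toy_imfset, [0.9, 0.8, 0.1, 0.05], k=2)
        np.testing.assert_allclose(out, toy_imfset.imfs[0] + toy_imfset.imfs[1])

    def test_full_selection_reconstructs_without_residual(self, toy_imfset):
        out = select_top_k(toy_imfset, [0.5, 0.5, 0.5, 0.5], k=4)
        np.testing.assert_allclose(out, toy_imfset.reconstruct() - toy_imfset.residual)

    def test_ties_break_toward_lower_index(self, toy_imfset):
        out = select_top_k(toy_imfset, [0.1, 0.7, 0.1, 0.7], k=1)
        np.testing.assert_allclose(out, toy_imfset.imfs[1])

    def test_oversized_k_warns_and_uses_all(self, toy_imfset):
        with pytest.warns(UserWarning, match="using all"):
            out = select_top_k(toy_imfset, [0.4, 0.3, 0.2, 0.1], k=9)
        np.testing.assert_allclose(out, toy_imfset.imfs.sum(axis=0))

    def test_auto_scores_prefer_inband_energy(self, toy_imfset):
        ref = toy_imfset.imfs[0] + 0.2 * np.random.default_rng(0).standard_normal(5000)
        scores = auto_select_scores(toy_imfset, ref)
        assert scores[0] > scores[2]  # 30 Hz tone beats 2 Hz tone
        assert np.argmax(scores) == 0  # matches the filtered reference

    def test_oracle_scores_identify_truth(self, toy_imfset, rng):
        truth = toy_imfset.imfs[1]
        scores = oracle_select_scores(toy_imfset, truth)
        assert scores[1] == pytest.approx(1.0)
        noise_set = eemd(rng.standard_normal(5000), EEMDConfig(ensemble_size=2, seed=0))
        null = oracle_select_scores(noise_set, np.sin(np.arange(5000) * 0.2))
        assert np.all(null < 0.1)

    def test_oracle_without_truth_rejected(self, toy_imfset):
        with pytest.raises(ValueError):
            oracle_select_scores(toy_imfset, None)


class TestPipeline:
    def test_easy_clean_case_recovers_fetal_waveform(self, clean_grid):
        rec = clean_grid[0]  # 1:1.17 amplitude ratio, no noise
        cfg = ExtractionConfig(selection_mode="oracle", eemd=EEMDConfig(seed=3))
        res = extract_fecg(rec.signal, rec.fs, cfg=cfg, fetal_truth=rec.fetal_clean)
        ref = butter_bandpass_zerophase(rec.fetal_clean, rec.fs, 10, 60, 4)
        assert abs(correlation_cc(res.fecg, ref, fs=rec.fs)) > 0.9

    def test_deterministic_given_seeds(self, noisy_grid):
        rec = noisy_grid[0]
        cfg = ExtractionConfig(selection_mode="oracle", eemd=EEMDConfig(seed=3))
        a = extract_fecg(rec.signal, rec.fs, cfg=cfg, fetal_truth=rec.fetal_clean)
        b = extract_fecg(rec.signal, rec.fs, cfg=cfg, fetal_truth=rec.fetal_clean)
        assert np.array_equal(a.fecg, b.fecg)
        assert np.array_equal(a.fetal_rpeaks, b.fetal_rpeaks)

    def test_stage_fidelity_improves_monotonically(self, noisy_grid):
        """Median CC against the fetal reference rises from raw AECG ->
        post-subtraction residual -> stage-1 estimate -> final output."""
        stages = []
        cfg = ExtractionConfig(selection_mode="oracle", eemd=EEMDConfig(seed=3))
        for rec in (noisy_grid[0], noisy_grid[5], noisy_grid[8]):
            res = extract_fecg(rec.signal, rec.fs, cfg=cfg, fetal_truth=rec.fetal_clean)
            ref = butter_bandpass_zerophase(rec.fetal_clean, rec.fs, 10, 60, 4)
            stages.append([
                abs(correlation_cc(x, ref, fs=rec.fs))
                for x in (res.preprocessed, res.residual, res.stage1_estimate, res.fecg)
            ])
        med = np.median(stages, axis=0)
        assert np.all(np.diff(med) > 0)

    def test_oracle_upper_bounds_auto(self, noisy_grid):
        ccs = {"oracle": [], "auto": []}
        for mode in ccs:
            cfg = ExtractionConfig(selection_mode=mode, eemd=EEMDConfig(seed=3))
            for rec in (noisy_grid[0], noisy_grid[5], noisy_grid[8]):
                res = extract_fecg(rec.signal, rec.fs, cfg=cfg, fetal_truth=rec.fetal_clean)
                ref = butter_bandpass_zerophase(rec.fetal_clean, rec.fs, 10, 60, 4)
                ccs[mode].append(abs(correlation_cc(res.fecg, ref, fs=rec.fs)))
        assert np.mean(ccs["oracle"]) >= np.mean(ccs["auto"]) - 0.02  # ties allowed

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ExtractionConfig(n1=0)
        with pytest.raises(ValueError):
            ExtractionConfig(n1=5, n2=4)  # exceeds the 8-IMF budget

    def test_cnn_mode_without_model_rejected(self, noisy_grid):
        rec = noisy_grid[0]
        with pytest.raises(ValueError, match="model"):
            extract_fecg(rec.signal, rec.fs, model=None,
                         cfg=ExtractionConfig(selection_mode="cnn"))
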