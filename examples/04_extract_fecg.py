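"""Run the full two-stage extraction pipeline on one noisy case.

Oracle selection (correlation against the known clean fetal component)
replaces the trained scorer here so the example is self-contained and
fast; swap selection_mode="cnn" and pass a trained model for the
learned pipeline.
"""
from fecgx.eemd import EEMDConfig
from fecgx.evaluation import correlation_cc, match_rpeaks, snr_improvement
from fecgx.extraction import ExtractionConfig, extract_fecg
from fecgx.preprocess import butter_bandpass_zerophase
from fecgx.study import simulated_grid_records

rec = simulated_grid_records(seed=1, duration_s=30.0, fs_gen=500.0)[0]
cfg = ExtractionConfig(n1=2, n2=1, selection_mode="oracle", eemd=EEMDConfig(seed=3))
res = extract_fecg(rec.signal, rec.fs, cfg=cfg, fetal_truth=rec.fetal_clean)

ref = butter_bandpass_zerophase(rec.fetal_clean, rec.fs, 10, 60, 4)
cc = correlation_cc(res.fecg, ref, fs=rec.fs)
m = match_rpeaks(res.fetal_rpeaks, rec.fetal_rpeaks, rec.fs)
snr = snr_improvement(rec.signal, res.fecg, rec.fetal_clean, (10, 60), rec.fs)

print(f"{rec.subject_id}: {res.maternal_rpeaks.size} maternal beats subtracted")
print(f"fetal R-peaks: {res.fetal_rpeaks.size} detected / {rec.fetal_rpeaks.size} true "
      f"-> precision {m.precision:.3f}, recall {m.recall:.3f}, F1 {m.f1:.3f}")
print(f"waveform CC vs clean fetal reference: {cc:.3f}")
print(f"SNR improvement over the raw abdominal trace: {snr:.1f} dB")
# CC near 0.9 and F1 near 1.0 on this high-fetal-amplitude case mean
# the recovered waveform tracks the true fetal ECG beat for beat.
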