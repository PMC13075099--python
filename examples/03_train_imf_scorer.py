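"""Leave-one-subject-out training of the IMF scorer, desk scale.

Uses five simulator cases (10 s each) and the slimmed five-block
architecture so the whole run takes well under a minute; the full
protocol is the same call with ClassifierSpec() and TrainConfig().
"""
import numpy as np

from fecgx.classifier import ClassifierSpec
from fecgx.eemd import EEMDConfig
from fecgx.study import run_loso_study, simulated_grid_records, smoke_train_config

records = simulated_grid_records(seed=1, duration_s=10.0, fs_gen=250.0)[:5]
dataset, folds, models = run_loso_study(
    records, EEMDConfig(seed=2), smoke_train_config(1), ClassifierSpec.smoke()
)
pos = sum(r.label for r in dataset)
print(f"labeled dataset: {len(dataset)} IMFs, {pos} fetal-related "
      f"({100 * pos / len(dataset):.1f}% positive)")
for f in folds:
    print(f"  held-out {f.held_out_subject}: AUC {f.auc_per_run[0]:.3f} "
          f"({f.n_val_pos}/{f.n_val_imfs} positive)")
print(f"mean AUC {np.mean([f.auc_per_run[0] for f in folds]):.3f}")
# AUC ~0.8-1.0 per fold: the scorer separates beat-locked fetal IMFs
# from maternal residue and noise on subjects it never saw.
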