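#!/usr/bin/env python
"""Train the brain-age regressors with grouped 5-fold cross-validation.

The pipeline trains one model per (modality, scope): wide-brain plus the
seven networks, for static and dynamic FNC. The demonstration run uses
the deterministic ridge baseline throughout; for comparison this script
additionally trains the desk-scale bidirectional LSTM on the wide-brain
dFNC sequences and reports both models' cross-validated MAE.
"""

import numpy as np
import pandas as pd

from common import RUN_DIR, demo_config
from dynbag.brainage import desk_config, evaluate_predictions, train_brainage_cv
from dynbag.pipeline import _load_features, run_pipeline
from dynbag.synthcohort import load_cohort

cfg = demo_config()
run_pipeline(cfg, RUN_DIR, stages=["train"])

summary = pd.read_csv(RUN_DIR / "train_summary.tsv", sep="\t")
print("cross-validated MAE (years) per model:")
print(summary.to_string(index=False))

# desk-scale recurrent model on the wide-brain dFNC sequences
sfnc, dfnc, scan_ids, subject_ids = _load_features(RUN_DIR)
pheno, _ = load_cohort(RUN_DIR / "cohort")
ages = pheno.set_index("id").loc[subject_ids, "age"].to_numpy()
iu = np.triu_indices(dfnc.shape[2], k=1)
seq = dfnc[:, :, iu[0], iu[1]]
model = train_brainage_cv(seq, ages, groups=np.array(subject_ids),
                          cfg=desk_config("bilstm", seed=cfg.seed + 100),
                          modality="dfnc")
ev = evaluate_predictions(model.oof_predictions, ages)
base = float(np.mean(np.abs(ages - ages.mean())))
print(f"\nwide-brain dFNC biLSTM (desk profile): out-of-fold MAE "
      f"{ev['mae']:.2f} y, r {ev['r']:.3f} "
      f"(selected epoch {model.selected_epoch}; mean-age baseline {base:.2f} y)")
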