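"""Multiply impute an incomplete data set with chained-equation PMM.

Shows the transformation search, the observed-support property of
predictive mean matching, and Rubin pooling of per-imputation estimates.
"""

import numpy as np

from valimpute import (ImputationSpec, SimulationConfig, auc, pool_rubin,
                       run_mice, simulate)

config = SimulationConfig(n=300, p1=3, auc_target=0.74, miss1=0.25,
                          mechanism="MCAR", seed=7)
data = simulate(config)

completed = run_mice(data, ImputationSpec(M=5, include_outcome=True, seed=3))

for var, info in completed.transform_log.items():
    best = info["transform"]
    print(f"{var}: transformation={best!r}  "
          f"Shapiro-W={info['shapiro_w'][best]:.4f}")

col = 0
observed = data.X[~data.mask[:, col], col]
imputed = completed.copies[0][data.mask[:, col], col]
print(f"\nimputed x1 values drawn from observed support: "
      f"{np.isin(np.round(imputed, 10), np.round(observed, 10)).all()}")

per_copy_auc = [auc(data.y, Xm[:, 0]) for Xm in completed.copies]
pooled = pool_rubin(per_copy_auc)
print(f"per-imputation AUC of x1 : {np.round(per_copy_auc, 3)}")
print(f"Rubin-pooled AUC of x1   : {pooled.point:.3f}")
print()
print("PMM only copies observed donor values, so imputations never leave")
print("the observed range; pooling averages the M completed-data results.")
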