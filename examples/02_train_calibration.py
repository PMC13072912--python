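"""Train the outlier-screened As/Pb calibration on a simulated study.

Uses a shortened training schedule so the example runs in ~10 s; drop
the `tc=` argument for the full 10,000-epoch default.

Run:  python examples/02_train_calibration.py
"""

from xrfquant import (
    TrainConfig,
    assemble_dataset,
    fit_calibration,
)
from xrfquant.simulate import (
    default_calibration_design,
    generate_calibration_set,
    generate_validation_set,
)
from xrfquant.spectra import DEFAULT_REGIONS

seed = 1
calibration = generate_calibration_set(default_calibration_design(seed))
validation = generate_validation_set(seed=seed + 3)   # external test table
test_table = assemble_dataset(validation, DEFAULT_REGIONS)

model, ledger, metrics = fit_calibration(
    calibration, DEFAULT_REGIONS,
    tc=TrainConfig(learning_rate=1e-4, n_epochs=2000, eval_every=500,
                   seed=seed),
    test=test_table)

print(f"best checkpoint: epoch {model.best_epoch} "
      f"(test RMSE {model.best_test_rmse:.1f} ug/kg)")
for element, m in metrics.items():
    print(f"{element}: R2 = {m.r2:.4f}, SEC = {m.sec:.2f} ug/kg "
          f"({m.relative_sec:.2f} % of range), "
          f"slope {m.slope:.3f}, intercept {m.intercept:.1f}")
print(f"outlier screen excluded {len(ledger.excluded_ids)} of "
      f"{len(ledger.records)} standards: {ledger.excluded_ids or 'none'}")
print("-> R2/SEC describe how tightly per-standard mean predictions track "
      "the known totals; the screen drops standards whose residual "
      "z-score exceeds |2.5| before the final fit.")
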