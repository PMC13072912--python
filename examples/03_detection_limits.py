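"""Eurachem detection/quantification limits in the two analytical
scenarios: trace As without (1) and with (2) strong Pb interference.

Run:  python examples/03_detection_limits.py   (~30 s)
"""

from xrfquant import (
    TrainConfig,
    aggregate_by_standard,
    assemble_dataset,
    detection_limits,
    fit_calibration,
    predict,
)
from xrfquant.simulate import (
    default_calibration_design,
    generate_calibration_set,
    generate_scenario_set,
    generate_validation_set,
)
from xrfquant.spectra import DEFAULT_REGIONS

seed = 1
cal = generate_calibration_set(default_calibration_design(seed))
test_table = assemble_dataset(generate_validation_set(seed=seed + 3),
                              DEFAULT_REGIONS)
model, _, _ = fit_calibration(
    cal, DEFAULT_REGIONS,
    tc=TrainConfig(learning_rate=1e-4, n_epochs=2000, eval_every=500,
                   seed=seed),
    test=test_table)

for scenario in (1, 2):
    standards = generate_scenario_set(scenario, seed=seed + scenario)
    table = assemble_dataset(standards, DEFAULT_REGIONS)
    agg = aggregate_by_standard(predict(model, table), table.groups)
    rows = [("As", "as_mean", 128.97)]
    if scenario == 2:
        rows.append(("Pb", "pb_mean", 208.95))
    for element, col, actual in rows:
        est = detection_limits(agg[col].to_numpy(), n=3, actual=actual,
                               element=element)
        print(f"scenario {scenario} {element}: actual {est.actual:7.2f}  "
              f"mean pred {est.mean_pred:7.2f}  bias {est.bias_abs:+6.2f}  "
              f"s0 {est.s0:5.2f}  LOD {est.lod:5.2f}  LOQ {est.loq:6.2f}")
print("-> LOD = 3*s0/sqrt(n), LOQ = 10*s0/sqrt(n) with s0 the SD of the 10 "
      "per-standard mean predictions and n = 3 averaged pellets; all in "
      "ug/kg.")
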