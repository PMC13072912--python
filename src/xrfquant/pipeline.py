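"""Stage orchestration: simulate → calibrate → limits → validate.

Each stage reads/writes the plain-text dialects of :mod:`xrfquant.spectra`
inside ``cfg.outdir`` and appends itself to a run manifest
(``manifest.json``) carrying the config digest, seeds, timings and the
output-file inventory, so any stage can be rerun standalone and a whole
run is reproducible from one master seed.

Sub-seed layout (all derived from ``cfg.seed``): calibration set +0,
scenario 1 +1, scenario 2 +2, validation set +3; network training uses
``cfg.train.seed``.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from xrfquant import __version__
from xrfquant.calibrate import (
    aggregate_by_standard,
    fit_calibration,
    predict,
    TrainedModel,
)
from xrfquant.config import RunConfig
from xrfquant.errors import ConfigError
from xrfquant.metrics import assess_agreement, category_summary, detection_limits
from xrfquant.simulate import (
    default_calibration_design,
    generate_calibration_set,
    generate_scenario_set,
    generate_validation_set,
    validation_categories,
    SimDesign,
)
from xrfquant.spectra import (
    assemble_dataset,
    load_standards,
    save_spectra,
    save_standards,
)

log = logging.getLogger("xrfquant")

FILES = {
    "cal_spectra": "calibration_spectra.csv",
    "cal_standards": "calibration_standards.csv",
    "sc1_spectra": "scenario1_spectra.csv",
    "sc1_standards": "scenario1_standards.csv",
    "sc2_spectra": "scenario2_spectra.csv",
    "sc2_standards": "scenario2_standards.csv",
    "val_spectra": "validation_spectra.csv",
    "val_standards": "validation_standards.csv",
    "model": "model.json",
    "cal_metrics": "calibration_metrics.json",
    "ledger": "outlier_ledger.csv",
    "plotdata": "calibration_plotdata.csv",
    "train_log": "training_log.csv",
}


def _update_manifest(cfg: RunConfig, stage: str, elapsed: float,
                     outputs: list[str]) -> None:
    path = cfg.outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "config_digest": cfg.digest(), "seed": cfg.seed,
        "version": __version__, "stages": {}}
    manifest["stages"][stage] = {"elapsed_s": round(elapsed, 3),
                                 "outputs": outputs}
    path.write_text(json.dumps(manifest, indent=2))


def run_simulate(cfg: RunConfig, design: SimDesign | None = None) -> dict:
    """Write the calibration design, both limit scenarios and the
    validation panel as spectrum + standards CSVs."""
    t0 = time.time()
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    d = cfg.detector
    design = (default_calibration_design(cfg.seed) if design is None
              else design)
    outputs = []

    def _write(standards, key_sp, key_st, role, extra=None):
        sp_path = cfg.outdir / FILES[key_sp]
        st_path = cfg.outdir / FILES[key_st]
        save_spectra([s for st in standards for s in st.spectra], sp_path)
        save_standards(standards, st_path, role=role)
        if extra:
            df = pd.read_csv(st_path, dtype={"standard_id": str})
            df["category"] = df["standard_id"].map(extra)
            df.to_csv(st_path, index=False)
        outputs.extend([sp_path.name, st_path.name])

    log.info("simulating calibration set (%d standards)", len(design.rows))
    _write(generate_calibration_set(design, d=d),
           "cal_spectra", "cal_standards", "train")
    for sc in (1, 2):
        _write(generate_scenario_set(sc, d=d, seed=cfg.seed + sc),
               f"sc{sc}_spectra", f"sc{sc}_standards", f"scenario{sc}")
    _write(generate_validation_set(d=d, seed=cfg.seed + 3),
           "val_spectra", "val_standards", "validation",
           extra=validation_categories())
    _update_manifest(cfg, "simulate", time.time() - t0, outputs)
    return {"n_standards": len(design.rows), "outputs": outputs}


def run_calibrate(cfg: RunConfig) -> dict:
    """Outlier-screened training; persists the model, metrics, ledger,
    training log and predicted-vs-actual plot data."""
    t0 = time.time()
    standards = load_standards(cfg.outdir / FILES["cal_spectra"],
                               cfg.outdir / FILES["cal_standards"])
    val_path = cfg.outdir / FILES["val_spectra"]
    if not val_path.exists():
        raise ConfigError("validation spectra (the test table) are missing; "
                          "run the simulate stage first")
    test_standards = load_standards(val_path,
                                    cfg.outdir / FILES["val_standards"])
    test_table = assemble_dataset(test_standards, cfg.regions)

    model, ledger, metrics = fit_calibration(
        standards, cfg.regions, cfg.net, cfg.train, test=test_table,
        z_threshold=cfg.z_threshold)

    model.save(cfg.outdir / FILES["model"])
    model.log.to_csv(cfg.outdir / FILES["train_log"], index=False)
    ledger.to_frame().to_csv(cfg.outdir / FILES["ledger"], index=False)

    kept = [st for st in standards
            if st.standard_id not in set(ledger.excluded_ids)]
    table = assemble_dataset(kept, cfg.regions)
    agg = aggregate_by_standard(predict(model, table), table.groups)
    actual = {st.standard_id: (st.as_conc, st.pb_conc) for st in kept}
    plotdata = agg.reset_index()
    plotdata["as_actual"] = [actual[s][0] for s in plotdata["standard_id"]]
    plotdata["pb_actual"] = [actual[s][1] for s in plotdata["standard_id"]]
    plotdata.to_csv(cfg.outdir / FILES["plotdata"], index=False)

    payload = {
        el: {"r2": m.r2, "sec": m.sec, "relative_sec": m.relative_sec,
             "slope": m.slope, "intercept": m.intercept}
        for el, m in metrics.items()}
    payload["best_epoch"] = model.best_epoch
    payload["best_test_rmse"] = model.best_test_rmse
    payload["n_excluded"] = len(ledger.excluded_ids)
    payload["excluded_ids"] = ledger.excluded_ids
    (cfg.outdir / FILES["cal_metrics"]).write_text(
        json.dumps(payload, indent=2))
    _update_manifest(cfg, "calibrate", time.time() - t0,
                     [FILES[k] for k in ("model", "train_log", "ledger",
                                         "plotdata", "cal_metrics")])
    return payload


def run_limits(cfg: RunConfig, scenario: int) -> dict:
    """Predict a scenario set and compute per-element limit estimates."""
    t0 = time.time()
    if scenario not in (1, 2):
        raise ConfigError(f"scenario must be 1 or 2, got {scenario}")
    model = TrainedModel.load(cfg.outdir / FILES["model"])
    standards = load_standards(cfg.outdir / FILES[f"sc{scenario}_spectra"],
                               cfg.outdir / FILES[f"sc{scenario}_standards"])
    if len(standards) != 10:
        warnings.warn(f"scenario {scenario} has {len(standards)} standards "
                      "(expected 10); proceeding")
    table = assemble_dataset(standards, cfg.regions)
    agg = aggregate_by_standard(predict(model, table), table.groups)

    elements = ["As"] if scenario == 1 else ["As", "Pb"]
    rows = {}
    for el in elements:
        col = "as_mean" if el == "As" else "pb_mean"
        actual = (standards[0].as_conc if el == "As"
                  else standards[0].pb_conc)
        est = detection_limits(agg[col].to_numpy(), n=cfg.limits_n,
                               actual=actual, element=el)
        rows[el] = {"actual": est.actual, "mean_pred": est.mean_pred,
                    "bias_abs": est.bias_abs, "bias_pct": est.bias_pct,
                    "s0": est.s0, "n": est.n, "lod": est.lod, "loq": est.loq}
    out = cfg.outdir / f"limits_scenario{scenario}.json"
    out.write_text(json.dumps(rows, indent=2))
    agg.to_csv(cfg.outdir / f"limits_scenario{scenario}_predictions.csv")
    _update_manifest(cfg, f"limits{scenario}", time.time() - t0,
                     [out.name, f"limits_scenario{scenario}_predictions.csv"])
    return rows


def _applicable_loqs(cfg: RunConfig) -> dict[str, float]:
    loqs = {"As": 0.0, "Pb": 0.0}
    p1 = cfg.outdir / "limits_scenario1.json"
    p2 = cfg.outdir / "limits_scenario2.json"
    if p1.exists():
        loqs["As"] = json.loads(p1.read_text())["As"]["loq"]
    if p2.exists():
        loqs["Pb"] = json.loads(p2.read_text())["Pb"]["loq"]
    return loqs


def run_validate(cfg: RunConfig) -> dict:
    """Per-sample agreement records and per-category error summaries."""
    t0 = time.time()
    model = TrainedModel.load(cfg.outdir / FILES["model"])
    standards = load_standards(cfg.outdir / FILES["val_spectra"],
                               cfg.outdir / FILES["val_standards"])
    cat_df = pd.read_csv(cfg.outdir / FILES["val_standards"],
                         dtype={"standard_id": str})
    cats = dict(zip(cat_df["standard_id"],
                    cat_df.get("category", pd.Series(dtype=str)).fillna("")))
    table = assemble_dataset(standards, cfg.regions)
    agg = aggregate_by_standard(predict(model, table), table.groups)
    loqs = _applicable_loqs(cfg)

    records = []
    for st in standards:
        if st.standard_id not in agg.index:
            log.warning("no spectra for %s; skipped", st.standard_id)
            continue
        for el, col, actual in (("As", "as_mean", st.as_conc),
                                ("Pb", "pb_mean", st.pb_conc)):
            records.append(assess_agreement(
                pred=float(agg.loc[st.standard_id, col]), actual=actual,
                threshold_pct=cfg.agreement_threshold_pct, loq=loqs[el],
                sample=st.standard_id, element=el,
                category=cats.get(st.standard_id, "")))
    rec_df = pd.DataFrame([vars(r) for r in records])
    rec_df.to_csv(cfg.outdir / "validation_records.csv", index=False)

    summary = {f"{cat}|{el}": stats
               for (cat, el), stats in category_summary(records).items()}
    n_agree = int(sum(1 for r in records
                      if r.element == "As" and r.agrees is True))
    n_as = int(sum(1 for r in records if r.element == "As" and r.quantifiable))
    summary["as_agreement"] = {"n_agree": n_agree, "n_quantifiable": n_as}
    (cfg.outdir / "validation_summary.json").write_text(
        json.dumps(summary, indent=2))
    _update_manifest(cfg, "validate", time.time() - t0,
                     ["validation_records.csv", "validation_summary.json"])
    return summary


def run_report(cfg: RunConfig) -> dict:
    """Collect every stage's headline numbers into one JSON report."""
    report: dict = {"config_digest": cfg.digest(), "seed": cfg.seed}
    for name, fname in (("calibration", FILES["cal_metrics"]),
                        ("limits_scenario1", "limits_scenario1.json"),
                        ("limits_scenario2", "limits_scenario2.json"),
                        ("validation", "validation_summary.json")):
        p = cfg.outdir / fname
        if p.exists():
            report[name] = json.loads(p.read_text())
    (cfg.outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
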