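"""End-to-end orchestration: simulate -> filter -> encode -> train -> domain.

`run_pipeline` executes the whole analysis under one configuration and one
global seed, writing diffable CSV/JSON artifacts plus a manifest with row
counts at every stage, so a rerun with the same config is byte-identical.
The stage order mirrors the screening workflow: generate (or load) a docked
library, sanitise docking scores into an activity table, encode peak lists
into fixed-length spectral codes, split train/test, select the top-k
descriptors by random-forest importance, train the classifier, evaluate by
ten-fold cross-validation and on the held-out test set, assess the
Tanimoto/probability applicability domain, and list high-confidence errors.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import domain as domain_mod
from .activity import (DockingResult, activity_table, calibrate_linear_map,
                       filter_docking_range)
from .descriptors import compute_fingerprint
from .models import (ModelConfig, ModelReport, QSDARModel, QSDARResults,
                     cross_val_predictions, cross_validate)
from .spectra import PeakList, encode
from .synthetic import (SyntheticConfig, generate_calibration_set,
                        generate_library, library_to_frame, peaklists_to_frame,
                        split_train_test)

__all__ = ["PipelineConfig", "PipelineState", "PipelineRun", "ScreenQuery",
           "run_pipeline", "screen"]

log = logging.getLogger("qsdar.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one pipeline run.

    Every stochastic stage derives its seed from ``seed`` by a fixed offset,
    so one integer pins the whole run.
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    proxy_mode: str = "thermodynamic"  # thermodynamic | calibrated
    calibration_n: int = 172
    encoding: str = "spinus570"  # spinus570 | gnn250 | combo820
    top_k: int = 200
    selector_trees: int = 200
    model: ModelConfig = field(default_factory=ModelConfig)
    test_ratio: float = 0.01  # ~100:1 train:test partition
    fingerprint_kind: str = "path2048"
    ad_tc_threshold: float = 0.90
    ad_prob_threshold: float = 0.8
    error_prob_threshold: float = 0.8
    write_features: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.proxy_mode not in ("thermodynamic", "calibrated"):
            raise ValueError(f"unknown proxy_mode: {self.proxy_mode!r}")
        if not 0.0 < self.test_ratio < 1.0:
            raise ValueError(f"test_ratio must be in (0, 1), got {self.test_ratio}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model"]["tuned_params"] = dict(self.model.tuned_params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("synthetic"), dict):
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        if isinstance(d.get("model"), dict):
            d["model"] = ModelConfig(**d["model"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineState:
    """Everything `screen` needs: the fitted model and the training context."""

    config: PipelineConfig
    results: QSDARResults
    selected_idx: np.ndarray
    training_fps: list
    training_ids: list[str]
    training_cv_pred: np.ndarray


@dataclass
class PipelineRun:
    out_dir: Path
    state: PipelineState
    cv_report: ModelReport
    test_report: ModelReport
    manifest: dict


@dataclass(frozen=True)
class ScreenQuery:
    id: str
    smiles: str
    peaks: PeakList


def _report_dict(rep: ModelReport) -> dict:
    m = rep.metrics
    d = {"scheme": rep.scheme, "n": rep.n, "algo": rep.config.algo,
         "task": rep.config.task}
    if hasattr(m, "mcc"):
        d.update(se=m.se, sp=m.sp, q=m.q, mcc=m.mcc, auc=m.auc)
        if rep.confusion is not None:
            d.update(tp=rep.confusion.tp, tn=rep.confusion.tn,
                     fp=rep.confusion.fp, fn=rep.confusion.fn)
    else:
        d.update(r2=m.r2, mae=m.mae, rmse=m.rmse)
    return d


def _setup_run_dir(out_dir) -> Path:
    if out_dir is None:
        out_dir = Path("runs") / time.strftime("run-%Y%m%d-%H%M%S")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return out_dir


def _json_log_handler(path: Path) -> logging.Handler:
    class _JsonLines(logging.FileHandler):
        def emit(self, record):
            record.msg = json.dumps({"t": record.created, "level": record.levelname,
                                     "msg": record.getMessage()})
            record.args = ()
            logging.FileHandler.emit(self, record)
    h = _JsonLines(path)
    h.setFormatter(logging.Formatter("%(message)s"))
    return h


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineRun:
    """Run the full analysis; returns reports and writes artifacts to disk."""
    out = _setup_run_dir(out_dir)
    handler = _json_log_handler(out / "pipeline.log.jsonl")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> PipelineRun:
    manifest: dict = {"config": config.to_dict(), "stages": {}}
    config.to_yaml(out / "config.yaml")

    # 1. library ------------------------------------------------------------
    library = generate_library(config.synthetic)
    log.info("generated library: %d molecules", len(library))
    manifest["stages"]["simulate"] = {"records_out": len(library)}
    library_to_frame(library).to_csv(out / "library.csv", index=False)
    peaklists_to_frame(library).to_csv(out / "peaks.csv", index=False)

    # 2. docking sanitation + activity proxy --------------------------------
    docking = [DockingResult(e.molecule.id, e.delta_g) for e in library]
    summary = filter_docking_range(docking)
    proxy = None
    if config.proxy_mode == "calibrated":
        calib = generate_calibration_set(
            config.calibration_n, config.synthetic.target_calibration_r,
            seed=config.seed + 101)
        proxy = calibrate_linear_map(calib["pic50_exp"], calib["dg_kcal_mol"])
        manifest["stages"]["calibrate"] = {
            "n": config.calibration_n, "slope": proxy.slope,
            "intercept": proxy.intercept, "fit_r": proxy.r}
    activity = activity_table(summary, proxy=proxy)
    activity.to_csv(out / "activity.csv", index=False)
    retained_ids = set(activity.loc[activity["retained"], "id"])
    manifest["stages"]["filter"] = {
        "records_in": len(library),
        "records_out": len(retained_ids),
        "records_removed": summary.n_removed,
        "records_errored": summary.n_errors,
    }
    log.info("docking filter: %d kept, %d removed", len(retained_ids),
             summary.n_removed)
    library = [e for e in library if e.molecule.id in retained_ids]

    # 3. spectral encoding ---------------------------------------------------
    vectors = np.stack([encode(e.peaks, config.encoding).values for e in library])
    ids = [e.molecule.id for e in library]
    y = np.array([e.activity_class for e in library])
    manifest["stages"]["encode"] = {
        "records_in": len(library), "records_out": len(library),
        "encoding": config.encoding, "n_descriptors": vectors.shape[1]}
    if config.write_features:
        feat = pd.DataFrame(vectors,
                            columns=[f"{config.encoding}_{i:03d}"
                                     for i in range(vectors.shape[1])])
        feat.insert(0, "id", ids)
        feat.to_csv(out / "features.csv", index=False)

    # 4. split ---------------------------------------------------------------
    idx_train, idx_test = split_train_test(list(range(len(library))),
                                           config.test_ratio,
                                           seed=config.seed + 211)
    tr, te = np.array(idx_train), np.array(idx_test)
    manifest["stages"]["split"] = {
        "records_in": len(library), "train": len(tr), "test": len(te)}
    log.info("split: %d train / %d test", len(tr), len(te))

    # 5. feature selection + training ---------------------------------------
    # the model's seed derives from the global seed like every other stage
    model_cfg = dataclasses.replace(config.model, seed=config.seed + 401)
    model = QSDARModel(vectors[tr], y[tr], config=model_cfg,
                       ids=[ids[i] for i in tr])
    k = min(config.top_k, vectors.shape[1])
    sel_idx, reduced = model.select_features(
        k, selector_config=ModelConfig(algo="rf", task=config.model.task,
                                       n_trees=config.selector_trees,
                                       seed=config.seed + 307))
    results = reduced.fit()
    cv_report = cross_validate(reduced.X, reduced.y, model_cfg)
    cv_pred, _cv_scores = cross_val_predictions(reduced.X, reduced.y, model_cfg)
    test_report = results.evaluate(vectors[te][:, sel_idx], y[te])
    manifest["stages"]["train"] = {
        "n_selected": int(k),
        "cv": _report_dict(cv_report),
        "external_test": _report_dict(test_report)}
    (out / "model_report.json").write_text(json.dumps(
        {"cv10": _report_dict(cv_report),
         "external_test": _report_dict(test_report)}, indent=2))
    log.info("model: cv %s / test %s", _report_dict(cv_report),
             _report_dict(test_report))

    # 6. applicability domain ------------------------------------------------
    train_ids = [ids[i] for i in tr]
    test_ids = [ids[i] for i in te]
    smiles_by_id = {e.molecule.id: e.molecule.smiles for e in library}
    train_fps = [compute_fingerprint(smiles_by_id[i], config.fingerprint_kind)
                 for i in train_ids]
    test_fps = [compute_fingerprint(smiles_by_id[i], config.fingerprint_kind)
                for i in test_ids]
    proba = results.positive_proba(vectors[te][:, sel_idx])
    pred = results.predict(vectors[te][:, sel_idx])
    pred_prob = np.where(pred == "active", proba, 1.0 - proba)  # prob of predicted class
    ad = domain_mod.assess_domain(test_ids, test_fps, pred_prob, train_fps,
                                  train_ids, config.ad_tc_threshold,
                                  config.ad_prob_threshold)
    ad_frame = pd.DataFrame([{
        "id": r.molecule_id, "tc_max": r.tc_max,
        "nearest_id": r.nearest_training_id, "probability": r.probability,
        "in_domain": r.in_domain, "predicted": p, "actual": a,
    } for r, p, a in zip(ad, pred, y[te])])
    ad_frame.to_csv(out / "ad_report.csv", index=False)
    mask = np.array([r.in_domain for r in ad])
    strat = domain_mod.stratified_metrics(pred, y[te], mask)
    manifest["stages"]["domain"] = {
        "records_in": len(te),
        "in_domain": int(mask.sum()),
        "out_of_domain": int((~mask).sum()),
        "in_domain_mcc": (strat.in_domain.metrics.mcc
                          if strat.in_domain.metrics else None),
        "out_of_domain_mcc": (strat.out_of_domain.metrics.mcc
                              if strat.out_of_domain.metrics else None)}
    log.info("applicability domain: %d of %d in-domain", int(mask.sum()), len(te))

    # 7. high-confidence errors ---------------------------------------------
    errors = domain_mod.high_confidence_errors(
        test_ids, pred, pred_prob, y[te], test_fps, train_fps, train_ids,
        cv_pred, prob_threshold=config.error_prob_threshold)
    pd.DataFrame([dataclasses.asdict(e) for e in errors]).to_csv(
        out / "error_report.csv", index=False)
    manifest["stages"]["errors"] = {"n_high_confidence": len(errors)}

    (out / "manifest.json").write_text(json.dumps(_versions() | manifest, indent=2))
    state = PipelineState(config=config, results=results, selected_idx=sel_idx,
                          training_fps=train_fps, training_ids=train_ids,
                          training_cv_pred=cv_pred)
    return PipelineRun(out_dir=out, state=state, cv_report=cv_report,
                       test_report=test_report, manifest=manifest)


def _versions() -> dict:
    import lightgbm
    import rdkit
    import sklearn

    from . import __version__
    return {"versions": {"qsdar": __version__, "sklearn": sklearn.__version__,
                         "lightgbm": lightgbm.__version__,
                         "rdkit": rdkit.__version__}}


def screen(state: PipelineState, queries: list[ScreenQuery]) -> pd.DataFrame:
    """Score query molecules with the trained classifier and flag the domain.

    Out-of-domain queries are still scored, never dropped.  Unparseable
    structures get a per-row ``error`` instead of aborting the screen.
    """
    rows = []
    cfg = state.config
    for q in queries:
        try:
            fp = compute_fingerprint(q.smiles, cfg.fingerprint_kind)
            vec = encode(q.peaks, cfg.encoding).values[state.selected_idx]
            pred = str(state.results.predict(vec[None, :])[0])
            p_active = float(state.results.positive_proba(vec[None, :])[0])
            p_pred = p_active if pred == "active" else 1.0 - p_active
            tc, _nn = domain_mod.max_train_similarity(fp, state.training_fps,
                                                      state.training_ids)
            rows.append({"id": q.id, "predicted": pred, "probability": p_pred,
                         "tc_max": tc,
                         "in_domain": domain_mod.in_domain(
                             tc, p_pred, cfg.ad_tc_threshold,
                             cfg.ad_prob_threshold),
                         "error": ""})
        except Exception as exc:  # per-row failure report
            rows.append({"id": q.id, "predicted": "", "probability": np.nan,
                         "tc_max": np.nan, "in_domain": False,
                         "error": str(exc)})
    return pd.DataFrame(rows, columns=["id", "predicted", "probability",
                                       "tc_max", "in_domain", "error"])
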