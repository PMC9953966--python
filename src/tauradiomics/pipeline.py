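"""Pipeline orchestration: configuration, staging, provenance and logging.

A run executes (optionally) simulate -> preprocess -> split -> define-rois
-> extract -> select -> classify inside a run directory, writing every
intermediate artifact plus JSON sidecars, so stages can also be invoked
individually from the CLI against an existing run directory. The split is
drawn *before* ROI definition and ROI definition, feature selection,
covariate fits and scaler fits all see training rows only; that discipline
is what the leakage tests audit.

Re-running with an identical config reproduces all outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import comparators as _comp
from .cohort import REFERENCE_NAME, CohortSpec, generate_cohort
from .image import (LabelMap, Mask, Volume, gaussian_smooth, mask_from_labels,
                    read_labelmap, read_volume, resample_isotropic,
                    resample_labels_isotropic, write_volume)
from .roi import ROI, ROISet, define_rois
from .selection import SelectionResult, select_features
from .texture import FEATURE_NAMES, extract_features

__all__ = ["PipelineConfig", "run_pipeline", "load_manifest"]

log = logging.getLogger("tauradiomics")

MANIFEST_META = ["id", "group", "cohort", "age", "sex", "mmse",
                 "tau_status", "apoe_status"]


def _setup_logging(run_dir: Path, verbose: bool = False) -> None:
    log.setLevel(logging.DEBUG if verbose else logging.INFO)
    log.handlers = []
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    log.addHandler(sh)
    fh = logging.FileHandler(run_dir / "pipeline.log")
    fh.setFormatter(fmt)
    log.addHandler(fh)


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, with defaults at the analysis' printed
    operating point (8 mm FWHM, 2 mm grid, FDR q = 0.01, cluster > 500,
    Ng = 64, |r| > 0.1, p < 0.005, 0.7/0.3 split, 5-fold CV x 100, C = 1)."""

    out_dir: str = "run"
    # inputs: either simulate, or point at existing data
    simulate: bool = True
    cohort: Dict = field(default_factory=dict)  # CohortSpec overrides
    manifest: Optional[str] = None
    atlas: Optional[str] = None
    # preprocessing
    fwhm_mm: float = 8.0
    iso_mm: float = 2.0
    # roi definition
    roi_q: float = 0.01
    min_cluster: int = 500
    connectivity: int = 18
    min_overlap: int = 64
    full_label: bool = False
    # features
    ng: int = 64
    # selection
    r_max: float = 0.1
    p_max: float = 0.005
    # classification
    train_frac: float = 0.7
    k_folds: int = 5
    n_reps: int = 100
    svm_c: float = 1.0
    covariate_mode: str = "residualize"
    # task
    task: Tuple[str, str] = ("AD", "NC")
    label_col: str = "group"
    roi_task: Optional[Tuple[str, str]] = None  # group pair for ROI defn
    models: Tuple[str, ...] = ("radiomics", "suvr", "clinical")
    reference_label: Optional[int] = None  # default: region named cerebellum_ref
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.roi_q < 1) or not (0 < self.p_max < 1):
            raise ValueError("thresholds out of range")
        if not (0 < self.r_max <= 1) or not (0 < self.train_frac < 1):
            raise ValueError("thresholds out of range")
        self.task = tuple(self.task)  # type: ignore[assignment]
        if self.roi_task is not None:
            self.roi_task = tuple(self.roi_task)  # type: ignore[assignment]
        self.models = tuple(self.models)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["task"] = list(self.task)
        d["models"] = list(self.models)
        if self.roi_task is not None:
            d["roi_task"] = list(self.roi_task)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "group": str,
                                            "cohort": str, "sex": str,
                                            "tau_status": str,
                                            "apoe_status": str})
    if "cohort" not in df.columns:
        df["cohort"] = "discovery"
    return df


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sidecar(path: Path, stage: str, params: Dict, inputs: Dict[str, Path]) -> None:
    payload = {"stage": stage, "params": params,
               "inputs": {k: _sha256(Path(v)) for k, v in inputs.items()
                          if Path(v).exists()}}
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, run: Path) -> Path:
    spec = CohortSpec(**{"seed": cfg.seed, **cfg.cohort})
    out = run / "cohort"
    manifest = generate_cohort(spec, out)
    log.info("simulated cohort: %s subjects -> %s",
             len(load_manifest(manifest)), out)
    return manifest


def stage_preprocess(cfg: PipelineConfig, run: Path, manifest: pd.DataFrame,
                     data_dir: Path, atlas_path: Path) -> Tuple[Path, LabelMap]:
    """Smooth (FWHM mm) and resample every volume; atlas goes nearest-neighbor."""
    out = run / "preproc"
    out.mkdir(parents=True, exist_ok=True)
    atlas = read_labelmap(atlas_path, _lookup_for(atlas_path))
    atlas = resample_labels_isotropic(atlas, cfg.iso_mm)
    for _, rec in manifest.iterrows():
        vol = read_volume(data_dir / rec["path"])
        if cfg.fwhm_mm > 0:
            vol = gaussian_smooth(vol, cfg.fwhm_mm)
        vol = resample_isotropic(vol, cfg.iso_mm)
        write_volume(vol, out / f"{rec['id']}.nii.gz")
    from .image import write_labelmap
    write_labelmap(atlas, out / "atlas.nii.gz", out / "atlas_labels.tsv")
    _sidecar(out / "preprocess.json", "preprocess",
             {"fwhm_mm": cfg.fwhm_mm, "iso_mm": cfg.iso_mm},
             {"atlas": atlas_path})
    log.info("preprocessed %d volumes (fwhm=%g mm, iso=%g mm)",
             len(manifest), cfg.fwhm_mm, cfg.iso_mm)
    return out, atlas


def _lookup_for(atlas_path: Path) -> Optional[Path]:
    cand = atlas_path.parent / "atlas_labels.tsv"
    return cand if cand.exists() else None


def stage_split(cfg: PipelineConfig, run: Path, manifest: pd.DataFrame
                ) -> _classify.SplitPlan:
    split = _classify.make_split(manifest, cfg.task, label_col=cfg.label_col,
                                 train_frac=cfg.train_frac, seed=cfg.seed)
    split.to_json(run / "split.json")
    log.info("split: %d train / %d validation / %d external test",
             len(split.train_ids), len(split.validation_ids),
             len(split.test_ids))
    return split


def _load_vol(preproc: Path, sid: str) -> Volume:
    return read_volume(preproc / f"{sid}.nii.gz")


def stage_rois(cfg: PipelineConfig, run: Path, manifest: pd.DataFrame,
               split: _classify.SplitPlan, preproc: Path, atlas: LabelMap
               ) -> ROISet:
    """Define ROIs from the training subjects of the ROI task (default: the
    classification task's group pair). Falls back to whole-atlas regions
    (reference excluded) when no cluster survives, so downstream stages
    still run on null data."""
    roi_task = cfg.roi_task or cfg.task
    tr = manifest[manifest["id"].isin(split.train_ids)]
    ga = [_load_vol(preproc, s) for s in tr.loc[tr[cfg.label_col] == roi_task[0], "id"]]
    gb = [_load_vol(preproc, s) for s in tr.loc[tr[cfg.label_col] == roi_task[1], "id"]]
    rs = define_rois(ga, gb, atlas, q=cfg.roi_q, min_cluster=cfg.min_cluster,
                     connectivity=cfg.connectivity, min_overlap=cfg.min_overlap,
                     full_label=cfg.full_label)
    if len(rs) == 0:
        log.warning("no ROI survived thresholding; falling back to whole-atlas "
                    "regions (reference excluded)")
        ref_id = _reference_id(cfg, atlas)
        rois = [ROI(rid, atlas.lookup[rid],
                    Mask(atlas.labels == rid, atlas.affine.copy()))
                for rid in atlas.ids() if rid != ref_id]
        rs = ROISet(rois, provenance={**rs.provenance, "fallback": "full_atlas"})
    out = run / "rois"
    out.mkdir(parents=True, exist_ok=True)
    rs.to_files(out / "rois.nii.gz", out / "rois.tsv", out / "rois.json")
    log.info("defined %d ROIs (train-only, groups %s)", len(rs), roi_task)
    return rs


def _reference_id(cfg: PipelineConfig, atlas: LabelMap) -> Optional[int]:
    if cfg.reference_label is not None:
        return cfg.reference_label
    for rid, name in atlas.lookup.items():
        if name == REFERENCE_NAME:
            return rid
    return None


def stage_extract(cfg: PipelineConfig, run: Path, manifest: pd.DataFrame,
                  preproc: Path, atlas: LabelMap, rois: ROISet
                  ) -> Dict[str, pd.DataFrame]:
    """Radiomics, SUVR and clinical feature tables for every subject."""
    out = run / "features"
    out.mkdir(parents=True, exist_ok=True)
    ref_id = _reference_id(cfg, atlas)
    ref_mask = (mask_from_labels(atlas, {ref_id}) if ref_id is not None else None)
    want_rad = "radiomics" in cfg.models
    rad_rows, suvr_rows = [], []
    for _, rec in manifest.iterrows():
        vol = _load_vol(preproc, rec["id"])
        meta = {k: rec[k] for k in MANIFEST_META if k in rec}
        if want_rad:
            rad_rows.append({**meta, **extract_features(vol, rois, ng=cfg.ng)})
        if ref_mask is not None:
            suvr_rows.append({**meta, **_comp.compute_suvr(vol, rois, ref_mask)})
    tables = {}
    if want_rad:
        tables["radiomics"] = pd.DataFrame(rad_rows)
        tables["radiomics"].to_csv(out / "radiomics.csv", index=False)
    if suvr_rows:
        tables["suvr"] = pd.DataFrame(suvr_rows)
        tables["suvr"].to_csv(out / "suvr.csv", index=False)
    clin = _comp.clinical_table(manifest)
    tables["clinical"] = clin
    clin.to_csv(out / "clinical.csv", index=False)
    _sidecar(out / "extraction.json", "extract",
             {"ng": cfg.ng, "n_rois": len(rois),
              "n_feature_columns": len(rois) * len(FEATURE_NAMES)}, {})
    log.info("extracted %d radiomics columns for %d subjects",
             len(rois) * len(FEATURE_NAMES), len(manifest))
    return tables


def stage_select(cfg: PipelineConfig, run: Path, rad: pd.DataFrame,
                 split: _classify.SplitPlan) -> SelectionResult:
    feats = [c for c in rad.columns if c not in MANIFEST_META]
    train = rad[rad["id"].isin(split.train_ids)]
    train = train[train[cfg.label_col].isin(cfg.task)]
    sel = select_features(train, feats, cfg.label_col, cfg.task,
                          r_max=cfg.r_max, p_max=cfg.p_max, seed=cfg.seed)
    out = run / "selection"
    out.mkdir(parents=True, exist_ok=True)
    sel.to_json(out / "selection.json")
    rad[MANIFEST_META + sel.kept].to_csv(out / "selected.csv", index=False)
    log.info("selection kept %d / %d features", len(sel.kept), len(feats))
    return sel


def _train_artifacts_json(artifacts: Dict) -> Dict:
    adj = artifacts.get("covariate_adjuster")
    scaler = artifacts["scaler"]
    svm = artifacts["svm"]
    return {
        "features": artifacts["features"],
        "covariate_coef": (adj.coef_.tolist() if adj is not None else None),
        "scaler_mean": scaler.mean_.tolist(),
        "scaler_scale": scaler.scale_.tolist(),
        "svm_coef": svm.coef_.tolist(),
        "svm_intercept": svm.intercept_.tolist(),
    }


def stage_classify(cfg: PipelineConfig, run: Path,
                   tables: Dict[str, pd.DataFrame], split: _classify.SplitPlan,
                   sel: Optional[SelectionResult]) -> Dict[str, _classify.EvalReport]:
    out = run / "reports"
    out.mkdir(parents=True, exist_ok=True)
    feature_sets: Dict[str, Sequence[str]] = {}
    if "radiomics" in cfg.models:
        feature_sets["radiomics"] = sel.kept if sel is not None else []
    if "suvr" in cfg.models and "suvr" in tables:
        feature_sets["suvr"] = [c for c in tables["suvr"].columns
                                if c.endswith("__suvr")]
    if "clinical" in cfg.models:
        feature_sets["clinical"] = ["clinical__mmse"]
    reports: Dict[str, _classify.EvalReport] = {}
    summary_lines = []
    for name, feats in feature_sets.items():
        rep, artifacts = _classify.run_model(
            tables[name], feats, split, cfg.task, label_col=cfg.label_col,
            covariate_mode=cfg.covariate_mode, k_folds=cfg.k_folds,
            n_reps=cfg.n_reps, C=cfg.svm_c, seed=cfg.seed, model_name=name)
        rep.to_json(out / f"eval_{name}.json")
        (out / f"train_artifacts_{name}.json").write_text(
            json.dumps(_train_artifacts_json(artifacts), indent=2) + "\n")
        _per_rep_csv(rep, out / f"per_repetition_{name}.csv")
        reports[name] = rep
        summary_lines.append(rep.table())
        log.info("model %s: validation accuracy %.1f%%", name,
                 rep.sections.get("validation", rep.sections["train_cv"])
                 .summary()["accuracy_mean_pct"])
    (out / "summary.txt").write_text("\n\n".join(summary_lines) + "\n")
    return reports


def _per_rep_csv(rep: _classify.EvalReport, path: Path) -> None:
    frames = []
    for sec_name, sec in rep.sections.items():
        frames.append(pd.DataFrame({
            "section": sec_name,
            "repetition": np.arange(len(sec.accuracy)),
            "accuracy": sec.accuracy, "sensitivity": sec.sensitivity,
            "specificity": sec.specificity, "auc": sec.auc}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all configured stages; returns the run directory."""
    run = Path(cfg.out_dir)
    run.mkdir(parents=True, exist_ok=True)
    _setup_logging(run, cfg.verbose)
    cfg.to_yaml(run / "config.yaml")
    stage = "setup"
    try:
        if cfg.simulate:
            stage = "simulate"
            manifest_path = stage_simulate(cfg, run)
            data_dir = run / "cohort"
            atlas_path = data_dir / "atlas.nii.gz"
        else:
            if cfg.manifest is None or cfg.atlas is None:
                raise ValueError("manifest and atlas paths required when "
                                 "simulate is false")
            manifest_path = Path(cfg.manifest)
            data_dir = manifest_path.parent
            atlas_path = Path(cfg.atlas)
        manifest = load_manifest(manifest_path)
        stage = "preprocess"
        preproc, atlas = stage_preprocess(cfg, run, manifest, data_dir, atlas_path)
        stage = "split"
        split = stage_split(cfg, run, manifest)
        stage = "define-rois"
        rois = stage_rois(cfg, run, manifest, split, preproc, atlas)
        stage = "extract"
        tables = stage_extract(cfg, run, manifest, preproc, atlas, rois)
        stage = "select"
        sel = (stage_select(cfg, run, tables["radiomics"], split)
               if "radiomics" in cfg.models else None)
        stage = "classify"
        stage_classify(cfg, run, tables, split, sel)
    except Exception as exc:  # partial outputs are kept for debugging
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    log.info("run complete: %s", run)
    return run
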