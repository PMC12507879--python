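"""End-to-end experiment orchestration.

``run_experiment`` wires the stages together, in memory:

    generate paired cohorts -> resample to 1 mm isotropic -> pool training
    ROI voxels -> fit cluster model + threshold per modality x method ->
    classify every subject -> habitat feature tables -> univariate screen
    -> backward-stepwise logistic model -> training/validation ROC +
    Youden operating point -> five-fold CV

plus a clinical covariate model fitted with the same recipe.  The
stage functions (``stage_generate`` ... ``stage_evaluate``) expose the same
computation as restartable steps over an output directory, which the CLI
maps onto subcommands.

Thresholds and logistic models are always *frozen on the training split*
and applied unchanged to validation subjects; the validation set never
contributes a voxel to pooling or a row to model fitting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import ClusterModel, classify_voxels, fit_cluster_model
from .errors import ConfigurationError, InputError
from .features import (HabitatFeatures, compute_features, feature_columns,
                       feature_table)
from .modeling import (CvResult, RecipeResult, RocSummary, fit_recipe,
                       five_fold_cv, roc_auc, score_with_model, split_cohort,
                       youden_cutoff)
from .synthetic import (GeneratorConfig, SyntheticSubject, generate_cohort,
                        records_frame, write_cohort)
from .volumes import (IntensityVolume, RoiMask, load_mask, load_volume,
                      pool_cohort, resample_isotropic, resample_mask)

log = logging.getLogger("sarcohab")

CLINICAL_COLS = ["age", "bmi", "albumin", "hemoglobin", "rbc"]
METHODS = ("otsu", "kmeans", "gmm")
TARGET_SPACING = (1.0, 1.0, 1.0)


@dataclass
class RunConfig:
    """Configuration of a full experiment run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    methods: tuple[str, ...] = METHODS
    modalities: tuple[str, ...] = ("CT", "MRI")
    split_seed: int = 0
    cv_seed: int = 0
    n_bins: int = 256
    train_fraction: float = 0.6
    include_clinical: bool = True
    #: rescale each MRI subject so its ROI median is 1 before pooling and
    #: classification; off by default (pooled thresholds are applied to the
    #: raw arbitrary-scale intensities)
    mri_median_normalize: bool = False
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if len(self.methods) == 0 or len(self.modalities) == 0:
            raise ConfigurationError(
                "select at least one method and one modality")
        for m in self.methods:
            if m not in METHODS:
                raise ConfigurationError(f"unknown method {m!r}")
        for m in self.modalities:
            if m not in ("CT", "MRI"):
                raise ConfigurationError(f"unknown modality {m!r}")

    def generator_for(self, modality: str) -> GeneratorConfig:
        """Generator config for one modality.

        Explicit intensity overrides in the base config apply only to the
        base config's own modality; the other modality runs on its
        defaults.  Anatomy, group sizes and seed are shared, so the two
        modalities image the same synthetic subjects.
        """
        if modality == self.generator.modality:
            return self.generator
        return replace(self.generator, modality=modality, muscle_mean=None,
                       fat_mean=None, component_sd=None,
                       intensity_jitter_sd=None, gain_jitter_sd=None)

    def config_hash(self) -> str:
        payload = {"generator": asdict(self.generator),
                   "methods": list(self.methods),
                   "modalities": list(self.modalities),
                   "split_seed": self.split_seed, "cv_seed": self.cv_seed,
                   "n_bins": self.n_bins,
                   "train_fraction": self.train_fraction,
                   "include_clinical": self.include_clinical}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        gen = raw.pop("generator", {}) or {}
        for key in ("roi_shape", "spacing", "fat_fraction_mean_by_group"):
            if key in gen and gen[key] is not None:
                gen[key] = tuple(gen[key])
        for key in ("methods", "modalities"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(generator=GeneratorConfig(**gen), **raw)


@dataclass
class ModelEvaluation:
    """Everything the pipeline learns about one modality x method."""

    modality: str
    method: str
    cluster_model: ClusterModel | None
    recipe: RecipeResult | None
    train_roc: RocSummary | None
    validation_roc: RocSummary | None
    cv: CvResult | None
    error: str | None = None

    @property
    def name(self) -> str:
        return f"{self.method}_{self.modality}"


@dataclass
class ExperimentReport:
    config: RunConfig
    records: pd.DataFrame
    train_ids: list[str]
    validation_ids: list[str]
    feature_tables: dict[str, pd.DataFrame]          # per modality
    evaluations: list[ModelEvaluation]
    clinical: ModelEvaluation | None
    manifest: dict

    def summary_frame(self) -> pd.DataFrame:
        """Flat table of AUC / operating-point metrics per model and split,
        shaped like a model-comparison table."""
        rows = []
        evals = list(self.evaluations)
        if self.clinical is not None:
            evals = [self.clinical] + evals
        for ev in evals:
            for split, roc in (("training", ev.train_roc),
                               ("validation", ev.validation_roc)):
                if roc is None:
                    continue
                rows.append({
                    "model": ev.name, "split": split, "auc": roc.auc,
                    "auc_ci_low": roc.auc_ci[0], "auc_ci_high": roc.auc_ci[1],
                    "sensitivity": roc.sensitivity,
                    "specificity": roc.specificity,
                    "accuracy": roc.accuracy, "youden": roc.youden,
                    "cutoff": roc.cutoff,
                    "cv_mean_auc": ev.cv.mean_auc if ev.cv else math.nan,
                })
        return pd.DataFrame(rows)


def _preprocess(subject: SyntheticSubject,
                median_normalize: bool = False
                ) -> tuple[IntensityVolume, RoiMask]:
    """Resample a subject's image and ROI to 1 mm isotropic if needed,
    optionally rescaling so the ROI median is 1 (MRI standardisation)."""
    vol, mask = subject.volume, subject.mask
    if vol.spacing != TARGET_SPACING:
        vol = resample_isotropic(vol, TARGET_SPACING)
        mask = resample_mask(mask, TARGET_SPACING)
    if median_normalize:
        med = float(np.median(vol.voxels[mask.voxels]))
        if med > 1e-12:  # an (unphysical) non-positive median is left alone
            vol = IntensityVolume(vol.voxels / med, vol.spacing, vol.modality)
    return vol, mask


def _evaluate_method(modality: str, method: str, table: pd.DataFrame,
                     train_mask: np.ndarray, cluster_model: ClusterModel,
                     config: RunConfig) -> ModelEvaluation:
    cols = [c for c in feature_columns(modality)
            if table[c].notna().any()]
    return _evaluate_predictors(
        ModelEvaluation(modality=modality, method=method,
                        cluster_model=cluster_model, recipe=None,
                        train_roc=None, validation_roc=None, cv=None),
        table, train_mask, cols, config)


def _evaluate_predictors(ev: ModelEvaluation, table: pd.DataFrame,
                         train_mask: np.ndarray, cols: Sequence[str],
                         config: RunConfig) -> ModelEvaluation:
    train_df = table[train_mask]
    val_df = table[~train_mask]
    recipe = fit_recipe(train_df, "sarcopenia", cols)
    ev.recipe = recipe
    if recipe.final_model is None:
        ev.error = "no predictor survived univariate screening"
        return ev
    model = recipe.final_model
    tr_scores, tr_labels = score_with_model(model, train_df, "sarcopenia")
    ev.train_roc = youden_cutoff(tr_scores, tr_labels)
    va_scores, va_labels = score_with_model(model, val_df, "sarcopenia")
    ev.validation_roc = youden_cutoff(va_scores, va_labels)
    counts = train_df["sarcopenia"].value_counts()
    if counts.min() >= 5:
        try:
            ev.cv = five_fold_cv(train_df, "sarcopenia", list(cols),
                                 seed=config.cv_seed)
        except Exception as exc:  # CV failure must not void the main fit
            log.warning("%s: cross-validation failed: %s", ev.name, exc)
            ev.error = f"cross-validation failed: {exc}"
    return ev


def build_feature_table(cohort: Sequence[SyntheticSubject],
                        threshold: float, modality: str,
                        records: pd.DataFrame,
                        median_normalize: bool = False) -> pd.DataFrame:
    """Classify every subject with a frozen threshold and tabulate
    habitat features joined with the subject records."""
    feats: list[HabitatFeatures] = []
    for subject in cohort:
        vol, mask = _preprocess(subject, median_normalize)
        labels = classify_voxels(vol, mask, threshold, modality)
        feats.append(compute_features(vol, mask, labels,
                                      subject.record.subject_id))
    return feature_table(feats, records=records, modality=modality)


def run_experiment(config: RunConfig,
                   write_outputs: bool | None = None) -> ExperimentReport:
    """Run the full pipeline for every selected modality and method.

    A failure in one modality x method is caught, logged, and flagged on
    its evaluation; the other combinations still run.
    """
    out_dir = Path(config.output_dir) if config.output_dir else None
    if write_outputs is None:
        write_outputs = out_dir is not None

    cohorts: dict[str, list[SyntheticSubject]] = {}
    for modality in config.modalities:
        log.info("generating %s cohort (n=%d)", modality,
                 config.generator.n_total)
        cohorts[modality] = generate_cohort(config.generator_for(modality))

    first = cohorts[config.modalities[0]]
    records = records_frame(first).drop(columns=["true_fat_fraction"])
    truth = records_frame(first)[["subject_id", "true_fat_fraction"]]
    labels = records["sarcopenia"].to_numpy()
    train_idx, val_idx = split_cohort(labels, config.train_fraction,
                                      config.split_seed)
    train_mask = np.zeros(len(records), dtype=bool)
    train_mask[train_idx] = True
    train_ids = records["subject_id"].iloc[train_idx].tolist()
    val_ids = records["subject_id"].iloc[val_idx].tolist()
    log.info("split: %d training / %d validation subjects",
             len(train_ids), len(val_ids))

    feature_tables: dict[str, pd.DataFrame] = {}
    evaluations: list[ModelEvaluation] = []
    cluster_models: dict[str, ClusterModel] = {}
    for modality in config.modalities:
        cohort = cohorts[modality]
        normalize = config.mri_median_normalize and modality == "MRI"
        pre = [_preprocess(s, normalize) for s in cohort]
        pooled = pool_cohort([pre[i][0] for i in train_idx],
                             [pre[i][1] for i in train_idx],
                             [cohort[i].record.subject_id for i in train_idx])
        mod_table: pd.DataFrame | None = None
        for method in config.methods:
            try:
                log.info("fitting %s on pooled %s intensities (%d voxels)",
                         method, modality, pooled.values.size)
                cmodel = fit_cluster_model(pooled, method, config.n_bins,
                                           seed=config.generator.seed)
                log.debug("%s_%s threshold=%.3f (initial %.3f)", method,
                          modality, cmodel.threshold, cmodel.initial_boundary)
                table = build_feature_table(cohort, cmodel.threshold,
                                            modality, records,
                                            median_normalize=normalize)
                ev = _evaluate_method(modality, method, table, train_mask,
                                      cmodel, config)
                cluster_models[f"{method}_{modality}"] = cmodel
                if mod_table is None:
                    mod_table = table
            except Exception as exc:  # keep other methods alive
                log.exception("%s_%s failed", method, modality)
                ev = ModelEvaluation(modality=modality, method=method,
                                     cluster_model=None, recipe=None,
                                     train_roc=None, validation_roc=None,
                                     cv=None, error=str(exc))
            evaluations.append(ev)
        if mod_table is not None:
            feature_tables[modality] = mod_table

    clinical = None
    if config.include_clinical:
        clin_table = records.copy()
        clinical = _evaluate_predictors(
            ModelEvaluation(modality="clinical", method="clinical",
                            cluster_model=None, recipe=None, train_roc=None,
                            validation_roc=None, cv=None),
            clin_table, train_mask, CLINICAL_COLS, config)
        clinical.method, clinical.modality = "clinical", "model"

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "generator_seed": config.generator.seed,
        "split_seed": config.split_seed,
        "cv_seed": config.cv_seed,
        "n_subjects": int(len(records)),
        "n_training": len(train_ids),
        "n_validation": len(val_ids),
        "models": {name: m.threshold for name, m in cluster_models.items()},
        "errors": {ev.name: ev.error for ev in evaluations if ev.error},
    }
    report = ExperimentReport(config=config, records=records,
                              train_ids=train_ids, validation_ids=val_ids,
                              feature_tables=feature_tables,
                              evaluations=evaluations, clinical=clinical,
                              manifest=manifest)
    report.manifest["truth"] = truth.set_index("subject_id")[
        "true_fat_fraction"].to_dict()
    if write_outputs and out_dir is not None:
        _write_report(report, out_dir, cluster_models)
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _roc_dict(roc: RocSummary | None) -> dict | None:
    if roc is None:
        return None
    return {"auc": roc.auc, "auc_ci": list(roc.auc_ci), "cutoff": roc.cutoff,
            "sensitivity": roc.sensitivity, "specificity": roc.specificity,
            "accuracy": roc.accuracy, "youden": roc.youden,
            "counts": asdict(roc.counts)}


def evaluation_json(ev: ModelEvaluation) -> dict:
    payload = {"model": ev.name, "error": ev.error,
               "training": _roc_dict(ev.train_roc),
               "validation": _roc_dict(ev.validation_roc),
               "cv": asdict(ev.cv) if ev.cv else None}
    if ev.recipe is not None:
        payload["screened"] = ev.recipe.screened
        payload["removal_order"] = ev.recipe.removal_order
        if ev.recipe.final_model is not None:
            payload["final_model"] = ev.recipe.final_model.summary_frame() \
                .to_dict(orient="records")
    return payload


def _write_report(report: ExperimentReport, out_dir: Path,
                  cluster_models: dict[str, ClusterModel]) -> None:
    out_dir = Path(out_dir)
    (out_dir / "models").mkdir(parents=True, exist_ok=True)
    (out_dir / "features").mkdir(exist_ok=True)
    (out_dir / "results").mkdir(exist_ok=True)
    report.config.to_yaml(out_dir / "config.yaml")
    for name, model in cluster_models.items():
        model.to_json(out_dir / "models" / f"{name}.json")
    for modality, table in report.feature_tables.items():
        table.to_csv(out_dir / "features" / f"{modality}.csv", index=False)
    for ev in report.evaluations + ([report.clinical] if report.clinical
                                    else []):
        (out_dir / "results" / f"{ev.name}.json").write_text(
            json.dumps(evaluation_json(ev), indent=2, default=_json_default))
    report.summary_frame().to_csv(out_dir / "results" / "summary.csv",
                                  index=False)
    (out_dir / "split.json").write_text(json.dumps(
        {"train": report.train_ids, "validation": report.validation_ids}))
    (out_dir / "manifest.json").write_text(
        json.dumps(report.manifest, indent=2, sort_keys=True,
                   default=_json_default))


# ---------------------------------------------------------------------------
# Directory-based stages (used by the CLI subcommands)

def stage_generate(config: RunConfig, out_dir: str | Path) -> Path:
    """Generate and write the raw cohorts, subject table and split."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    records = None
    for modality in config.modalities:
        cohort = generate_cohort(config.generator_for(modality))
        write_cohort(cohort, out / "raw" / modality,
                     config.generator_for(modality))
        if records is None:
            records = records_frame(cohort)
    labels = records["sarcopenia"].to_numpy()
    train_idx, val_idx = split_cohort(labels, config.train_fraction,
                                      config.split_seed)
    ids = records["subject_id"]
    (out / "split.json").write_text(json.dumps(
        {"train": ids.iloc[train_idx].tolist(),
         "validation": ids.iloc[val_idx].tolist()}))
    return out


def _load_raw(out: Path, modality: str
              ) -> tuple[pd.DataFrame, list[IntensityVolume], list[RoiMask]]:
    raw = out / "raw" / modality
    records = pd.read_csv(raw / "subjects.csv")
    volumes, masks = [], []
    for sid in records["subject_id"]:
        vol = load_volume(raw / "volumes" / f"{sid}_{modality}.nii.gz",
                          modality)
        mask = load_mask(raw / "masks" / f"{sid}.nii.gz")
        if vol.spacing != TARGET_SPACING:
            vol = resample_isotropic(vol, TARGET_SPACING)
            mask = resample_mask(mask, TARGET_SPACING)
        volumes.append(vol)
        masks.append(mask)
    return records, volumes, masks


def stage_segment(out_dir: str | Path, method: str, modality: str,
                  n_bins: int = 256, seed: int = 0) -> ClusterModel:
    """Fit the cohort-level cluster model on the training split and write
    the model JSON plus per-subject habitat label maps."""
    out = Path(out_dir)
    records, volumes, masks = _load_raw(out, modality)
    split = json.loads((out / "split.json").read_text())
    train_set = set(split["train"])
    keep = [i for i, sid in enumerate(records["subject_id"])
            if sid in train_set]
    pooled = pool_cohort([volumes[i] for i in keep],
                         [masks[i] for i in keep],
                         [records["subject_id"].iloc[i] for i in keep])
    model = fit_cluster_model(pooled, method, n_bins, seed=seed)
    (out / "models").mkdir(exist_ok=True)
    model.to_json(out / "models" / f"{method}_{modality}.json")
    label_dir = out / "labelmaps" / f"{method}_{modality}"
    label_dir.mkdir(parents=True, exist_ok=True)
    import nibabel as nib
    for sid, vol, mask in zip(records["subject_id"], volumes, masks):
        labels = classify_voxels(vol, mask, model.threshold, modality)
        affine = np.diag((*vol.spacing, 1.0))
        nib.save(nib.Nifti1Image(labels.astype(np.uint8), affine),
                 str(label_dir / f"{sid}.nii.gz"))
    return model


def stage_features(out_dir: str | Path, method: str, modality: str) -> Path:
    """Compute the habitat feature table from stored label maps."""
    import nibabel as nib
    out = Path(out_dir)
    records, volumes, masks = _load_raw(out, modality)
    label_dir = out / "labelmaps" / f"{method}_{modality}"
    feats = []
    for sid, vol, mask in zip(records["subject_id"], volumes, masks):
        labels = np.asarray(nib.load(str(label_dir / f"{sid}.nii.gz"))
                            .dataobj).astype(np.int8)
        feats.append(compute_features(vol, mask, labels, sid))
    table = feature_table(feats, records=records, modality=modality)
    (out / "features").mkdir(exist_ok=True)
    path = out / "features" / f"{method}_{modality}.csv"
    table.to_csv(path, index=False)
    return path


def stage_model(out_dir: str | Path, method: str, modality: str,
                cv_seed: int = 0) -> dict:
    """Fit and evaluate the prediction model for one feature table."""
    out = Path(out_dir)
    table = pd.read_csv(out / "features" / f"{method}_{modality}.csv")
    split = json.loads((out / "split.json").read_text())
    train_mask = table["subject_id"].isin(split["train"]).to_numpy()
    config = RunConfig.from_yaml(out / "config.yaml")
    config = replace(config, cv_seed=cv_seed)
    ev = _evaluate_method(modality, method, table, train_mask,
                          cluster_model=None, config=config)
    payload = evaluation_json(ev)
    (out / "results").mkdir(exist_ok=True)
    (out / "results" / f"{method}_{modality}.json").write_text(
        json.dumps(payload, indent=2, default=_json_default))
    return payload


def stage_evaluate(out_dir: str | Path, plot: bool = True) -> pd.DataFrame:
    """Aggregate per-model results into one comparison table (and a bar
    chart of AUCs when ``plot``)."""
    out = Path(out_dir)
    rows = []
    for path in sorted((out / "results").glob("*.json")):
        payload = json.loads(path.read_text())
        for split in ("training", "validation"):
            roc = payload.get(split)
            if roc is None:
                continue
            rows.append({"model": payload["model"], "split": split,
                         "auc": roc["auc"], "auc_ci_low": roc["auc_ci"][0],
                         "auc_ci_high": roc["auc_ci"][1],
                         "sensitivity": roc["sensitivity"],
                         "specificity": roc["specificity"],
                         "accuracy": roc["accuracy"],
                         "youden": roc["youden"], "cutoff": roc["cutoff"]})
    table = pd.DataFrame(rows)
    table.to_csv(out / "results" / "summary.csv", index=False)
    if plot and len(table):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(7, 4))
        for split, sub in table.groupby("split"):
            ax.bar([f"{m}\n{split[:5]}" for m in sub["model"]], sub["auc"],
                   label=split, alpha=0.7)
        ax.set_ylabel("AUC")
        ax.set_ylim(0, 1.05)
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "results" / "auc_comparison.png", dpi=120)
        plt.close(fig)
    return table
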