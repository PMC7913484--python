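"""End-to-end studies: per-parameter calibration with external validation,
and discriminant classification of honey type, with report tables shaped
like the classical chemometric summaries (calibration descriptors,
validation residuals, discriminant diagnostics, confusion matrix)."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic as syn
from .calibration import (DEFAULT_TREATMENT_GRID, CalibrationError,
                          GridEntry, SelectionResult, external_validate,
                          select_best_model)
from .discriminant import (DiscriminantModel, classify, confusion_report,
                           diagnostics_frame, fit_lda, function_diagnostics)
from .preprocess import apply_treatment
from .spectra import SpectraSet
from .synthetic import (NONNEGATIVE_PARAMETERS, PARAMETER_LABELS,
                        SyntheticConfig, SyntheticDataset, generate_dataset)

logger = logging.getLogger("honeynir")

MAIN_POLLEN_FEATURES = ("Castanea", "Eucalyptus", "Erica", "Rubus")


@dataclass
class RunConfig:
    """Study configuration; exactly one of ``data_dir`` (CSV directory) or
    ``synthetic`` (generator config) supplies the dataset."""

    data_dir: str | None = None
    synthetic: SyntheticConfig | None = None
    treatments: tuple = DEFAULT_TREATMENT_GRID
    cv_groups: int = 8
    max_factors: int = 16
    h_threshold: float = 3.0
    t_threshold: float = 2.5
    priors: str = "proportional"
    loo: bool = False
    seed: int = 0
    out_dir: str | None = None
    rpd_on: str = "sec"

    def __post_init__(self) -> None:
        if (self.data_dir is None) == (self.synthetic is None):
            raise ValueError(
                "provide exactly one of data_dir or synthetic config")
        if self.h_threshold <= 0 or self.t_threshold <= 0:
            raise ValueError("thresholds must be > 0")

    def load_dataset(self) -> SyntheticDataset:
        if self.data_dir is not None:
            return SyntheticDataset.read(self.data_dir)
        return generate_dataset(self.synthetic)


@dataclass
class ParameterResult:
    parameter: str
    selection: SelectionResult
    validation: object | None      # ValidationStats
    removal_log: pd.DataFrame


@dataclass
class CalibrationStudyResult:
    parameters: dict[str, ParameterResult]
    table2: pd.DataFrame
    table3: pd.DataFrame
    removal_log: pd.DataFrame


def _model_record(entry: GridEntry) -> dict:
    m = entry.model
    return {
        "parameter": m.parameter,
        "treatment": str(m.treatment),
        "n_factors": int(m.n_factors),
        "modified": bool(m.modified),
        "x_mean": m.x_mean.tolist(),
        "y_mean": float(m.y_mean),
        "coefficients": m.coefficients.tolist(),
        "retained_ids": list(m.retained_ids),
        "msc_reference": (None if m.msc_reference is None
                          else np.asarray(m.msc_reference).tolist()),
    }


def predict_with_record(record: dict, spectra: SpectraSet) -> np.ndarray:
    """Apply a serialized model (treatment + linear coefficients) to spectra."""
    msc_ref = record.get("msc_reference")
    treated = apply_treatment(
        spectra, record["treatment"],
        msc_reference=None if msc_ref is None else np.asarray(msc_ref, float))
    x = treated.values
    coef = np.asarray(record["coefficients"], float)
    x_mean = np.asarray(record["x_mean"], float)
    return record["y_mean"] + (x - x_mean) @ coef


def run_calibration_study(config: RunConfig,
                          dataset: SyntheticDataset | None = None,
                          parameters: list[str] | None = None
                          ) -> CalibrationStudyResult:
    """Calibrate every physicochemical parameter on the calibration split
    and externally validate on the held-out split.

    Per parameter: treatment grid -> PCA/H screening -> grouped CV ->
    T-criterion elimination -> refit -> descriptors; then prediction of the
    validation samples with the winning model and paired-test comparison.
    """
    if dataset is None:
        dataset = config.load_dataset()
    params = parameters or [c for c in dataset.reference.columns]
    missing = [p for p in params if p not in dataset.reference.columns]
    if missing:
        raise CalibrationError(
            f"reference table lacks parameter columns {missing}; "
            f"available: {list(dataset.reference.columns)}")

    cal_ids = dataset.ids_in("calibration")
    val_ids = dataset.ids_in("validation")
    spectra_cal = dataset.spectra.subset(cal_ids)
    spectra_val = dataset.spectra.subset(val_ids)

    results: dict[str, ParameterResult] = {}
    t2_rows, t3_rows, log_rows = [], [], []
    for param in params:
        y_cal = dataset.reference.loc[cal_ids, param].to_numpy(float)
        selection = select_best_model(
            spectra_cal, y_cal, parameter=param,
            treatment_grid=config.treatments, n_groups=config.cv_groups,
            max_factors=config.max_factors, seed=config.seed,
            h_threshold=config.h_threshold, t_threshold=config.t_threshold,
            nonnegative=param in NONNEGATIVE_PARAMETERS,
            rpd_on=config.rpd_on)
        best = selection.best
        for sid in best.h_removed:
            log_rows.append({"parameter": param, "sample_id": sid,
                             "criterion": "H"})
        for sid in best.t_removed:
            log_rows.append({"parameter": param, "sample_id": sid,
                             "criterion": "T"})
        logger.info("%s: %s, %d factors, removed %d (H) + %d (T)",
                    param, best.treatment, best.model.n_factors,
                    len(best.h_removed), len(best.t_removed))

        validation = None
        if len(val_ids) >= 3:
            y_val = dataset.reference.loc[val_ids, param].to_numpy(float)
            y_pred = predict_with_record(_model_record(best), spectra_val)
            validation = external_validate(y_val, y_pred)
            t3_rows.append({
                "Constituent": PARAMETER_LABELS.get(param, param),
                "Mean Residual": validation.mean_abs_residual,
                "RMSE": validation.RMSE,
                "p": validation.t_p_value,
            })
        s = best.stats
        t2_rows.append({
            "Variable": PARAMETER_LABELS.get(param, param),
            "Math Treatment": str(best.treatment),
            "N": s.N, "Mean": s.mean, "SD": s.SD,
            "Est.Min": s.est_min, "Est.Max": s.est_max,
            "SEC": s.SEC, "RSQ": s.RSQ, "SECV": s.SECV, "RPD": s.RPD,
        })
        param_log = pd.DataFrame(
            [r for r in log_rows if r["parameter"] == param],
            columns=["parameter", "sample_id", "criterion"])
        results[param] = ParameterResult(param, selection, validation, param_log)

    table2 = pd.DataFrame(t2_rows)
    table3 = pd.DataFrame(t3_rows)
    removal_log = pd.DataFrame(log_rows,
                               columns=["parameter", "sample_id", "criterion"])
    out = CalibrationStudyResult(results, table2, table3, removal_log)
    if config.out_dir:
        _write_calibration_outputs(out, results, config.out_dir)
    return out


def _display_round(df: pd.DataFrame, spec: dict[str, int]) -> pd.DataFrame:
    disp = df.copy()
    for col, nd in spec.items():
        if col in disp.columns:
            disp[col] = disp[col].astype(float).round(nd)
    return disp


def _write_calibration_outputs(out: CalibrationStudyResult, results, out_dir):
    path = Path(out_dir)
    path.mkdir(parents=True, exist_ok=True)
    out.table2.to_csv(path / "calibration_stats_full.csv", index=False)
    _display_round(out.table2, {
        "Mean": 1, "SD": 1, "Est.Min": 1, "Est.Max": 1, "SEC": 1,
        "RSQ": 2, "SECV": 1, "RPD": 1,
    }).to_csv(path / "calibration_stats.csv", index=False)
    out.table3.to_csv(path / "external_validation_full.csv", index=False)
    _display_round(out.table3, {"Mean Residual": 2, "RMSE": 2, "p": 2}
                   ).to_csv(path / "external_validation.csv", index=False)
    out.removal_log.to_csv(path / "removed_samples.csv", index=False)
    models_dir = path / "models"
    models_dir.mkdir(exist_ok=True)
    for param, res in results.items():
        with open(models_dir / f"{param}.json", "w") as fh:
            json.dump(_model_record(res.selection.best), fh, indent=1)


@dataclass
class DiscriminantStudyResult:
    model: DiscriminantModel
    table5: pd.DataFrame
    table6: pd.DataFrame
    confusion: object
    predicted: pd.Series
    scores: pd.DataFrame


def assemble_lda_features(dataset: SyntheticDataset) -> pd.DataFrame:
    """Physicochemical table joined with the main pollen percentages."""
    pollen_cols = [c for c in MAIN_POLLEN_FEATURES if c in dataset.pollen.columns]
    return dataset.reference.join(dataset.pollen[pollen_cols])


def run_discriminant_study(config: RunConfig,
                           dataset: SyntheticDataset | None = None
                           ) -> DiscriminantStudyResult:
    """LDA of honey type on physicochemical + main-pollen features.

    The confusion matrix is resubstitution by default; ``config.loo``
    switches to leave-one-out refitting.
    """
    if dataset is None:
        dataset = config.load_dataset()
    features = assemble_lda_features(dataset)
    labels = dataset.labels.loc[features.index]
    model = fit_lda(features, labels.to_numpy(), priors=config.priors)
    if config.loo:
        preds = np.empty(len(features), dtype=object)
        idx_all = np.arange(len(features))
        x = features.to_numpy(float)
        lab = labels.to_numpy()
        for i in idx_all:
            rest = idx_all[idx_all != i]
            m_i = fit_lda(x[rest], lab[rest], priors=config.priors)
            preds[i] = classify(m_i, x[i:i + 1])[0][0]
        scores = model.canonical_scores(x)
    else:
        preds, scores = classify(model, features)
    report = confusion_report(labels.to_numpy(), preds, model.groups)
    diags = function_diagnostics(model)
    table5 = diagnostics_frame(diags)
    table6 = report.to_frame()
    result = DiscriminantStudyResult(
        model, table5, table6, report,
        pd.Series(preds, index=features.index, name="predicted"),
        pd.DataFrame(scores, index=features.index,
                     columns=[f"F{k + 1}" for k in range(scores.shape[1])]))
    if config.out_dir:
        path = Path(config.out_dir)
        path.mkdir(parents=True, exist_ok=True)
        table5.to_csv(path / "discriminant_functions_full.csv", index=False)
        _display_round(table5, {
            "Eigenvalue": 2, "Relative Percentage": 2,
            "Canonical Correlation": 2, "Wilks Lambda": 2, "Chi-Square": 2,
        }).to_csv(path / "discriminant_functions.csv", index=False)
        table6.to_csv(path / "confusion_matrix.csv")
        result.scores.join(result.predicted).to_csv(path / "canonical_scores.csv")
        with open(path / "classification_summary.txt", "w") as fh:
            fh.write(f"Percent of cases correctly classified: "
                     f"{report.overall_correct_pct:.1f}%\n")
    return result
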