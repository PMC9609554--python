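"""Peak-table pre-treatment: impute, drift-correct, RSD-filter, average, scale.

The stage order is fixed — missing-value imputation, QC-based signal
correction, QC-reproducibility (RSD) filtering, technical-replicate
averaging, autoscaling, and finally column-binding of the two polarity
tables — and each stage's output satisfies the next stage's preconditions.

Signal correction follows the pooled-QC strategy: for every feature a
regression model (gradient-boosted trees by default) is trained on the QC
injections only, with injection order and batch as covariates, and the
corrected peak area of every injection is

    S_corrected = S_observed / S_predicted × 1000

so a cell predicted exactly is mapped to the constant 1000 and systematic
intensity drift common to QC and study samples divides out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor

from .core_model import PeakTable, PeakTableError, bind_polarities

__all__ = [
    "CorrectionModel",
    "QcReport",
    "PretreatmentConfig",
    "PretreatmentResult",
    "impute_missing",
    "qc_drift_correct",
    "rsd_filter",
    "average_technical",
    "autoscale",
    "pretreat_study",
]

logger = logging.getLogger("metaboselect")

#: scale constant of the correction equation
CORRECTION_TARGET = 1000.0

#: prediction floor, relative to the feature's QC mean
PREDICTION_FLOOR_REL = 1e-6

DEFAULT_CORRECTION_PARAMS: dict[str, Any] = {
    "n_estimators": 100,
    "max_depth": 2,
    "learning_rate": 0.1,
}


@dataclass
class CorrectionModel:
    """Per-feature QC-trained regressors of intensity on injection covariates."""

    regressors: dict[str, Any]
    target_constant: float = CORRECTION_TARGET
    floors: dict[str, float] = field(default_factory=dict)

    def predict(self, feature_id: str, covariates: np.ndarray) -> np.ndarray:
        pred = self.regressors[feature_id].predict(covariates)
        return np.maximum(pred, self.floors.get(feature_id, 0.0))


@dataclass
class QcReport:
    """Feature-wise QC relative standard deviations (%), before/after a stage."""

    rsd_before: pd.Series
    rsd_after: pd.Series | None = None
    threshold_pct: float = 30.0

    def fraction_below(self, which: str = "before") -> float:
        rsd = self.rsd_before if which == "before" else self.rsd_after
        if rsd is None:
            raise ValueError("no post-stage RSDs recorded")
        ok = rsd.dropna() < self.threshold_pct
        return float(ok.mean()) if len(ok) else float("nan")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"rsd_before_pct": self.rsd_before})
        if self.rsd_after is not None:
            out["rsd_after_pct"] = self.rsd_after
        return out


def qc_rsd(table: PeakTable) -> pd.Series:
    """Per-feature RSD (%) over the QC rows: sd(n−1) / mean × 100.

    Zero-mean features yield NaN rather than an error.
    """
    qc = table.values[table.role_mask("qc")]
    if qc.shape[0] < 2:
        raise PeakTableError("RSD needs at least two QC rows")
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mean != 0, sd / mean * 100.0, np.nan)
    return pd.Series(rsd, index=table.feature_ids, name="rsd_pct")


# ---------------------------------------------------------------------------
# missing-value imputation (iterative random-forest, missForest scheme)
# ---------------------------------------------------------------------------

def impute_missing(table: PeakTable, max_iter: int = 10, seed: int = 0,
                   n_estimators: int = 100,
                   regressor_factory: Callable[[int], Any] | None = None
                   ) -> PeakTable:
    """Iterative model-based imputation of missing peak areas.

    Missing cells are initialized at the feature mean; then, sweeping
    features in order of increasing missingness, each incomplete feature is
    regressed on all other features (random-forest ensemble by default) and
    its holes replaced by predictions.  Sweeps repeat until the normalized
    squared difference between successive imputations first increases, or
    ``max_iter`` is reached; the imputation before the increase is returned.
    Observed cells are never modified.

    Raises
    ------
    PeakTableError
        If a feature has no observed value at all.
    """
    vals = table.values
    holes = np.isnan(vals)
    if not holes.any():
        return table
    all_missing = holes.all(axis=0)
    if all_missing.any():
        raise PeakTableError(
            "fully missing features: "
            f"{list(table.feature_ids[all_missing])}"
        )
    if regressor_factory is None:
        def regressor_factory(rs: int) -> Any:
            return RandomForestRegressor(
                n_estimators=n_estimators, max_features="sqrt",
                random_state=rs, n_jobs=1,
            )

    X = vals.copy()
    col_means = np.nanmean(vals, axis=0)
    X[holes] = np.take(col_means, np.nonzero(holes)[1])

    miss_count = holes.sum(axis=0)
    sweep_cols = np.argsort(miss_count, kind="stable")
    sweep_cols = [int(j) for j in sweep_cols if miss_count[j] > 0]

    rng = np.random.default_rng(seed)
    prev_delta = np.inf
    best = X.copy()
    for _ in range(max_iter):
        X_old = X.copy()
        for j in sweep_cols:
            obs = ~holes[:, j]
            other = np.delete(X, j, axis=1)
            model = regressor_factory(int(rng.integers(2**31)))
            model.fit(other[obs], X[obs, j])
            X[holes[:, j], j] = model.predict(other[holes[:, j]])
        num = float(((X - X_old)[holes] ** 2).sum())
        den = float((X[holes] ** 2).sum())
        delta = num / den if den > 0 else 0.0
        if delta >= prev_delta:
            X = X_old  # divergence: keep the previous sweep
            break
        best = X.copy()
        prev_delta = delta
        if delta == 0.0:
            break
    out = table.copy()
    out.values = best
    return out


# ---------------------------------------------------------------------------
# QC-based signal correction
# ---------------------------------------------------------------------------

def qc_drift_correct(table: PeakTable,
                     model_params: dict[str, Any] | None = None,
                     regressor_factory: Callable[[], Any] | None = None
                     ) -> tuple[PeakTable, CorrectionModel, QcReport]:
    """QC-based signal correction of every intensity in the table.

    One regressor per feature is trained on the QC injections (covariates:
    injection order and batch; blanks and study samples never enter
    training) and predicts the expected QC-level intensity of every
    injection.  Each cell is replaced by observed / predicted × 1000, with
    predictions floored at ``1e-6`` of the feature's QC mean.

    Returns the corrected table, the fitted :class:`CorrectionModel` and a
    :class:`QcReport` with per-feature QC RSD before and after correction.
    """
    if np.isnan(table.values).any():
        raise PeakTableError("correction requires a complete (imputed) table")
    qc_mask = table.role_mask("qc")
    if qc_mask.sum() < 3:
        raise PeakTableError(
            f"signal correction needs >= 3 QC rows, got {int(qc_mask.sum())}"
        )
    params = dict(DEFAULT_CORRECTION_PARAMS)
    if model_params:
        params.update(model_params)
    if regressor_factory is None:
        def regressor_factory() -> Any:
            return GradientBoostingRegressor(random_state=0, **params)

    covs = table.samples[["injection_order", "batch"]].to_numpy(float)
    qc_covs = covs[qc_mask]
    rsd_before = qc_rsd(table)

    corrected = np.empty_like(table.values)
    regressors: dict[str, Any] = {}
    floors: dict[str, float] = {}
    for j, fid in enumerate(table.feature_ids):
        y_qc = table.values[qc_mask, j]
        model = regressor_factory()
        model.fit(qc_covs, y_qc)
        floor = PREDICTION_FLOOR_REL * max(float(y_qc.mean()), np.finfo(float).tiny)
        pred = np.maximum(model.predict(covs), floor)
        corrected[:, j] = table.values[:, j] / pred * CORRECTION_TARGET
        regressors[fid] = model
        floors[fid] = floor

    out = table.copy()
    out.values = corrected
    report = QcReport(rsd_before=rsd_before, rsd_after=qc_rsd(out))
    return out, CorrectionModel(regressors, CORRECTION_TARGET, floors), report


# ---------------------------------------------------------------------------
# RSD reproducibility filter
# ---------------------------------------------------------------------------

def rsd_filter(table: PeakTable, threshold_pct: float = 30.0
               ) -> tuple[PeakTable, QcReport]:
    """Remove features whose QC RSD exceeds ``threshold_pct``.

    Features whose QC mean is zero have undefined RSD and are removed and
    flagged.  Features with identical QC values (RSD 0) are always kept.
    """
    if threshold_pct <= 0:
        raise ValueError("threshold_pct must be positive")
    rsd = qc_rsd(table)
    undefined = rsd.isna()
    if undefined.any():
        logger.warning("removing %d features with zero QC mean: %s",
                       undefined.sum(), list(rsd.index[undefined][:10]))
    keep = (~undefined) & (rsd <= threshold_pct)
    report = QcReport(rsd_before=rsd, threshold_pct=threshold_pct)
    return table.subset_features(rsd.index[keep]), report


# ---------------------------------------------------------------------------
# technical-replicate averaging
# ---------------------------------------------------------------------------

def average_technical(table: PeakTable) -> PeakTable:
    """Average technical replicates into one row per biological sample.

    QC and blank injections are dropped at this stage; the averaged rows
    keep cultivar and biological replicate but lose batch and injection
    order (they no longer describe a single injection).
    """
    study = table.subset_samples(table.role_mask("study"))
    key = list(zip(study.samples["cultivar"], study.samples["bio_rep"]))
    groups: dict[tuple, list[int]] = {}
    for i, k in enumerate(key):
        groups.setdefault(k, []).append(i)
    rows, meta = [], []
    for (cultivar, bio), idx in groups.items():
        rows.append(study.values[idx].mean(axis=0))
        meta.append(dict(
            sample_id=f"{str(cultivar).replace(' ', '-')}_b{int(bio)}",
            role="study", cultivar=cultivar, bio_rep=int(bio),
            tech_rep=np.nan, batch=np.nan, injection_order=np.nan,
        ))
    samples = pd.DataFrame(meta).set_index("sample_id")
    return PeakTable(np.vstack(rows), samples, table.features.copy(),
                     scaled=table.scaled)


# ---------------------------------------------------------------------------
# autoscaling
# ---------------------------------------------------------------------------

def autoscale(table: PeakTable, return_params: bool = False):
    """Center each feature to mean 0 and scale to unit sample variance.

    Zero-variance features cannot be scaled and are dropped with a warning.
    The returned table carries ``scaled=True``, releasing the
    nonnegativity invariant.  With ``return_params=True`` the per-feature
    means and standard deviations are returned as well, allowing exact
    unscaling.
    """
    if np.isnan(table.values).any():
        raise PeakTableError("autoscale requires a complete table")
    means = table.values.mean(axis=0)
    sds = table.values.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance features", int((~keep).sum()))
    scaled = (table.values[:, keep] - means[keep]) / sds[keep]
    out = PeakTable(scaled, table.samples.copy(), table.features.loc[keep].copy(),
                    scaled=True)
    if return_params:
        index = table.feature_ids[keep]
        return out, pd.Series(means[keep], index=index), pd.Series(sds[keep], index=index)
    return out


# ---------------------------------------------------------------------------
# full pre-treatment chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PretreatmentConfig:
    """Tunable parameters of the pre-treatment chain."""

    rsd_threshold_pct: float = 30.0
    imputation_max_iter: int = 10
    imputation_n_estimators: int = 100
    correction_params: dict[str, Any] = field(
        default_factory=lambda: dict(DEFAULT_CORRECTION_PARAMS))
    seed: int = 0


@dataclass
class PretreatmentResult:
    """Analysis-ready outputs of the pre-treatment chain.

    ``table_raw`` is the corrected, RSD-filtered, technically averaged,
    polarity-bound table on the raw (positive) intensity scale — the input
    of fold-change and moderated-t calculations.  ``table_scaled`` is its
    autoscaled counterpart used by PCA, HCA and PLS.
    """

    table_raw: PeakTable
    table_scaled: PeakTable
    qc_reports: dict[str, QcReport]
    correction_models: dict[str, CorrectionModel]
    scale_means: pd.Series
    scale_sds: pd.Series


def pretreat_study(pos: PeakTable, neg: PeakTable,
                   config: PretreatmentConfig | None = None
                   ) -> PretreatmentResult:
    """Run the whole chain on a two-polarity experiment.

    Stages per polarity: impute → QC drift correction → RSD filter →
    technical averaging; then the two tables are bound by columns and the
    bound table autoscaled.  The post-correction RSDs are recorded in the
    reports but never re-filter (correction is expected to improve, not
    gate, reproducibility).
    """
    cfg = config or PretreatmentConfig()
    staged: dict[str, PeakTable] = {}
    reports: dict[str, QcReport] = {}
    models: dict[str, CorrectionModel] = {}
    for name, tab in (("positive", pos), ("negative", neg)):
        t0 = impute_missing(tab, max_iter=cfg.imputation_max_iter,
                            seed=cfg.seed,
                            n_estimators=cfg.imputation_n_estimators)
        t1, model, corr_report = qc_drift_correct(t0, cfg.correction_params)
        t2, filt_report = rsd_filter(t1, cfg.rsd_threshold_pct)
        logger.info("%s polarity: %d/%d features pass RSD <= %.0f%%",
                    name, t2.n_features, t1.n_features, cfg.rsd_threshold_pct)
        staged[name] = average_technical(t2)
        reports[f"{name}_correction"] = corr_report
        reports[f"{name}_filter"] = filt_report
        models[name] = model
    bound_raw = bind_polarities(staged["positive"], staged["negative"])
    bound_scaled, means, sds = autoscale(bound_raw, return_params=True)
    return PretreatmentResult(
        table_raw=bound_raw, table_scaled=bound_scaled,
        qc_reports=reports, correction_models=models,
        scale_means=means, scale_sds=sds,
    )
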