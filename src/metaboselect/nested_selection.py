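"""Nested bootstrap/cross-validation marker selection.

The selector wraps a three-criterion "rational cut-off" — BH-adjusted
moderated-t p-value, fold change and PLS VIP — in a nested resampling
scheme so that held-out data never informs selection:

* the samples are split into ``n_outer`` stratified folds (outer loop);
* for each outer fold, the remaining nine folds define nine inner
  iterations; in each, the inner-training set (the other eight folds) is
  bootstrapped ``n_boot`` times and the cut-off applied to every bootstrap;
* the per-iteration bootstrap sets are intersected, the nine iteration sets
  are intersected into the outer set ``S_o``, and a logistic GLM restricted
  to ``S_o`` is trained on the outer-training samples and scored on the
  held-out outer fold;
* the final marker set is the strict intersection of all outer sets.

All intersections are strict; an empty outer set is recorded (accuracy
undefined for that fold) and propagates to an empty final set, reported
loudly rather than silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .stats_core import (
    bh_adjust,
    fit_logistic_glm,
    fit_pls,
    log_fold_change,
    moderated_t_test,
    stratified_folds,
    tune_pls_components,
)

__all__ = [
    "CutoffCriteria",
    "SelectionResult",
    "rational_cutoff",
    "bootstrap_resample",
    "glm_validate",
    "run_nested_selection",
]

logger = logging.getLogger("metaboselect")


@dataclass(frozen=True)
class CutoffCriteria:
    """The three simultaneous selection criteria.

    A feature is selected iff its BH-adjusted moderated-t p-value is below
    ``alpha_adjusted``, its fold change passes per ``fc_mode`` (default:
    ``|log2 FC| > fc_threshold``) and its VIP from a component-tuned PLS
    fit exceeds ``vip_threshold``.
    """

    alpha_adjusted: float = 0.05
    fc_threshold: float = 1.0
    vip_threshold: float = 1.0
    fc_mode: Literal["abs_log2", "signed_log2", "raw_ratio"] = "abs_log2"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_adjusted <= 1.0:
            raise ValueError("alpha_adjusted must be in (0, 1]")
        if self.fc_threshold < 0 or self.vip_threshold < 0:
            raise ValueError("thresholds must be nonnegative")


@dataclass
class SelectionResult:
    """Outcome of one nested selection run."""

    outer_sets: list[set[str]]
    outer_accuracies: list[float]  # NaN where the outer set was empty
    final_set: set[str]
    diagnostics: list[dict] = field(default_factory=list)

    @property
    def n_outer(self) -> int:
        return len(self.outer_sets)


def _pls_response(labels) -> np.ndarray:
    """Class coding for PLS: first group +1, second −1."""
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError("labels must contain exactly two classes")
    return np.where(labels == levels[0], 1.0, -1.0)


def rational_cutoff(train_scaled: np.ndarray, train_raw: np.ndarray,
                    labels, criteria: CutoffCriteria,
                    feature_ids: Sequence[str],
                    pls_max_components: int = 5,
                    pls_cv_folds: int = 10,
                    seed: int = 0) -> set[str]:
    """Features passing all three criteria on one (resampled) training set.

    The moderated t-test runs on the log2 of the raw (corrected, positive)
    intensities, the fold change on the raw intensities, and the VIP comes
    from a PLS fit on the autoscaled matrix whose component count is tuned
    by cross-validated Q².
    """
    train_scaled = np.asarray(train_scaled, dtype=float)
    train_raw = np.asarray(train_raw, dtype=float)
    labels = np.asarray(labels)
    feature_ids = list(feature_ids)
    if train_scaled.shape != train_raw.shape:
        raise ValueError("scaled and raw matrices disagree in shape")
    if train_scaled.shape[1] != len(feature_ids):
        raise ValueError("feature_ids length does not match the matrices")
    if len(np.unique(labels)) < 2:
        raise ValueError("single-class labels")

    log_raw = np.log2(np.maximum(train_raw, np.finfo(float).tiny))
    test = moderated_t_test(log_raw, labels)
    pass_p = test.p_adjusted < criteria.alpha_adjusted

    lfc = log_fold_change(train_raw, labels)
    if criteria.fc_mode == "abs_log2":
        pass_fc = np.abs(lfc) > criteria.fc_threshold
    elif criteria.fc_mode == "signed_log2":
        pass_fc = lfc > criteria.fc_threshold
    elif criteria.fc_mode == "raw_ratio":
        pass_fc = np.exp2(lfc) > criteria.fc_threshold
    else:
        raise ValueError(f"unknown fc_mode {criteria.fc_mode!r}")

    y = _pls_response(labels)
    n_folds = min(pls_cv_folds, len(y))
    n_comp, _, _ = tune_pls_components(train_scaled, y,
                                       max_components=pls_max_components,
                                       n_folds=n_folds, seed=seed)
    model = fit_pls(train_scaled, y, n_comp)
    pass_vip = model.vip > criteria.vip_threshold

    selected = pass_p & pass_fc & pass_vip
    return {feature_ids[j] for j in np.flatnonzero(selected)}


def bootstrap_resample(indices: Sequence[int], labels, seed: int) -> np.ndarray:
    """Stratified bootstrap of sample indices to the original size.

    Sampling with replacement happens within each class, so both classes
    are always present in the draw and class proportions are preserved.
    """
    indices = np.asarray(indices)
    labels = np.asarray(labels)
    if len(indices) != len(labels):
        raise ValueError("indices and labels differ in length")
    levels = np.unique(labels)
    if len(levels) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    draw: list[np.ndarray] = []
    for level in levels:
        pool = indices[labels == level]
        draw.append(rng.choice(pool, size=len(pool), replace=True))
    return np.concatenate(draw)


def glm_validate(train: np.ndarray, train_labels, test: np.ndarray,
                 test_labels, ridge: float = 1e-3) -> float:
    """Held-out accuracy of a logistic GLM on a selected feature subset."""
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[1] == 0:
        raise ValueError("empty feature set")
    model = fit_logistic_glm(train, train_labels, ridge=ridge)
    return model.accuracy(np.asarray(test, dtype=float), test_labels)


def run_nested_selection(table_scaled, table_raw, labels,
                         criteria: CutoffCriteria | None = None,
                         n_outer: int = 10, n_boot: int = 5, seed: int = 0,
                         pls_max_components: int = 5, pls_cv_folds: int = 10,
                         inner_mode: Literal["cv", "literal"] = "cv",
                         glm_ridge: float = 1e-3,
                         accuracy_floor: float | None = None) -> SelectionResult:
    """Run the full nested feature-selection scheme.

    Parameters
    ----------
    table_scaled, table_raw
        Either :class:`~metaboselect.core_model.PeakTable` objects or plain
        arrays over the same samples and features; the scaled table feeds
        PLS and the GLM, the raw one the t-test and fold change.
    labels
        Binary class per sample (typically the metabolome-based clusters).
    inner_mode
        ``"cv"`` (default): each of the nine retained folds defines an
        inner iteration whose *training* set (the other eight folds) is
        bootstrapped — a fold of five samples alone could not support a
        PLS fit.  ``"literal"``: each retained fold itself is bootstrapped,
        for comparison with the stricter reading of the scheme.
    accuracy_floor
        Off by default: the GLM accuracy is a diagnostic and never vetoes
        an outer set.  When set, outer sets whose held-out accuracy falls
        below the floor are excluded from the final intersection (recorded
        in the diagnostics).
    """
    scaled, raw, feature_ids = _unpack_tables(table_scaled, table_raw)
    labels = np.asarray(labels)
    criteria = criteria or CutoffCriteria()
    if len(labels) != scaled.shape[0]:
        raise ValueError("labels length does not match the tables")
    if len(labels) < n_outer:
        raise ValueError("fewer samples than outer folds")

    rng = np.random.default_rng(seed)
    folds = stratified_folds(labels, n_outer, rng)
    all_idx = np.arange(len(labels))

    outer_sets: list[set[str]] = []
    outer_acc: list[float] = []
    diagnostics: list[dict] = []
    for o, test_idx in enumerate(folds):
        train_folds = [f for i, f in enumerate(folds) if i != o]
        iteration_sets: list[set[str]] = []
        inner_sizes: list[int] = []
        for i in range(len(train_folds)):
            if inner_mode == "cv":
                pool = np.concatenate(
                    [f for j, f in enumerate(train_folds) if j != i])
            else:
                pool = train_folds[i]
            boot_sets: list[set[str]] = []
            for _ in range(n_boot):
                bseed = int(rng.integers(2**31))
                idx = bootstrap_resample(pool, labels[pool], seed=bseed)
                sel = rational_cutoff(
                    scaled[idx], raw[idx], labels[idx], criteria, feature_ids,
                    pls_max_components=pls_max_components,
                    pls_cv_folds=min(pls_cv_folds, len(idx)),
                    seed=int(rng.integers(2**31)),
                )
                boot_sets.append(sel)
            iteration_set = set.intersection(*boot_sets)
            iteration_sets.append(iteration_set)
            inner_sizes.append(len(iteration_set))
        S_o = set.intersection(*iteration_sets)
        outer_sets.append(S_o)
        if S_o:
            cols = [feature_ids.index(f) for f in sorted(S_o)]
            train_idx = np.setdiff1d(all_idx, test_idx)
            acc = glm_validate(scaled[np.ix_(train_idx, cols)],
                               labels[train_idx],
                               scaled[np.ix_(test_idx, cols)],
                               labels[test_idx], ridge=glm_ridge)
        else:
            logger.warning("outer fold %d selected no features; "
                           "accuracy undefined", o + 1)
            acc = float("nan")
        outer_acc.append(acc)
        diagnostics.append({
            "outer_fold": o + 1,
            "outer_set_size": len(S_o),
            "inner_set_sizes": inner_sizes,
            "test_size": int(len(test_idx)),
        })
    if accuracy_floor is None:
        retained = outer_sets
    else:
        retained = [S for S, a in zip(outer_sets, outer_acc)
                    if not np.isnan(a) and a >= accuracy_floor]
        for d, a in zip(diagnostics, outer_acc):
            d["vetoed_by_accuracy_floor"] = bool(
                np.isnan(a) or a < accuracy_floor)
    final_set = set.intersection(*retained) if retained else set()
    if not final_set:
        logger.warning("final intersected marker set is EMPTY")
    return SelectionResult(outer_sets=outer_sets, outer_accuracies=outer_acc,
                           final_set=final_set, diagnostics=diagnostics)


def _unpack_tables(table_scaled, table_raw):
    """Accept PeakTables or arrays; return aligned arrays + feature ids."""
    from .core_model import PeakTable  # local import to avoid cycle

    if isinstance(table_scaled, PeakTable):
        if not isinstance(table_raw, PeakTable):
            raise TypeError("pass both tables as PeakTable or both as arrays")
        if not table_scaled.sample_ids.equals(table_raw.sample_ids):
            raise ValueError("tables disagree on samples")
        common = [f for f in table_scaled.feature_ids
                  if f in set(table_raw.feature_ids)]
        raw = table_raw.subset_features(common)
        scaled = table_scaled.subset_features(common)
        return scaled.values, raw.values, common
    scaled = np.asarray(table_scaled, dtype=float)
    raw = np.asarray(table_raw, dtype=float)
    if scaled.shape != raw.shape:
        raise ValueError("scaled and raw matrices disagree in shape")
    return scaled, raw, [f"f{j}" for j in range(scaled.shape[1])]
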