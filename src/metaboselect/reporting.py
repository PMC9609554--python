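"""Post-selection reporting: retention-time grouping and the marker table.

Selected signals that share a retention time window usually belong to one
compound (isotopes, adducts, in-source fragments, opposite-polarity ions),
so the report clusters them by single-linkage chaining on |Δrt| and
attaches a group id.  The marker table re-states each selected feature
with its m/z, retention time, polarity, VIP and log2 fold change, the two
statistics recomputed once on the full analysis-ready dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_model import PeakTable
from .nested_selection import SelectionResult, _pls_response
from .stats_core import fit_pls, log_fold_change, tune_pls_components

__all__ = ["group_features_by_rt", "build_marker_table"]

MARKER_COLUMNS = ["feature_id", "polarity", "mz", "rt", "vip",
                  "log2_fold_change", "rt_group"]


def group_features_by_rt(features: pd.DataFrame, tolerance_min: float = 0.1
                         ) -> dict[str, int]:
    """Single-linkage grouping of features on retention time.

    Two features chain into one group whenever their retention times are
    within ``tolerance_min`` minutes of each other (transitively), polarity
    ignored — positive and negative ions of one compound co-group.  Group
    ids are contiguous from 1 in order of elution.
    """
    if tolerance_min <= 0:
        raise ValueError("tolerance_min must be positive")
    if len(features) == 0:
        return {}
    order = features["rt"].sort_values(kind="stable")
    groups: dict[str, int] = {}
    gid = 1
    prev_rt = None
    for fid, rt in order.items():
        if prev_rt is not None and rt - prev_rt > tolerance_min:
            gid += 1
        groups[fid] = gid
        prev_rt = rt
    return groups


def build_marker_table(selection: SelectionResult, table_raw: PeakTable,
                       table_scaled: PeakTable, labels,
                       rt_tolerance_min: float = 0.1,
                       pls_max_components: int = 5, seed: int = 0
                       ) -> pd.DataFrame:
    """Assemble the marker report for the final intersected feature set.

    VIP values come from one component-tuned PLS fit on the full autoscaled
    dataset and fold changes from the full raw (corrected, unscaled)
    dataset, so the report describes the markers in the context of the
    whole experiment rather than any resampled subset.  An empty selection
    yields a header-only table.
    """
    final = sorted(selection.final_set)
    if not final:
        return pd.DataFrame(columns=MARKER_COLUMNS)

    labels = np.asarray(labels)
    y = _pls_response(labels)
    n_comp, _, _ = tune_pls_components(
        table_scaled.values, y, max_components=pls_max_components,
        n_folds=min(10, table_scaled.n_samples), seed=seed)
    model = fit_pls(table_scaled.values, y, n_comp)
    vip = pd.Series(model.vip, index=table_scaled.feature_ids)
    lfc = pd.Series(log_fold_change(table_raw.values, labels),
                    index=table_raw.feature_ids)

    feats = table_scaled.features.loc[final]
    rt_groups = group_features_by_rt(feats, rt_tolerance_min)
    out = pd.DataFrame({
        "feature_id": final,
        "polarity": feats["polarity"].to_numpy(),
        "mz": feats["mz"].to_numpy(),
        "rt": feats["rt"].to_numpy(),
        "vip": vip.loc[final].to_numpy(),
        "log2_fold_change": lfc.loc[final].to_numpy(),
        "rt_group": [rt_groups[f] for f in final],
    })
    return out.sort_values(["rt_group", "rt", "feature_id"],
                           kind="stable").reset_index(drop=True)
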