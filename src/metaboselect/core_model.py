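"""Domain types, validation and delimited-text I/O for LC-MS peak tables.

The central container is :class:`PeakTable`: an injections × features matrix
of chromatographic peak areas together with aligned sample and feature
metadata.  Every pipeline stage consumes and produces this object.

On-disk format is plain CSV.  The reserved metadata columns are
``sample_id, role, cultivar, bio_rep, tech_rep, batch, injection_order``;
every remaining column is one feature, with the header encoding its metadata
as ``polarity|mz|rt|feature_id``.  Missing intensities are written as empty
cells (or a configurable sentinel such as ``NA``) and held internally as NaN
— never as zero, because downstream stages impute rather than zero-fill.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "METADATA_COLUMNS",
    "ROLES",
    "POLARITIES",
    "PeakTable",
    "StudyDesign",
    "PeakTableError",
    "read_peak_table",
    "write_peak_table",
    "bind_polarities",
    "load_cultivar_annotations",
]

#: reserved sample-metadata columns, in on-disk order
METADATA_COLUMNS = (
    "sample_id",
    "role",
    "cultivar",
    "bio_rep",
    "tech_rep",
    "batch",
    "injection_order",
)

ROLES = ("study", "qc", "blank")
POLARITIES = ("positive", "negative")

#: instrument acquisition range in Thomson
MZ_RANGE = (120.0, 850.0)


class PeakTableError(ValueError):
    """Raised when a peak table violates a structural invariant."""


@dataclass(frozen=True)
class StudyDesign:
    """Replication / batch / injection-order structure of an experiment.

    Attributes
    ----------
    n_cultivars, n_bio, n_tech
        Number of cultivars, biological replicates per cultivar and
        technical replicates (repeat injections) per biological replicate.
    n_batches
        Number of acquisition batches; study injections are distributed
        evenly over batches, both technical replicates of a sample always
        falling in the same batch.
    qc_per_batch, blank_per_batch
        Pooled-QC and blank injections interleaved into every batch.
    cultivar_annotations
        Optional table mapping cultivar → region / genetic_origin /
        usage_type (and, for simulations, a latent group).
    """

    n_cultivars: int = 18
    n_bio: int = 3
    n_tech: int = 2
    n_batches: int = 9
    qc_per_batch: int = 5
    blank_per_batch: int = 3
    cultivar_annotations: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("n_cultivars", "n_bio", "n_tech", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.qc_per_batch < 0 or self.blank_per_batch < 0:
            raise ValueError("qc_per_batch / blank_per_batch must be >= 0")
        n_samples = self.n_cultivars * self.n_bio
        if n_samples % self.n_batches:
            raise ValueError(
                f"{n_samples} biological samples are not distributable over "
                f"{self.n_batches} batches"
            )

    @property
    def n_study_injections(self) -> int:
        return self.n_cultivars * self.n_bio * self.n_tech

    @property
    def n_injections(self) -> int:
        return self.n_study_injections + self.n_batches * (
            self.qc_per_batch + self.blank_per_batch
        )


@dataclass
class PeakTable:
    """Intensity matrix plus aligned sample and feature metadata.

    Parameters
    ----------
    values
        ``(n_injections, n_features)`` float array of peak areas
        (arbitrary units); NaN marks a missing value.
    samples
        One row per injection, indexed by unique ``sample_id``; columns
        ``role`` (study/qc/blank), ``cultivar``, ``bio_rep``, ``tech_rep``,
        ``batch``, ``injection_order``.  Batch and injection order may be
        absent after technical-replicate averaging.
    features
        One row per feature, indexed by unique ``feature_id``; columns
        ``polarity`` (positive/negative), ``mz`` (Th), ``rt`` (min).
    scaled
        Set once the table has been autoscaled; releases the
        nonnegativity invariant.
    """

    values: np.ndarray
    samples: pd.DataFrame
    features: pd.DataFrame
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PeakTableError("values must be a 2-D matrix")
        self.validate()

    # -- structural checks -------------------------------------------------

    def validate(self) -> None:
        n, p = self.values.shape
        if len(self.samples) != n:
            raise PeakTableError(
                f"{n} intensity rows but {len(self.samples)} sample records"
            )
        if len(self.features) != p:
            raise PeakTableError(
                f"{p} intensity columns but {len(self.features)} feature records"
            )
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()].unique()
            raise PeakTableError(f"duplicate sample ids: {list(dup)}")
        if self.features.index.has_duplicates:
            dup = self.features.index[self.features.index.duplicated()].unique()
            raise PeakTableError(f"duplicate feature ids: {list(dup)}")
        bad_roles = set(self.samples["role"]) - set(ROLES)
        if bad_roles:
            raise PeakTableError(f"unknown sample roles: {sorted(bad_roles)}")
        study = self.samples["role"] == "study"
        if study.any():
            missing = self.samples.loc[study, "cultivar"].isna()
            if missing.any():
                raise PeakTableError(
                    "study samples without cultivar: "
                    f"{list(self.samples.index[study][missing])}"
                )
        if "injection_order" in self.samples:
            order = self.samples["injection_order"].dropna()
            if order.duplicated().any():
                raise PeakTableError("injection_order values are not unique")
        if not self.scaled and np.nanmin(self.values, initial=0.0) < 0:
            raise PeakTableError("negative intensity in unscaled table")
        bad_pol = set(self.features["polarity"]) - set(POLARITIES)
        if bad_pol:
            raise PeakTableError(f"unknown polarities: {sorted(bad_pol)}")
        if len(self.features):
            mz = self.features["mz"].to_numpy(float)
            rt = self.features["rt"].to_numpy(float)
            if ((mz < MZ_RANGE[0]) | (mz > MZ_RANGE[1])).any():
                raise PeakTableError(
                    f"m/z outside the acquisition range {MZ_RANGE}")
            if (rt < 0).any():
                raise PeakTableError("negative retention time")

    # -- convenience accessors --------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    def role_mask(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return (self.samples["role"] == role).to_numpy()

    def subset_samples(self, mask: np.ndarray | Sequence[bool]) -> "PeakTable":
        mask = np.asarray(mask)
        return PeakTable(
            self.values[mask],
            self.samples.iloc[mask] if mask.dtype == bool else self.samples.iloc[mask],
            self.features,
            scaled=self.scaled,
        )

    def subset_features(self, ids: Iterable[str]) -> "PeakTable":
        ids = list(ids)
        idx = self.features.index.get_indexer(ids)
        if (idx < 0).any():
            unknown = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"unknown feature ids: {unknown}")
        return PeakTable(
            self.values[:, idx], self.samples, self.features.loc[ids],
            scaled=self.scaled,
        )

    def copy(self) -> "PeakTable":
        return PeakTable(
            self.values.copy(), self.samples.copy(), self.features.copy(),
            scaled=self.scaled,
        )

    def equals(self, other: "PeakTable", rtol: float = 0.0, atol: float = 0.0) -> bool:
        return (
            self.scaled == other.scaled
            and self.samples.equals(other.samples)
            and self.features.equals(other.features)
            and np.allclose(self.values, other.values, rtol=rtol, atol=atol,
                            equal_nan=True)
        )


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _feature_header(features: pd.DataFrame) -> list[str]:
    # repr() is the shortest exact decimal round-trip for a float
    return [
        f"{row.polarity}|{float(row.mz)!r}|{float(row.rt)!r}|{fid}"
        for fid, row in features.iterrows()
    ]


def _parse_feature_header(col: str) -> tuple[str, float, float, str]:
    parts = col.split("|")
    if len(parts) != 4:
        raise PeakTableError(
            f"feature column {col!r} is not of the form polarity|mz|rt|feature_id"
        )
    polarity, mz, rt, fid = parts
    return polarity, float(mz), float(rt), fid


def write_peak_table(table: PeakTable, path: str | Path, *,
                     missing_sentinel: str = "") -> None:
    """Write a peak table as CSV, parseable by :func:`read_peak_table`.

    Missing values are written as ``missing_sentinel`` (empty cell by
    default), never as zero.
    """
    table.validate()
    meta = table.samples.reset_index()
    meta = meta.rename(columns={meta.columns[0]: "sample_id"})
    for col in METADATA_COLUMNS:
        if col not in meta:
            meta[col] = np.nan
    meta = meta[list(METADATA_COLUMNS)]
    intens = pd.DataFrame(
        table.values, columns=_feature_header(table.features), index=meta.index
    )
    out = pd.concat([meta, intens], axis=1)
    out.to_csv(path, index=False, na_rep=missing_sentinel)


def read_peak_table(path: str | Path, *, missing_sentinel: str = "NA",
                    scaled: bool = False) -> PeakTable:
    """Read a CSV peak table written by :func:`write_peak_table`.

    Empty cells and ``missing_sentinel`` both become missing markers (NaN).
    Validation errors (duplicate ids, negative intensities, unknown roles)
    raise :class:`PeakTableError`.
    """
    df = pd.read_csv(path, na_values=[missing_sentinel], keep_default_na=True,
                     dtype={"sample_id": str, "cultivar": str})
    missing_meta = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_meta:
        raise PeakTableError(f"missing reserved metadata columns: {missing_meta}")
    feature_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    parsed = [_parse_feature_header(c) for c in feature_cols]
    features = pd.DataFrame(
        {
            "polarity": [p[0] for p in parsed],
            "mz": [p[1] for p in parsed],
            "rt": [p[2] for p in parsed],
        },
        index=pd.Index([p[3] for p in parsed], name="feature_id"),
    )
    samples = df[list(METADATA_COLUMNS)].set_index("sample_id")
    for col in ("bio_rep", "tech_rep", "batch", "injection_order"):
        samples[col] = pd.to_numeric(samples[col], errors="coerce")
    values = df[feature_cols].to_numpy(dtype=float)
    return PeakTable(values, samples, features, scaled=scaled)


# ---------------------------------------------------------------------------
# polarity binding
# ---------------------------------------------------------------------------

_POLARITY_PREFIX = {"positive": "pos_", "negative": "neg_"}


def bind_polarities(pos: PeakTable, neg: PeakTable) -> PeakTable:
    """Column-bind the positive- and negative-mode tables of one experiment.

    Rows are aligned by ``sample_id`` (the order of ``pos`` wins); feature
    ids are namespaced with ``pos_`` / ``neg_`` prefixes so uniqueness holds
    even when both acquisitions produced the same raw id.

    Raises
    ------
    PeakTableError
        If the two tables do not cover the same sample set or are at
        different processing stages.
    """
    if pos.scaled != neg.scaled:
        raise PeakTableError("cannot bind tables at different processing stages")
    ids_pos, ids_neg = set(pos.sample_ids), set(neg.sample_ids)
    if ids_pos != ids_neg:
        only_pos = sorted(ids_pos - ids_neg)
        only_neg = sorted(ids_neg - ids_pos)
        raise PeakTableError(
            f"sample sets differ: only in positive {only_pos}, "
            f"only in negative {only_neg}"
        )
    order = neg.samples.index.get_indexer(pos.sample_ids)
    neg_values = neg.values[order]

    def _prefixed(features: pd.DataFrame) -> pd.DataFrame:
        out = features.copy()
        out.index = pd.Index(
            [_POLARITY_PREFIX[p] + fid
             for fid, p in zip(features.index, features["polarity"])],
            name="feature_id",
        )
        return out

    features = pd.concat([_prefixed(pos.features), _prefixed(neg.features)])
    values = np.hstack([pos.values, neg_values])
    return PeakTable(values, pos.samples.copy(), features, scaled=pos.scaled)


# ---------------------------------------------------------------------------
# packaged study metadata
# ---------------------------------------------------------------------------

def load_cultivar_annotations() -> pd.DataFrame:
    """Load the packaged 18-cultivar hop panel.

    Columns: ``region`` (growth region, 6 cultivars each), ``genetic_origin``
    (EST-SSR germplasm assignment), ``usage_type`` (aroma / dual use) and
    ``metabolome_group`` (the two-cluster metabolome-based assignment, used
    as the default latent grouping of the simulator).  Indexed by cultivar.
    """
    ref = importlib.resources.files("metaboselect.data") / "cultivar_annotations.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return df.set_index("cultivar")
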