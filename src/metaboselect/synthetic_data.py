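"""Synthetic LC-MS study generator.

Emulates the statistical structure of a multi-batch untargeted profiling
experiment on a cultivar panel: each cultivar measured in biological and
technical replicates, injections randomized over batches, pooled-QC and
blank injections interleaved into every batch, smooth injection-order drift
with per-batch offsets, intensity-dependent missing values, planted
group-discriminative marker features, and two polarity tables acquired on
the same injection sequence.

The generative model works on the log2 scale.  A feature's study intensity
for cultivar *c* is

    log2 I = base_f + cultivar_effect_{f,c} + marker_shift_{f,c} + noise

with ``base_f ~ N(base_log_mean, base_log_sd)``, a between-cultivar
biological effect ``~ N(0, cultivar_log_sd)``, a ``±marker_log2_effect/2``
shift on planted markers according to the cultivar's latent group (group 1
up), and iid injection noise ``~ N(0, noise_log_sd)``.  Pooled QC rows take
the arithmetic mean of all study-sample pre-noise intensities on the raw
scale (ideal pooling) and then pass through the same drift, batch and noise
nuisances as any injection.  Blanks sit three orders of magnitude below the
study signal.  Drift is a per-feature multiplicative exponential trend in
within-batch injection position times a per-batch offset shared across
features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_model import PeakTable, StudyDesign, load_cultivar_annotations

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_study", "inject_missing"]

_BLANK_LOG2_OFFSET = -10.0  # blanks ~2^-10 (≈0.1%) of study signal
_MZ_RANGE = (120.0, 850.0)
_RT_RANGE = (0.5, 47.0)  # elution window, min


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated study.

    Defaults mirror the emulated design: an 18-cultivar panel with
    3 biological × 2 technical replicates acquired in 9 batches with
    5 QC + 3 blank injections per batch, ~3000 features over two
    polarities, and 62 planted markers.
    """

    design: StudyDesign = field(default_factory=StudyDesign)
    n_features_pos: int = 1550
    n_features_neg: int = 1450
    n_markers: int = 62
    marker_log2_effect: float = 1.0
    base_log_mean: float = 17.0
    base_log_sd: float = 2.0
    cultivar_log_sd: float = 0.5
    noise_log_sd: float = 0.2
    drift_amplitude: float = 0.3
    batch_offset_sd: float = 0.1
    missing_rate: float = 0.05
    censor_strength: float = 1.0
    group_split: Mapping[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers > self.n_features_pos + self.n_features_neg:
            raise ValueError("n_markers exceeds the total feature count")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        for name in ("noise_log_sd", "drift_amplitude", "batch_offset_sd",
                     "censor_strength", "cultivar_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated study (for recovery experiments).

    ``marker_ids`` holds generator feature ids (``P####`` / ``N####``);
    :meth:`marker_ids_bound` translates them to the polarity-prefixed ids
    carried by a column-bound table.
    """

    marker_ids: set[str]
    group_of_cultivar: dict[str, int]
    drift_curves: dict[str, np.ndarray]  # polarity -> (n_injections, n_features)
    batch_offsets: np.ndarray

    def marker_ids_bound(self) -> set[str]:
        prefix = {"P": "pos_", "N": "neg_"}
        return {prefix[fid[0]] + fid for fid in self.marker_ids}

    def group_labels(self, samples: pd.DataFrame) -> np.ndarray:
        """Latent group per study row of a samples table."""
        return np.array(
            [self.group_of_cultivar[c] for c in samples["cultivar"]], dtype=int
        )


# ---------------------------------------------------------------------------
# injection layout
# ---------------------------------------------------------------------------

def _batch_role_layout(n_study: int, n_qc: int, n_blank: int) -> list[str]:
    """Roles of one batch's injection slots, in acquisition order.

    Blanks bracket the batch (system-stability checks), QC injections are
    spread evenly through it, study injections fill the gaps.
    """
    size = n_study + n_qc + n_blank
    roles = [None] * size
    blank_pos = np.unique(
        np.round(np.linspace(0, size - 1, n_blank)).astype(int)
    ) if n_blank else np.array([], dtype=int)
    for pos in blank_pos:
        roles[pos] = "blank"
    free = [i for i in range(size) if roles[i] is None]
    qc_pos = (
        np.unique(np.round(np.linspace(0, len(free) - 1, n_qc)).astype(int))
        if n_qc else np.array([], dtype=int)
    )
    for j in qc_pos:
        roles[free[j]] = "qc"
    for i in range(size):
        if roles[i] is None:
            roles[i] = "study"
    return roles


def _build_sample_sheet(design: StudyDesign, cultivars: list[str],
                        rng: np.random.Generator) -> pd.DataFrame:
    """Randomize the injection sequence of the whole experiment.

    Biological samples are shuffled over batches (both technical replicates
    of a sample stay within one batch, emulating repeat injection of a
    prepared extract), then injection order within each batch is shuffled.
    """
    bio_samples = [(c, b) for c in cultivars for b in range(1, design.n_bio + 1)]
    order = rng.permutation(len(bio_samples))
    per_batch = len(bio_samples) // design.n_batches
    rows: list[dict] = []
    injection = 0
    for batch in range(1, design.n_batches + 1):
        chunk = [bio_samples[i] for i in
                 order[(batch - 1) * per_batch: batch * per_batch]]
        study_queue = [(c, b, t) for (c, b) in chunk
                       for t in range(1, design.n_tech + 1)]
        study_queue = [study_queue[i] for i in rng.permutation(len(study_queue))]
        roles = _batch_role_layout(
            len(study_queue), design.qc_per_batch, design.blank_per_batch
        )
        qc_i = bl_i = 0
        for role in roles:
            injection += 1
            if role == "study":
                c, b, t = study_queue.pop(0)
                sid = f"S_{c.replace(' ', '-')}_b{b}_t{t}"
                rows.append(dict(sample_id=sid, role="study", cultivar=c,
                                 bio_rep=b, tech_rep=t, batch=batch,
                                 injection_order=injection))
            elif role == "qc":
                qc_i += 1
                rows.append(dict(sample_id=f"QC_b{batch}_{qc_i}", role="qc",
                                 cultivar=None, bio_rep=None, tech_rep=None,
                                 batch=batch, injection_order=injection))
            else:
                bl_i += 1
                rows.append(dict(sample_id=f"BL_b{batch}_{bl_i}", role="blank",
                                 cultivar=None, bio_rep=None, tech_rep=None,
                                 batch=batch, injection_order=injection))
    return pd.DataFrame(rows).set_index("sample_id")


def _default_group_split(cultivars: list[str]) -> dict[str, int]:
    """Latent two-group split: the packaged panel's metabolome groups when
    the cultivar names match, otherwise an alternating assignment."""
    annot = load_cultivar_annotations()
    if set(cultivars) <= set(annot.index):
        return {c: int(annot.loc[c, "metabolome_group"]) for c in cultivars}
    return {c: 1 + i % 2 for i, c in enumerate(sorted(cultivars))}


# ---------------------------------------------------------------------------
# intensity model
# ---------------------------------------------------------------------------

def _simulate_polarity(samples: pd.DataFrame, polarity: str, n_features: int,
                       marker_idx: np.ndarray, cfg: SimulationConfig,
                       group_of_cultivar: Mapping[str, int],
                       batch_offsets: np.ndarray,
                       rng: np.random.Generator) -> tuple[PeakTable, np.ndarray]:
    prefix = "P" if polarity == "positive" else "N"
    fids = pd.Index([f"{prefix}{i:04d}" for i in range(1, n_features + 1)],
                    name="feature_id")
    features = pd.DataFrame(
        {
            "polarity": polarity,
            "mz": rng.uniform(*_MZ_RANGE, size=n_features).round(4),
            "rt": rng.uniform(*_RT_RANGE, size=n_features).round(3),
        },
        index=fids,
    )

    cultivars = sorted({c for c in samples["cultivar"].dropna()})
    base = rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=n_features)
    cult_eff = rng.normal(0.0, cfg.cultivar_log_sd,
                          size=(len(cultivars), n_features))
    shift = np.zeros((len(cultivars), n_features))
    half = cfg.marker_log2_effect / 2.0
    for ci, c in enumerate(cultivars):
        sign = 1.0 if group_of_cultivar[c] == 1 else -1.0
        shift[ci, marker_idx] = sign * half
    # pre-noise linear-scale means per cultivar and for the pooled QC
    cult_mean = np.exp2(base[None, :] + cult_eff + shift)
    qc_mean = cult_mean.mean(axis=0)
    blank_mean = np.exp2(base + _BLANK_LOG2_OFFSET)

    # per-feature drift trend: amplitude jittered around the configured
    # relative change over one batch, direction random
    jitter = np.exp(rng.normal(0.0, 0.25, size=n_features))
    amp = np.log1p(cfg.drift_amplitude * jitter)
    sign = rng.choice([-1.0, 1.0], size=n_features)
    batch = samples["batch"].to_numpy(int)
    # within-batch position scaled to [0, 1]
    pos_in_batch = np.empty(len(samples))
    for b in np.unique(batch):
        m = batch == b
        o = samples.loc[m, "injection_order"].to_numpy(float)
        span = o.max() - o.min()
        pos_in_batch[m] = (o - o.min()) / (span if span > 0 else 1.0)
    drift = np.exp(pos_in_batch[:, None] * (sign * amp)[None, :])

    ci_of = {c: i for i, c in enumerate(cultivars)}
    mean_rows = np.empty((len(samples), n_features))
    for r, (_, row) in enumerate(samples.iterrows()):
        if row["role"] == "study":
            mean_rows[r] = cult_mean[ci_of[row["cultivar"]]]
        elif row["role"] == "qc":
            mean_rows[r] = qc_mean
        else:
            mean_rows[r] = blank_mean

    noise = np.exp2(rng.normal(0.0, cfg.noise_log_sd,
                               size=(len(samples), n_features)))
    values = mean_rows * drift * batch_offsets[batch - 1][:, None] * noise
    table = PeakTable(values, samples.copy(), features)
    return table, drift


def simulate_study(config: SimulationConfig
                   ) -> tuple[PeakTable, PeakTable, SimulationTruth]:
    """Generate the positive- and negative-mode peak tables of one study.

    Returns the two polarity tables (identical sample metadata, disjoint
    features) and the :class:`SimulationTruth` recording planted markers,
    drift curves and the latent cultivar grouping.  The same configuration
    and seed reproduce the output bit for bit.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    design = cfg.design
    if design.cultivar_annotations is not None:
        cultivars = list(design.cultivar_annotations.index)[: design.n_cultivars]
    elif design.n_cultivars == 18:
        cultivars = list(load_cultivar_annotations().index)
    else:
        cultivars = [f"cv{i:02d}" for i in range(1, design.n_cultivars + 1)]
    if len(cultivars) != design.n_cultivars:
        raise ValueError("cultivar annotation table shorter than n_cultivars")

    group_of_cultivar = (
        dict(cfg.group_split) if cfg.group_split is not None
        else _default_group_split(cultivars)
    )
    missing_groups = set(cultivars) - set(group_of_cultivar)
    if missing_groups:
        raise ValueError(f"group_split misses cultivars: {sorted(missing_groups)}")

    samples = _build_sample_sheet(design, cultivars, rng)
    batch_offsets = np.exp(rng.normal(0.0, cfg.batch_offset_sd,
                                      size=design.n_batches))

    # allocate planted markers over polarities proportionally to table size
    n_total = cfg.n_features_pos + cfg.n_features_neg
    n_mark_pos = int(round(cfg.n_markers * cfg.n_features_pos / n_total))
    n_mark_pos = min(n_mark_pos, cfg.n_features_pos)
    n_mark_neg = min(cfg.n_markers - n_mark_pos, cfg.n_features_neg)
    mark_pos = (np.sort(rng.choice(cfg.n_features_pos, n_mark_pos, replace=False))
                if n_mark_pos else np.array([], dtype=int))
    mark_neg = (np.sort(rng.choice(cfg.n_features_neg, n_mark_neg, replace=False))
                if n_mark_neg else np.array([], dtype=int))

    pos, drift_pos = _simulate_polarity(samples, "positive", cfg.n_features_pos,
                                        mark_pos, cfg, group_of_cultivar,
                                        batch_offsets, rng)
    neg, drift_neg = _simulate_polarity(samples, "negative", cfg.n_features_neg,
                                        mark_neg, cfg, group_of_cultivar,
                                        batch_offsets, rng)

    if cfg.missing_rate > 0:
        pos = inject_missing(pos, cfg.missing_rate, cfg.censor_strength,
                             seed=int(rng.integers(2**31)))
        neg = inject_missing(neg, cfg.missing_rate, cfg.censor_strength,
                             seed=int(rng.integers(2**31)))

    truth = SimulationTruth(
        marker_ids=(
            set(pos.feature_ids[mark_pos]) | set(neg.feature_ids[mark_neg])
        ),
        group_of_cultivar=group_of_cultivar,
        drift_curves={"positive": drift_pos, "negative": drift_neg},
        batch_offsets=batch_offsets,
    )
    return pos, neg, truth


# ---------------------------------------------------------------------------
# intensity-dependent missingness
# ---------------------------------------------------------------------------

def inject_missing(table: PeakTable, rate: float, censor_strength: float,
                   seed: int) -> PeakTable:
    """Punch missing values into a table, preferentially at low intensity.

    A cell's missingness probability is proportional to
    ``exp(-censor_strength * z)`` with ``z`` the standardized log2
    intensity, rescaled so the overall missing fraction matches ``rate``
    (within ±10% relative).  ``censor_strength = 0`` gives MCAR holes.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if table.scaled:
        raise ValueError("inject_missing expects an unscaled table")
    if rate == 0.0:
        return table
    rng = np.random.default_rng(seed)
    out = table.copy()
    vals = out.values
    observed = ~np.isnan(vals)
    z = np.zeros_like(vals)
    logv = np.log2(np.maximum(vals[observed], 1e-12))
    z_obs = (logv - logv.mean()) / (logv.std() or 1.0)
    w = np.exp(-censor_strength * z_obs)
    p = rate * w / w.mean()
    # clipping at 0.95 biases the mean down; rescale a few times to hold rate
    for _ in range(5):
        p = np.clip(p, 0.0, 0.95)
        m = p.mean()
        if m == 0:
            break
        p *= rate / m
    p = np.clip(p, 0.0, 0.95)
    holes = rng.random(p.shape) < p
    z[observed] = holes  # reuse buffer as mask staging
    vals[observed & (z > 0)] = np.nan
    return out
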