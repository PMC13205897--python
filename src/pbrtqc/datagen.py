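"""Synthetic tumor-marker result streams.

Real PBRTQC studies run on a hospital's chronological stream of patient
results.  This module generates stand-in streams with the statistical
features PBRTQC algorithms react to:

* heavy right-skewed marginals — a log-normal core calibrated to the
  analyte preset's training-set median and mean/median ratio, mixed
  with a small Pareto upper tail and clipped to the reportable range;
* covariate structure — age, sex, patient category, department and
  diagnosis shift the log-scale value, with the fraction of log-scale
  variance they explain set by ``covariate_effect_fraction`` (this is
  the signal a residual-regression monitor can exploit);
* latent subpopulations in multi-analyte panels — shared group labels
  shift the target and its companion analytes jointly, so a
  pre-classification monitor has clusters to find;
* chronological ordering with a train/validation/test split.

All randomness flows through one :class:`numpy.random.Generator`; the
same seed reproduces a stream bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .presets import AnalyteSpec

__all__ = [
    "GeneratorConfig",
    "AnalyteStream",
    "generate_stream",
    "generate_panel",
    "split_chronological",
    "write_stream_csv",
    "read_stream_csv",
    "validate_panel",
    "STREAM_COLUMNS",
]

STREAM_COLUMNS = [
    "barcode",
    "order_index",
    "analyte",
    "value",
    "age",
    "sex",
    "patient_category",
    "department",
    "diagnosis",
]

# Categorical covariate levels and their sampling frequencies.  The mix
# approximates a tertiary-hospital tumor-marker workload: mostly
# outpatients, oncology-heavy departments, a handful of coded diagnoses.
_SEX_LEVELS = ["F", "M"]
_SEX_P = [0.55, 0.45]
_CATEGORY_LEVELS = ["outpatient", "inpatient", "checkup"]
_CATEGORY_P = [0.55, 0.30, 0.15]
_DEPT_LEVELS = [
    "oncology",
    "gastroenterology",
    "respiratory",
    "surgery",
    "gynecology",
    "general",
]
_DEPT_P = [0.28, 0.18, 0.14, 0.16, 0.12, 0.12]
_DIAG_LEVELS = [f"D{i:02d}" for i in range(8)]
_DIAG_P = [0.24, 0.18, 0.15, 0.12, 0.10, 0.09, 0.07, 0.05]

# Raw (unscaled) log-value effects per covariate level; rescaled at
# generation time so the covariate block explains exactly the requested
# share of log-scale variance.
_SEX_EFF = {"F": 0.0, "M": 0.25}
_CATEGORY_EFF = {"outpatient": 0.0, "inpatient": 0.50, "checkup": -0.30}
_DEPT_EFF = {
    "oncology": 0.90,
    "gastroenterology": 0.30,
    "respiratory": 0.20,
    "surgery": 0.10,
    "gynecology": 0.0,
    "general": -0.20,
}
_DIAG_EFF = dict(zip(_DIAG_LEVELS, [1.2, 0.8, 0.6, 0.3, 0.1, 0.0, -0.2, -0.4]))
_AGE_COEF = 0.30  # per standardized-age unit

_PARETO_SHAPE = 1.5  # upper-tail mixture component


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-stream generator.

    Parameters
    ----------
    n : int
        Number of records.
    seed : int
        Seed for the stream's random generator.
    covariate_effect_fraction : float
        Share of log-scale variance explained by the covariates
        (0 = pure noise stream, 0.5 = covariates and noise contribute
        equally).
    tail_mixture_weight : float
        Fraction of records whose value is multiplied by a Pareto
        factor, producing the extreme upper tail seen in tumor-marker
        data.
    n_groups, group_separation : int, float
        Latent subpopulation structure for multi-analyte panels:
        number of groups and their spacing in units of the
        within-group log-scale SD.
    panel_log_sd : float
        Within-group log-scale SD of panel analytes.  Pre-classified
        subpopulations are far more homogeneous than the pooled
        stream, so this is well below the pooled log-scale SD.
    missing_companion_fraction : float
        Fraction of panel rows whose companion results are absent
        (exercises the likelihood-based fallback grouping).
    """

    n: int
    seed: int = 0
    covariate_effect_fraction: float = 0.5
    tail_mixture_weight: float = 0.02
    n_groups: int = 2
    group_separation: float = 6.0
    panel_log_sd: float = 0.35
    missing_companion_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not 0.0 <= self.covariate_effect_fraction < 1.0:
            raise ValueError("covariate_effect_fraction must be in [0, 1)")
        if not 0.0 <= self.tail_mixture_weight < 0.5:
            raise ValueError("tail_mixture_weight must be in [0, 0.5)")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")


@dataclass
class AnalyteStream:
    """An ordered sequence of patient results for one analyte.

    ``frame`` holds one row per result with the columns of
    :data:`STREAM_COLUMNS` (panels carry extra companion/group columns).
    """

    spec: AnalyteSpec
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.frame):
            oi = self.frame["order_index"].to_numpy()
            if not np.all(np.diff(oi) > 0):
                raise ValueError("order_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy(dtype=float)


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    age = np.clip(np.rint(rng.normal(58.0, 15.0, n)), 18, 90).astype(int)
    return pd.DataFrame(
        {
            "age": age,
            "sex": rng.choice(_SEX_LEVELS, n, p=_SEX_P),
            "patient_category": rng.choice(_CATEGORY_LEVELS, n, p=_CATEGORY_P),
            "department": rng.choice(_DEPT_LEVELS, n, p=_DEPT_P),
            "diagnosis": rng.choice(_DIAG_LEVELS, n, p=_DIAG_P),
        }
    )


def _covariate_effect(cov: pd.DataFrame) -> np.ndarray:
    """Raw (unscaled) linear log-value effect of the covariate design."""
    age_z = (cov["age"].to_numpy(dtype=float) - 58.0) / 15.0
    eff = _AGE_COEF * age_z
    eff = eff + cov["sex"].map(_SEX_EFF).to_numpy(dtype=float)
    eff = eff + cov["patient_category"].map(_CATEGORY_EFF).to_numpy(dtype=float)
    eff = eff + cov["department"].map(_DEPT_EFF).to_numpy(dtype=float)
    eff = eff + cov["diagnosis"].map(_DIAG_EFF).to_numpy(dtype=float)
    return eff


def _scaled_effect(raw: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale a raw effect vector to a prescribed variance."""
    if target_var <= 0.0 or len(raw) < 2:
        return np.zeros_like(raw)
    centered = raw - raw.mean()
    sd = centered.std()
    if sd == 0.0:
        return np.zeros_like(raw)
    return centered * (np.sqrt(target_var) / sd)


def _finalize_values(
    log_vals: np.ndarray,
    spec: AnalyteSpec,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    add_tail: bool = True,
) -> np.ndarray:
    """Tail-mix, median-calibrate, clip and round a log-value vector."""
    u = np.exp(log_vals)
    if add_tail and cfg.tail_mixture_weight > 0.0 and len(u):
        tail = rng.random(len(u)) < cfg.tail_mixture_weight
        u[tail] *= 1.0 + rng.pareto(_PARETO_SHAPE, int(tail.sum()))
    if len(u):
        u *= spec.ref_median / np.median(u)  # exact sample-median calibration
    return np.clip(np.round(u, 2), spec.range_lo, spec.range_hi)


def generate_stream(spec: AnalyteSpec, cfg: GeneratorConfig) -> AnalyteStream:
    """Generate one synthetic chronological result stream.

    Values are drawn on the log scale as covariate effect + Gaussian
    noise (variance partitioned by ``cfg.covariate_effect_fraction``,
    total log-scale SD taken from the preset's mean/median ratio),
    exponentiated, mixed with a Pareto upper tail, scaled so the sample
    median equals ``spec.ref_median`` exactly, then clipped to the
    reportable range and rounded to two decimals.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    cov = _draw_covariates(rng, n)

    sigma2 = spec.log_sigma**2
    eff = _scaled_effect(_covariate_effect(cov), cfg.covariate_effect_fraction * sigma2)
    noise_sd = np.sqrt((1.0 - cfg.covariate_effect_fraction) * sigma2)
    log_vals = eff + rng.normal(0.0, noise_sd, n)
    values = _finalize_values(log_vals, spec, cfg, rng)

    frame = pd.DataFrame(
        {
            "barcode": [f"{spec.name}{cfg.seed:04d}{i:08d}" for i in range(n)],
            "order_index": np.arange(n, dtype=int),
            "analyte": spec.name,
            "value": values,
        }
    )
    frame = pd.concat([frame, cov], axis=1)[STREAM_COLUMNS]
    return AnalyteStream(spec=spec, frame=frame)


def generate_panel(
    target: AnalyteSpec,
    companions: list[AnalyteSpec],
    cfg: GeneratorConfig,
) -> AnalyteStream:
    """Generate a multi-analyte panel keyed by barcode.

    Each row carries the target result (``value``), one column per
    companion analyte, the covariates, and a latent ``group`` label
    (kept for testing only — monitors must not read it).  All three
    analytes share the group label: group ``g`` shifts each analyte's
    log-value by ``g * group_separation * panel_log_sd``, so the
    MOM/log/IQR-mapped 3-D cloud is clusterable.  Within a group the
    target additionally carries the covariate effect (fraction
    ``covariate_effect_fraction`` of the within-group log variance).
    The heavy upper tail is sample-level: a tail row's Pareto factor
    multiplies the target AND its companions jointly, as pathological
    extremes co-elevate the markers a clinician co-orders.  A
    ``missing_companion_fraction`` share of rows has both companion
    results absent.
    """
    if len(companions) < 2:
        raise ValueError("a panel needs at least 2 companion analytes")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    cov = _draw_covariates(rng, n)
    groups = rng.integers(0, cfg.n_groups, n)
    offsets = groups.astype(float) * cfg.group_separation * cfg.panel_log_sd

    sigma2 = cfg.panel_log_sd**2
    eff = _scaled_effect(_covariate_effect(cov), cfg.covariate_effect_fraction * sigma2)
    noise_sd = np.sqrt((1.0 - cfg.covariate_effect_fraction) * sigma2)

    tail_ln = np.zeros(n)
    if cfg.tail_mixture_weight > 0.0 and n:
        tail_rows = rng.random(n) < cfg.tail_mixture_weight
        tail_ln[tail_rows] = np.log1p(rng.pareto(_PARETO_SHAPE, int(tail_rows.sum())))

    target_log = offsets + eff + rng.normal(0.0, noise_sd, n) + tail_ln
    target_vals = _finalize_values(target_log, target, cfg, rng, add_tail=False)

    frame = pd.DataFrame(
        {
            "barcode": [f"{target.name}{cfg.seed:04d}{i:08d}" for i in range(n)],
            "order_index": np.arange(n, dtype=int),
            "analyte": target.name,
            "value": target_vals,
        }
    )
    frame = pd.concat([frame, cov], axis=1)[STREAM_COLUMNS]

    missing = rng.random(n) < cfg.missing_companion_fraction
    for comp in companions:
        comp_log = offsets + rng.normal(0.0, cfg.panel_log_sd, n) + tail_ln
        comp_vals = _finalize_values(comp_log, comp, cfg, rng, add_tail=False).astype(float)
        comp_vals[missing] = np.nan
        frame[comp.name] = comp_vals
    frame["group"] = groups
    validate_panel(frame)
    return AnalyteStream(spec=target, frame=frame)


def validate_panel(frame: pd.DataFrame) -> None:
    """Reject panels with duplicate barcodes."""
    if frame["barcode"].duplicated().any():
        dupes = frame.loc[frame["barcode"].duplicated(), "barcode"].head(3).tolist()
        raise ValueError(f"duplicate barcodes in panel: {dupes} ...")


def split_chronological(
    stream: AnalyteStream,
    trainval_fraction: float = 0.8,
    train_within: float = 0.6,
) -> tuple[AnalyteStream, AnalyteStream, AnalyteStream]:
    """Chronological train/validation/test split.

    The first ``trainval_fraction`` of the stream is divided
    ``train_within`` / ``1 - train_within`` into train and validation
    (60/40 by default); the remainder is the test partition.  Ordering
    is preserved throughout.
    """
    for name, frac in (("trainval_fraction", trainval_fraction), ("train_within", train_within)):
        if not 0.0 < frac < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {frac}")
    n = len(stream)
    if n < 3:
        raise ValueError("stream too short to split (need >= 3 records)")
    n_tv = int(np.floor(n * trainval_fraction))
    n_train = int(np.floor(n_tv * train_within))
    if n_train == 0 or n_tv - n_train == 0 or n - n_tv == 0:
        raise ValueError(
            f"split fractions leave an empty partition: sizes "
            f"({n_train}, {n_tv - n_train}, {n - n_tv})"
        )
    frames = (
        stream.frame.iloc[:n_train],
        stream.frame.iloc[n_train:n_tv],
        stream.frame.iloc[n_tv:],
    )
    return tuple(
        AnalyteStream(spec=stream.spec, frame=f.reset_index(drop=True)) for f in frames
    )


def write_stream_csv(stream: AnalyteStream, path) -> None:
    """Write a stream to CSV (UTF-8, '.' decimal separator)."""
    stream.frame.to_csv(path, index=False, encoding="utf-8")


def read_stream_csv(path, spec: AnalyteSpec) -> AnalyteStream:
    """Read a stream CSV written by :func:`write_stream_csv`."""
    frame = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in STREAM_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"stream CSV missing columns: {missing}")
    return AnalyteStream(spec=spec, frame=frame)
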