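"""Evaluation harness: FAR, NPed/tANPed, paired tests, experiment driver.

Specificity is the false alarm rate (FAR): the alarm fraction on
error-free windows, averaged over replicates with equal weight.
Sensitivity is the number of patient results affected before error
detection (NPed): the count of samples from the bias onset up to and
including the first alarming sample.  Over the 10 replicates of a
condition the single largest NPed is dropped and the rest averaged
(tANPed), which blunts outlier replicates.  Undetected replicates are
censored at the post-bias window length; a condition with no
detections at all reports NOT_DETECTED.  Models are compared per
condition with a classical paired t-test on replicate NPeds sharing
an injection record (alpha = 0.05, no multiplicity correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import biasinject, datagen, nnqc, pcrtqc, spc
from .presets import get_preset, load_companions

__all__ = [
    "NOT_DETECTED",
    "PairedTestResult",
    "ExperimentConfig",
    "far",
    "nped",
    "tanped",
    "paired_test",
    "fit_models",
    "evaluate_condition",
    "run_experiment",
    "export_chart",
]


class _NotDetected:
    """Sentinel: no alarm occurred after the bias onset."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NOT_DETECTED"


NOT_DETECTED = _NotDetected()


def far(control: spc.ControlSeries) -> float:
    """Alarm fraction of an error-free monitored window."""
    if len(control.alarms) == 0:
        raise ValueError("cannot compute FAR of an empty window")
    return float(control.alarms.mean())


def nped(control: spc.ControlSeries, bias_start_index: int):
    """Patient results affected before detection, for one replicate.

    The first alarm at or after the bias onset, counted inclusively:
    an alarm on the first biased sample gives 1.  Returns
    :data:`NOT_DETECTED` when no post-onset alarm exists.
    """
    if not 0 <= bias_start_index < len(control.alarms):
        raise ValueError("bias start outside the window")
    post = np.flatnonzero(control.alarms[bias_start_index:])
    if post.size == 0:
        return NOT_DETECTED
    return int(post[0]) + 1


def tanped(npeds: list, censor: float | None = None):
    """Max-trimmed mean of replicate NPeds.

    The single largest value is dropped (one of the ties, if tied) and
    the remainder averaged.  :data:`NOT_DETECTED` entries are replaced
    by ``censor`` (the post-bias window length) before trimming; if no
    replicate detected at all, the summary itself is NOT_DETECTED.
    """
    if len(npeds) == 0:
        raise ValueError("tanped needs at least one replicate NPed")
    detected = [x for x in npeds if x is not NOT_DETECTED]
    if not detected:
        return NOT_DETECTED
    if len(detected) < len(npeds):
        if censor is None:
            raise ValueError("censor length required when some replicates are undetected")
        values = [censor if x is NOT_DETECTED else float(x) for x in npeds]
    else:
        values = [float(x) for x in npeds]
    if len(values) == 1:
        return float(values[0])
    values = sorted(values)[:-1]
    return float(np.mean(values))


@dataclass(frozen=True)
class PairedTestResult:
    """Classical paired t-test outcome (two-sided)."""

    t: float
    p: float
    degenerate: bool = False  # zero-variance differences: p undefined


def paired_test(npeds_a: list, npeds_b: list) -> PairedTestResult:
    """Paired t-test on replicate NPeds sharing injection records."""
    a = np.asarray(npeds_a, dtype=float)
    b = np.asarray(npeds_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired test needs two equal-length samples of size >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        t = 0.0 if np.allclose(d.mean(), 0.0) else float(np.sign(d.mean()) * np.inf)
        return PairedTestResult(t=t, p=float("nan"), degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedTestResult(t=float(res.statistic), p=float(res.pvalue))


# ---------------------------------------------------------------------------
# experiment orchestration


@dataclass
class ExperimentConfig:
    """Settings for one comparative experiment run."""

    analytes: tuple = ("CEA",)
    models: tuple = ("traditional", "pcrtqc", "nn")
    n: int = 20000
    seed: int = 1
    reps: int = 10
    window: int = 3000
    margin: int = 500
    multipliers: tuple = (-2, -1, 0, 1, 2)
    error_types: tuple = ("CE", "PE")
    trainval_fraction: float = 0.8
    train_within: float = 0.6
    covariate_effect_fraction: float = 0.5
    dfar: float = 0.001
    tuning_reps: int = 3
    outdir: str | None = None
    charts: bool = False


@dataclass
class FittedModels:
    """Tuned monitors for one analyte stream."""

    train: datagen.AnalyteStream
    validation: datagen.AnalyteStream
    test: datagen.AnalyteStream
    traditional: spc.GridSearchResult | None = None
    nn_model: nnqc.ResidualModel | None = None
    nn_search: spc.GridSearchResult | None = None
    pcrtqc_model: pcrtqc.PCRTQCModel | None = None
    train_residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def monitor(self, model_name: str, window_frame: pd.DataFrame) -> spc.ControlSeries:
        """Run one tuned monitor over a (possibly biased) window frame."""
        train_values = self.train.values
        if model_name == "traditional":
            return spc.run_monitor(
                window_frame["value"].to_numpy(dtype=float),
                self.traditional.params,
                train_values,
            )
        if model_name == "nn":
            return nnqc.run_nn_monitor(
                window_frame, self.nn_model, self.nn_search.params, self.train_residuals
            )
        if model_name == "pcrtqc":
            return pcrtqc.run_pcrtqc(window_frame, self.pcrtqc_model)
        raise KeyError(f"unknown model {model_name!r}")


def fit_models(
    stream: datagen.AnalyteStream, cfg: ExperimentConfig, nn_seed: int = 0
) -> FittedModels:
    """Split a stream chronologically and tune the requested monitors."""
    train, validation, test = datagen.split_chronological(
        stream, cfg.trainval_fraction, cfg.train_within
    )
    fitted = FittedModels(train=train, validation=validation, test=test)
    tune_window = min(cfg.window, len(validation))
    if "traditional" in cfg.models:
        fitted.traditional = spc.grid_search(
            train, validation, dfar=cfg.dfar, reps=cfg.tuning_reps,
            window=tune_window, margin=cfg.margin, seed=cfg.seed,
        )
    if "nn" in cfg.models:
        fitted.nn_model = nnqc.fit_residual_model(
            train, nnqc.NNConfig(seed=nn_seed)
        )
        fitted.train_residuals = nnqc.residual_stream(train.frame, fitted.nn_model)
        fitted.nn_search = nnqc.tune_nn_monitor(
            train, validation, fitted.nn_model, dfar=cfg.dfar, reps=cfg.tuning_reps,
            window=tune_window, margin=cfg.margin, seed=cfg.seed,
        )
    if "pcrtqc" in cfg.models:
        fitted.pcrtqc_model = pcrtqc.fit_pcrtqc(
            train, validation, dfar=cfg.dfar, seed=cfg.seed
        )
    return fitted


def evaluate_condition(
    fitted: FittedModels,
    model_name: str,
    bias: biasinject.BiasSpec,
    cfg: ExperimentConfig,
    seed: int,
) -> dict:
    """Evaluate one (model, error type, multiplier) condition.

    Error-free conditions (n = 0) report the mean replicate FAR;
    biased conditions report per-replicate NPeds, the trimmed mean and
    the detection count.
    """
    window = min(cfg.window, len(fitted.test))
    margin = min(cfg.margin, window // 4)
    replicates = biasinject.sample_replicates(
        fitted.test, bias, n_reps=cfg.reps, window=window, seed=seed, margin=margin
    )
    row: dict = {
        "model": model_name,
        "error_type": bias.error_type,
        "n": bias.n,
        "far_percent": np.nan,
        "tanped": np.nan,
        "detected_count": np.nan,
        "npeds": None,
    }
    if bias.n == 0:
        fars = [far(fitted.monitor(model_name, frame)) for frame, _ in replicates]
        row["far_percent"] = float(np.mean(fars)) * 100.0
        return row
    npeds, censors = [], []
    for frame, record in replicates:
        cs = fitted.monitor(model_name, frame)
        npeds.append(nped(cs, record.bias_start_index))
        censors.append(window - record.bias_start_index)
    censor = float(max(censors))
    t = tanped(npeds, censor=censor)
    row["tanped"] = np.nan if t is NOT_DETECTED else t
    row["detected_count"] = sum(x is not NOT_DETECTED for x in npeds)
    row["npeds"] = [censor if x is NOT_DETECTED else float(x) for x in npeds]
    return row


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run the full comparative experiment.

    For every analyte a synthetic panel is generated and split; the
    requested monitors are tuned on train/validation; every
    (model, error type, multiplier) condition is evaluated on
    ``cfg.reps`` injected test replicates.  Rows with n = 0 carry the
    FAR, biased rows carry tANPed, detection counts and the paired
    p-value against the traditional monitor.  With ``cfg.charts`` and
    an ``outdir``, one control chart (PNG + tidy CSV) is exported per
    condition.
    """
    presets_companions = load_companions()
    rows = []
    for analyte in cfg.analytes:
        spec = get_preset(analyte)
        companions = [get_preset(c) for c in presets_companions[analyte]]
        gen_cfg = datagen.GeneratorConfig(
            n=cfg.n, seed=cfg.seed,
            covariate_effect_fraction=cfg.covariate_effect_fraction,
        )
        panel = datagen.generate_panel(spec, companions, gen_cfg)
        fitted = fit_models(panel, cfg, nn_seed=cfg.seed)
        for etype in cfg.error_types:
            cond_rows = {}
            for n_mult in cfg.multipliers:
                bias = biasinject.BiasSpec(error_type=etype, n=n_mult)
                # one replicate-window draw per error type: multipliers are
                # applied to the same windows (paired severity comparison)
                cond_seed = (cfg.seed * 104729 + {"CE": 0, "PE": 1}[etype] * 101) % (2**31)
                for model_name in cfg.models:
                    row = evaluate_condition(fitted, model_name, bias, cfg, cond_seed)
                    row["analyte"] = analyte
                    cond_rows[(model_name, n_mult)] = row
                    if cfg.charts and cfg.outdir:
                        _export_condition_chart(fitted, model_name, bias, cfg, cond_seed)
            for (model_name, n_mult), row in cond_rows.items():
                base = cond_rows.get(("traditional", n_mult))
                if (
                    model_name != "traditional"
                    and base is not None
                    and row["npeds"] is not None
                ):
                    res = paired_test(row["npeds"], base["npeds"])
                    row["p_vs_traditional"] = res.p
                else:
                    row["p_vs_traditional"] = np.nan
                rows.append(row)
    table = pd.DataFrame(rows).drop(columns="npeds")
    cols = [
        "analyte", "model", "error_type", "n",
        "far_percent", "tanped", "detected_count", "p_vs_traditional",
    ]
    table = table[cols]
    if cfg.outdir:
        import pathlib

        out = pathlib.Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results.csv", index=False)
    return table


def export_chart(
    control: spc.ControlSeries, bias_start: int | None, path_png, path_csv=None
) -> None:
    """Save one control chart as PNG (and optionally a tidy CSV)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(control.statistic, lw=0.6, color="steelblue")
    ax.axhline(control.lower, color="red", lw=1.0)
    ax.axhline(control.upper, color="red", lw=1.0)
    if bias_start is not None:
        ax.axvline(bias_start, color="gray", ls="--", lw=0.8)
    if control.alarms.any():
        idx = np.flatnonzero(control.alarms)
        ax.plot(idx, control.statistic[idx], ".", color="red", ms=3)
    ax.set_xlabel("sample")
    ax.set_ylabel("monitored statistic")
    fig.tight_layout()
    fig.savefig(path_png, dpi=120)
    plt.close(fig)
    if path_csv is not None:
        pd.DataFrame(
            {
                "statistic": control.statistic,
                "lower": control.lower,
                "upper": control.upper,
                "alarm": control.alarms,
            }
        ).to_csv(path_csv, index=False)


def _export_condition_chart(fitted, model_name, bias, cfg, seed) -> None:
    import pathlib

    window = min(cfg.window, len(fitted.test))
    margin = min(cfg.margin, window // 4)
    frame, record = biasinject.sample_replicates(
        fitted.test, bias, n_reps=1, window=window, seed=seed, margin=margin
    )[0]
    cs = fitted.monitor(model_name, frame)
    out = pathlib.Path(cfg.outdir) / "charts"
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{fitted.train.spec.name}_{model_name}_{bias.error_type}_{bias.n:+d}"
    export_chart(
        cs,
        record.bias_start_index if bias.n != 0 else None,
        out / f"{stem}.png",
        out / f"{stem}.csv",
    )
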