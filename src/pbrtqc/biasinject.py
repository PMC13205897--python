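"""Systematic-error simulation: CE/PE injection, clipping, replicate sampling.

Two step-change error types are simulated on a test-partition window:

* constant error (CE): ``x' = x + n * TEa * median`` — an additive
  shift sized by the total allowable error and the training-set median
  (the median, not the mean, because the marginals are heavily skewed);
* proportional error (PE): ``x' = x * (1 + n * TEa)`` — a
  multiplicative shift.

``n`` runs over {-2, -1, 0, +1, +2}: |1| is the clinically tolerated
threshold, |2| a gross malfunction, 0 the error-free control.  Biased
values are clipped back into the analyte's reportable range.  Every
replicate is fully traceable through an :class:`InjectionRecord` and
can be replayed bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datagen import AnalyteStream
from .presets import AnalyteSpec

__all__ = [
    "MULTIPLIERS",
    "BiasSpec",
    "InjectionRecord",
    "inject_ce",
    "inject_pe",
    "clip_to_range",
    "apply_bias",
    "sample_replicates",
    "replay",
]

MULTIPLIERS = (-2, -1, 0, 1, 2)


@dataclass(frozen=True)
class BiasSpec:
    """One error condition: type (CE/PE) and multiplier n."""

    error_type: str  # "CE" or "PE"
    n: int

    def __post_init__(self) -> None:
        if self.error_type not in ("CE", "PE"):
            raise ValueError(f"error_type must be 'CE' or 'PE', got {self.error_type!r}")
        if self.n not in MULTIPLIERS:
            raise ValueError(f"multiplier n must be one of {MULTIPLIERS}, got {self.n}")


@dataclass(frozen=True)
class InjectionRecord:
    """Traceability record for one injected replicate.

    Stores everything needed to reproduce the biased window from the
    un-biased test partition: where the window starts, the error type
    and magnitude, where within the window the bias begins, and the
    barcodes of the affected samples.
    """

    replicate_id: int
    sampling_start: int  # index into the test partition
    error_type: str
    n: int
    bias_start_index: int  # index within the window
    window: int = 3000
    affected_barcodes: tuple = field(default_factory=tuple)
    seed: int = 0


def inject_ce(x, n: int, tea: float, ref_median: float):
    """Constant (additive) error: x + n * TEa * median, before clipping."""
    return x + n * tea * ref_median


def inject_pe(x, n: int, tea: float):
    """Proportional (multiplicative) error: x * (1 + n * TEa), before clipping."""
    return x * (1.0 + n * tea)


def clip_to_range(x, spec: AnalyteSpec):
    """Clip a value (or array) into the analyte's reportable range."""
    return np.clip(x, spec.range_lo, spec.range_hi)


def apply_bias(
    values: np.ndarray, bias: BiasSpec, spec: AnalyteSpec, bias_start: int
) -> np.ndarray:
    """Apply a step bias from ``bias_start`` onward, then clip.

    Samples before ``bias_start`` are untouched; samples at and after
    it are transformed by the chosen error equation and clipped to the
    reportable range.  ``n == 0`` returns an unmodified copy.
    """
    out = np.asarray(values, dtype=float).copy()
    if bias.n == 0:
        return out
    post = out[bias_start:]
    if bias.error_type == "CE":
        post = inject_ce(post, bias.n, spec.tea, spec.ref_median)
    else:
        post = inject_pe(post, bias.n, spec.tea)
    out[bias_start:] = clip_to_range(post, spec)
    return out


def sample_replicates(
    test_partition: AnalyteStream,
    bias: BiasSpec,
    n_reps: int = 10,
    window: int = 3000,
    seed: int = 0,
    margin: int = 500,
) -> list[tuple[pd.DataFrame, InjectionRecord]]:
    """Draw independent replicate windows and inject the bias.

    Each replicate is ``window`` consecutive test-partition records
    starting at an independently drawn random position (windows may
    overlap).  Within each window a bias start is drawn uniformly so
    that at least ``margin`` samples remain on either side — every
    replicate then yields both a false-alarm-bearing prefix and a
    measurable detection delay.  Returns ``(biased_window_frame,
    record)`` pairs; the frame's ``value`` column carries the biased
    values, all other columns are untouched.
    """
    n = len(test_partition)
    if n < window:
        raise ValueError(f"test partition ({n}) shorter than window ({window})")
    if window < 2 * margin:
        raise ValueError(f"window ({window}) must be >= 2 * margin ({margin})")
    spec = test_partition.spec
    out = []
    for rep, child in enumerate(np.random.SeedSequence(seed).spawn(n_reps)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(rep_seed)
        start = int(rng.integers(0, n - window + 1))
        bias_start = int(rng.integers(margin, window - margin + 1))
        frame = test_partition.frame.iloc[start : start + window].reset_index(drop=True)
        biased = apply_bias(frame["value"].to_numpy(dtype=float), bias, spec, bias_start)
        frame = frame.assign(value=biased)
        affected = ()
        if bias.n != 0:
            affected = tuple(frame["barcode"].iloc[bias_start:].tolist())
        record = InjectionRecord(
            replicate_id=rep,
            sampling_start=start,
            error_type=bias.error_type,
            n=bias.n,
            bias_start_index=bias_start,
            window=window,
            affected_barcodes=affected,
            seed=rep_seed,
        )
        out.append((frame, record))
    return out


def replay(test_partition: AnalyteStream, record: InjectionRecord) -> pd.DataFrame:
    """Reconstruct a biased replicate window from its traceability record."""
    spec = test_partition.spec
    start = record.sampling_start
    frame = test_partition.frame.iloc[start : start + record.window].reset_index(drop=True)
    bias = BiasSpec(error_type=record.error_type, n=record.n)
    biased = apply_bias(
        frame["value"].to_numpy(dtype=float), bias, spec, record.bias_start_index
    )
    return frame.assign(value=biased)
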