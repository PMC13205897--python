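"""Analyte presets: units, reportable ranges, error budgets, distribution targets.

Presets for the six serum tumor markers (CEA, AFP, CA19-9, CA125,
CYFRA21-1, PROGRP) ship with the package as a YAML file.  Each preset
records the analyzer's reportable fluctuation range, the total allowable
error (TEa, 25% for all six markers), the training-set median used to
size constant errors and calibrate the synthetic generator, and the
marginal-distribution summaries (mean, median, SD, skewness, kurtosis)
the generator emulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = ["AnalyteSpec", "load_presets", "load_companions", "get_preset"]


@dataclass(frozen=True)
class AnalyteSpec:
    """Per-analyte constants for generation, bias injection and monitoring.

    Parameters
    ----------
    name : str
        Analyte label, e.g. ``"CEA"``.
    unit : str
        Reporting unit, e.g. ``"ng/mL"``.
    range_lo, range_hi : float
        Reportable fluctuation range; all values (raw and biased) are
        clipped into ``[range_lo, range_hi]``.
    tea : float
        Total allowable error as a fraction (0.25 means 25%).
    ref_median : float
        Training-set median in analyte units.  Anchors the additive
        constant-error formula and the generator's median calibration.
    dist_targets : dict
        ``{"train": (mean, median, sd, skewness, kurtosis), "test": ...}``.
    """

    name: str
    unit: str
    range_lo: float
    range_hi: float
    tea: float
    ref_median: float
    dist_targets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.range_lo < self.range_hi:
            raise ValueError(
                f"{self.name}: range_lo ({self.range_lo}) must be < range_hi ({self.range_hi})"
            )
        if not 0.0 < self.tea < 1.0:
            raise ValueError(f"{self.name}: tea must be in (0, 1), got {self.tea}")
        if not self.range_lo <= self.ref_median <= self.range_hi:
            raise ValueError(
                f"{self.name}: ref_median {self.ref_median} outside "
                f"[{self.range_lo}, {self.range_hi}]"
            )

    @property
    def log_sigma(self) -> float:
        """Log-scale spread implied by the training mean/median ratio.

        For a log-normal law mean/median = exp(sigma^2 / 2), so
        sigma = sqrt(2 ln(mean/median)).  Used as the generator's total
        log-scale standard deviation.
        """
        mean, median = self.dist_targets["train"][0], self.dist_targets["train"][1]
        return math.sqrt(2.0 * math.log(mean / median))


def _read_yaml() -> dict:
    text = resources.files("pbrtqc").joinpath("presets.yaml").read_text(encoding="utf-8")
    return yaml.safe_load(text)


def load_presets() -> dict[str, AnalyteSpec]:
    """Load all shipped analyte presets, keyed by analyte name."""
    raw = _read_yaml()
    specs: dict[str, AnalyteSpec] = {}
    for name, cfg in raw["analytes"].items():
        specs[name] = AnalyteSpec(
            name=name,
            unit=cfg["unit"],
            range_lo=float(cfg["range_lo"]),
            range_hi=float(cfg["range_hi"]),
            tea=float(cfg["tea"]),
            ref_median=float(cfg["ref_median"]),
            dist_targets={k: tuple(v) for k, v in cfg["dist_targets"].items()},
        )
    return specs


def load_companions() -> dict[str, list[str]]:
    """Companion-analyte map: target -> two most co-ordered markers."""
    return {k: list(v) for k, v in _read_yaml()["companions"].items()}


def get_preset(name: str) -> AnalyteSpec:
    """Return one shipped preset by analyte name (case-sensitive)."""
    presets = load_presets()
    try:
        return presets[name]
    except KeyError:
        raise KeyError(f"unknown analyte {name!r}; known: {sorted(presets)}") from None
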