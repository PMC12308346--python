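"""Configuration objects for the synthetic bioassay generator.

A :class:`SyntheticConfig` fully determines one experimental series: the
treatment arms (molar concentrations of the deuterated pheromone added to
each bucket, plus an optional vehicle control), the between-male baseline
release-rate distribution, the treatment response model, and every noise
source the measurement chain introduces.  Identical config + seed yields a
bit-identical simulated experiment.

The three presets :func:`series_1`, :func:`series_2` and :func:`series_3`
reproduce the geometry of the three experimental series the pipeline is
designed around (concentration ladders 5e-7..5e-13 M, 5e-12..5e-14 M and
5e-12..5e-16 M plus vehicle controls).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

from .errors import ConfigError

#: Treatments at or above this molarity elicit the full intercept response
#: by default (5e-13 M is the lowest concentration with a detected response).
DEFAULT_RESPONSE_THRESHOLD_M = 5e-13


@dataclass(frozen=True)
class TreatmentArm:
    """One treatment group: molar concentration (0.0 = vehicle control) and size."""

    molar: float
    n: int

    @property
    def label(self) -> str:
        return "C" if self.molar == 0.0 else f"{self.molar:.0e}"


@dataclass
class SyntheticConfig:
    """All parameters of one simulated static-water exposure series.

    Baseline release rates are lognormal across males:
    log10(rate / mg h^-1) ~ N(baseline_log10_mean, baseline_log10_sd).
    The response model on the natural-log scale is

        ln(fold-change) = alpha(treatment) + beta * (ln x - mu_ln) + eps,

    with alpha = ``response_intercept_alpha`` for arms at or above
    ``response_threshold`` and 0 otherwise (controls and sub-threshold arms
    have expected fold-change 1), ``mu_ln`` the population mean log
    baseline, and eps ~ N(0, response_noise_sd).
    """

    series_label: str = "S1"
    treatments: Sequence[TreatmentArm] = field(default_factory=list)
    baseline_log10_mean: float = -2.0
    baseline_log10_sd: float = 0.5
    response_intercept_alpha: float = math.log(2.5)
    response_slope_beta: float = -0.3
    response_threshold: float = DEFAULT_RESPONSE_THRESHOLD_M
    response_noise_sd: float = 0.25
    measurement_cv: float = 0.05
    background_conc_mean: float = 0.006
    background_conc_sd: float = 0.004
    is_failure_prob: float = 0.02
    low_releaser_prob: float = 0.0
    volume_l: float = 3.0
    baseline_duration_min: float = 30.0
    post_duration_min: float = 10.0
    sample_volume_ml: float = 50.0
    treatment_volume_ml: float = 1.0
    volume_correction: bool = True
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if not self.treatments:
            raise ConfigError("treatments: at least one treatment arm is required")
        for arm in self.treatments:
            if arm.n < 1:
                raise ConfigError(f"treatments: group size must be >= 1 (got n={arm.n} for {arm.label})")
            if arm.molar < 0:
                raise ConfigError(f"treatments: molar concentration must be >= 0 (got {arm.molar})")
        for name in ("baseline_log10_sd", "response_noise_sd", "measurement_cv",
                     "background_conc_mean", "background_conc_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0 (got {getattr(self, name)})")
        for name in ("is_failure_prob", "low_releaser_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}: must lie in [0, 1] (got {p})")
        for name in ("volume_l", "baseline_duration_min", "post_duration_min"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be > 0 (got {getattr(self, name)})")
        if self.sample_volume_ml < 0 or self.sample_volume_ml >= self.volume_l * 1000.0:
            raise ConfigError(f"sample_volume_ml: must lie in [0, volume) (got {self.sample_volume_ml})")
        if self.treatment_volume_ml < 0:
            raise ConfigError(f"treatment_volume_ml: must be >= 0 (got {self.treatment_volume_ml})")
        if self.response_threshold < 0:
            raise ConfigError(f"response_threshold: must be >= 0 (got {self.response_threshold})")
        return self

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["treatments"] = [{"molar": a.molar, "n": a.n} for a in self.treatments]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticConfig":
        known = {f for f in cls.__dataclass_fields__}  # noqa: C401
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        arms = data.pop("treatments", [])
        parsed = []
        for a in arms:
            extra = set(a) - {"molar", "n"}
            if extra:
                raise ConfigError(f"treatments: unknown keys {sorted(extra)}")
            parsed.append(TreatmentArm(molar=float(a["molar"]), n=int(a["n"])))
        return cls(treatments=parsed, **data).validate()

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping at top level")
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _ladder(high: float, low: float) -> list[float]:
    """Concentrations from `high` down to `low` in factor-10 steps."""
    out, c = [], high
    while c > low * 1.0000001:
        out.append(c)
        c /= 10.0
    out.append(low)
    return out


def series_1(n_per_arm: int = 12, seed: int = 0, **overrides) -> SyntheticConfig:
    """Series 1: vehicle control plus 5e-7 .. 5e-13 M; deionized water (no background)."""
    arms = [TreatmentArm(0.0, n_per_arm)] + [TreatmentArm(c, n_per_arm) for c in _ladder(5e-7, 5e-13)]
    cfg = SyntheticConfig(series_label="S1", treatments=arms, seed=seed,
                          background_conc_mean=0.0, background_conc_sd=0.0)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg.validate()


def series_2(n_per_arm: int = 12, seed: int = 0, **overrides) -> SyntheticConfig:
    """Series 2: vehicle control plus 5e-12 .. 5e-14 M; lake water background."""
    arms = [TreatmentArm(0.0, n_per_arm)] + [TreatmentArm(c, n_per_arm) for c in _ladder(5e-12, 5e-14)]
    cfg = SyntheticConfig(series_label="S2", treatments=arms, seed=seed)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg.validate()


def series_3(n_per_arm: int = 13, seed: int = 0, **overrides) -> SyntheticConfig:
    """Series 3: vehicle control plus 5e-12 .. 5e-16 M; many near-zero releasers.

    ``low_releaser_prob`` defaults to 0.3 here to emulate the large fraction of
    immature males whose release rates fall below the water threshold, which in
    turn collapses the control group below a usable size and triggers the
    baseline-substitution analysis cascade downstream.
    """
    arms = [TreatmentArm(0.0, n_per_arm)] + [TreatmentArm(c, n_per_arm) for c in _ladder(5e-12, 5e-16)]
    cfg = SyntheticConfig(series_label="S3", treatments=arms, seed=seed,
                          low_releaser_prob=0.3)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg.validate()
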