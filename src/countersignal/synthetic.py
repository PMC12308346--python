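"""Simulated static-water pheromone exposure experiments.

Each simulated male sits in a bucket of still water; pheromone released
through the gills accumulates for a 30 min baseline window, a 50 ml water
sample is withdrawn, 1 ml of treatment solution (isotope-labelled pheromone
or vehicle) is added, and a second sample is taken 10 min later.  Measured
concentrations therefore reflect the male's release rate, the volume
bookkeeping of the sampling manipulations, dissolved background pheromone in
the source water, and multiplicative measurement error of the mass-spec
quantification.  The internal quantification standard occasionally fails to
be detected, which invalidates that sample.

The generator emits two tables: the *observable* water-sample table (the only
thing the analysis stages may read) and a *hidden truth* table holding each
male's true baseline release rate and fold-change, used solely to validate
parameter recovery.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import SyntheticConfig, TreatmentArm

#: log10 shift applied to the baseline rate of a "low releaser" (immature male).
LOW_RELEASER_LOG10_SHIFT = -2.5

SAMPLE_COLUMNS = [
    "male_id", "series", "treatment_molar", "timepoint",
    "conc_ng_per_ml", "is_detected", "volume_l", "duration_min",
]

TRUTH_COLUMNS = ["male_id", "series", "treatment_molar",
                 "true_baseline_mg_per_h", "true_fold_change"]


def _series_key(label: str) -> int:
    # stable small integer derived from the label bytes (not hash(): PYTHONHASHSEED)
    return sum((i + 1) * b for i, b in enumerate(label.encode())) % (2**20)


def _male_rng(cfg: SyntheticConfig, arm_index: int, male_index: int) -> np.random.Generator:
    """Counter-based substream: one generator per male.

    Keyed by (seed, series, arm, male) so changing one arm's group size
    never reshuffles the draws of any other male.
    """
    ss = np.random.SeedSequence(entropy=cfg.seed,
                                spawn_key=(_series_key(cfg.series_label), arm_index, male_index))
    return np.random.default_rng(ss)


def _unit_mean_lognormal(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative error with mean exactly 1 and relative sd `cv`."""
    z = rng.standard_normal()
    if cv == 0.0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return math.exp(sigma * z - 0.5 * sigma * sigma)


def simulate_experiment(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one series; return (water_samples, hidden_truth).

    The water-sample table has two rows per male (baseline, post).  Post
    concentrations carry over the baseline-accumulated mass after the 50 ml
    sample withdrawal and 1 ml treatment addition (the added treatment is
    isotope-labelled, so it does not contribute to the measured natural
    analyte), plus mass released during the 10 min post window at
    baseline_rate x fold_change.
    """
    config.validate()
    mu_ln = config.baseline_log10_mean * math.log(10.0)

    v_base_ml = config.volume_l * 1000.0
    if config.volume_correction:
        removed = config.sample_volume_ml
        v_post_ml = v_base_ml - removed + config.treatment_volume_ml
    else:
        removed = 0.0
        v_post_ml = v_base_ml

    sample_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    for ai, arm in enumerate(config.treatments):
        for mi in range(arm.n):
            rng = _male_rng(config, ai, mi)
            # fixed draw order so toggling one noise source leaves others unchanged
            z_base = rng.standard_normal()
            u_low = rng.uniform()
            z_fold = rng.standard_normal()
            z_bg = rng.standard_normal()
            err_base = _unit_mean_lognormal(rng, config.measurement_cv)
            err_post = _unit_mean_lognormal(rng, config.measurement_cv)
            u_det_base = rng.uniform()
            u_det_post = rng.uniform()

            log10_x = config.baseline_log10_mean + config.baseline_log10_sd * z_base
            if u_low < config.low_releaser_prob:
                log10_x += LOW_RELEASER_LOG10_SHIFT
            x = 10.0 ** log10_x  # true baseline release rate, mg/h

            responds = arm.molar > 0.0 and arm.molar >= config.response_threshold * (1 - 1e-12)
            alpha = config.response_intercept_alpha if responds else 0.0
            ln_fold = alpha + config.response_slope_beta * (math.log(x) - mu_ln)
            ln_fold += config.response_noise_sd * z_fold
            fold = math.exp(ln_fold)

            background = max(config.background_conc_mean + config.background_conc_sd * z_bg, 0.0)

            mass_base_ng = x * (config.baseline_duration_min / 60.0) * 1e6
            conc_base_true = mass_base_ng / v_base_ml + background
            mass_post_ng = x * fold * (config.post_duration_min / 60.0) * 1e6
            conc_post_true = (conc_base_true * (v_base_ml - removed) + mass_post_ng) / v_post_ml

            male_id = f"{config.series_label}_{arm.label}_{mi:02d}"
            det_base = int(u_det_base >= config.is_failure_prob)
            det_post = int(u_det_post >= config.is_failure_prob)
            sample_rows.append((male_id, config.series_label, arm.molar, "baseline",
                                conc_base_true * err_base, det_base,
                                v_base_ml / 1000.0, config.baseline_duration_min))
            sample_rows.append((male_id, config.series_label, arm.molar, "post",
                                conc_post_true * err_post, det_post,
                                v_post_ml / 1000.0, config.post_duration_min))
            truth_rows.append((male_id, config.series_label, arm.molar, x, fold))

    samples = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return samples, truth


# ---------------------------------------------------------------------------
# deterministic QC fixture
# ---------------------------------------------------------------------------

#: expected fate of each fixture male under the full filter chain
QC_FIXTURE_EXPECTED = {
    "QC_M01": "none", "QC_M02": "none", "QC_M03": "none",
    "QC_M04": "none", "QC_M05": "none", "QC_M06": "none",
    "QC_M07": "is_not_detected", "QC_M08": "is_not_detected",
    "QC_M09": "no_increase", "QC_M10": "no_increase",
    "QC_M11": "below_water_threshold", "QC_M12": "below_water_threshold",
}


def make_qc_fixture() -> pd.DataFrame:
    """Deterministic 12-male table exercising every exclusion rule.

    By construction: M01-M06 are clean; M07/M08 have an undetected internal
    standard (baseline and post sample respectively); M09/M10 show no
    concentration increase between timepoints; M11/M12 release but stay below
    the lake-water release-rate threshold at both timepoints.  Disabling the
    threshold filter therefore yields 8 survivors instead of 6.
    """
    v_base, v_post = 3.0, 2.951  # litres: 50 ml sampled, 1 ml treatment added
    rows = []

    def male(mid, cb, cp, det_b=1, det_p=1):
        rows.append((mid, "QC", 5e-9, "baseline", cb, det_b, v_base, 30.0))
        rows.append((mid, "QC", 5e-9, "post", cp, det_p, v_post, 10.0))

    # clean males: healthy baselines and a clear mass increase after exposure
    male("QC_M01", 0.50, 0.80)
    male("QC_M02", 0.90, 1.30)
    male("QC_M03", 0.30, 0.55)
    male("QC_M04", 1.20, 1.80)
    male("QC_M05", 0.70, 0.95)
    male("QC_M06", 0.45, 0.60)
    # internal standard failures (otherwise clean)
    male("QC_M07", 0.60, 0.90, det_b=0)
    male("QC_M08", 0.55, 0.85, det_p=0)
    # no mass increase: post mass <= baseline mass remaining after sampling
    male("QC_M09", 0.50, 0.45)
    male("QC_M10", 0.80, 0.70)
    # below-threshold releasers: both rates under 0.00025 mg/h but increasing
    male("QC_M11", 0.020, 0.0268)
    male("QC_M12", 0.030, 0.0368)

    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def pooled_responders(n: int, seed: int, *,
                      alpha: float | None = None,
                      beta: float | None = None,
                      noise_sd: float | None = None,
                      baseline_log10_mean: float = -2.0,
                      baseline_log10_sd: float = 0.5,
                      measurement_cv: float = 0.05) -> SyntheticConfig:
    """Config for a single pooled arm of n responding males.

    Convenience for simulations of the baseline-coupling analysis, which
    pools males from all treatments with a detected response.
    """
    cfg = SyntheticConfig(
        series_label="POOL",
        treatments=[TreatmentArm(5e-9, n)],
        baseline_log10_mean=baseline_log10_mean,
        baseline_log10_sd=baseline_log10_sd,
        measurement_cv=measurement_cv,
        background_conc_mean=0.0,
        background_conc_sd=0.0,
        is_failure_prob=0.0,
        seed=seed,
    )
    if alpha is not None:
        cfg.response_intercept_alpha = alpha
    if beta is not None:
        cfg.response_slope_beta = beta
    if noise_sd is not None:
        cfg.response_noise_sd = noise_sd
    return cfg.validate()
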