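"""Release-rate quantification and record-level quality control.

Concentrations measured in bucket water (ng/ml) are converted to pheromone
release rates (mg/h) by mass balance: baseline rate from the mass accumulated
over the 30 min baseline window, post-exposure rate from the incremental mass
between the two samples over the 10 min post window, with optional volume
bookkeeping for the 50 ml sample withdrawal and 1 ml treatment addition.

QC rules mirror the field protocol: a record is discarded when the internal
standard was not detected, when the analyte concentration did not increase
between timepoints (male not observed to release), when samples were lost, or
when the male did not release more than the maximum release rate calculated
for unconditioned lake water (0.00025 mg/h).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import DataError, DomainError

NG_PER_MG = 1e6
ML_PER_L = 1e3
MIN_PER_H = 60.0

EXCLUSION_REASONS = ("sample_lost", "is_not_detected", "no_increase",
                     "below_water_threshold", "none")


@dataclass(frozen=True)
class AssayConstants:
    """Physical and protocol constants of the static-water assay."""

    water_threshold_mg_per_h: float = 0.00025   # max release rate of unconditioned lake water
    background_conc_ng_per_ml: float = 0.006    # mean lake-water analyte background
    internal_standard_conc_ng_per_ml: float = 0.1
    molar_mass_3kpzs_g_per_mol: float = 472.64        # free acid
    molar_mass_3kpzs_na_g_per_mol: float = 494.62     # sodium salt

    def __post_init__(self):
        for f in ("water_threshold_mg_per_h", "background_conc_ng_per_ml",
                  "internal_standard_conc_ng_per_ml", "molar_mass_3kpzs_g_per_mol",
                  "molar_mass_3kpzs_na_g_per_mol"):
            if getattr(self, f) <= 0:
                raise DomainError(f"{f} must be > 0")


DEFAULT_CONSTANTS = AssayConstants()


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def release_rate(conc_ng_per_ml: float, volume_l: float, duration_min: float) -> float:
    """Release rate (mg/h) from a concentration accumulated over `duration_min`.

    rate = conc * volume[ml] * (60/duration) * 1e-6 mg/ng
    """
    if volume_l <= 0:
        raise DomainError(f"volume_l must be > 0 (got {volume_l})")
    if duration_min <= 0:
        raise DomainError(f"duration_min must be > 0 (got {duration_min})")
    if conc_ng_per_ml < 0:
        raise DomainError(f"conc_ng_per_ml must be >= 0 (got {conc_ng_per_ml})")
    return conc_ng_per_ml * (volume_l * ML_PER_L) * (MIN_PER_H / duration_min) / NG_PER_MG


class PostExposureRate(NamedTuple):
    """Incremental post-exposure release rate plus the mass-increase flag."""

    rate_mg_per_h: float
    increased: bool


def post_exposure_rate(conc_baseline: float, conc_post: float,
                       volume_baseline_l: float, volume_post_l: float,
                       post_duration_min: float,
                       sample_volume_ml: float = 50.0) -> PostExposureRate:
    """Post-exposure release rate from the mass increment between samples.

    The analyte mass present at the post sample is compared with the baseline
    mass remaining after `sample_volume_ml` was withdrawn; the increment over
    `post_duration_min` gives the post-window release rate.  When the mass did
    not increase the male was not observed to release during the post window
    and the record is flagged for exclusion rather than assigned a negative
    rate.
    """
    if volume_baseline_l <= 0 or volume_post_l <= 0:
        raise DomainError("volumes must be > 0")
    if post_duration_min <= 0:
        raise DomainError("post_duration_min must be > 0")
    if conc_baseline < 0 or conc_post < 0:
        raise DomainError("concentrations must be >= 0")
    remaining_ml = volume_baseline_l * ML_PER_L - sample_volume_ml
    if remaining_ml < 0:
        raise DomainError("sample_volume_ml exceeds baseline volume")
    increment_ng = conc_post * volume_post_l * ML_PER_L - conc_baseline * remaining_ml
    rate = increment_ng * (MIN_PER_H / post_duration_min) / NG_PER_MG
    return PostExposureRate(rate, increment_ng > 0.0)


def rate_from_molarity(molarity: float, duration_s: float, volume_l: float,
                       molar_mass_g_per_mol: float) -> float:
    """Mass release rate (ng/s) that accumulates to `molarity` in `duration_s`."""
    _require_positive(molarity=molarity, duration_s=duration_s, volume_l=volume_l,
                      molar_mass_g_per_mol=molar_mass_g_per_mol)
    return molarity * volume_l * molar_mass_g_per_mol * 1e9 / duration_s


def molarity_from_rate(rate_ng_per_s: float, duration_s: float, volume_l: float,
                       molar_mass_g_per_mol: float) -> float:
    """Molar concentration reached by releasing at `rate_ng_per_s` for `duration_s`."""
    _require_positive(rate_ng_per_s=rate_ng_per_s, duration_s=duration_s,
                      volume_l=volume_l, molar_mass_g_per_mol=molar_mass_g_per_mol)
    return rate_ng_per_s * duration_s * 1e-9 / (volume_l * molar_mass_g_per_mol)


def mass_for_molarity(molarity: float, volume_l: float, molar_mass_g_per_mol: float) -> float:
    """Mass (ng) of compound needed to reach `molarity` in `volume_l` litres."""
    _require_positive(molarity=molarity, volume_l=volume_l,
                      molar_mass_g_per_mol=molar_mass_g_per_mol)
    return molarity * volume_l * molar_mass_g_per_mol * 1e9


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise DomainError(f"{name} must be > 0 (got {value})")


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

RECORD_COLUMNS = ["male_id", "series", "treatment_molar",
                  "baseline_rate_mg_per_h", "post_rate_mg_per_h", "fold_change",
                  "qc_status", "exclusion_reason"]


@dataclass
class QcAudit:
    """Per-series exclusion accounting plus one line per excluded male."""

    counts: pd.DataFrame = field(default_factory=pd.DataFrame)  # series x reason
    lines: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        out = ["QC audit", "========"]
        if not self.counts.empty:
            out.append(self.counts.to_string())
        out.extend(self.lines)
        return "\n".join(out) + "\n"


def apply_qc_filters(samples: pd.DataFrame,
                     constants: AssayConstants = DEFAULT_CONSTANTS,
                     *,
                     sample_volume_ml: float = 50.0,
                     subtract_background: bool = False,
                     threshold_on: str = "either") -> tuple[pd.DataFrame, QcAudit]:
    """Convert paired water samples to per-male records and apply exclusions.

    Filter order (fixed so audit counts are deterministic):
    missing pair (sample_lost) -> internal standard not detected ->
    no concentration increase -> below the lake-water release threshold.
    ``threshold_on='either'`` excludes a male only when *neither* the baseline
    nor the post rate exceeds the threshold; ``'baseline'`` tests baseline only.

    Returns the record table (one row per input male, included or excluded
    with exactly one reason) and the audit log.
    """
    if threshold_on not in ("either", "baseline"):
        raise DomainError(f"threshold_on must be 'either' or 'baseline' (got {threshold_on!r})")
    if samples.empty:
        return pd.DataFrame(columns=RECORD_COLUMNS), QcAudit()
    dup = samples.duplicated(subset=["male_id", "timepoint"])
    if dup.any():
        bad = samples.loc[dup, "male_id"].unique()
        raise DataError(f"duplicated (male_id, timepoint) rows for males: {list(bad)}")

    records: list[dict] = []
    audit_lines: list[str] = []
    # preserve first-appearance order of males
    order = samples["male_id"].drop_duplicates().tolist()
    grouped = dict(list(samples.groupby("male_id", sort=False)))
    for male_id in order:
        g = grouped[male_id]
        series = g["series"].iloc[0]
        molar = g["treatment_molar"].iloc[0]
        rec = {"male_id": male_id, "series": series, "treatment_molar": molar,
               "baseline_rate_mg_per_h": np.nan, "post_rate_mg_per_h": np.nan,
               "fold_change": np.nan, "qc_status": "excluded", "exclusion_reason": "none"}

        base = g[g["timepoint"] == "baseline"]
        post = g[g["timepoint"] == "post"]
        if len(base) != 1 or len(post) != 1:
            rec["exclusion_reason"] = "sample_lost"
            audit_lines.append(f"{male_id}\tsample_lost\ttimepoints={sorted(g['timepoint'])}")
            records.append(rec)
            continue
        base, post = base.iloc[0], post.iloc[0]

        conc_b = base["conc_ng_per_ml"]
        conc_p = post["conc_ng_per_ml"]
        if subtract_background:
            conc_b = max(conc_b - constants.background_conc_ng_per_ml, 0.0)
            conc_p = max(conc_p - constants.background_conc_ng_per_ml, 0.0)

        x = release_rate(conc_b, base["volume_l"], base["duration_min"])
        y, increased = post_exposure_rate(conc_b, conc_p, base["volume_l"],
                                          post["volume_l"], post["duration_min"],
                                          sample_volume_ml=sample_volume_ml)
        rec["baseline_rate_mg_per_h"] = x
        rec["post_rate_mg_per_h"] = y if increased else np.nan

        if not (base["is_detected"] and post["is_detected"]):
            rec["exclusion_reason"] = "is_not_detected"
            audit_lines.append(f"{male_id}\tis_not_detected\t"
                               f"detected=(baseline={int(base['is_detected'])},post={int(post['is_detected'])})")
        elif not increased:
            rec["exclusion_reason"] = "no_increase"
            audit_lines.append(f"{male_id}\tno_increase\tconc=({conc_b:.6g},{conc_p:.6g})")
        else:
            thr = constants.water_threshold_mg_per_h
            released = (max(x, y) > thr) if threshold_on == "either" else (x > thr)
            if not released:
                rec["exclusion_reason"] = "below_water_threshold"
                audit_lines.append(f"{male_id}\tbelow_water_threshold\trates=({x:.6g},{y:.6g})")
            elif x <= 0:
                # cannot form a fold-change without a positive baseline
                rec["exclusion_reason"] = "no_increase"
                audit_lines.append(f"{male_id}\tno_increase\tbaseline rate {x:.6g}")
            else:
                rec["qc_status"] = "included"
                rec["exclusion_reason"] = "none"
                rec["fold_change"] = y / x
        records.append(rec)

    table = pd.DataFrame(records, columns=RECORD_COLUMNS)
    excluded = table[table["qc_status"] == "excluded"]
    counts = (excluded.groupby(["series", "exclusion_reason"]).size()
              .unstack(fill_value=0) if not excluded.empty else pd.DataFrame())
    return table, QcAudit(counts=counts, lines=audit_lines)


def included_records(records: pd.DataFrame) -> pd.DataFrame:
    """Rows that survived QC."""
    return records[records["qc_status"] == "included"].reset_index(drop=True)
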