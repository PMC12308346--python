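"""End-to-end orchestration: simulate -> quantify -> filter -> infer -> report.

The pipeline mirrors the experimental analysis plan: per-series rank-based
treatment x time interaction tests with BH-adjusted post hoc pairwise
comparisons (series with a usable vehicle control), a Wilcoxon-then-ATS
cascade for series whose control collapsed under QC (baseline release rates
stand in for the control), and a pooled coupling-corrected test of whether
fold-change responses depend on baseline release rate.

Every stage is a pure function of (inputs, config, seed); identical config
and seed produce byte-identical report tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assay, coupling, paired, rankstats
from .assay import AssayConstants, DEFAULT_CONSTANTS, QcAudit
from .config import SyntheticConfig, series_1, series_2, series_3
from .errors import ConfigError
from .synthetic import simulate_experiment

CSV_FLOAT_FORMAT = "%.12g"


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs."""

    series_configs: list[SyntheticConfig] = field(default_factory=list)
    samples_csv: str | None = None          # analyse an existing table instead of simulating
    alpha: float = 0.05
    posthoc_family: str = "all_pairs"       # or "vs_control"
    null_method: str = "tu_default"
    variance_corrected: bool = True
    n_perm: int = 1000
    min_group_n: int = 6
    subtract_background: bool = False
    threshold_on: str = "either"
    cascade_series: tuple[str, ...] = ()    # series analysed Wilcoxon-first regardless of control size
    force_pool: list[tuple[str, float]] | None = None  # (series, molar) arms to pool for the coupling test
    constants: AssayConstants = field(default_factory=AssayConstants)
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> "PipelineConfig":
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha: must lie in (0, 1) (got {self.alpha})")
        if self.posthoc_family not in ("all_pairs", "vs_control"):
            raise ConfigError(f"posthoc_family: unknown family {self.posthoc_family!r}")
        if not self.series_configs and self.samples_csv is None:
            raise ConfigError("series_configs: provide generator configs or a samples_csv")
        return self


def default_pipeline_config(seed: int = 0, **overrides) -> PipelineConfig:
    """The three-series experiment with its standard analysis plan."""
    cfg = PipelineConfig(
        series_configs=[
            series_1(seed=_derive_seed(seed, 1)),
            series_2(seed=_derive_seed(seed, 2)),
            series_3(seed=_derive_seed(seed, 3)),
        ],
        cascade_series=("S3",),
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg.validate()


def _derive_seed(seed: int, k: int) -> int:
    return (seed * 100_003 + 7919 * k) % (2**31 - 1)


@dataclass
class PipelineResult:
    samples: pd.DataFrame
    truth: pd.DataFrame | None
    records: pd.DataFrame
    audit: QcAudit
    effects: pd.DataFrame        # series, effect, statistic, df, p_value
    posthoc: pd.DataFrame        # series, group_1, group_2, statistic, df, p_raw, p_bh
    wilcoxon: pd.DataFrame       # series, treatment, n, statistic, p_value, increased
    coupling_result: coupling.CouplingTestResult | None
    permutation_null: coupling.PermutationNullResult | None
    fold_summary: pd.DataFrame   # series, treatment, n, median/quartiles of fold-change
    quartile_response: pd.DataFrame  # pooled responders, response by baseline quartile
    pooled_ids: list[str]


def _arm_label(molar: float) -> str:
    return "C" if molar == 0.0 else f"{molar:.0e}"


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()

    # ---- stage 1: obtain water samples -------------------------------
    truth: pd.DataFrame | None = None
    if config.samples_csv is not None:
        samples = pd.read_csv(config.samples_csv)
        per_series_sample_ml = {}
    else:
        frames, truths = [], []
        per_series_sample_ml = {}
        for scfg in config.series_configs:
            s, t = simulate_experiment(scfg)
            frames.append(s)
            truths.append(t)
            per_series_sample_ml[scfg.series_label] = (
                scfg.sample_volume_ml if scfg.volume_correction else 0.0)
        samples = pd.concat(frames, ignore_index=True)
        truth = pd.concat(truths, ignore_index=True)

    # ---- stage 2: quantification + QC, per series --------------------
    rec_frames, audit = [], QcAudit()
    count_frames = []
    for series, sub in samples.groupby("series", sort=False):
        rec, aud = assay.apply_qc_filters(
            sub, config.constants,
            sample_volume_ml=per_series_sample_ml.get(series, 50.0),
            subtract_background=config.subtract_background,
            threshold_on=config.threshold_on)
        rec_frames.append(rec)
        audit.lines.extend(aud.lines)
        if not aud.counts.empty:
            count_frames.append(aud.counts)
    records = pd.concat(rec_frames, ignore_index=True)
    if count_frames:
        audit.counts = pd.concat(count_frames).fillna(0).astype(int)

    analysis = analyze_records(records, config, audit=audit)

    return PipelineResult(samples=samples, truth=truth, records=records, audit=audit,
                          **analysis)


def analyze_records(records: pd.DataFrame, config: PipelineConfig,
                    audit: QcAudit | None = None) -> dict:
    """Stages 3-4: per-series inference plus the pooled coupling analysis.

    Takes a QC'd record table (as produced by ``apply_qc_filters``) and
    returns the keyword arguments of :class:`PipelineResult` downstream of
    QC.  Exposed separately so an existing record table can be re-analysed
    without regenerating samples.
    """
    if audit is None:
        audit = QcAudit()
    effect_rows, posthoc_frames, wilcoxon_rows = [], [], []
    fold_rows = []
    responder_arms: list[tuple[str, float]] = []

    for series, rec in records.groupby("series", sort=False):
        inc = assay.included_records(rec)
        sizes = inc.groupby("treatment_molar").size()
        usable = sizes[sizes >= config.min_group_n].index
        dropped = sizes[sizes < config.min_group_n]
        for molar, n in dropped.items():
            audit.lines.append(f"{series}\tgroup_dropped\t{_arm_label(molar)} n={n} < {config.min_group_n}")
        inc = inc[inc["treatment_molar"].isin(usable)]

        for molar, grp in inc.groupby("treatment_molar"):
            f = grp["fold_change"]
            fold_rows.append({"series": series, "treatment": _arm_label(molar),
                              "n": len(grp), "fold_median": f.median(),
                              "fold_q1": f.quantile(0.25), "fold_q3": f.quantile(0.75)})

        has_control = 0.0 in set(inc["treatment_molar"])
        cascade = series in config.cascade_series or not has_control

        if not cascade:
            data = rankstats.longitudinal_from_records(inc)
            data["group"] = [_arm_label(m) for m in data["group"]]
            for effect in rankstats.EFFECTS:
                res = rankstats.ats_test(data, effect=effect)
                effect_rows.append({"series": series, "effect": effect,
                                    "statistic": res.statistic, "df": res.df_numerator,
                                    "p_value": res.p_value})
            labels = list(pd.unique(data["group"]))
            if config.posthoc_family == "vs_control" and "C" in labels:
                pairs = [("C", g) for g in labels if g != "C"]
            else:
                pairs = None
            ph = rankstats.pairwise_posthoc(data, pairs=pairs)
            ph.insert(0, "series", series)
            posthoc_frames.append(ph)
            # responders: treatments whose vs-control comparison is significant
            vs_c = ph[(ph["group_1"] == "C") | (ph["group_2"] == "C")]
            for _, row in vs_c.iterrows():
                if row["p_bh"] < config.alpha:
                    g = row["group_2"] if row["group_1"] == "C" else row["group_1"]
                    molar = float(g)
                    med = inc.loc[inc["treatment_molar"] == molar, "fold_change"].median()
                    if med > 1.0:
                        responder_arms.append((series, molar))
        else:
            # control unusable: baseline substitutes for it; Wilcoxon per arm first
            treats = [m for m in pd.unique(inc["treatment_molar"]) if m != 0.0]
            increased = []
            for molar in treats:
                grp = inc[inc["treatment_molar"] == molar]
                res = paired.wilcoxon_signed_rank(grp["baseline_rate_mg_per_h"],
                                                  grp["post_rate_mg_per_h"])
                up = res.p_value < config.alpha and grp["fold_change"].median() > 1.0
                wilcoxon_rows.append({"series": series, "treatment": _arm_label(molar),
                                      "n": res.n, "statistic": res.statistic,
                                      "p_value": res.p_value, "increased": up})
                if up:
                    increased.append(molar)
                    responder_arms.append((series, molar))
            if len(increased) >= 2:
                sub = inc[inc["treatment_molar"].isin(increased)]
                data = rankstats.longitudinal_from_records(sub)
                data["group"] = [_arm_label(m) for m in data["group"]]
                res = rankstats.ats_test(data, effect="interaction")
                effect_rows.append({"series": series, "effect": "interaction",
                                    "statistic": res.statistic, "df": res.df_numerator,
                                    "p_value": res.p_value})
                if len(increased) > 2:
                    ph = rankstats.pairwise_posthoc(data)
                    ph.insert(0, "series", series)
                    posthoc_frames.append(ph)

    effects = pd.DataFrame(effect_rows,
                           columns=["series", "effect", "statistic", "df", "p_value"])
    posthoc = (pd.concat(posthoc_frames, ignore_index=True) if posthoc_frames
               else pd.DataFrame(columns=["series", "group_1", "group_2",
                                          "statistic", "df", "p_raw", "p_bh"]))
    wilcoxon = pd.DataFrame(wilcoxon_rows,
                            columns=["series", "treatment", "n", "statistic",
                                     "p_value", "increased"])
    fold_summary = pd.DataFrame(fold_rows,
                                columns=["series", "treatment", "n", "fold_median",
                                         "fold_q1", "fold_q3"])

    # ---- stage 4: pooled coupling analysis ---------------------------
    pool_arms = config.force_pool if config.force_pool is not None else responder_arms
    incl = assay.included_records(records)
    mask = [(s, m) in set(pool_arms) for s, m in
            zip(incl["series"], incl["treatment_molar"])]
    pooled = incl[np.asarray(mask, dtype=bool)] if len(incl) else incl
    coupling_result = permutation_null = None
    quartile_response = pd.DataFrame(columns=["quartile", "n", "mean_percent_of_baseline",
                                              "sem_percent_of_baseline"])
    if len(pooled) >= 4:
        x = pooled["baseline_rate_mg_per_h"].to_numpy()
        y = pooled["post_rate_mg_per_h"].to_numpy()
        coupling_result = coupling.coupling_test(
            x, y, null_method=config.null_method,
            variance_corrected=config.variance_corrected)
        permutation_null = coupling.permutation_null_oracle(
            x, y, n_perm=config.n_perm, seed=_derive_seed(config.seed, 99))
        quartile_response = quartile_response_summary(x, y)
    else:
        audit.lines.append(f"coupling\tskipped\tonly {len(pooled)} pooled responders (need >= 4)")

    return dict(effects=effects, posthoc=posthoc, wilcoxon=wilcoxon,
                coupling_result=coupling_result, permutation_null=permutation_null,
                fold_summary=fold_summary, quartile_response=quartile_response,
                pooled_ids=list(pooled["male_id"]) if len(pooled) else [])


def quartile_response_summary(x, y) -> pd.DataFrame:
    """Mean response (post as % of baseline) by quartile of baseline rate."""
    x = np.asarray(x, dtype=float)
    fold_pct = 100.0 * np.asarray(y, dtype=float) / x
    q = pd.qcut(x, 4, labels=[1, 2, 3, 4], duplicates="drop")
    df = pd.DataFrame({"quartile": q, "pct": fold_pct})
    out = df.groupby("quartile", observed=True)["pct"].agg(["size", "mean", "sem"]).reset_index()
    out.columns = ["quartile", "n", "mean_percent_of_baseline", "sem_percent_of_baseline"]
    return out


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

def write_report(result: PipelineResult, outdir: str | Path) -> list[Path]:
    """Write all report tables as CSV plus a text summary; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def dump(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, index=False, float_format=CSV_FLOAT_FORMAT)
        written.append(p)

    dump(result.samples, "samples.csv")
    if result.truth is not None:
        dump(result.truth, "truth.csv")
    dump(result.records, "records.csv")
    dump(result.effects, "effects.csv")
    dump(result.posthoc, "posthoc.csv")
    dump(result.wilcoxon, "wilcoxon.csv")
    dump(result.fold_summary, "fold_summary.csv")
    dump(result.quartile_response, "quartile_response.csv")
    if result.coupling_result is not None:
        c = result.coupling_result
        dump(pd.DataFrame([{
            "n": c.n, "r_obs": c.r_obs, "r_xy": c.r_xy, "r_null": c.r_null,
            "z_stat": c.z_stat, "p_value": c.p_value, "null_method": c.null_method,
            "perm_null_mean": result.permutation_null.null_mean,
            "perm_p_value": result.permutation_null.p_value,
        }]), "coupling.csv")
    audit_path = outdir / "audit.txt"
    audit_path.write_text(result.audit.to_text())
    written.append(audit_path)
    report_path = outdir / "report.txt"
    report_path.write_text(render_report(result))
    written.append(report_path)
    return written


def render_report(result: PipelineResult) -> str:
    lines = ["Countersignalling bioassay analysis", "=" * 36, ""]
    n_inc = int((result.records["qc_status"] == "included").sum())
    lines.append(f"Males analysed: {n_inc} included / {len(result.records)} total")
    lines.append("")
    if not result.effects.empty:
        lines.append("Rank-based treatment x time tests (ANOVA-type statistic):")
        lines.append(result.effects.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")
    if not result.wilcoxon.empty:
        lines.append("Within-treatment baseline vs post (exact Wilcoxon signed-rank):")
        lines.append(result.wilcoxon.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")
    if not result.fold_summary.empty:
        lines.append("Fold-change (post/baseline) by treatment:")
        lines.append(result.fold_summary.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")
    if result.coupling_result is not None:
        c = result.coupling_result
        lines.append("Baseline-coupling test on pooled responders:")
        lines.append(f"  n = {c.n}, r(x, y/x) = {c.r_obs:.4f}, r_null = {c.r_null:.4f}, "
                     f"z = {c.z_stat:.3f}, p = {c.p_value:.4g}")
        lines.append(f"  permutation oracle: null mean = {result.permutation_null.null_mean:.4f}, "
                     f"p = {result.permutation_null.p_value:.4g}")
        lines.append("")
    if not result.quartile_response.empty:
        lines.append("Response (post as % of baseline) by baseline quartile:")
        lines.append(result.quartile_response.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")
    return "\n".join(lines)
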