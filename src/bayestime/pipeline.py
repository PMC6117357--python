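"""End-to-end pipeline: simulate a cohort, fit, model, compare, report.

A run writes a self-contained directory::

    run/
      config.json               the exact configuration (round-trips)
      trials/                   one CSV per subject x condition x task
      fits/psychometric.csv     PSE / sigma / Weber fraction per condition
      fits/central_tendency.csv slope / intercept / bias per condition
      fits/prior_widths.csv     inverted prior widths per unisensory condition
      models/predictions.csv    model1/model2 audiovisual predictions vs measured
      models/ct_wf_curves.csv   central tendency vs Weber fraction curve family
      stats/stats.json          bootstrap contrasts, t tests, regressions
      report.md                 human-readable summary tables
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import models as bm
from .design import AV_COMBINATIONS, Condition, DesignSpec, make_design
from .observer import (
    DEFAULT_PRIOR_WIDTH,
    DEFAULT_WF,
    ObserverParams,
    simulate_discrimination,
    simulate_reproduction,
)
from .psychometrics import fit_cumulative_normal
from .reproduction import fit_central_tendency
from .stats import PairedSample, bonferroni, bootstrap_paired_test, paired_t, regress_pred_vs_meas

#: slopes at or above 1 can occur under sampling noise; they carry no
#: information about the prior width, so they are clipped just below 1
#: before inversion
CT_CLIP = 0.995


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of one simulated experiment."""

    n_subjects: int = 7
    seed: int = 0
    n_levels: int = 7
    reps_discrimination: int = 24
    reps_reproduction: int = 60
    wf: dict = field(default_factory=lambda: dict(DEFAULT_WF))
    prior_width_ms: dict = field(default_factory=lambda: dict(DEFAULT_PRIOR_WIDTH))
    prior_mean_ms: float | str = "auto"
    motor_noise_cv: float = 0.0
    av_architecture: str = "model2"
    subject_jitter_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if self.subject_jitter_sd < 0:
            raise ValueError("subject_jitter_sd must be nonnegative")
        # delegate the remaining validation to the component types
        self.design()
        self.base_params()

    def design(self) -> DesignSpec:
        return make_design(
            n_levels=self.n_levels,
            reps_discrimination=self.reps_discrimination,
            reps_reproduction=self.reps_reproduction,
        )

    def base_params(self) -> ObserverParams:
        return ObserverParams(
            wf=dict(self.wf),
            prior_width_ms=dict(self.prior_width_ms),
            prior_mean_ms=self.prior_mean_ms,
            motor_noise_cv=self.motor_noise_cv,
            av_architecture=self.av_architecture,
            seed=self.seed,
        )

    def subject_params(self, subject_index: int) -> ObserverParams:
        """Per-subject parameters: log-normal jitter around the base values."""
        base = self.base_params()
        if self.subject_jitter_sd == 0:
            return base
        rng = np.random.default_rng([self.seed, 100, subject_index])
        wf = {k: v * np.exp(rng.normal(0, self.subject_jitter_sd)) for k, v in base.wf.items()}
        pw = {
            k: v * np.exp(rng.normal(0, self.subject_jitter_sd))
            for k, v in base.prior_width_ms.items()
        }
        return dataclasses.replace(base, wf=wf, prior_width_ms=pw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: Path | str) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _subject_id(i: int) -> str:
    return f"s{i + 1:02d}"


def _cond_slug(cond: Condition) -> str:
    return cond.key.replace(":", "-")


def simulate_cohort(config: RunConfig, outdir: Path | str) -> Path:
    """Simulate all subjects and conditions; write trial CSVs and the config."""
    outdir = Path(outdir)
    trials_dir = outdir / "trials"
    trials_dir.mkdir(parents=True, exist_ok=True)
    config.save(outdir / "config.json")
    design = config.design()
    for i in range(config.n_subjects):
        params = config.subject_params(i)
        sid = _subject_id(i)
        for cond in design.conditions:
            disc = simulate_discrimination(design, params, cond, subject=sid, subject_index=i)
            disc.to_csv(trials_dir / f"discrimination_{sid}_{_cond_slug(cond)}.csv", index=False)
            repro = simulate_reproduction(design, params, cond, subject=sid, subject_index=i)
            repro.to_csv(trials_dir / f"reproduction_{sid}_{_cond_slug(cond)}.csv", index=False)
    return outdir


def _condition_row(cond: Condition) -> dict:
    return {
        "condition": cond.key,
        "modality": cond.modality,
        "vis_noise": cond.vis_noise,
        "aud_noise": cond.aud_noise,
    }


def fit_cohort_discrimination(outdir: Path | str) -> pd.DataFrame:
    """Fit a psychometric function per subject x condition; write fits CSV."""
    outdir = Path(outdir)
    config = RunConfig.load(outdir / "config.json")
    design = config.design()
    rows = []
    for i in range(config.n_subjects):
        sid = _subject_id(i)
        for cond in design.conditions:
            path = outdir / "trials" / f"discrimination_{sid}_{_cond_slug(cond)}.csv"
            trials = pd.read_csv(path)
            fit = fit_cumulative_normal(trials)
            rows.append(
                {
                    "subject": sid,
                    **_condition_row(cond),
                    "pse_ms": fit.pse_ms,
                    "sigma_ms": fit.sigma_ms,
                    "weber_fraction": fit.weber_fraction,
                    "n_trials": fit.n_trials,
                    "loglik": fit.loglik,
                    "converged": fit.converged,
                }
            )
    fits = pd.DataFrame(rows)
    fits_dir = outdir / "fits"
    fits_dir.mkdir(exist_ok=True)
    fits.to_csv(fits_dir / "psychometric.csv", index=False)
    return fits


def fit_cohort_reproduction(outdir: Path | str) -> pd.DataFrame:
    """Fit the central tendency per subject x condition; write fits CSV."""
    outdir = Path(outdir)
    config = RunConfig.load(outdir / "config.json")
    design = config.design()
    rows = []
    for i in range(config.n_subjects):
        sid = _subject_id(i)
        for cond in design.conditions:
            path = outdir / "trials" / f"reproduction_{sid}_{_cond_slug(cond)}.csv"
            trials = pd.read_csv(path)
            fit = fit_central_tendency(trials)
            rows.append(
                {
                    "subject": sid,
                    **_condition_row(cond),
                    "slope": fit.slope,
                    "intercept_ms": fit.intercept_ms,
                    "overall_bias_ms": fit.overall_bias_ms,
                    "n_used": fit.n_used,
                    "n_excluded": fit.n_excluded,
                    "r2": fit.r2,
                }
            )
    fits = pd.DataFrame(rows)
    fits_dir = outdir / "fits"
    fits_dir.mkdir(exist_ok=True)
    fits.to_csv(fits_dir / "central_tendency.csv", index=False)
    return fits


def estimate_cohort_priors(outdir: Path | str) -> pd.DataFrame:
    """Invert the central-tendency slope for the prior width, per unisensory condition."""
    outdir = Path(outdir)
    config = RunConfig.load(outdir / "config.json")
    design = config.design()
    wf = pd.read_csv(outdir / "fits" / "psychometric.csv")
    ct = pd.read_csv(outdir / "fits" / "central_tendency.csv")
    merged = wf.merge(
        ct[["subject", "condition", "slope"]], on=["subject", "condition"], how="inner"
    )
    uni = merged[merged["modality"] != "AV"].copy()
    dbar = design.mean_duration_ms
    uni["ct_clipped"] = uni["slope"].clip(upper=CT_CLIP)
    uni["prior_width_ms"] = [
        bm.estimate_prior_width(row.ct_clipped, row.weber_fraction, dbar)
        for row in uni.itertuples()
    ]
    out = uni[
        ["subject", "condition", "modality", "vis_noise", "aud_noise",
         "weber_fraction", "slope", "prior_width_ms"]
    ]
    out.to_csv(outdir / "fits" / "prior_widths.csv", index=False)
    return out


def compare_cohort_models(outdir: Path | str) -> dict:
    """Predict audiovisual behavior from unisensory fits under both architectures.

    Writes the per-subject prediction table, the central-tendency versus
    Weber-fraction curve family, and a stats report with the bootstrap
    contrasts (audiovisual vs best unisensory, Bonferroni-corrected for the
    three noise combinations), predicted-vs-measured regressions, paired t
    tests of each architecture, and the winning model by mean absolute
    central-tendency error.
    """
    outdir = Path(outdir)
    config = RunConfig.load(outdir / "config.json")
    design = config.design()
    dbar = design.mean_duration_ms
    durations = design.reproduction_levels_ms
    wf = pd.read_csv(outdir / "fits" / "psychometric.csv").set_index(["subject", "condition"])
    ct = pd.read_csv(outdir / "fits" / "central_tendency.csv").set_index(["subject", "condition"])
    priors = pd.read_csv(outdir / "fits" / "prior_widths.csv").set_index(["subject", "condition"])

    rows = []
    for i in range(config.n_subjects):
        sid = _subject_id(i)
        for vn, an in AV_COMBINATIONS:
            kv, ka = f"V:{vn}", f"A:{an}"
            kav = f"AV:{vn}:{an}"
            wf_v = float(wf.loc[(sid, kv), "weber_fraction"])
            wf_a = float(wf.loc[(sid, ka), "weber_fraction"])
            sp_v = float(priors.loc[(sid, kv), "prior_width_ms"])
            sp_a = float(priors.loc[(sid, ka), "prior_width_ms"])
            m1 = bm.predict_model1(
                wf_v, wf_a,
                prior_v=bm.GaussianBelief(dbar, sp_v),
                prior_a=bm.GaussianBelief(dbar, sp_a),
                durations=durations,
            )
            m2 = bm.predict_model2(wf_v, wf_a, sp_v, sp_a, durations, prior_mean_ms=dbar)
            rows.append(
                {
                    "subject": sid,
                    "condition": kav,
                    "wf_v": wf_v,
                    "wf_a": wf_a,
                    "prior_width_v_ms": sp_v,
                    "prior_width_a_ms": sp_a,
                    "predicted_av_wf": m2.predicted_av_wf,
                    "measured_av_wf": float(wf.loc[(sid, kav), "weber_fraction"]),
                    "model1_predicted_ct": m1.predicted_av_slope,
                    "model2_predicted_ct": m2.predicted_av_slope,
                    "measured_av_ct": float(ct.loc[(sid, kav), "slope"]),
                    "unisensory_min_wf": min(wf_v, wf_a),
                    "unisensory_max_ct": max(
                        float(ct.loc[(sid, kv), "slope"]), float(ct.loc[(sid, ka), "slope"])
                    ),
                }
            )
    pred = pd.DataFrame(rows)
    models_dir = outdir / "models"
    models_dir.mkdir(exist_ok=True)
    pred.to_csv(models_dir / "predictions.csv", index=False)

    curve_rows = []
    wf_grid = np.round(np.linspace(0.05, 0.4, 36), 3)
    for sp in (100, 200, 300, 400, 500):
        for wf_val, slope in bm.ct_wf_curve(sp, wf_grid, dbar):
            curve_rows.append({"prior_width_ms": sp, "weber_fraction": wf_val, "ct_slope": slope})
    pd.DataFrame(curve_rows).to_csv(models_dir / "ct_wf_curves.csv", index=False)

    stats: dict = {"wf_contrasts": {}, "ct_contrasts": {}}
    seed_base = config.seed + 10_000
    raw_wf_p, raw_ct_p, av_keys = [], [], []
    for j, (vn, an) in enumerate(AV_COMBINATIONS):
        kav = f"AV:{vn}:{an}"
        av_keys.append(kav)
        sub = pred[pred["condition"] == kav]
        s_wf = PairedSample.from_arrays(sub["subject"], sub["unisensory_min_wf"], sub["measured_av_wf"])
        s_ct = PairedSample.from_arrays(sub["subject"], sub["measured_av_ct"], sub["unisensory_max_ct"])
        b_wf = bootstrap_paired_test(s_wf, seed=seed_base + 2 * j)
        b_ct = bootstrap_paired_test(s_ct, seed=seed_base + 2 * j + 1)
        stats["wf_contrasts"][kav] = {"p_raw": b_wf.p_value, "cohen_d": b_wf.effect_size_d}
        stats["ct_contrasts"][kav] = {"p_raw": b_ct.p_value, "cohen_d": b_ct.effect_size_d}
    for key, adj in zip(av_keys, bonferroni([stats["wf_contrasts"][k]["p_raw"] for k in av_keys])):
        stats["wf_contrasts"][key]["p_bonferroni"] = adj
    for key, adj in zip(av_keys, bonferroni([stats["ct_contrasts"][k]["p_raw"] for k in av_keys])):
        stats["ct_contrasts"][key]["p_bonferroni"] = adj

    reg_wf = regress_pred_vs_meas(pred["predicted_av_wf"], pred["measured_av_wf"])
    stats["pred_vs_meas_wf"] = {"slope": reg_wf.slope, "intercept": reg_wf.intercept,
                                "r": reg_wf.r, "p": reg_wf.p_value}
    for name in ("model1", "model2"):
        col = f"{name}_predicted_ct"
        t, df, p, d = paired_t(
            PairedSample.from_arrays(pred["subject"], pred[col], pred["measured_av_ct"])
        )
        reg = regress_pred_vs_meas(pred[col], pred["measured_av_ct"])
        stats[name] = {
            "t": t, "df": df, "p": p, "cohen_d": d,
            "regression": {"slope": reg.slope, "intercept": reg.intercept,
                           "r": reg.r, "p": reg.p_value},
            "mean_abs_ct_error": float((pred[col] - pred["measured_av_ct"]).abs().mean()),
        }
    stats["model_selection"] = {
        "selected": "model1"
        if stats["model1"]["mean_abs_ct_error"] < stats["model2"]["mean_abs_ct_error"]
        else "model2"
    }

    stats_dir = outdir / "stats"
    stats_dir.mkdir(exist_ok=True)
    (stats_dir / "stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True))
    return stats


REQUIRED_ARTIFACTS = (
    "config.json",
    "fits/psychometric.csv",
    "fits/central_tendency.csv",
    "fits/prior_widths.csv",
    "models/predictions.csv",
    "stats/stats.json",
)


def _condition_summary(df: pd.DataFrame, value: str) -> pd.DataFrame:
    g = df.groupby("condition", sort=False)[value]
    out = pd.DataFrame({"mean": g.mean(), "sem": g.sem(), "n": g.size()})
    return out.reset_index()


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.4g}") -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for _, row in df.iterrows():
        cells = [
            floatfmt.format(v) if isinstance(v, (float, np.floating)) else str(v)
            for v in row
        ]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def report(run_dir: Path | str) -> str:
    """Summarize a completed run as markdown; writes and returns report.md."""
    run_dir = Path(run_dir)
    missing = [a for a in REQUIRED_ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        raise FileNotFoundError(f"run directory {run_dir} is missing artifacts: {missing}")
    config = RunConfig.load(run_dir / "config.json")
    wf = pd.read_csv(run_dir / "fits" / "psychometric.csv")
    ct = pd.read_csv(run_dir / "fits" / "central_tendency.csv")
    priors = pd.read_csv(run_dir / "fits" / "prior_widths.csv")
    pred = pd.read_csv(run_dir / "models" / "predictions.csv")
    stats = json.loads((run_dir / "stats" / "stats.json").read_text())

    parts = [
        "# Simulated multisensory timing experiment",
        "",
        f"Cohort: {config.n_subjects} subjects, seed {config.seed}, "
        f"generator architecture {config.av_architecture}.",
        "",
        "## Weber fractions by condition (mean ± SEM)",
        "",
        _md_table(_condition_summary(wf, "weber_fraction")),
        "",
        "## Central tendency (regression slope) by condition",
        "",
        _md_table(_condition_summary(ct, "slope")),
        "",
        "## Overall reproduction bias (ms) by condition",
        "",
        _md_table(_condition_summary(ct, "overall_bias_ms")),
        "",
        "## Estimated prior widths (ms) by unisensory condition",
        "",
        _md_table(_condition_summary(priors, "prior_width_ms")),
        "",
        "## Audiovisual model predictions vs measurements",
        "",
        _md_table(
            pred.groupby("condition", sort=False)[
                ["predicted_av_wf", "measured_av_wf",
                 "model1_predicted_ct", "model2_predicted_ct", "measured_av_ct"]
            ].mean().reset_index()
        ),
        "",
        "## Statistics",
        "",
        "```json",
        json.dumps(stats, indent=2, sort_keys=True),
        "```",
        "",
    ]
    text = "\n".join(parts)
    (run_dir / "report.md").write_text(text)
    return text


def select_architecture_for_cohort(config: RunConfig) -> dict:
    """Simulate one cohort in memory and pick the better-fitting architecture.

    For every audiovisual noise combination and subject, the unisensory
    Weber fractions (discrimination fits) and central tendencies
    (reproduction fits) are estimated, prior widths inverted, and both
    architecture predictions compared against the measured audiovisual
    central tendency.  Returns the mean absolute central-tendency error of
    each model and the winner.  This is the file-free core of the model
    comparison, used for replicate self-consistency studies.
    """
    design = config.design()
    dbar = design.mean_duration_ms
    durations = design.reproduction_levels_ms
    err1, err2 = [], []
    for i in range(config.n_subjects):
        params = config.subject_params(i)
        uni_keys = {f"V:{vn}" for vn, _ in AV_COMBINATIONS}
        uni_keys |= {f"A:{an}" for _, an in AV_COMBINATIONS}
        wf_fit, ct_fit, prior_fit = {}, {}, {}
        for key in sorted(uni_keys):
            disc = simulate_discrimination(design, params, key, subject_index=i)
            wf_fit[key] = fit_cumulative_normal(disc).weber_fraction
            repro = simulate_reproduction(design, params, key, subject_index=i)
            ct_fit[key] = fit_central_tendency(repro).slope
            prior_fit[key] = bm.estimate_prior_width(
                min(ct_fit[key], CT_CLIP), wf_fit[key], dbar
            )
        for vn, an in AV_COMBINATIONS:
            kv, ka = f"V:{vn}", f"A:{an}"
            av = simulate_reproduction(design, params, f"AV:{vn}:{an}", subject_index=i)
            measured = fit_central_tendency(av).slope
            m1 = bm.predict_model1(
                wf_fit[kv], wf_fit[ka],
                prior_v=bm.GaussianBelief(dbar, prior_fit[kv]),
                prior_a=bm.GaussianBelief(dbar, prior_fit[ka]),
                durations=durations,
            )
            m2 = bm.predict_model2(
                wf_fit[kv], wf_fit[ka], prior_fit[kv], prior_fit[ka],
                durations, prior_mean_ms=dbar,
            )
            err1.append(abs(m1.predicted_av_slope - measured))
            err2.append(abs(m2.predicted_av_slope - measured))
    mae1 = float(np.mean(err1))
    mae2 = float(np.mean(err2))
    return {
        "mean_abs_ct_error_model1": mae1,
        "mean_abs_ct_error_model2": mae2,
        "selected": "model1" if mae1 < mae2 else "model2",
    }


def run_experiment(config: RunConfig, outdir: Path | str) -> Path:
    """Full pipeline: simulate, fit both tasks, invert priors, compare models, report."""
    outdir = Path(outdir)
    simulate_cohort(config, outdir)
    fit_cohort_discrimination(outdir)
    fit_cohort_reproduction(outdir)
    estimate_cohort_priors(outdir)
    compare_cohort_models(outdir)
    report(outdir)
    return outdir
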