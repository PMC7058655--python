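"""End-to-end orchestration: preprocess -> fit -> compare -> slopes -> report.

A run is driven by a :class:`RunConfig`, executes every stage in order,
and writes a results bundle (delimited tables, JSON records, figures and
a manifest) to the output directory. One root seed spawns independent
per-stage substreams so any stage can be rerun in isolation; reruns with
the same config and seed are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .broken_stick import (
    DEFAULT_C_SEARCH,
    DEFAULT_GRID_STEP,
    FitError,
    InferenceError,
    breakpoint_cis,
)
from .datatypes import WINDOW, Biomarker, MicrobialGroup, PatientRecord
from .inference import PARAMETERS, bootstrap_group_difference, one_group_vs_reference
from .preprocess import (
    CRP_LOD,
    PA_FLOOR,
    daily_means,
    exclude_implausible_pa,
    impute_below_lod,
    select_cohort,
    select_cohort_both,
    window_measurements,
)
from .simulate import SimulationScenario, generate_cohort
from .slopes import (
    DEFAULT_WINDOWS,
    compute_slope_pairs,
    slope_pairs_to_frame,
    summarize_slope_patterns,
)

__all__ = ["RunConfig", "run_analysis", "cohort_flow_report", "preprocess_cohort"]

logger = logging.getLogger(__name__)

_COMPARED_GROUPS = (
    MicrobialGroup.GRAM_POS,
    MicrobialGroup.GRAM_NEG,
    MicrobialGroup.POLYMICROBIAL,
)


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Exactly one input source is used: a simulation ``scenario``, or a
    ``measurements_path`` (optionally with ``patients_path``) pointing at
    delimited-text tables.
    """

    out_dir: str | Path
    scenario: SimulationScenario | None = None
    measurements_path: str | Path | None = None
    patients_path: str | Path | None = None
    biomarkers: tuple[Biomarker, ...] = (Biomarker.CRP, Biomarker.PA)
    window: tuple[int, int] = WINDOW
    lod: float = CRP_LOD
    pa_floor: float = PA_FLOOR
    c_search: tuple[float, float] = DEFAULT_C_SEARCH
    grid_step: float = DEFAULT_GRID_STEP
    n_reps: int = 1000
    seed: int = 0
    make_figures: bool = True
    min_group_size: int = 10  # groups smaller than this skip per-group fits

    def validate(self) -> None:
        if (self.scenario is None) == (self.measurements_path is None):
            raise ValueError(
                "exactly one of scenario and measurements_path must be given"
            )
        if self.window[0] >= self.window[1]:
            raise ValueError("window start must precede window end")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def preprocess_cohort(
    patients: list[PatientRecord],
    lod: float = CRP_LOD,
    pa_floor: float = PA_FLOOR,
    window: tuple[int, int] = WINDOW,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[PatientRecord], dict]:
    """Window, impute CRP below-LOD values and drop implausible albumin.

    Returns the cleaned cohort and a small report of what each filter did.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    patients = window_measurements(patients, window)
    n_flagged = 0
    n_pa_removed = 0
    cleaned: list[PatientRecord] = []
    for p in patients:
        crp = [m for m in p.measurements if m.biomarker is Biomarker.CRP]
        pa = [m for m in p.measurements if m.biomarker is Biomarker.PA]
        n_flagged += sum(m.below_lod for m in crp)
        crp = impute_below_lod(crp, lod=lod, rng=rng)
        kept_pa = exclude_implausible_pa(pa, floor=pa_floor)
        n_pa_removed += len(pa) - len(kept_pa)
        cleaned.append(PatientRecord(p.patient_id, p.microbial_group, crp + kept_pa))
    report = {
        "n_patients_in": len(patients),
        "n_crp_below_lod_imputed": n_flagged,
        "n_pa_implausible_removed": n_pa_removed,
    }
    return cleaned, report


def cohort_flow_report(patients: list[PatientRecord]) -> dict:
    """Patient counts at each eligibility stage.

    Mirrors the cohort-flow accounting of the analysis: patients entering,
    eligible per biomarker (>=1 pre-diagnosis and >=1 diagnosis-day
    measurement of that biomarker), eligible for both, and eligible for
    the per-patient two-window slope analysis.
    """
    report = {"n_entering": len(patients)}
    for bm in Biomarker:
        eligible = select_cohort(patients, bm)
        pairs, _ = compute_slope_pairs(eligible, bm)
        report[f"eligible_{bm.value.lower()}"] = len(eligible)
        report[f"slope_eligible_{bm.value.lower()}"] = len(pairs)
    report["eligible_both"] = len(select_cohort_both(patients))
    return report


def _fit_kwargs(config: RunConfig) -> dict:
    return {"c_search": config.c_search, "grid_step": config.grid_step}


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and write the results bundle.

    Stages: load or simulate the cohort; preprocess; cohort-flow report;
    per-biomarker broken-stick fit with bootstrap CIs (overall and per
    microbial group); pairwise bootstrap group comparisons for every
    parameter; change-point-vs-day-0 tests per group; per-patient slope
    pairs and their summary; figures; manifest. Returns the run report as
    a dictionary (also written to ``report.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    ss_sim, ss_pre, ss_ci, ss_cmp = root.spawn(4)

    if config.scenario is not None:
        sim_seed = int(ss_sim.generate_state(1)[0] % (2**31))
        patients = generate_cohort(config.scenario, seed=sim_seed)
    else:
        patients = bio.read_cohort(config.measurements_path, config.patients_path)
        sim_seed = None
    if not patients:
        raise ValueError("empty cohort: no patients to analyse")

    patients, pre_report = preprocess_cohort(
        patients, config.lod, config.pa_floor, config.window,
        rng=np.random.default_rng(ss_pre),
    )
    bio.write_cohort(patients, out / "measurements_clean.csv")
    bio.write_patients(patients, out / "patients.csv")

    flow = cohort_flow_report(patients)
    report: dict = {"preprocessing": pre_report, "cohort_flow": flow,
                    "fits": [], "comparisons": [], "slope_summaries": {}}

    rng_ci = np.random.default_rng(ss_ci)
    all_series = []
    for bm in config.biomarkers:
        eligible = select_cohort(patients, bm)
        if not eligible:
            raise ValueError(f"empty eligible cohort for {bm.value}")
        series = daily_means(eligible, bm)
        all_series.append(series.to_frame())
        fit = breakpoint_cis(eligible, bm, n_reps=config.n_reps, rng=rng_ci,
                             window=config.window, **_fit_kwargs(config))
        report["fits"].append(bio.fit_to_record(fit, biomarker=bm.value,
                                                group="all"))
        for g in _COMPARED_GROUPS:
            members = [p for p in eligible if p.microbial_group is g]
            if len(members) < config.min_group_size:
                logger.info("skipping %s fit for %s: only %d patients",
                            bm.value, g.value, len(members))
                continue
            try:
                gfit = breakpoint_cis(members, bm, n_reps=config.n_reps,
                                      rng=rng_ci, window=config.window,
                                      **_fit_kwargs(config))
            except (FitError, InferenceError) as exc:
                logger.warning("%s fit failed for group %s: %s",
                               bm.value, g.value, exc)
                continue
            report["fits"].append(bio.fit_to_record(gfit, biomarker=bm.value,
                                                    group=g.value))

        rng_cmp = np.random.default_rng(ss_cmp.spawn(1)[0])
        present = [g for g in _COMPARED_GROUPS
                   if sum(p.microbial_group is g for p in eligible)
                   >= config.min_group_size]
        for (ga, gb), param in itertools.product(
            itertools.combinations(present, 2), PARAMETERS
        ):
            try:
                d = bootstrap_group_difference(
                    eligible, bm, ga, gb, param, n_reps=config.n_reps,
                    rng=rng_cmp, window=config.window, **_fit_kwargs(config))
            except InferenceError as exc:
                logger.warning("comparison %s-%s (%s) failed: %s",
                               ga.value, gb.value, param, exc)
                continue
            report["comparisons"].append(_diff_row(bm, d))
        for g in present:
            try:
                d = one_group_vs_reference(
                    eligible, bm, g, "c", 0.0, n_reps=config.n_reps,
                    rng=rng_cmp, window=config.window, **_fit_kwargs(config))
            except InferenceError as exc:
                logger.warning("reference test for %s (%s) failed: %s",
                               g.value, bm.value, exc)
                continue
            report["comparisons"].append(_diff_row(bm, d))

        pairs, excluded = compute_slope_pairs(eligible, bm)
        slope_pairs_to_frame(pairs).to_csv(
            out / f"slope_pairs_{bm.value.lower()}.csv", index=False)
        if pairs:
            summ = summarize_slope_patterns(pairs, bm)
            report["slope_summaries"][bm.value] = {
                "n": summ.n,
                "direction": summ.direction,
                "proportion_acute": summ.proportion_acute,
                "n_excluded": len(excluded),
            }

    pd.concat(all_series).to_csv(out / "daily_means.csv", index=False)
    pd.DataFrame(report["comparisons"]).to_csv(out / "comparisons.csv", index=False)
    bio.write_fits(report["fits"], out / "fits.json")
    with open(out / "cohort_flow.csv", "w") as fh:
        fh.write("stage,count\n")
        for k, v in flow.items():
            fh.write(f"{k},{v}\n")

    if config.make_figures:
        _make_figures(out)

    manifest = {
        "config": _config_record(config),
        "config_sha256": hashlib.sha256(
            json.dumps(_config_record(config), sort_keys=True).encode()
        ).hexdigest(),
        "root_seed": config.seed,
        "simulation_seed": sim_seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _diff_row(bm: Biomarker, d) -> dict:
    return {
        "biomarker": bm.value,
        "parameter": d.parameter,
        "group_a": d.group_a,
        "group_b": d.group_b,
        "ci_lo": d.ci95[0],
        "ci_hi": d.ci95[1],
        "significant": d.significant,
        "n_failed": d.n_failed,
        "n_reps": d.n_reps,
    }


def _config_record(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["out_dir"] = str(d["out_dir"])
    for key in ("measurements_path", "patients_path"):
        if d[key] is not None:
            d[key] = str(d[key])
    d["biomarkers"] = [bm.value for bm in config.biomarkers]
    if config.scenario is not None:
        from .simulate import _scenario_to_dict

        d["scenario"] = _scenario_to_dict(config.scenario)
    return d


def _make_figures(out: Path) -> None:
    """Render the three report figures from the *saved* stage outputs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    daily = pd.read_csv(out / "daily_means.csv")
    with open(out / "fits.json") as fh:
        fits = json.load(fh)

    # daily specimen counts
    fig, ax = plt.subplots(figsize=(7, 4))
    for bm, sub in daily.groupby("biomarker"):
        ax.plot(sub["day"], sub["count"], marker="o", ms=3, label=bm)
    ax.set_xlabel("day relative to blood culture (D0)")
    ax.set_ylabel("specimens per day")
    ax.legend()
    fig.savefig(out / "fig_specimen_counts.png", dpi=150)
    plt.close(fig)

    # mean curves with fitted stick and change-point arrow
    overall = {f["biomarker"]: f for f in fits if f["group"] == "all"}
    fig, axes = plt.subplots(len(overall), 1, figsize=(7, 4 * len(overall)),
                             squeeze=False)
    for ax, (bm, f) in zip(axes.ravel(), overall.items()):
        sub = daily[daily["biomarker"] == bm]
        ax.plot(sub["day"], sub["mean"], "o", ms=4, label="daily mean")
        t = np.linspace(sub["day"].min(), sub["day"].max(), 400)
        dt = t - f["c"]
        pred = f["level_at_c"] + np.where(dt <= 0, f["slope_pre"] * dt,
                                          f["slope_post"] * dt)
        ax.plot(t, pred, "-", label="broken-stick fit")
        ax.annotate("change-point", xy=(f["c"], f["level_at_c"]),
                    xytext=(f["c"] - 8, f["level_at_c"]),
                    arrowprops={"arrowstyle": "->"})
        ax.set_title(bm)
        ax.set_xlabel("day relative to D0")
        ax.set_ylabel("mg/l" if bm == "CRP" else "g/l")
        ax.legend()
    fig.tight_layout()
    fig.savefig(out / "fig_mean_curves.png", dpi=150)
    plt.close(fig)

    # individual slope scatter
    markers = {"gram_pos": "o", "gram_neg": "^", "polymicrobial": "s",
               "unknown": "x"}
    for bm in ("crp", "pa"):
        path = out / f"slope_pairs_{bm}.csv"
        if not path.exists():
            continue
        pairs = pd.read_csv(path)
        if pairs.empty:
            continue
        fig, ax = plt.subplots(figsize=(5, 5))
        for g, sub in pairs.groupby("group"):
            ax.scatter(sub["slope_early"], sub["slope_late"],
                       marker=markers.get(g, "o"), s=15, label=g, alpha=0.6)
        ax.axhline(0, color="grey", lw=0.6)
        ax.axvline(0, color="grey", lw=0.6)
        ax.set_xlabel("early-window slope (units/day)")
        ax.set_ylabel("late-window slope (units/day)")
        ax.set_title(bm.upper())
        ax.legend()
        fig.savefig(out / f"fig_slopes_{bm}.png", dpi=150)
        plt.close(fig)
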