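"""End-to-end orchestration: simulate (or load) -> summarize/exclude -> fit ->
learning curves -> group statistics, with seeded determinism and a hashed
output manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (CohortConfig, GroupSpec, default_group_specs,
                     export_cohort, generate_cohort, subjects_frame)
from .curves import (compute_learning_curves, compare_growth_parameters,
                     fit_logistic_growth, learning_initiation, ratio_identity)
from .fitting import (FitConfig, FitResult, fit_quality_analysis,
                      fit_results_to_frame, fit_subject, write_fit_results)
from .stats import (age_trend, anova_by_factor, apply_exclusion,
                    compare_groups, logistic_age_classifier,
                    parameter_correlation_matrix, rt_parameter_regression,
                    speed_accuracy_analysis, summaries_frame,
                    summarize_subject)
from .task import (SubjectDataset, TaskConfig, read_trials, records_to_frame,
                   write_trials)

log = logging.getLogger("rlwm")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; echoes into the outputs."""

    cohort: Optional[CohortConfig] = None       # simulate when given ...
    trials_path: Optional[str] = None           # ... else load these files
    subjects_path: Optional[str] = None
    fit: FitConfig = field(default_factory=lambda: FitConfig(
        n_starts=5, k_grid=(3,), fixed={"beta": 8.0}))
    seed: int = 0
    out_dir: str = "rlwm_out"
    classifier_cutoffs: tuple = tuple(range(35, 45))
    initiation_fraction: float = 0.1
    jobs: int = 1

    @staticmethod
    def from_file(path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return PipelineConfig.from_dict(data)

    @staticmethod
    def from_dict(data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        if kwargs.get("cohort"):
            c = kwargs["cohort"]
            task = TaskConfig(**{**c.get("task", {}),
                                 **({"set_sizes": tuple(c["task"]["set_sizes"]),
                                     "presentations": tuple(c["task"]["presentations"])}
                                    if c.get("task") else {})}) if c.get("task") else TaskConfig()
            groups = [GroupSpec(**{**g,
                                   "age_range": tuple(g["age_range"]),
                                   "moca_range": tuple(g["moca_range"])})
                      for g in c["groups"]] if c.get("groups") else default_group_specs()
            kwargs["cohort"] = CohortConfig(groups=groups, task=task,
                                            seed=c.get("seed", kwargs.get("seed", 0)))
        if kwargs.get("fit"):
            f = dict(kwargs["fit"])
            if "k_grid" in f:
                f["k_grid"] = tuple(f["k_grid"])
            kwargs["fit"] = FitConfig(**f)
        if "classifier_cutoffs" in kwargs:
            kwargs["classifier_cutoffs"] = tuple(kwargs["classifier_cutoffs"])
        return PipelineConfig(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # provenance must not depend on where it is written
        return d


def small_cohort_config(seed: int = 0) -> CohortConfig:
    """Miniature cohort (2 subjects per group, 3 learning blocks)."""
    task = TaskConfig(n_learning_blocks=3, set_sizes=(2, 3, 4),
                      presentations=(12, 12, 12), include_training=False)
    groups = [dataclasses.replace(g, n=2) for g in default_group_specs()]
    return CohortConfig(groups=groups, task=task, seed=seed)


def load_cohort(trials_path: str | Path,
                subjects_path: Optional[str | Path] = None) -> list[SubjectDataset]:
    """Rebuild SubjectDatasets from a trial-log CSV plus optional demographics."""
    records = read_trials(trials_path)
    df = records_to_frame(records)
    demo = pd.read_csv(subjects_path, dtype={"subject_id": str}) if subjects_path else None
    datasets = []
    for sid, sub in df.groupby("subject_id", sort=True):
        ds = SubjectDataset(subject_id=str(sid), trials=sub.reset_index(drop=True))
        if demo is not None:
            row = demo[demo["subject_id"] == sid]
            if len(row):
                ds.age = float(row["age"].iloc[0])
                ds.group = str(row["group"].iloc[0])
                ds.moca = int(row["moca"].iloc[0])
        datasets.append(ds)
    return datasets


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=1, sort_keys=True))


def fit_cohort(datasets: Sequence[SubjectDataset], fit_config: FitConfig,
               seed: int, jobs: int = 1) -> list[FitResult]:
    """Fit every subject; per-subject seeds make results independent of job
    count and of subject order."""
    seeds = {ds.subject_id:
             int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
             for i, ds in enumerate(datasets)}
    if jobs > 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=jobs)(
            delayed(fit_subject)(ds, fit_config, seeds[ds.subject_id])
            for ds in datasets)
        return list(results)
    return [fit_subject(ds, fit_config, seeds[ds.subject_id]) for ds in datasets]


def _analysis(datasets, summaries, fits, config) -> dict:
    """The statistical battery over a fitted cohort."""
    sframe = summaries_frame(summaries)
    kept_ids = set(sframe["subject_id"])
    data = [d for d in datasets if d.subject_id in kept_ids]
    fit_map = {f.subject_id: f for f in fits}
    table = pd.DataFrame([
        {"subject_id": d.subject_id, "group": d.group, "age": d.age,
         "moca": d.moca, **fit_map[d.subject_id].params.to_dict(),
         "nll": fit_map[d.subject_id].nll}
        for d in data if d.subject_id in fit_map])
    report: dict = {}
    have_groups = table["group"].notna().all() and table["group"].nunique() >= 2
    params4 = ("alpha", "phi", "rho", "epsilon")

    # parameter group comparisons (one Bonferroni family per contrast table)
    if have_groups:
        for label, pair in (("young_vs_normal_mid", ("young", "normal_mid")),
                            ("normal_vs_mci", ("normal_mid", "mci_mid"))):
            if not all((table["group"] == g).sum() >= 3 for g in pair):
                continue
            fam = {}
            for p in params4:
                fam[p] = compare_groups(
                    {g: table.loc[table["group"] == g, p].to_numpy() for g in pair},
                    family_size=len(params4))
            report[f"params_{label}"] = fam

    # behavioral comparisons: accuracy / RT / IES between young and middle-aged
    merged = summaries_frame(summaries)
    if have_groups:
        merged["age_group"] = np.where(merged["group"] == "young", "young", "middle")
        merged["moca_status"] = np.where(merged["moca"] >= 26, "normal", "mci")
        beh = {}
        for metric in ("accuracy", "mean_rt", "ies"):
            vals = merged.dropna(subset=[metric])
            g = {name: grp[metric].to_numpy()
                 for name, grp in vals.groupby("age_group")}
            if len(g) == 2 and all(len(v) >= 3 for v in g.values()):
                beh[metric] = compare_groups(g, family_size=3)
        report["behavior_young_vs_middle"] = beh
        # one-way ANOVAs of RT and accuracy by age group and MoCA status
        anovas = {}
        for metric in ("mean_rt", "accuracy"):
            vals = merged.dropna(subset=[metric])
            try:
                anovas[f"{metric}_by_age_group"] = anova_by_factor(
                    vals[metric], vals["age_group"])
                anovas[f"{metric}_by_moca_status"] = anova_by_factor(
                    vals[metric], vals["moca_status"])
            except ValueError as exc:
                anovas[f"{metric}_error"] = str(exc)
        report["anovas"] = anovas

    # age trends of the four parameters, per subset
    trends = {}
    if table["age"].notna().all() and len(table) >= 4:
        subsets = {"all": table}
        if have_groups:
            subsets.update({
                "young_and_normal_mid": table[table["group"].isin(["young", "normal_mid"])],
                "young": table[table["group"] == "young"],
                "middle": table[table["group"] != "young"],
                "normal_mid": table[table["group"] == "normal_mid"],
                "mci_mid": table[table["group"] == "mci_mid"],
            })
        for name, sub in subsets.items():
            if len(sub) < 4:
                continue
            trends[name] = {p: age_trend(sub[p], sub["age"], name) for p in params4}
    report["age_trends"] = trends

    # parameter correlation matrices per group
    if have_groups:
        mats = {}
        for g, sub in table.groupby("group"):
            if len(sub) >= 4:
                mats[g] = parameter_correlation_matrix(sub)
        report["parameter_correlations"] = mats

    # learning curves and growth fits
    curves_all = compute_learning_curves(data, by_set_size=True)
    pooled = compute_learning_curves(data, by_set_size=False)
    report["growth_pooled_all"] = fit_logistic_growth(pooled)
    growth_by_group = {}
    subject_growth_rows = []
    if have_groups:
        for g in table["group"].unique():
            members = [d for d in data if d.group == g]
            gc = compute_learning_curves(members, by_set_size=False)
            growth_by_group[g] = fit_logistic_growth(gc)
        for d in data:
            try:
                sc = compute_learning_curves([d], by_set_size=False)
                f = fit_logistic_growth(sc)
                subject_growth_rows.append(
                    {"subject_id": d.subject_id, "group": d.group,
                     "age_group": "young" if d.group == "young" else "middle",
                     "A": f.A, "k": f.k, "degenerate": f.degenerate})
            except (ValueError, RuntimeError):
                continue
        report["growth_by_group"] = growth_by_group
        subject_growth = pd.DataFrame(subject_growth_rows)
        if not subject_growth.empty and subject_growth["age_group"].nunique() == 2 \
                and subject_growth.groupby("age_group").size().min() >= 2:
            report["growth_anova"] = compare_growth_parameters(
                subject_growth, group_col="age_group")
        report["subject_growth"] = subject_growth

        # ratio identity between young and normal middle-aged
        pair = ("young", "normal_mid")
        if all(g in growth_by_group for g in pair) and \
                all((merged["group"] == g).any() for g in pair):
            mean_rt = {g: float(merged.loc[merged["group"] == g, "mean_rt"].mean())
                       for g in pair}
            if all(np.isfinite(v) for v in mean_rt.values()):
                report["ratio_identity"] = ratio_identity(
                    mean_alpha={g: float(table.loc[table["group"] == g, "alpha"].mean()) for g in pair},
                    mean_phi={g: float(table.loc[table["group"] == g, "phi"].mean()) for g in pair},
                    tau={g: 1.0 / growth_by_group[g].k for g in pair},
                    rt=mean_rt, g1=pair[0], g2=pair[1])

        # speed vs accuracy
        report["speed_accuracy"] = speed_accuracy_analysis(
            data, growth_fits=growth_by_group,
            initiation_fraction=config.initiation_fraction)

    # logistic age classifier
    if merged["age"].notna().all() and len(merged) >= 12:
        feat_cols = [f"rt{n}" for n in (2, 3, 4, 5)]
        if merged[feat_cols].notna().all().all():
            report["age_classifier"] = logistic_age_classifier(
                merged, cutoffs=config.classifier_cutoffs, seed=config.seed)

    # RT ~ phi + prior regression per age group
    if have_groups and merged["mean_rt"].notna().all():
        rt_reg = {}
        for label, sub in (("young", table[table["group"] == "young"]),
                           ("middle", table[table["group"] != "young"])):
            if len(sub) >= 4:
                m = merged.set_index("subject_id").loc[sub["subject_id"]]
                rt_reg[label] = rt_parameter_regression(
                    m["mean_rt"].to_numpy(), sub["phi"].to_numpy(),
                    sub["rho"].to_numpy())
        report["rt_regression"] = rt_reg

    # fit quality
    if have_groups and len(fits) >= 3:
        labels = ["young" if d.group == "young" else "middle" for d in data
                  if d.subject_id in fit_map]
        report["fit_quality"] = fit_quality_analysis(
            [fit_map[d.subject_id] for d in data if d.subject_id in fit_map],
            labels)

    report["curves_by_set_size"] = curves_all
    report["curve_pooled"] = pooled
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json(out / "pipeline_config.json", config.to_dict())

    if config.cohort is not None:
        log.info("simulating cohort (%d groups)", len(config.cohort.groups))
        datasets = generate_cohort(config.cohort)
        export_cohort(datasets, config.cohort, out / "cohort")
    elif config.trials_path:
        log.info("loading trials from %s", config.trials_path)
        datasets = load_cohort(config.trials_path, config.subjects_path)
    else:
        raise ValueError("config needs either a cohort spec or a trials_path")

    summaries = [summarize_subject(d) for d in datasets]
    kept, excluded = apply_exclusion(summaries)
    if len(kept) < 2:
        raise RuntimeError("fewer than 2 subjects after exclusion")
    summaries_frame(kept + excluded).to_csv(out / "summaries.csv", index=False)
    kept_ids = {s.subject_id for s in kept}
    kept_data = [d for d in datasets if d.subject_id in kept_ids]
    if any(g.n < 5 for g in (config.cohort.groups if config.cohort else [])):
        log.warning("small group sizes: statistics will be unstable")

    log.info("fitting %d subjects", len(kept_data))
    fits = fit_cohort(kept_data, config.fit, config.seed, jobs=config.jobs)
    write_fit_results(fits, out / "fits.jsonl")
    fit_results_to_frame(fits).to_csv(out / "params.csv", index=False)

    report = _analysis(kept_data, kept, fits, config)
    report["curves_by_set_size"].to_csv(out / "curves.csv", index=False)
    report["curve_pooled"].to_csv(out / "curve_pooled.csv", index=False)
    sg = report.pop("subject_growth", None)
    if sg is not None and not getattr(sg, "empty", True):
        sg.to_csv(out / "subject_growth.csv", index=False)
    _write_json(out / "analysis.json", {
        k: v for k, v in report.items()
        if k not in ("curves_by_set_size", "curve_pooled")})

    manifest = {"version": __version__, "seed": config.seed, "files": {}}
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(out))] = hashlib.sha256(
                f.read_bytes()).hexdigest()
    _write_json(out / "manifest.json", manifest)
    log.info("wrote %d artifacts to %s", len(manifest["files"]), out)
    return report


def make_fixtures(seed: int = 0, out_dir: str | Path = "fixtures") -> list[SubjectDataset]:
    """Tiny deterministic cohort (6 subjects, 3 learning blocks) for tests."""
    cfg = small_cohort_config(seed=seed)
    datasets = generate_cohort(cfg)
    export_cohort(datasets, cfg, out_dir)
    return datasets
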