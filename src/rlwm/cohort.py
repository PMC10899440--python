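"""Synthetic study cohorts: demographics, group-structured RLWM parameters,
simulated choice data, and reaction times.

The generator emulates a 48-subject aging study: a young group (ages 25-40),
a cognitively normal middle-aged group (41-65, MoCA >= 26) and a middle-aged
MCI group (41-65, MoCA 18-25).  Agent parameters are drawn from truncated
normals whose group means encode the reported effect directions and sizes:
relative to the young group, middle-aged subjects have a lower RL learning
rate (standardised difference ~0.56), higher WM decay (~0.54) and higher
lapse noise (~0.44); the MCI group additionally has higher lapse noise than
normal middle-aged (~0.53); the WM prior weight is equal across groups.

Reaction times are generated at the subject level as a linear function of the
WM decay and WM prior parameters (group-specific coefficients), with an
additive per-trial error-response increment and Gaussian noise, clipped to
the 7-second response window.  No response-time process model is attempted:
the agent has no RT likelihood.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .agent import RLWMParams, simulate_agent
from .task import SubjectDataset, TaskConfig, generate_schedule, write_trials

PARAM_SD = 0.15  # common within-group SD of all sampled parameters

#: group means chosen so that realized standardised separations of the
#: truncated-normal draws match the target effect sizes (see docs/methods.md)
GROUP_MEANS = {
    "young":      {"alpha": 0.400, "phi": 0.250, "rho": 0.85, "epsilon": 0.2500},
    "normal_mid": {"alpha": 0.316, "phi": 0.331, "rho": 0.85, "epsilon": 0.3160},
    "mci_mid":    {"alpha": 0.316, "phi": 0.331, "rho": 0.85, "epsilon": 0.3955},
}


@dataclass(frozen=True)
class GroupSpec:
    """Sampling recipe for one cohort group."""

    name: str
    n: int
    age_range: tuple[float, float]
    param_means: dict
    param_sds: dict
    moca_range: tuple[int, int]                 # inclusive
    beta: float = 8.0
    K: int = 3
    rt_intercept: float = 700.0                 # ms
    rt_coef_phi: float = 722.22                 # ms per unit WM decay
    rt_coef_prior: float = 137.07               # ms per unit WM prior
    rt_noise_sd: float = 150.0                  # per-trial ms
    rt_error_increment: float = 100.0           # extra ms on error trials
    age_slope_phi: float = 0.0                  # per year, centred on range midpoint
    age_slope_epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for v in self.param_sds.values():
            if v <= 0:
                raise ValueError("parameter SDs must be positive")
        lo, hi = self.age_range
        if not (18 <= lo <= hi <= 65):
            raise ValueError("age range must lie within 18-65")


def default_group_specs(n_young: int = 22, n_normal: int = 11,
                        n_mci: int = 15) -> list[GroupSpec]:
    """The default three-group cohort (48 subjects at the default sizes)."""
    sds = {k: PARAM_SD for k in ("alpha", "phi", "rho", "epsilon")}
    return [
        GroupSpec(name="young", n=n_young, age_range=(25, 40),
                  param_means=GROUP_MEANS["young"], param_sds=sds,
                  moca_range=(26, 30),
                  rt_intercept=700.0, rt_coef_phi=722.22, rt_coef_prior=137.07),
        GroupSpec(name="normal_mid", n=n_normal, age_range=(41, 65),
                  param_means=GROUP_MEANS["normal_mid"], param_sds=sds,
                  moca_range=(26, 30),
                  rt_intercept=750.0, rt_coef_phi=2355.98, rt_coef_prior=156.34,
                  age_slope_phi=0.002, age_slope_epsilon=0.002),
        GroupSpec(name="mci_mid", n=n_mci, age_range=(41, 65),
                  param_means=GROUP_MEANS["mci_mid"], param_sds=sds,
                  moca_range=(18, 25),
                  rt_intercept=900.0, rt_coef_phi=2355.98, rt_coef_prior=156.34,
                  age_slope_phi=0.002, age_slope_epsilon=0.002),
    ]


@dataclass(frozen=True)
class CohortConfig:
    groups: Sequence[GroupSpec] = field(default_factory=default_group_specs)
    task: TaskConfig = field(default_factory=TaskConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "task": dataclasses.asdict(self.task),
            "groups": [dataclasses.asdict(g) for g in self.groups],
        }


def _truncnorm_draw(mean: float, sd: float, rng: np.random.Generator) -> float:
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_subject(spec: GroupSpec, rng: np.random.Generator):
    """Draw one subject's demographics and agent parameters.

    Age is uniform in the group range; parameters are truncated normals in
    [0, 1]; within middle-aged groups the WM decay and lapse means drift
    linearly with age at the configured slopes (centred on the range
    midpoint, so the group mean is preserved).
    """
    lo, hi = spec.age_range
    age = float(rng.uniform(lo, hi))
    mid = 0.5 * (lo + hi)
    means = dict(spec.param_means)
    means["phi"] = float(np.clip(means["phi"] + spec.age_slope_phi * (age - mid), 0, 1))
    means["epsilon"] = float(np.clip(means["epsilon"] + spec.age_slope_epsilon * (age - mid), 0, 1))
    drawn = {k: _truncnorm_draw(means[k], spec.param_sds[k], rng)
             for k in ("alpha", "phi", "rho", "epsilon")}
    params = RLWMParams(**drawn, beta=spec.beta, K=spec.K)
    moca = int(rng.integers(spec.moca_range[0], spec.moca_range[1] + 1))
    demographics = {"age": age, "moca": moca, "group": spec.name}
    return demographics, params


def generate_reaction_times(params: RLWMParams, spec: GroupSpec,
                            trials: pd.DataFrame,
                            rng: np.random.Generator) -> np.ndarray:
    """Attach RTs: a parameter-determined subject mean, an error increment,
    and per-trial noise, clipped to (0, 7000] ms."""
    subject_mean = (spec.rt_intercept
                    + spec.rt_coef_phi * params.phi
                    + spec.rt_coef_prior * params.rho)
    errors = 1.0 - trials["reward"].fillna(0).to_numpy(dtype=float)
    noise = rng.normal(0.0, spec.rt_noise_sd, size=len(trials)) if spec.rt_noise_sd > 0 \
        else np.zeros(len(trials))
    rt = subject_mean + spec.rt_error_increment * errors + noise
    return np.clip(rt, 1.0, 7000.0)


def generate_cohort(config: CohortConfig) -> list[SubjectDataset]:
    """Sample and simulate every subject; fully reproducible from the seed."""
    ss = np.random.SeedSequence(config.seed)
    datasets: list[SubjectDataset] = []
    idx = 0
    for spec in config.groups:
        for _ in range(spec.n):
            child = ss.spawn(1)[0]
            sched_seed, sim_seed, rt_seed, demo_seed = [
                int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(4)]
            demo, params = sample_subject(spec, np.random.default_rng(demo_seed))
            schedule = generate_schedule(config.task, sched_seed)
            subject_id = f"{spec.name}_{idx:03d}"
            ds = simulate_agent(params, schedule, sim_seed, subject_id=subject_id)
            ds.trials["rt_ms"] = generate_reaction_times(
                params, spec, ds.trials, np.random.default_rng(rt_seed))
            ds.age = demo["age"]
            ds.group = demo["group"]
            ds.moca = demo["moca"]
            datasets.append(ds)
            idx += 1
    return datasets


def subjects_frame(datasets: Sequence[SubjectDataset]) -> pd.DataFrame:
    return pd.DataFrame([{"subject_id": d.subject_id, "age": d.age,
                          "group": d.group, "moca": d.moca} for d in datasets])


def export_cohort(datasets: Sequence[SubjectDataset], config: CohortConfig,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write trials.csv, subjects.csv and the generating config (provenance)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = pd.concat([d.trials for d in datasets], ignore_index=True)
    paths = {
        "trials": out / "trials.csv",
        "subjects": out / "subjects.csv",
        "config": out / "cohort_config.json",
    }
    write_trials(trials, paths["trials"])
    subjects_frame(datasets).to_csv(paths["subjects"], index=False)
    paths["config"].write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True))
    return paths
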