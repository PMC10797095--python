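"""End-to-end orchestration: simulate -> describe -> impute -> fit -> pool.

Every run writes a self-contained directory of text artifacts (CSV/JSON)
plus a manifest recording the resolved configuration, seeds, package
versions and per-stage wall-clock.  A single master seed streams into
per-stage seeds, so re-running a config reproduces every artifact.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cohort as sc
from . import data as dio
from . import descriptives as desc
from . import impute as imp
from . import model as mdl
from . import pooling as pool
from .data import N_SKILLS

log = logging.getLogger("ordmm")

RHAT_FLAG_THRESHOLD = 1.05


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run.

    ``preset`` picks the scale: "full" uses the full study-shaped cohort
    design and the 4 x 5,000 (1,000 warm-up) chain layout; "desk" uses a
    small two-cohort design and short chains for interactive work.
    Explicit ``design``/``mcmc`` objects override the preset.
    """

    out_dir: str
    seed: int = 0
    preset: str = "desk"
    skills: tuple[int, ...] = tuple(range(1, N_SKILLS + 1))
    design: sc.CohortDesign | None = None
    hyper: sc.EffectHyper = field(default_factory=sc.EffectHyper)
    plan: sc.MissingnessPlan | None = None
    imputation: imp.ImputationConfig = field(default_factory=imp.ImputationConfig)
    priors: mdl.Priors = field(default_factory=mdl.Priors)
    mcmc: mdl.McmcConfig | None = None
    dataset_path: str | None = None

    def __post_init__(self):
        if self.preset not in ("full", "desk"):
            raise ValueError("preset must be 'full' or 'desk'")
        if self.design is None:
            self.design = (sc.CohortDesign.default() if self.preset == "full"
                           else sc.CohortDesign.small(60, 8))
        if self.mcmc is None:
            self.mcmc = (mdl.McmcConfig.full_scale() if self.preset == "full"
                         else mdl.McmcConfig.desk())
        if self.plan is None:
            self.plan = (sc.MissingnessPlan.default() if self.preset == "full"
                         else sc.MissingnessPlan(blocks=(("A", 0),), item_rate=0.05))

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        """Build a config from a flat YAML mapping of simple keys."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw: dict = {"out_dir": raw.pop("out_dir")}
        for key in ("seed", "preset", "dataset_path"):
            if key in raw:
                kw[key] = raw.pop(key)
        if "skills" in raw:
            kw["skills"] = tuple(int(s) for s in raw.pop("skills"))
        if {"n_students", "n_courses"} & raw.keys():
            kw["design"] = sc.CohortDesign.small(
                int(raw.pop("n_students", 200)), int(raw.pop("n_courses", 20)))
        hyper_keys = {k: raw.pop(k) for k in ("beta", "sigma_c", "sigma_s")
                      if k in raw}
        if hyper_keys:
            kw["hyper"] = sc.EffectHyper(**hyper_keys)
        imp_keys = {k: raw.pop(k) for k in ("m", "k_donors", "n_cycles") if k in raw}
        if imp_keys:
            kw["imputation"] = imp.ImputationConfig(**imp_keys)
        mcmc_keys = {k: raw.pop(k) for k in ("n_chains", "n_iter", "n_warmup")
                     if k in raw}
        if mcmc_keys:
            kw["mcmc"] = mdl.McmcConfig(**mcmc_keys)
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return RunConfig(**kw)

    def resolved(self) -> dict:
        d = {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "preset": self.preset,
            "skills": list(self.skills),
            "dataset_path": self.dataset_path,
            "hyper": asdict(self.hyper),
            "imputation": asdict(self.imputation),
            "priors": asdict(self.priors),
            "mcmc": asdict(self.mcmc),
            "design": {
                "n_courses": self.design.n_courses,
                "max_courses": self.design.max_courses,
                "cohorts": [
                    {"label": c.label, "n_students": c.n_students,
                     "rows_per_stage": {str(k): v for k, v in c.rows_per_stage.items()}}
                    for c in self.design.cohorts
                ],
            },
            "plan": {"blocks": [list(b) for b in self.plan.blocks],
                     "item_rate": self.plan.item_rate},
        }
        return d


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sub_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run(config: RunConfig) -> Path:
    """Execute every stage and return the run directory.

    Any stage failure aborts with the stage name; artifacts written so far
    are left in place for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    seeds = _sub_seeds(config.seed, 3)
    manifest: dict = {"version": __version__, "config": config.resolved(),
                      "seeds": {"simulate": seeds[0], "impute": seeds[1],
                                "fit": seeds[2]}}

    stage = "simulate"
    t0 = time.perf_counter()
    try:
        if config.dataset_path:
            dataset = dio.read_long_csv(config.dataset_path)
        else:
            gen = sc.generate(config.design, config.hyper, config.plan,
                              seed=seeds[0])
            dataset = gen.dataset
            gen.true_params.to_json(out / "true_params.json")
            (out / "mask.json").write_text(json.dumps({
                "columns": list(gen.mask.columns),
                "rows": gen.mask.to_numpy().astype(int).tolist(),
            }))
        dio.write_long_csv(dataset, out / "dataset.csv")
        violations = dio.validate(dataset)
        dio.write_violations(violations, out / "violations.jsonl")
        if violations:
            raise ValueError(f"{len(violations)} dataset invariant violations")
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageFailure(stage, e) from e
    timings[stage] = time.perf_counter() - t0
    log.info("stage %s done in %.1fs", stage, timings[stage])

    stage = "describe"
    t0 = time.perf_counter()
    try:
        summary = desc.summary_table(dataset)
        summary.to_csv(out / "descriptives.csv", index=False)
        props = {str(i): desc.category_proportions(dataset, i).to_dict("records")
                 for i in config.skills}
        (out / "proportions.json").write_text(json.dumps(props))
    except Exception as e:
        raise StageFailure(stage, e) from e
    timings[stage] = time.perf_counter() - t0
    log.info("stage %s done in %.1fs", stage, timings[stage])

    stage = "impute"
    t0 = time.perf_counter()
    try:
        icfg = imp.ImputationConfig(
            m=config.imputation.m, k_donors=config.imputation.k_donors,
            n_cycles=config.imputation.n_cycles, seed=seeds[1])
        imputed = imp.multiple_impute(dataset, icfg)
        for ds in imputed:
            dio.write_long_csv(ds.dataset, out / f"imputed_{ds.index}.csv")
        (out / "provenance.json").write_text(json.dumps({
            "n_imputed_cells": int(imputed[0].provenance.to_numpy().sum()),
            "m": icfg.m,
        }))
    except Exception as e:
        raise StageFailure(stage, e) from e
    timings[stage] = time.perf_counter() - t0
    log.info("stage %s done in %.1fs", stage, timings[stage])

    stage = "fit"
    t0 = time.perf_counter()
    fits_by_skill: dict[int, list[mdl.PosteriorFit]] = {}
    try:
        fit_seeds = _sub_seeds(seeds[2], len(config.skills) * icfg.m)
        k = 0
        for skill in config.skills:
            fits_by_skill[skill] = []
            for ds in imputed:
                data = dio.to_model_inputs(ds.dataset, skill)
                fit = mdl.fit(data, config.priors, config.mcmc,
                              seed=fit_seeds[k], imputation=ds.index)
                fits_by_skill[skill].append(fit)
                fname = out / f"fit_skill{skill}_imp{ds.index}.csv"
                fit.summary.to_csv(fname, index=False)
                log.info("fitted skill %d imputation %d (max rhat %.3f)",
                         skill, ds.index, fit.max_rhat)
                k += 1
    except Exception as e:
        raise StageFailure(stage, e) from e
    timings[stage] = time.perf_counter() - t0

    stage = "pool"
    t0 = time.perf_counter()
    try:
        table = pool.pooled_effect_table(fits_by_skill)
        table.to_csv(out / "pooled_table.csv", index=False)
        u_cols = {s: pool.course_effect_estimates(f)
                  for s, f in fits_by_skill.items()}
        u_mat = np.column_stack([u_cols[s] for s in sorted(u_cols)])
        pd.DataFrame(u_mat,
                     columns=[f"skill_{s}" for s in sorted(u_cols)]).to_csv(
            out / "course_effects.csv", index=False)
        if len(config.skills) >= 2 and u_mat.shape[0] >= 3:
            corr = pool.cross_skill_correlation(u_mat)
            pd.DataFrame(corr,
                         index=[f"skill_{s}" for s in sorted(u_cols)],
                         columns=[f"skill_{s}" for s in sorted(u_cols)]).to_csv(
                out / "correlation.csv")
        densities = {}
        for s in sorted(u_cols):
            vals = u_cols[s]
            if np.std(vals) > 0 and len(vals) >= 2:
                grid, dens = pool.effect_density(vals)
                densities[str(s)] = {"grid": grid.tolist(),
                                     "density": dens.tolist()}
        (out / "density.json").write_text(json.dumps(densities))
    except Exception as e:
        raise StageFailure(stage, e) from e
    timings[stage] = time.perf_counter() - t0

    manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    manifest["n_fits"] = sum(len(v) for v in fits_by_skill.values())
    manifest["expected_fits"] = len(config.skills) * icfg.m
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


REQUIRED_ARTIFACTS = ("dataset.csv", "descriptives.csv", "pooled_table.csv",
                      "manifest.json")


def report(run_dir: str | Path) -> str:
    """Human-readable pooled summary of a completed run.

    Lists per-skill pooled effects with odds and ~95% course-effect ranges
    and flags any fit whose maximum split R-hat exceeds the threshold; an
    incomplete run is reported by its missing artifacts.
    """
    run_dir = Path(run_dir)
    missing = [a for a in REQUIRED_ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        return "INCOMPLETE RUN - missing artifacts: " + ", ".join(missing)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    table = pd.read_csv(run_dir / "pooled_table.csv")
    lines = [f"ordmm run {run_dir.name} (seed {manifest['config']['seed']}, "
             f"preset {manifest['config']['preset']})",
             f"fits: {manifest['n_fits']} (expected "
             f"{manifest['expected_fits']})"]
    if manifest["n_fits"] != manifest["expected_fits"]:
        lines.append("WARNING: fit count does not match skills x imputations")
    for _, row in table.iterrows():
        flag = "  [CONVERGENCE FLAG]" if row["max_rhat"] > RHAT_FLAG_THRESHOLD else ""
        lines.append(
            f"skill {int(row['skill'])}: beta={row['beta']:+.3f} "
            f"(total SE {row['total_se']:.3f}), odds={row['odds']:.2f}, "
            f"95% course-effect range [{row['effect_lower_95']:+.3f}, "
            f"{row['effect_upper_95']:+.3f}], sigma_c={row['sigma_c']:.3f}, "
            f"sigma_s={row['sigma_s']:.3f}, max rhat={row['max_rhat']:.3f}{flag}"
        )
    return "\n".join(lines)
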