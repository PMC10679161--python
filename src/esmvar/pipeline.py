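"""End-to-end orchestration: simulate/ingest -> filter -> grid -> fit -> report.

``run_pipeline`` executes the full analysis under a single master seed and
writes every artifact (descriptives, effect tables, correlation table,
convergence reports, manifest) to an output directory. Stage seeds are
derived from the master seed with ``numpy.random.SeedSequence(master,
spawn_key=(stage,))`` so stages are individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import EsmDataset
from .design import build_time_grid, completion_stats, exclusion_filter, lag_pairs
from .model import (SMOKE_SAMPLER, SamplerSettings, convergence, fit,
                    gender_moderation, specify_model)
from .params import bivariate_study_params, trivariate_study_params
from .postprocess import between_correlations, effect_table, within_r2
from .synthetic import simulate_study

log = logging.getLogger("esmvar.pipeline")

_STAGES = ("simulate", "fit_model1", "fit_model2", "moderation")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    output_dir: str
    seed: int
    n_persons: int = 134
    n_days: int = 6
    prompts_per_day: int = 10
    waking_minutes: int = 780
    min_gap: int = 15
    interval_minutes: float = 60.0
    min_fraction: float = 1.0 / 3.0
    scenario: str = "trivariate"      # synthetic scenario, or "csv"
    esm_csv: str | None = None        # used when scenario == "csv"
    baseline_csv: str | None = None
    run_model1: bool = True
    run_model2: bool = True
    run_moderation: bool = False
    sampler: SamplerSettings = field(default_factory=lambda: SMOKE_SAMPLER)

    def __post_init__(self):
        if self.scenario not in ("bivariate", "trivariate", "csv"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "csv":
            for p in (self.esm_csv, self.baseline_csv):
                if p is None or not Path(p).exists():
                    raise ValueError(f"csv input not resolvable: {p}")
        if self.seed is None:
            raise ValueError("a master seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sampler = raw.pop("sampler", None)
        cfg = cls(**raw)
        if sampler:
            cfg.sampler = SamplerSettings(**sampler)
        return cfg

    def stage_seed(self, stage: str) -> int:
        key = _STAGES.index(stage)
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return int(ss.generate_state(1)[0] % (2 ** 31))

    def config_hash(self) -> str:
        payload = {k: (v if not isinstance(v, SamplerSettings) else vars(v))
                   for k, v in vars(self).items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def describe_sample(data: EsmDataset, baseline: pd.DataFrame) -> pd.DataFrame:
    """Sample-characteristics table: n (%) for categoricals, M (SD) otherwise.

    ``baseline`` must cover every person in the dataset (rows are joined on
    ``person_id``; orphan persons raise).
    """
    persons = pd.Index(data.scheduled.index, name="person_id")
    tab = baseline.set_index("person_id")
    orphans = persons.difference(tab.index)
    if len(orphans):
        raise ValueError(f"baseline table lacks persons {list(orphans[:5])}")
    tab = tab.loc[persons]
    rows = [("N", float(len(tab)), "count")]
    for col in tab.columns:
        series = tab[col]
        if series.nunique() <= 4 and not np.issubdtype(series.dtype, np.floating):
            for value, cnt in series.value_counts().sort_index().items():
                rows.append((f"{col}={value}",
                             round(100.0 * cnt / len(tab), 1), "n (%)"))
        else:
            rows.append((f"{col} mean", float(series.mean()), "M"))
            rows.append((f"{col} sd", float(series.std(ddof=1)), "SD"))
    return pd.DataFrame(rows, columns=["characteristic", "value", "kind"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order; return the manifest (also written to disk).

    Identical config and seed give byte-identical table artifacts. On a
    stage failure the artifacts written so far are moved under ``failed/``
    and the error re-raised with the stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {}
    timings: dict = {}
    clock = {"stage": "input", "t": time.perf_counter()}

    def enter_stage(name: str) -> str:
        now = time.perf_counter()
        timings[clock["stage"]] = round(
            timings.get(clock["stage"], 0.0) + now - clock["t"], 3)
        log.info(json.dumps({"stage": name, "event": "start"}))
        clock["stage"], clock["t"] = name, now
        return name

    def save_df(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.6g")
        written.append(path)

    def save_json(obj, name: str) -> None:
        path = out / name
        path.write_text(json.dumps(obj, indent=1, default=str))
        written.append(path)

    stage = "input"
    try:
        # ----- data ---------------------------------------------------
        if config.scenario == "csv":
            baseline = pd.read_csv(config.baseline_csv)
            raw = pd.read_csv(config.esm_csv)
            variables = [c for c in ("social_anxiety", "paranoia", "loneliness")
                         if c in raw.columns]
            sched = pd.Series(config.n_days * config.prompts_per_day,
                              index=pd.Index(sorted(raw["person_id"].unique()),
                                             name="person_id"))
            data = EsmDataset(raw, tuple(variables), sched)
            params = None
        else:
            stage = enter_stage("simulate")
            params = (trivariate_study_params() if config.scenario == "trivariate"
                      else bivariate_study_params())
            data, effects = simulate_study(
                params, n_persons=config.n_persons, n_days=config.n_days,
                prompts_per_day=config.prompts_per_day,
                waking_minutes=config.waking_minutes, min_gap=config.min_gap,
                seed=config.stage_seed("simulate"),
            )
            baseline = effects.baseline_table()
            data.to_csv(out / "esm_long.csv")
            written.append(out / "esm_long.csv")
            save_df(effects.table, "true_person_effects.csv")

        # ----- filter + descriptives ----------------------------------
        stage = enter_stage("filter")
        if data.n_persons < 10:
            log.warning("small sample: %d persons; between-level estimates "
                        "will be unstable", data.n_persons)
        kept, report = exclusion_filter(data, config.min_fraction)
        save_json(report, "exclusion_report.json")
        stats = completion_stats(kept)
        save_json(stats.as_dict(), "completion_stats.json")
        save_df(describe_sample(kept, baseline), "sample_descriptives.csv")
        summary["n_persons"] = kept.n_persons
        summary["total_entries"] = stats.total_entries
        summary["mean_completion_rate"] = stats.mean_rate

        # ----- grid ---------------------------------------------------
        stage = enter_stage("grid")
        grid = build_time_grid(kept, config.interval_minutes)
        save_df(grid.to_wide_frame(), "grid_wide.csv")
        save_df(grid.collisions, "grid_collisions.csv")
        summary["lag_pairs"] = int(lag_pairs(grid).sum())

        # ----- models -------------------------------------------------
        model_specs = []
        if config.run_model1:
            model_specs.append(("model1", ("social_anxiety", "paranoia"), ()))
        if config.run_model2 and len(data.variables) >= 3:
            model_specs.append(
                ("model2",
                 ("social_anxiety", "paranoia", "loneliness"), ("schemas",)))
        for name, variables, covs in model_specs:
            stage = enter_stage(f"fit_{name}")
            spec = specify_model(variables, covariates=covs,
                                 settings=config.sampler,
                                 available_columns=data.variables)
            post = fit(grid, spec, baseline=baseline,
                       seed=config.stage_seed(f"fit_{name}"))
            table = effect_table(post)
            save_df(table.table, f"{name}_effects.csv")
            save_df(within_r2(post), f"{name}_r2.csv")
            save_json(convergence(post).as_dict(), f"{name}_convergence.json")
            if "schemas" in covs:
                corr = between_correlations(post)
                save_df(corr.table, f"{name}_schema_correlations.csv")
            summary[f"{name}_worst_psr"] = convergence(post).worst_psr
            if config.run_moderation and "gender" in baseline.columns:
                stage = enter_stage(f"moderation_{name}")
                mod, _ = gender_moderation(
                    grid, spec, baseline,
                    seed=config.stage_seed("moderation"))
                save_df(mod.table, f"{name}_gender_moderation.csv")
    except Exception as err:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for path in written:
            path.rename(failed / path.name)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    enter_stage("done")  # flush the last stage's timing
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in _STAGES},
        "stage_seconds": timings,
        "summary": summary,
        "artifacts": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
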