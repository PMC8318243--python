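"""End-to-end pipeline runner with reproducibility bookkeeping.

A run is driven by a serializable :class:`RunConfig` (YAML on disk).  One
master seed fans out deterministically to per-stage seeds via hashed seed
sequences, so every stochastic stage is independently reproducible.  Each run
writes a manifest (config echo, derived seeds, package version, per-stage
timings and failure point) next to its outputs.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from . import __version__
from .core import ConfigError, filter_cohort, load_cohort
from .evaluation import build_marker_graph, make_cv_plan, run_cv
from .outcome import TSDefinition, derive_ts, select_ts_definition
from .simulation import pooled_simulation, reallocation_matrix
from .synthetic import InteractionSpec, SurvivalSpec, SyntheticConfig, generate_cohort
from .training import MultSettings


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from one master seed."""
    h = np.random.SeedSequence(
        [int(master), *(ord(ch) for ch in stage)])
    return int(h.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Everything needed to reproduce a full run."""

    # data source: either per-table paths, or a synthetic generator spec
    clinical_path: str | None = None
    expression_path: str | None = None
    treatment_path: str | None = None
    response_path: str | None = None
    survival_path: str | None = None
    synthetic: dict | None = None

    pipeline: str = "mult"
    alpha: float = 0.05
    beta: float = 0.75
    n_folds: int = 10
    seed: int = 0
    simulate: bool = True
    ts_cut_index: int | None = None   # skip TS-definition search when set
    min_treatment_n: int = 10
    max_missing_frac: float = 0.10
    settings: dict = field(default_factory=dict)  # MultSettings overrides
    fast: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_settings(self) -> MultSettings:
        s = MultSettings.fast() if self.fast else MultSettings()
        s.alpha, s.beta = self.alpha, self.beta
        for k, v in self.settings.items():
            if not hasattr(s, k):
                raise ConfigError(f"unknown settings key {k!r}")
            setattr(s, k, v)
        return s

    def build_synthetic_config(self) -> SyntheticConfig:
        spec = dict(self.synthetic or {})
        if "interaction" in spec and spec["interaction"] is not None:
            spec["interaction"] = InteractionSpec(**spec["interaction"])
        if "survival" in spec and spec["survival"] is not None:
            spec["survival"] = SurvivalSpec(**spec["survival"])
        spec.setdefault("seed", derive_seed(self.seed, "synthetic"))
        return SyntheticConfig(**spec)


def run_full(config: RunConfig, out_dir) -> Path:
    """Execute load -> filter -> TS definition -> CV -> simulation.

    Returns the output directory; a ``manifest.json`` records seeds, timings
    and, on error, the failing stage with partial outputs preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": asdict(config),
                "seeds": {}, "timings": {}, "status": "running"}

    def save_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))

    stage = "validate"
    try:
        t0 = time.time()
        if config.synthetic is None:
            for name in ("clinical_path", "expression_path",
                         "treatment_path", "response_path"):
                p = getattr(config, name)
                if p is None or not Path(p).exists():
                    raise ConfigError(f"{name} missing or does not exist: {p}")

        stage = "load"
        if config.synthetic is not None:
            syn = config.build_synthetic_config()
            manifest["seeds"]["synthetic"] = syn.seed
            cohort, truth = generate_cohort(syn)
            cohort.write(out / "cohort")
            truth.write(out / "cohort")
        else:
            cohort = load_cohort(config.clinical_path, config.expression_path,
                                 config.treatment_path, config.response_path,
                                 config.survival_path)
        manifest["timings"]["load"] = time.time() - t0

        stage = "filter"
        t0 = time.time()
        cohort, flog = filter_cohort(cohort, config.min_treatment_n,
                                     config.max_missing_frac)
        flog.to_csv(out / "filter_log.tsv", sep="\t", index=False)
        manifest["timings"]["filter"] = time.time() - t0

        stage = "ts_define"
        t0 = time.time()
        if config.ts_cut_index is not None:
            definition = TSDefinition(cut_index=config.ts_cut_index)
        elif cohort.ddp_days is not None:
            definition = select_ts_definition(
                cohort.response, cohort.ddp_days, cohort.ddp_event)
        else:
            definition = TSDefinition()  # default: CR/SCR sensitive
        cohort = cohort.with_ts(derive_ts(cohort.response, definition))
        (out / "ts_definition.json").write_text(json.dumps({
            "classes": definition.classes,
            "cut_index": definition.cut_index,
            "sensitive_classes": definition.sensitive_classes,
            "pvalues": {str(k): v for k, v in definition.pvalues.items()},
        }, indent=2))
        manifest["timings"]["ts_define"] = time.time() - t0

        stage = "cv"
        t0 = time.time()
        cv_seed = derive_seed(config.seed, "cv")
        manifest["seeds"]["cv"] = cv_seed
        plan = make_cv_plan(cohort, config.n_folds, seed=cv_seed)
        result = run_cv(cohort, plan, pipeline=config.pipeline,
                        seed=derive_seed(config.seed, "train"),
                        settings=config.to_settings())
        result.fold_metrics.to_csv(out / "fold_metrics.tsv", sep="\t", index=False)
        result.per_treatment.to_csv(out / "per_treatment_metrics.tsv",
                                    sep="\t", index=False)
        result.scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        (out / "pooled_metrics.json").write_text(
            json.dumps(result.pooled, indent=2, default=float))
        if result.reports:
            graph = build_marker_graph(result.reports)
            nx.write_graphml(graph, out / "marker_graph.graphml")
        manifest["timings"]["cv"] = time.time() - t0
        manifest["cv_failures"] = result.failures

        if config.simulate and config.pipeline == "mult" and result.predictors:
            stage = "simulate"
            t0 = time.time()
            kept = cohort.subset(list(plan.fold.index))
            sim = pooled_simulation(result.predictors, kept, plan)
            sim.write(out / "simulation.tsv")
            reallocation_matrix(sim).to_csv(out / "reallocation_matrix.tsv",
                                            sep="\t")
            manifest["switch_fraction"] = sim.switch_fraction
            manifest["timings"]["simulate"] = time.time() - t0

        manifest["status"] = "ok"
        manifest["pooled"] = result.pooled
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        save_manifest()
        raise
    save_manifest()
    return out
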