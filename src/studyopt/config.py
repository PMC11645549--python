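"""YAML run configuration: schema, defaults, and builders.

The config has four blocks — design_space, query, schedule, evaluator —
plus a master seed and an output directory.  Unknown keys are rejected,
and every defaulted value is echoed explicitly when the resolved config is
written back, so a run directory always records the exact settings used.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .optimizer import Schedule, ScoreConfig
from .space import DesignSpace, VariableSpec
from .synthetic import (
    CohortParams,
    DetectionModel,
    EvaluatorConfig,
    MultiplicativeCostSpec,
    SyntheticEvaluator,
    TumorParams,
    default_design_space,
)


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class VariableConfig(_Strict):
    name: str
    type: Literal["continuous", "integer", "categorical", "boolean"]
    lower: Optional[float] = None
    upper: Optional[float] = None
    levels: Optional[list] = None

    def to_spec(self) -> VariableSpec:
        levels = tuple(self.levels) if self.levels is not None else None
        return VariableSpec(self.name, self.type, self.lower, self.upper, levels)


class QueryConfig(_Strict):
    objective: Literal[
        "mutation_discovery", "costed_discovery", "sv_rate",
        "power_threshold", "cohort_recall",
    ] = "mutation_discovery"
    lam: float = 0.0
    threshold: float = 0.33
    oriented: bool = True
    max_cost: Optional[float] = None  # hard budget b on the query's cost g


class ScheduleConfig(_Strict):
    M: int = 150
    n0: int = 30
    nj: int = 20
    e0: float = 0.5
    taper_e: float = 0.8
    e_min: float = 0.05
    delta0: float = 0.1
    taper_delta: float = 0.9
    delta_min: float = 1e-3
    alpha_g: float = 0.1
    taper_g: float = 0.9
    alpha_g_min: float = 1e-3
    alpha_v: float = 1.0
    pool_size: int = 200
    gamma: float = 0.05
    ball_fraction: float = 0.05
    mesh_share: float = 0.5
    patience: int = 5
    improvement_tol: Optional[float] = None
    maximin_iterations: int = 200

    def to_schedule(self) -> Schedule:
        return Schedule(**self.model_dump())


class CostSpecConfig(_Strict):
    linear: dict[str, float] = {}
    interactions: list[tuple[str, str, float]] = []


class EvaluatorBlock(_Strict):
    kind: Literal["synthetic"] = "synthetic"
    tumor: dict = {}
    detection: dict = {}
    cohort: dict = {}
    cohort_n_train: int = 10
    cohort_n_test: int = 7
    cohort_seed: int = 20240
    cost_spec: Optional[CostSpecConfig] = None

    @model_validator(mode="after")
    def _check_fields(self):
        for block, cls in (
            (self.tumor, TumorParams),
            (self.detection, DetectionModel),
            (self.cohort, CohortParams),
        ):
            known = {f.name for f in dataclasses.fields(cls)}
            bad = set(block) - known
            if bad:
                raise ValueError(f"unknown {cls.__name__} key(s): {sorted(bad)}")
        return self


class RunConfig(_Strict):
    seed: int = 0
    output_dir: str = "studyopt_out"
    design_space: Optional[list[VariableConfig]] = None  # None -> default space
    query: QueryConfig = QueryConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    evaluator: EvaluatorBlock = EvaluatorBlock()


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected with
    an error naming every offending key."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError("invalid run config:\n" + "\n".join(lines)) from exc


def dump_config(cfg: RunConfig, path) -> None:
    """Write the fully resolved config (all defaults made explicit)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_space(cfg: RunConfig) -> DesignSpace:
    if cfg.design_space is None:
        return default_design_space()
    return DesignSpace([v.to_spec() for v in cfg.design_space])


def build_evaluator(cfg: RunConfig) -> SyntheticEvaluator:
    ev_cfg = EvaluatorConfig(
        tumor=TumorParams(**cfg.evaluator.tumor),
        detection=DetectionModel(**cfg.evaluator.detection),
        cohort=CohortParams(**cfg.evaluator.cohort),
        cohort_n_train=cfg.evaluator.cohort_n_train,
        cohort_n_test=cfg.evaluator.cohort_n_test,
        cohort_seed=cfg.evaluator.cohort_seed,
        lam=cfg.query.lam,
        threshold=cfg.query.threshold,
        oriented=cfg.query.oriented,
    )
    if cfg.evaluator.cost_spec is not None:
        ev_cfg.cost_spec = MultiplicativeCostSpec(
            linear=dict(cfg.evaluator.cost_spec.linear),
            interactions=[tuple(t) for t in cfg.evaluator.cost_spec.interactions],
        )
    return SyntheticEvaluator(cfg.query.objective, ev_cfg)


def build_score_config(cfg: RunConfig, evaluator: SyntheticEvaluator) -> ScoreConfig:
    budget_fn, budget = None, None
    if cfg.query.max_cost is not None:
        cost_fn = evaluator.cost_fn()
        if cost_fn is None:
            raise ConfigError(
                f"query {cfg.query.objective!r} has zero cost; max_cost budget "
                "is not applicable"
            )
        budget_fn, budget = cost_fn, cfg.query.max_cost
    return evaluator.score_config(budget_fn=budget_fn, budget=budget)


CONFIG_TEMPLATE = """\
# studyopt run configuration
seed: 1
output_dir: studyopt_out

# Omit design_space entirely to use the standard somatic sequencing space
# (samples, single_cells, read_length, fragment_length, coverage,
#  error_rate, paired, whole_genome, informatics).
# design_space:
#   - {name: coverage, type: integer, lower: 1, upper: 100}
#   - {name: error_rate, type: continuous, lower: 0.0, upper: 0.1}
#   - {name: informatics, type: categorical, levels: [callerA, callerB]}

query:
  # one of: mutation_discovery, costed_discovery, sv_rate,
  #         power_threshold, cohort_recall
  objective: mutation_discovery
  lam: 0.0          # cost-prioritization weight in score = lam*g + loss
  threshold: 0.33   # power_threshold central-band half-width
  oriented: true    # report recall-like losses as 1 - recall
  # max_cost: 0.8   # hard budget b on the query's cost g (f(x) <= b)

schedule:
  M: 150        # total evaluation budget
  n0: 30        # initial maximin Latin hypercube size
  nj: 20        # batch size per round
  e0: 0.5       # initial exploration coefficient (tapered by taper_e)
  alpha_v: 1.0  # LCB exploration weight
  patience: 5   # rounds without significant improvement before stopping

evaluator:
  kind: synthetic
  # tumor:     {snv_mean: 100.0, sv_mean: 30.0, n_subclones: 5}
  # detection: {p_max: 0.95, coverage_half: 20.0, caller_fail_prob: 0.0}
  # cohort:    {variants_mean: 40.0, coverage_half: 5.0}
"""


def write_template(path) -> None:
    Path(path).write_text(CONFIG_TEMPLATE)
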