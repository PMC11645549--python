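"""The outer active-learning loop.

Round 0 evaluates a feasible maximin Latin hypercube.  Each later round
refits the score surrogate, proposes ⌊e_j·n_j⌋ LCB-exploration candidates,
n_m mesh-search candidates around the incumbent and n_g surrogate-gradient
steps from the lowest-scoring evaluated designs, evaluates them, and tapers
the exploration coefficient, mesh fineness and gradient step.  The loop
stops on budget exhaustion or after ``patience`` rounds without a
significant score improvement.  Every stochastic sub-step is seeded from
the master seed; per-design evaluation seeds derive from
(master seed, round, index), so runs are reproducible regardless of how
the evaluator parallelizes a batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .sampling import InfeasibleDesignSpace, _is_feasible, feasible_fill, frame_row_to_design, maximin_improve
from .search import (
    AcquisitionConfig,
    GradientConfig,
    MeshState,
    gradient_step,
    mesh_search_batch,
    select_exploration_batch,
)
from .space import DesignSpace, StudyDesign
from .surrogate import FitConfig, GPModel, fit_gp


@dataclass
class Schedule:
    """Evaluation budget and per-round batch composition.

    Each round's n_j points split into ⌊e_j·n_j⌋ exploration picks and an
    exploitation remainder divided between mesh search (n_m) and gradient
    descent (n_g = n_j − ⌊e_j·n_j⌋ − n_m).  e_j, Δ_j and α_g decay by their
    taper factors after every round, clipped at configured minima.
    """

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
    improvement_tol: float | None = None
    maximin_iterations: int = 200
    replicates: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.e0 <= 1:
            raise ValueError("e0 must lie in [0, 1]")
        if self.M < self.n0:
            raise ValueError("evaluation budget M must cover the initial sample n0")
        if self.nj < 1:
            raise ValueError("nj must be at least 1")

    def batch_composition(self, e_j: float) -> tuple[int, int, int]:
        """(n_explore, n_mesh, n_gradient) for one round."""
        n_explore = math.floor(e_j * self.nj)
        n_exploit = self.nj - n_explore
        n_mesh = int(round(self.mesh_share * n_exploit))
        n_grad = n_exploit - n_mesh
        assert n_grad >= 0
        return n_explore, n_mesh, n_grad


class ScoreConfig:
    """Score definition: score(x) = λ·g(x) + L_q(x), subject to f(x) ≤ b."""

    def __init__(
        self,
        lam: float = 0.0,
        cost_fn=None,
        budget_fn=None,
        budget=None,
        cost_is_closed_form: bool = True,
        failure_loss: float | None = None,
    ):
        if lam < 0:
            raise ValueError("lambda must be nonnegative")
        self.lam = lam
        self.cost_fn = cost_fn
        self.budget_fn = budget_fn
        self.budget = budget
        self.cost_is_closed_form = cost_is_closed_form
        self.failure_loss = failure_loss

    def cost(self, x: StudyDesign) -> float:
        return 0.0 if self.cost_fn is None else float(self.cost_fn(x))

    def score(self, x: StudyDesign, loss: float) -> float:
        return self.lam * self.cost(x) + loss


@dataclass
class EvaluationRecord:
    """One evaluated design: loss, cost, score, round and realization seed."""

    design: StudyDesign
    loss: float
    cost: float
    score: float
    round: int
    instance_seed: int


@dataclass
class OptimizationState:
    space: DesignSpace
    schedule: Schedule
    score_cfg: ScoreConfig
    seed: int
    round: int = 0
    history: list[EvaluationRecord] = field(default_factory=list)
    surrogate: GPModel | None = None
    mesh: MeshState | None = None
    e_j: float = 0.5
    delta_j: float = 0.1
    alpha_g_j: float = 0.1
    best_by_round: list[float] = field(default_factory=list)
    stop_reason: str | None = None

    @property
    def n_evaluations(self) -> int:
        return len(self.history)

    @property
    def best_record(self) -> EvaluationRecord:
        if not self.history:
            raise RuntimeError("no evaluations yet")
        return min(self.history, key=lambda r: r.score)

    @property
    def best_queue(self) -> list[EvaluationRecord]:
        return sorted(self.history, key=lambda r: (r.score, r.cost))


def design_seed(master_seed: int, round_idx: int, index: int) -> int:
    """Deterministic per-design realization seed from (master, round, index)."""
    ss = np.random.SeedSequence([master_seed, round_idx, index])
    return int(ss.generate_state(1)[0] % (2**31))


def _evaluate(
    state: OptimizationState,
    evaluator: Callable,
    designs: Sequence[StudyDesign],
    round_idx: int,
) -> None:
    if not designs:
        return
    cfg = state.score_cfg
    seeds = [design_seed(state.seed, round_idx, i) for i in range(len(designs))]
    losses = list(evaluator(list(designs), seeds))
    if len(losses) != len(designs):
        raise RuntimeError("evaluator returned a wrong-length loss batch")
    for x, loss, s in zip(designs, losses, seeds):
        loss = float(loss)
        if not np.isfinite(loss):
            if cfg.failure_loss is None:
                raise RuntimeError(f"evaluator returned non-finite loss for {x!r}")
            loss = float(cfg.failure_loss)
        cost = cfg.cost(x)
        state.history.append(
            EvaluationRecord(
                design=x, loss=loss, cost=cost,
                score=cfg.lam * cost + loss, round=round_idx, instance_seed=s,
            )
        )


class _CompositeSurrogate:
    """T̂ = λ·ĝ + L̂ for queries whose cost lacks a closed form."""

    def __init__(self, loss_model: GPModel, cost_model: GPModel, lam: float):
        self.loss_model = loss_model
        self.cost_model = cost_model
        self.lam = lam

    def predict(self, designs):
        ml, vl = self.loss_model.predict(designs)
        mg, vg = self.cost_model.predict(designs)
        return ml + self.lam * mg, vl + self.lam**2 * vg


def _fit_surrogate(state: OptimizationState, fit_seed: int) -> None:
    X = [r.design for r in state.history]
    if state.score_cfg.cost_is_closed_form:
        y = [r.score for r in state.history]
        state.surrogate = fit_gp(state.space, X, y, FitConfig(), seed=fit_seed)
    else:
        loss_model = fit_gp(
            state.space, X, [r.loss for r in state.history], FitConfig(), seed=fit_seed
        )
        cost_model = fit_gp(
            state.space, X, [r.cost for r in state.history], FitConfig(), seed=fit_seed + 1
        )
        state.surrogate = _CompositeSurrogate(loss_model, cost_model, state.score_cfg.lam)


def check_stopping(state: OptimizationState) -> str:
    """'budget_exhausted', 'stalled' or 'continue'."""
    if state.n_evaluations >= state.schedule.M:
        return "budget_exhausted"
    tol = state.schedule.improvement_tol
    if tol is None:
        scores = [r.score for r in state.history]
        spread = (max(scores) - min(scores)) if scores else 0.0
        tol = 1e-3 * spread if spread > 0 else 1e-9
    best = state.best_by_round
    if len(best) > state.schedule.patience:
        recent = best[-(state.schedule.patience + 1) :]
        if recent[0] - min(recent[1:]) < tol:
            return "stalled"
    return "continue"


def update_schedule(state: OptimizationState) -> OptimizationState:
    """Taper e_j, Δ_j and α_g multiplicatively, clipped at their minima."""
    s = state.schedule
    state.e_j = max(s.e_min, s.taper_e * state.e_j)
    state.delta_j = max(s.delta_min, s.taper_delta * state.delta_j)
    state.alpha_g_j = max(s.alpha_g_min, s.taper_g * state.alpha_g_j)
    return state


def run_optimization(
    space: DesignSpace,
    evaluator: Callable,
    score_cfg: ScoreConfig,
    schedule: Schedule,
    seed: int,
    log: Callable[[str], None] | None = None,
) -> OptimizationState:
    """Run the full loop and return the final state.

    ``evaluator(designs, seeds)`` must return one stochastic loss per
    design; determinism under ``seed`` requires the evaluator to honor the
    per-design seeds.
    """
    state = OptimizationState(
        space=space, schedule=schedule, score_cfg=score_cfg, seed=seed,
        e_j=schedule.e0, delta_j=schedule.delta0, alpha_g_j=schedule.alpha_g,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11CE]))

    try:
        init = feasible_fill(
            space, schedule.n0, score_cfg.budget_fn, score_cfg.budget,
            seed=int(rng.integers(2**31)),
        )
    except InfeasibleDesignSpace as exc:
        raise InfeasibleDesignSpace(f"initialization infeasible: {exc}") from exc
    init = maximin_improve(
        init, schedule.maximin_iterations, int(rng.integers(2**31)),
        score_cfg.budget_fn, score_cfg.budget,
    )
    _evaluate(state, evaluator, init.rows, round_idx=0)
    state.best_by_round.append(state.best_record.score)
    if log:
        log(f"round 0: {state.n_evaluations} evals, best score {state.best_by_round[-1]:.6g}")

    while True:
        reason = check_stopping(state)
        if reason != "continue":
            state.stop_reason = reason
            break
        state.round += 1
        _fit_surrogate(state, fit_seed=int(rng.integers(2**31)))
        n_explore, n_mesh, n_grad = schedule.batch_composition(state.e_j)
        remaining = schedule.M - state.n_evaluations
        proposals: list[StudyDesign] = []

        if n_explore > 0:
            acq = AcquisitionConfig(alpha_v=schedule.alpha_v, pool_size=schedule.pool_size)
            proposals += select_exploration_batch(
                state.surrogate, space, n_explore, acq,
                score_cfg.budget_fn, score_cfg.budget, seed=int(rng.integers(2**31)),
            )

        best = state.best_record.design
        state.mesh = MeshState(center=best, delta=state.delta_j, round=state.round)
        if n_mesh > 0:
            mesh_batch, state.mesh = mesh_search_batch(
                space, state.mesh, n_mesh, score_cfg.budget_fn, score_cfg.budget,
                seed=int(rng.integers(2**31)), ball_fraction=schedule.ball_fraction,
            )
            state.delta_j = state.mesh.delta
            proposals += mesh_batch

        if n_grad > 0:
            grad_cfg = GradientConfig(gamma=schedule.gamma, alpha_g=state.alpha_g_j)
            starts: list[StudyDesign] = []
            seen = set()
            for rec in state.best_queue:
                if rec.design.key() not in seen:
                    seen.add(rec.design.key())
                    starts.append(rec.design)
                if len(starts) == n_grad:
                    break
            for x0 in starts:
                cand, moved = gradient_step(
                    state.surrogate, space, x0, grad_cfg,
                    score_cfg.budget_fn, score_cfg.budget,
                )
                if moved:
                    proposals.append(cand)

        proposals = proposals[:remaining]
        # contract: nothing infeasible is ever evaluated
        proposals = [x for x in proposals if _is_feasible(score_cfg.budget_fn, score_cfg.budget, x)]
        _evaluate(state, evaluator, proposals, round_idx=state.round)
        state.best_by_round.append(state.best_record.score)
        update_schedule(state)
        if log:
            log(
                f"round {state.round}: {state.n_evaluations} evals, "
                f"best score {state.best_by_round[-1]:.6g}"
            )
    return state


def best_designs(
    state: OptimizationState, k: int
) -> list[tuple[StudyDesign, float, int]]:
    """Top-k designs by mean observed score (ascending); repeat evaluations
    of one design are aggregated; ties break toward lower cost, then
    insertion order."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if not state.history:
        raise RuntimeError("no evaluations in history")
    agg: dict[tuple, dict] = {}
    for idx, rec in enumerate(state.history):
        key = rec.design.key()
        slot = agg.setdefault(
            key, {"design": rec.design, "scores": [], "costs": [], "first": idx}
        )
        slot["scores"].append(rec.score)
        slot["costs"].append(rec.cost)
    ranked = sorted(
        agg.values(),
        key=lambda s: (
            float(np.mean(s["scores"])),
            float(np.mean(s["costs"])),
            s["first"],
        ),
    )
    return [
        (s["design"], float(np.mean(s["scores"])), len(s["scores"]))
        for s in ranked[:k]
    ]


# ---------------------------------------------------------------------------
# evaluation ledger I/O
# ---------------------------------------------------------------------------

def ledger_frame(state: OptimizationState) -> pd.DataFrame:
    space = state.space
    rows = []
    for rec in state.history:
        row = {"round": rec.round}
        row.update({name: rec.design[name] for name in space.names})
        row.update(
            loss=rec.loss, cost=rec.cost, score=rec.score,
            instance_seed=rec.instance_seed,
        )
        rows.append(row)
    cols = ["round", *space.names, "loss", "cost", "score", "instance_seed"]
    return pd.DataFrame(rows, columns=cols)


def write_ledger(state: OptimizationState, path) -> None:
    """Tab-separated evaluation ledger with a fixed column order."""
    ledger_frame(state).to_csv(path, sep="\t", index=False)


def read_ledger(space: DesignSpace, path) -> list[EvaluationRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for rec in df.to_dict("records"):
        design = frame_row_to_design(space, rec)
        records.append(
            EvaluationRecord(
                design=design,
                loss=float(rec["loss"]),
                cost=float(rec["cost"]),
                score=float(rec["score"]),
                round=int(rec["round"]),
                instance_seed=int(rec["instance_seed"]),
            )
        )
    return records
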