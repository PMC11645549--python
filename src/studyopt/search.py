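"""Candidate proposal for the active-learning loop.

Three proposal mechanisms: (i) lower-confidence-bound winnowing of a
space-filling candidate pool (exploration), (ii) mixed-integer mesh search
around the incumbent — continuous lattice steps, discrete neighbors, and
their combinations — with mesh shrinkage on budget violation, and (iii)
gradient descent on the surrogate with central-difference gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .sampling import _is_feasible, feasible_fill
from .space import DesignSpace, StudyDesign


@dataclass
class AcquisitionConfig:
    """LCB exploration settings: α_v weights the posterior sd, pool_size is
    the number of LHS candidates scored per round."""

    alpha_v: float = 1.0
    pool_size: int = 200

    def __post_init__(self) -> None:
        if self.alpha_v < 0:
            raise ValueError("alpha_v must be nonnegative")
        if self.pool_size < 1:
            raise ValueError("pool_size must be at least 1")


def lcb(model, x: StudyDesign, alpha_v: float) -> float:
    """Lower confidence bound μ(x) − α_v·σ(x) of the score surrogate."""
    mean, var = model.predict([x])
    return float(mean[0] - alpha_v * math.sqrt(max(float(var[0]), 0.0)))


def select_exploration_batch(
    model,
    space: DesignSpace,
    count: int,
    acq: AcquisitionConfig,
    f: Callable | None,
    b,
    seed: int,
) -> list[StudyDesign]:
    """Feasible LHS pool scored by LCB; the ``count`` lowest win."""
    if count <= 0:
        return []
    pool = feasible_fill(space, acq.pool_size, f, b, seed).rows
    mean, var = model.predict(pool)
    values = mean - acq.alpha_v * np.sqrt(np.clip(var, 0.0, None))
    order = np.argsort(values, kind="stable")
    return [pool[i] for i in order[:count]]


# ---------------------------------------------------------------------------
# mesh search
# ---------------------------------------------------------------------------

def coordinate_directions(n_c: int) -> np.ndarray:
    """±unit coordinate vectors: the minimal positive spanning set used as
    the default direction matrix (n_c × 2·n_c)."""
    eye = np.eye(n_c)
    return np.hstack([eye, -eye])


@dataclass
class MeshState:
    """Mesh around the incumbent: center, fineness Δ, direction columns."""

    center: StudyDesign
    delta: float
    directions: np.ndarray | None = None
    round: int = 0
    warning: bool = False

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("mesh fineness delta must be positive")


def _mesh_directions(space: DesignSpace, mesh: MeshState) -> np.ndarray:
    n_c = space.n_continuous
    if mesh.directions is not None:
        D = np.asarray(mesh.directions, dtype=float)
        if D.shape[0] != n_c:
            raise ValueError(f"directions must have {n_c} rows")
        return D
    return coordinate_directions(n_c)


def continuous_neighbors(space: DesignSpace, mesh: MeshState) -> list[StudyDesign]:
    """One candidate per direction column: x_c + Δ·d_j on the encoded unit
    cube (clipped to the domain), discrete part unchanged.  Candidates that
    clip back onto the center are dropped."""
    cont = space.continuous_idx
    if cont.size == 0:
        return []
    D = _mesh_directions(space, mesh)
    e0 = space.encode(mesh.center)
    out = []
    for j in range(D.shape[1]):
        e = e0.copy()
        e[cont] = np.clip(e0[cont] + mesh.delta * D[:, j], 0.0, 1.0)
        if np.allclose(e, e0):
            continue
        out.append(space.decode(e))
    return out


def discrete_neighbors(
    space: DesignSpace, mesh: MeshState, ball_fraction: float = 0.05
) -> list[StudyDesign]:
    """Single-variable discrete substitutions around the center.

    Categorical/boolean variables contribute one candidate per alternative
    level (levels are mutually equidistant); integer variables contribute
    candidates at ±1…±⌈ball_fraction·range⌉ steps within bounds.
    """
    center = mesh.center
    out = []
    for var in space.variables:
        v0 = center[var.name]
        if var.vartype in ("categorical", "boolean"):
            for lev in var.levels:
                if lev != v0:
                    out.append(StudyDesign({**center.values, var.name: lev}))
        elif var.vartype == "integer":
            radius = max(1, math.ceil(ball_fraction * var.range))
            for step in range(1, radius + 1):
                for sgn in (+1, -1):
                    v = int(v0) + sgn * step
                    if var.lower <= v <= var.upper and v != v0:
                        out.append(StudyDesign({**center.values, var.name: v}))
    return out


def extended_neighbors(
    space: DesignSpace,
    mesh: MeshState,
    ball_fraction: float = 0.05,
    budget: int | None = None,
) -> list[StudyDesign]:
    """Continuous mesh step combined with one discrete substitution — the
    continuous neighborhood of the discrete neighbors.  Emitted only with
    spare local-search budget (``budget`` > 0 or None)."""
    if budget is not None and budget <= 0:
        return []
    cont = space.continuous_idx
    if cont.size == 0:
        return []
    D = _mesh_directions(space, mesh)
    e0 = space.encode(mesh.center)
    out = []
    for disc in discrete_neighbors(space, mesh, ball_fraction):
        ed = space.encode(disc)
        for j in range(D.shape[1]):
            e = ed.copy()
            e[cont] = np.clip(ed[cont] + mesh.delta * D[:, j], 0.0, 1.0)
            if np.allclose(e[cont], e0[cont]):
                continue  # continuous part must actually move
            out.append(space.decode(e))
            if budget is not None and len(out) >= budget:
                return out
    return out


def mesh_search_batch(
    space: DesignSpace,
    mesh: MeshState,
    n_m: int,
    f: Callable | None,
    b,
    seed: int,
    ball_fraction: float = 0.05,
    max_shrinks: int = 6,
    min_delta: float = 1e-4,
) -> tuple[list[StudyDesign], MeshState]:
    """Sample up to ``n_m`` mesh candidates, ordered continuous-neighborhood
    pool first, then discrete neighbors, then extended neighbors; any budget
    violation among the picks halves Δ (bounded retries) before resampling.

    On Δ underflow the feasible subset found so far is returned with the
    ``warning`` flag set on the mesh state.
    """
    if n_m <= 0:
        return [], mesh
    rng = np.random.default_rng(seed)
    delta = mesh.delta
    feasible_found: list[StudyDesign] = []
    for attempt in range(max_shrinks + 1):
        state = replace(mesh, delta=delta)
        C = continuous_neighbors(space, state)
        Dn = discrete_neighbors(space, state, ball_fraction)
        rng_local = np.random.default_rng(rng.integers(2**31))
        C = [C[i] for i in rng_local.permutation(len(C))]
        Dn = [Dn[i] for i in rng_local.permutation(len(Dn))]
        spare = n_m - len(C) - len(Dn)
        E = extended_neighbors(space, state, ball_fraction, budget=spare) if spare > 0 else []
        E = [E[i] for i in rng_local.permutation(len(E))]
        picked = (C + Dn + E)[:n_m]
        feas = [x for x in picked if _is_feasible(f, b, x)]
        if len(feas) == len(picked):
            return picked, replace(mesh, delta=delta, warning=False)
        feasible_found = feas
        delta /= 2.0
        if delta < min_delta:
            break
    return feasible_found, replace(mesh, delta=delta, warning=True)


# ---------------------------------------------------------------------------
# gradient step
# ---------------------------------------------------------------------------

@dataclass
class GradientConfig:
    """Central-difference gradient step on the score surrogate.

    ``gamma`` is the per-variable perturbation as a fraction of the
    variable's range (integers are perturbed by at least one unit so they
    remain integral); ``alpha_g`` the step size.  With ``normalize`` the
    step moves alpha_g (encoded units) along the negative normalized
    gradient — scale-free across heterogeneous variable ranges — otherwise
    the raw update x − α_g·∇T̂ is applied literally.
    """

    gamma: float = 0.05
    alpha_g: float = 0.1
    normalize: bool = True
    max_backtracks: int = 6

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.alpha_g <= 0:
            raise ValueError("alpha_g must be positive")


def gradient_step(
    model,
    space: DesignSpace,
    x: StudyDesign,
    grad_cfg: GradientConfig,
    f: Callable | None = None,
    b=None,
) -> tuple[StudyDesign, bool]:
    """One surrogate-gradient descent step from ``x``.

    Returns ``(design, moved)``; ``moved`` is False when the space has no
    numeric variables, the gradient vanishes, or every feasibility
    backtrack failed (in which case ``x`` is returned unchanged).
    Categorical coordinates are never touched.
    """
    space.require_valid(x)
    numeric = [v for v in space.variables if v.is_numeric]
    if not numeric:
        return x, False

    grad: dict[str, float] = {}
    for var in numeric:
        v0 = float(x[var.name])
        h = grad_cfg.gamma * var.range
        if var.vartype == "integer":
            h = max(1.0, round(h))
        v_plus = min(var.upper, v0 + h)
        v_minus = max(var.lower, v0 - h)
        if var.vartype == "integer":
            v_plus, v_minus = round(v_plus), round(v_minus)
        if v_plus == v_minus:
            grad[var.name] = 0.0
            continue
        xp = StudyDesign({**x.values, var.name: _coerce(var, v_plus)})
        xm = StudyDesign({**x.values, var.name: _coerce(var, v_minus)})
        (tp,), _ = model.predict([xp])
        (tm,), _ = model.predict([xm])
        grad[var.name] = (float(tp) - float(tm)) / (v_plus - v_minus)

    gvec = np.array([grad[v.name] for v in numeric])
    if np.allclose(gvec, 0.0):
        return x, False

    if grad_cfg.normalize:
        # gradient in encoded units, unit-normalized; step length alpha_g
        enc_g = gvec * np.array([v.range for v in numeric])
        norm = np.linalg.norm(enc_g)
        enc_step = -grad_cfg.alpha_g * enc_g / norm
        raw_step = enc_step * np.array([v.range for v in numeric])
    else:
        raw_step = -gvec * grad_cfg.alpha_g

    alpha_scale = 1.0
    for _ in range(grad_cfg.max_backtracks + 1):
        values = dict(x.values)
        for var, dv in zip(numeric, raw_step * alpha_scale):
            v = float(x[var.name]) + dv
            v = min(max(v, var.lower), var.upper)
            values[var.name] = _coerce(var, v)
        cand = StudyDesign(values)
        if cand.key() == x.key():
            return x, False
        if _is_feasible(f, b, cand):
            return cand, True
        alpha_scale /= 2.0
    return x, False


def _coerce(var, v: float):
    return int(round(v)) if var.vartype == "integer" else float(v)
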