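"""Space-filling initialization: Latin hypercube sampling with maximin
improvement and rejection against a hard budget constraint.

Continuous and integer variables are stratified into ``n0`` equal intervals
of their range with exactly one draw per stratum; categorical/boolean
variables are spread over their levels as evenly as ``n0`` allows.  The
maximin step permutes values within columns — which preserves stratum
occupancy — accepting swaps that do not decrease the minimum pairwise
mixed distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .space import DesignSpace, DesignError, StudyDesign


class InfeasibleDesignSpace(RuntimeError):
    """Raised when rejection sampling cannot reach the target count."""


@dataclass
class DesignMatrix:
    """A batch of designs sharing one :class:`DesignSpace`."""

    space: DesignSpace
    rows: list[StudyDesign]
    round: int = 0
    role: str = "loss-init"

    def __len__(self) -> int:
        return len(self.rows)

    def encoded(self) -> np.ndarray:
        return self.space.encode_matrix(self.rows)

    def min_pairwise_distance(self) -> float:
        dm = self.space.pairwise_distances(self.encoded())
        n = dm.shape[0]
        if n < 2:
            return math.inf
        iu = np.triu_indices(n, 1)
        return float(dm[iu].min())

    # -- TSV round trip ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{name: x[name] for name in self.space.names} for x in self.rows],
            columns=list(self.space.names),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, space: DesignSpace, path, **kwargs) -> "DesignMatrix":
        df = pd.read_csv(path, sep="\t")
        missing = set(space.names) - set(df.columns)
        if missing:
            raise DesignError(f"TSV missing design columns: {sorted(missing)}")
        rows = [frame_row_to_design(space, rec) for rec in df.to_dict("records")]
        return cls(space=space, rows=rows, **kwargs)


def frame_row_to_design(space: DesignSpace, record: dict) -> StudyDesign:
    """Build a design from one table record, coercing types per variable."""
    values = {}
    for var in space.variables:
        v = record[var.name]
        if var.vartype == "integer":
            v = int(v)
        elif var.vartype == "continuous":
            v = float(v)
        elif var.vartype == "boolean":
            # levels may be python bools serialized as strings
            if v not in var.levels:
                for lev in var.levels:
                    if str(lev) == str(v):
                        v = lev
                        break
        values[var.name] = v
    design = StudyDesign(values)
    space.require_valid(design)
    return design


def lhs_sample(space: DesignSpace, n0: int, seed: int, *, role: str = "loss-init") -> DesignMatrix:
    """Stratified Latin hypercube of ``n0`` designs.

    Each numeric variable's range is cut into ``n0`` equal strata with one
    draw per stratum; per-variable columns are combined by independent
    random permutation.  Integer variables draw the stratum midpoint-free
    uniform integer whose encoded coordinate stays inside the stratum
    whenever the range admits one.
    """
    if n0 < 2:
        raise ValueError("n0 must be at least 2")
    rng = np.random.default_rng(seed)
    columns: dict[str, list] = {}
    for var in space.variables:
        if var.is_numeric:
            strata = rng.permutation(n0)
            u = rng.random(n0)
            col = []
            for i, s in enumerate(strata):
                lo = var.lower + s * var.range / n0
                hi = var.lower + (s + 1) * var.range / n0
                if var.vartype == "integer":
                    ilo, ihi = math.ceil(lo), math.floor(hi)
                    if ihi >= hi and s < n0 - 1:
                        ihi -= 1  # keep half-open strata disjoint
                    if ilo > ihi:  # stratum narrower than integer spacing
                        col.append(int(round(min(max(lo, var.lower), var.upper))))
                    else:
                        col.append(int(rng.integers(ilo, ihi + 1)))
                else:
                    col.append(lo + u[i] * (hi - lo))
            columns[var.name] = col
        else:
            levels = list(var.levels)
            if n0 < len(levels):
                warnings.warn(
                    f"{var.name}: n0={n0} smaller than {len(levels)} levels; "
                    "stratification coarser than the level set",
                    stacklevel=2,
                )
            reps = [levels[i % len(levels)] for i in range(n0)]
            rng.shuffle(reps)
            columns[var.name] = reps
    rows = [
        StudyDesign({name: columns[name][i] for name in space.names})
        for i in range(n0)
    ]
    return DesignMatrix(space=space, rows=rows, round=0, role=role)


def maximin_improve(
    m: DesignMatrix,
    iterations: int,
    seed: int,
    f: Callable | None = None,
    b=None,
) -> DesignMatrix:
    """Improve the maximin score of an LHS matrix by within-column swaps.

    Each iteration proposes swapping one variable's values between two rows
    (stratum occupancy is untouched) and accepts the swap iff the minimum
    pairwise mixed distance does not decrease — and, when a budget
    constraint ``f(x) <= b`` is supplied, iff both swapped rows stay
    feasible.  Deterministic under seed.
    """
    if iterations == 0 or len(m) < 2:
        return DesignMatrix(space=m.space, rows=list(m.rows), round=m.round, role=m.role)
    rng = np.random.default_rng(seed)
    space = m.space
    enc = m.encoded().copy()
    dm = space.pairwise_distances(enc)
    np.fill_diagonal(dm, np.inf)
    n = enc.shape[0]
    best_min = float(dm.min())
    for _ in range(iterations):
        i, j = rng.choice(n, size=2, replace=False)
        col = int(rng.integers(space.d))
        if enc[i, col] == enc[j, col]:
            continue
        cand = enc.copy()
        cand[[i, j], col] = cand[[j, i], col]
        if f is not None and not all(
            _is_feasible(f, b, space.decode(cand[r])) for r in (i, j)
        ):
            continue
        dm_cand = dm.copy()
        for r in (i, j):
            for s_ in range(n):
                if s_ == r:
                    continue
                d_ = space.encoded_distance(cand[r], cand[s_])
                dm_cand[r, s_] = dm_cand[s_, r] = d_
        new_min = float(dm_cand.min())
        if new_min >= best_min:
            enc, dm, best_min = cand, dm_cand, new_min
    rows = [space.decode(enc[k]) for k in range(n)]
    return DesignMatrix(space=space, rows=rows, round=m.round, role=m.role)


def _is_feasible(f: Callable | None, b, design: StudyDesign) -> bool:
    if f is None or b is None:
        return True
    val = np.atleast_1d(np.asarray(f(design), dtype=float))
    if np.any(val < 0):
        raise ValueError("budget function must be nonnegative")
    bound = np.broadcast_to(np.atleast_1d(np.asarray(b, dtype=float)), val.shape)
    return bool(np.all(val <= bound))


def feasible_fill(
    space: DesignSpace,
    n_target: int,
    f: Callable | None,
    b,
    seed: int,
    max_rejects: int | None = None,
    *,
    maximin_iterations: int = 0,
    role: str = "loss-init",
) -> DesignMatrix:
    """LHS designs satisfying the hard budget f(x) ≤ b, by rejection.

    Draws LHS batches (optionally maximin-improved), keeps feasible rows
    and repeats with fresh sub-seeds until ``n_target`` rows are collected.
    """
    if max_rejects is None:
        max_rejects = 100 * n_target
    ss = np.random.SeedSequence(seed)
    kept: list[StudyDesign] = []
    rejects = 0
    attempts = 0
    while len(kept) < n_target:
        sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        batch = lhs_sample(space, max(n_target, 2), sub, role=role)
        if maximin_iterations:
            batch = maximin_improve(batch, maximin_iterations, sub + 1)
        for x in batch.rows:
            attempts += 1
            if _is_feasible(f, b, x):
                kept.append(x)
                if len(kept) == n_target:
                    break
            else:
                rejects += 1
                if rejects > max_rejects:
                    rate = (attempts - rejects) / attempts
                    raise InfeasibleDesignSpace(
                        f"exhausted {rejects} rejections before reaching "
                        f"{n_target} feasible designs (acceptance rate {rate:.3g})"
                    )
    return DesignMatrix(space=space, rows=kept[:n_target], round=0, role=role)
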