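"""Mixed-variable Gaussian-process surrogate of the study-design score.

The covariance factors into a Matérn 3/2 kernel on the encoded numeric
(continuous + integer) coordinates,

    k_c(x, x') = σ² (1 + √3 θ d(x, x')) exp(−√3 θ d(x, x')),

multiplied by a homoscedastic hypersphere-parameterized correlation per
categorical/boolean variable (unit diagonal, positive off-diagonal
correlations, positive semidefinite by construction).  Hyperparameters are
chosen by maximizing the Gaussian marginal likelihood with σ² profiled out
and multi-restart L-BFGS over the remaining parameters; the posterior is
the standard GP conditional with the data term *subtracted* from the prior
variance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .sampling import DesignMatrix, frame_row_to_design
from .space import DesignSpace, StudyDesign

SQRT3 = np.sqrt(3.0)

#: above this many levels a single exchangeable correlation is fitted
#: instead of the full hypersphere angle set, to bound parameter count
MAX_FULL_HYPERSPHERE_LEVELS = 5


class SurrogateError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def hypersphere_correlation(n_levels: int, angles: np.ndarray) -> np.ndarray:
    """Correlation matrix over levels from hypersphere decomposition.

    The Cholesky factor's i-th row lies on the unit hypersphere with
    coordinates given by angles; the product L Lᵀ has unit diagonal and is
    PSD for any angles.  Angles in (0, π/2) give positive correlations.
    """
    n_angles = n_levels * (n_levels - 1) // 2
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (n_angles,):
        raise ValueError(f"expected {n_angles} angles for {n_levels} levels")
    L = np.zeros((n_levels, n_levels))
    L[0, 0] = 1.0
    pos = 0
    for i in range(1, n_levels):
        row_angles = angles[pos : pos + i]
        pos += i
        sin_prod = 1.0
        for j in range(i):
            L[i, j] = np.cos(row_angles[j]) * sin_prod
            sin_prod *= np.sin(row_angles[j])
        L[i, i] = sin_prod
    return L @ L.T


def exchangeable_correlation(n_levels: int, rho: float) -> np.ndarray:
    """All off-diagonal correlations equal; PSD for ρ ≥ −1/(L−1)."""
    R = np.full((n_levels, n_levels), float(rho))
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class KernelParams:
    """Hyperparameters of the mixed kernel."""

    sigma2: float = 1.0
    theta: float = 1.0
    cat_corr: dict[str, np.ndarray] = field(default_factory=dict)
    nugget: float = 1e-6

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise SurrogateError("sigma2 must be positive")
        if np.any(np.asarray(self.theta) <= 0):
            raise SurrogateError("theta must be positive")
        if self.nugget < 0:
            raise SurrogateError("nugget must be nonnegative")


def _numeric_distance(space: DesignSpace, e1: np.ndarray, e2: np.ndarray) -> float:
    idx = space.numeric_idx
    if idx.size == 0:
        return 0.0
    diff = e1[idx] - e2[idx]
    return float(np.sqrt(diff @ diff))


def matern32(space: DesignSpace, x1: StudyDesign, x2: StudyDesign, params: KernelParams) -> float:
    """Matérn 3/2 kernel on the encoded numeric coordinates."""
    e1, e2 = space.encode(x1), space.encode(x2)
    r = params.theta * _numeric_distance(space, e1, e2)
    return float(params.sigma2 * (1.0 + SQRT3 * r) * np.exp(-SQRT3 * r))


def categorical_kernel(level1, level2, levels: Sequence, corr: np.ndarray) -> float:
    """Correlation between two levels of one categorical variable."""
    levels = list(levels)
    if level1 not in levels or level2 not in levels:
        raise SurrogateError(f"unknown level in {level1!r}/{level2!r}")
    return float(corr[levels.index(level1), levels.index(level2)])


def mixed_kernel(space: DesignSpace, x1: StudyDesign, x2: StudyDesign, params: KernelParams) -> float:
    """Product of the Matérn 3/2 numeric kernel and per-categorical-variable
    level correlations."""
    k = matern32(space, x1, x2, params)
    for var in space.level_vars:
        corr = params.cat_corr.get(var.name)
        if corr is None:
            corr = np.eye(len(var.levels))
        k *= categorical_kernel(x1[var.name], x2[var.name], var.levels, corr)
    return k


def kernel_matrix(
    space: DesignSpace, E1: np.ndarray, E2: np.ndarray, params: KernelParams
) -> np.ndarray:
    """Vectorized mixed-kernel cross matrix for encoded design matrices."""
    num, lev = space.numeric_idx, space.level_idx
    if num.size:
        a, b = E1[:, num], E2[:, num]
        sq = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
        r = params.theta * np.sqrt(np.maximum(sq, 0.0))
    else:
        r = np.zeros((E1.shape[0], E2.shape[0]))
    K = params.sigma2 * (1.0 + SQRT3 * r) * np.exp(-SQRT3 * r)
    for var, col in zip(space.level_vars, lev):
        corr = params.cat_corr.get(var.name)
        if corr is None:
            continue
        i1 = E1[:, col].astype(int)
        i2 = E2[:, col].astype(int)
        K *= corr[np.ix_(i1, i2)]
    return K


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    n_restarts: int = 3
    theta_bounds: tuple[float, float] = (1e-2, 1e2)
    nugget_rel: float = 1e-6  # relative to standardized unit variance
    max_iter: int = 100


@dataclass
class GPModel:
    """Fitted surrogate: training data, hyperparameters, solve cache."""

    space: DesignSpace
    X: list[StudyDesign]
    y: np.ndarray
    params: KernelParams
    y_mean: float
    y_std: float
    X_encoded: np.ndarray
    K_XX: np.ndarray
    _chol: tuple = field(repr=False, default=None)
    _alpha: np.ndarray = field(repr=False, default=None)

    # -- prediction -------------------------------------------------------
    def predict(self, designs: Sequence[StudyDesign]) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and variance (original y units) at new designs."""
        if self._chol is None:
            raise SurrogateError("model is not fitted")
        E = self.space.encode_matrix(list(designs))
        Ks = kernel_matrix(self.space, E, self.X_encoded, self.params)
        mean_std = Ks @ self._alpha
        v = cho_solve(self._chol, Ks.T)
        prior = self.params.sigma2
        var_std = prior - np.einsum("ij,ji->i", Ks, v)
        var_std = np.clip(var_std, 0.0, None)
        mean = self.y_mean + self.y_std * mean_std
        var = (self.y_std**2) * var_std
        return mean, var

    def posterior(self, x: StudyDesign) -> tuple[float, float]:
        m, v = self.predict([x])
        return float(m[0]), float(v[0])

    # -- serialization ----------------------------------------------------
    def to_archive(self, path) -> None:
        """Write hyperparameters and training table as one structured-text
        archive, so a trained surrogate can be returned to the user."""
        table = DesignMatrix(space=self.space, rows=self.X).to_frame()
        table["__y__"] = self.y
        buf = io.StringIO()
        table.to_csv(buf, sep="\t", index=False)
        payload = {
            "params": {
                "sigma2": float(self.params.sigma2),
                "theta": float(self.params.theta),
                "nugget": float(self.params.nugget),
                "cat_corr": {
                    k: np.asarray(v).tolist() for k, v in self.params.cat_corr.items()
                },
            },
            "y_mean": float(self.y_mean),
            "y_std": float(self.y_std),
            "training_table_tsv": buf.getvalue(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_archive(cls, space: DesignSpace, path) -> "GPModel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        df = pd.read_csv(io.StringIO(payload["training_table_tsv"]), sep="\t")
        y = df.pop("__y__").to_numpy(dtype=float)
        rows = [frame_row_to_design(space, rec) for rec in df.to_dict("records")]
        p = payload["params"]
        params = KernelParams(
            sigma2=p["sigma2"],
            theta=p["theta"],
            nugget=p["nugget"],
            cat_corr={k: np.asarray(v) for k, v in p["cat_corr"].items()},
        )
        return _assemble(space, rows, y, params, payload["y_mean"], payload["y_std"])


def _assemble(
    space: DesignSpace,
    X: list[StudyDesign],
    y: np.ndarray,
    params: KernelParams,
    y_mean: float,
    y_std: float,
) -> GPModel:
    E = space.encode_matrix(X)
    K = kernel_matrix(space, E, E, params)
    n = len(X)
    nug = params.nugget
    for bump in range(8):
        try:
            chol = cho_factor(K + nug * np.eye(n), lower=True)
            break
        except np.linalg.LinAlgError:
            nug = max(nug, 1e-10) * 10.0
    else:  # pragma: no cover - pathological
        raise SurrogateError("kernel matrix could not be factorized")
    params = replace(params, nugget=nug)
    y_standardized = (np.asarray(y, dtype=float) - y_mean) / y_std
    alpha = cho_solve(chol, y_standardized)
    return GPModel(
        space=space,
        X=list(X),
        y=np.asarray(y, dtype=float),
        params=params,
        y_mean=y_mean,
        y_std=y_std,
        X_encoded=E,
        K_XX=K,
        _chol=chol,
        _alpha=alpha,
    )


def _cat_param_layout(space: DesignSpace) -> list[tuple[str, int, int]]:
    """(variable name, n_levels, n free parameters) per categorical var."""
    layout = []
    for var in space.level_vars:
        L = len(var.levels)
        if L == 1:
            n_par = 0
        elif L <= MAX_FULL_HYPERSPHERE_LEVELS:
            n_par = L * (L - 1) // 2
        else:
            n_par = 1  # shared exchangeable rho
        layout.append((var.name, L, n_par))
    return layout


def _unpack_cat(layout, vec: np.ndarray) -> dict[str, np.ndarray]:
    corrs = {}
    pos = 0
    for name, L, n_par in layout:
        if n_par == 0:
            corrs[name] = np.ones((1, 1))
            continue
        block = vec[pos : pos + n_par]
        pos += n_par
        if L <= MAX_FULL_HYPERSPHERE_LEVELS:
            corrs[name] = hypersphere_correlation(L, block)
        else:
            rho = float(np.cos(block[0]))  # angle → correlation in (0,1)
            corrs[name] = exchangeable_correlation(L, rho)
    return corrs


def fit_gp(
    space: DesignSpace,
    X: DesignMatrix | Sequence[StudyDesign],
    y: Sequence[float],
    fit_config: FitConfig | None = None,
    seed: int = 0,
) -> GPModel:
    """Fit the mixed GP by maximum marginal likelihood.

    σ² is profiled analytically; log θ and the categorical angles are
    optimized by L-BFGS-B from ``n_restarts`` seeded starting points.
    Observations are centered/scaled internally and un-scaled on
    prediction.
    """
    rows = list(X.rows) if isinstance(X, DesignMatrix) else list(X)
    y = np.asarray(list(y), dtype=float)
    if len(rows) < 2:
        raise SurrogateError("need at least 2 training designs")
    if len(rows) != len(y):
        raise SurrogateError("X and y length mismatch")
    if not np.all(np.isfinite(y)):
        raise SurrogateError("non-finite loss/score observations")
    cfg = fit_config or FitConfig()
    E = space.encode_matrix(rows)
    if np.unique(E, axis=0).shape[0] == 1:
        raise SurrogateError("degenerate training set: all designs are duplicates")

    y_mean = float(np.mean(y))
    y_std = float(np.std(y))
    if y_std < 1e-12:
        # constant observations: posterior mean is that constant everywhere
        params = KernelParams(sigma2=1e-10, theta=1.0, nugget=cfg.nugget_rel)
        return _assemble(space, rows, y, params, y_mean, 1.0)
    ys = (y - y_mean) / y_std
    n = len(rows)
    layout = _cat_param_layout(space)
    n_cat = sum(p for _, _, p in layout)
    log_tb = np.log(cfg.theta_bounds)

    def nll(vec: np.ndarray) -> float:
        theta = float(np.exp(vec[0]))
        params = KernelParams(
            sigma2=1.0, theta=theta, cat_corr=_unpack_cat(layout, vec[1:]),
            nugget=cfg.nugget_rel,
        )
        C = kernel_matrix(space, E, E, params) + params.nugget * np.eye(n)
        try:
            chol = cho_factor(C, lower=True)
        except np.linalg.LinAlgError:
            return 1e12
        quad = float(ys @ cho_solve(chol, ys))
        if quad <= 0:
            return 1e12
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        sigma2_hat = quad / n
        return 0.5 * (n * np.log(sigma2_hat) + logdet)

    rng = np.random.default_rng(seed)
    bounds = [(log_tb[0], log_tb[1])] + [(1e-3, np.pi / 2 - 1e-3)] * n_cat
    best = None
    for r in range(cfg.n_restarts):
        if r == 0:
            x0 = np.concatenate([[0.0], np.full(n_cat, np.pi / 4)])
        else:
            x0 = np.concatenate(
                [
                    rng.uniform(log_tb[0], log_tb[1], size=1),
                    rng.uniform(0.1, np.pi / 2 - 0.1, size=n_cat),
                ]
            )
        res = minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": cfg.max_iter},
        )
        if best is None or res.fun < best.fun:
            best = res
    vec = best.x
    theta = float(np.exp(vec[0]))
    corrs = _unpack_cat(layout, vec[1:])
    unit = KernelParams(sigma2=1.0, theta=theta, cat_corr=corrs, nugget=cfg.nugget_rel)
    C = kernel_matrix(space, E, E, unit) + unit.nugget * np.eye(n)
    chol = cho_factor(C, lower=True)
    sigma2_hat = float(ys @ cho_solve(chol, ys) / n)
    sigma2_hat = max(sigma2_hat, 1e-12)
    params = KernelParams(
        sigma2=sigma2_hat,
        theta=theta,
        cat_corr=corrs,
        nugget=cfg.nugget_rel * sigma2_hat,
    )
    return _assemble(space, rows, y, params, y_mean, y_std)


def make_model(
    space: DesignSpace,
    X: Sequence[StudyDesign],
    y: Sequence[float],
    params: KernelParams,
) -> GPModel:
    """Assemble a model with *given* hyperparameters (no fitting); y is used
    unstandardized.  Useful for oracle comparisons and controlled tests."""
    return _assemble(space, list(X), np.asarray(list(y), dtype=float), params, 0.0, 1.0)


def gp_posterior(model: GPModel, x_star: StudyDesign) -> tuple[float, float]:
    """Posterior mean/variance at one design (functional alias)."""
    return model.posterior(x_star)
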