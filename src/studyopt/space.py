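"""Mixed continuous/discrete study-design spaces.

A *study design* is one point in a mixed domain of sequencing and sampling
parameters: continuous variables (e.g. error rate), integers (coverage,
read length, number of samples), booleans (paired-end, whole-genome) and
categoricals (informatics pipeline).  The space defines validation,
an affine [0, 1] encoding used by the sampler, the surrogate kernels and
the mesh search, and a mixed Euclidean/Hamming distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

CONTINUOUS = "continuous"
INTEGER = "integer"
CATEGORICAL = "categorical"
BOOLEAN = "boolean"

_VARTYPES = (CONTINUOUS, INTEGER, CATEGORICAL, BOOLEAN)

#: vartypes whose encoded coordinate is an affine [0, 1] rescaling and which
#: therefore enter the Euclidean part of the mixed distance.
NUMERIC_TYPES = (CONTINUOUS, INTEGER)
#: vartypes treated as unordered level sets.
LEVEL_TYPES = (CATEGORICAL, BOOLEAN)


class DesignError(ValueError):
    """Structural problem with a design or space definition."""


@dataclass(frozen=True)
class VariableSpec:
    """One study-design variable: its type and admissible values."""

    name: str
    vartype: str
    lower: float | None = None
    upper: float | None = None
    levels: tuple[Any, ...] | None = None

    def __post_init__(self) -> None:
        if self.vartype not in _VARTYPES:
            raise DesignError(
                f"variable {self.name!r}: unknown vartype {self.vartype!r}"
            )
        if self.vartype in NUMERIC_TYPES:
            if self.lower is None or self.upper is None:
                raise DesignError(f"variable {self.name!r}: bounds required")
            if not self.lower < self.upper:
                raise DesignError(
                    f"variable {self.name!r}: lower must be < upper "
                    f"({self.lower} vs {self.upper})"
                )
            if self.vartype == INTEGER and (
                self.lower != int(self.lower) or self.upper != int(self.upper)
            ):
                raise DesignError(f"variable {self.name!r}: integer bounds must be integral")
        else:
            levels = self.levels
            if self.vartype == BOOLEAN and levels is None:
                levels = (False, True)
            if not levels:
                raise DesignError(f"variable {self.name!r}: levels required")
            if len(set(levels)) != len(levels):
                raise DesignError(f"variable {self.name!r}: duplicate levels")
            if self.vartype == BOOLEAN and len(levels) != 2:
                raise DesignError(f"variable {self.name!r}: boolean needs exactly 2 levels")
            object.__setattr__(self, "levels", tuple(levels))

    @property
    def is_numeric(self) -> bool:
        return self.vartype in NUMERIC_TYPES

    @property
    def range(self) -> float:
        if not self.is_numeric:
            raise DesignError(f"variable {self.name!r} has no numeric range")
        return float(self.upper) - float(self.lower)

    def check(self, value: Any) -> str | None:
        """Return a violation message, or None if the value is admissible."""
        if self.is_numeric:
            try:
                v = float(value)
            except (TypeError, ValueError):
                return f"{self.name}: non-numeric value {value!r}"
            if not np.isfinite(v):
                return f"{self.name}: non-finite value {value!r}"
            if v < self.lower:
                return f"{self.name}: value {value!r} below lower bound {self.lower}"
            if v > self.upper:
                return f"{self.name}: value {value!r} above upper bound {self.upper}"
            if self.vartype == INTEGER and v != int(v):
                return f"{self.name}: value {value!r} not integral"
            return None
        if value not in self.levels:
            return f"{self.name}: unknown level {value!r} (levels: {list(self.levels)})"
        return None


@dataclass(frozen=True)
class StudyDesign:
    """One point x in the design space: a variable-name → value mapping."""

    values: Mapping[str, Any]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, name: str) -> Any:
        return self.values[name]

    def key(self) -> tuple:
        """Hashable identity used for aggregation across repeat evaluations."""
        return tuple(sorted(self.values.items(), key=lambda kv: kv[0]))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        inner = ", ".join(f"{k}={v!r}" for k, v in self.values.items())
        return f"StudyDesign({inner})"


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violations: tuple[str, ...] = ()


class DesignSpace:
    """Ordered collection of :class:`VariableSpec` defining the mixed domain.

    The ordering as declared is authoritative: encodings, distances, kernels
    and meshes all index variables in this order.
    """

    def __init__(self, variables: Sequence[VariableSpec]):
        names = [v.name for v in variables]
        if len(set(names)) != len(names):
            raise DesignError("duplicate variable names in design space")
        self.variables: tuple[VariableSpec, ...] = tuple(variables)
        self._by_name = {v.name: v for v in self.variables}
        self.numeric_vars = tuple(v for v in self.variables if v.is_numeric)
        self.level_vars = tuple(v for v in self.variables if not v.is_numeric)
        self.continuous_vars = tuple(v for v in self.variables if v.vartype == CONTINUOUS)
        self.integer_vars = tuple(v for v in self.variables if v.vartype == INTEGER)

    # -- bookkeeping ------------------------------------------------------
    @property
    def d(self) -> int:
        return len(self.variables)

    @property
    def n_continuous(self) -> int:
        return len(self.continuous_vars)

    @property
    def n_discrete(self) -> int:
        return self.d - self.n_continuous

    def __iter__(self) -> Iterable[VariableSpec]:
        return iter(self.variables)

    def __getitem__(self, name: str) -> VariableSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise DesignError(f"unknown variable {name!r}") from None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    # -- validation -------------------------------------------------------
    def validate(self, design: StudyDesign) -> ValidationReport:
        """Check a design against the space; unknown/missing names are
        structural errors raised as :class:`DesignError`, bound and level
        problems are collected into the report."""
        unknown = set(design.values) - set(self._by_name)
        if unknown:
            raise DesignError(f"unknown variable(s) in design: {sorted(unknown)}")
        missing = set(self._by_name) - set(design.values)
        if missing:
            raise DesignError(f"design missing variable(s): {sorted(missing)}")
        violations = []
        for var in self.variables:
            msg = var.check(design[var.name])
            if msg is not None:
                violations.append(msg)
        return ValidationReport(ok=not violations, violations=tuple(violations))

    def require_valid(self, design: StudyDesign) -> None:
        report = self.validate(design)
        if not report.ok:
            raise DesignError("invalid design: " + "; ".join(report.violations))

    # -- encoding ---------------------------------------------------------
    def encode(self, design: StudyDesign, *, check: bool = True) -> np.ndarray:
        """Encode a design as a length-d float vector.

        Continuous/integer coordinates are affinely rescaled to [0, 1];
        categorical/boolean coordinates carry the level index.
        """
        if check:
            self.require_valid(design)
        out = np.empty(self.d)
        for i, var in enumerate(self.variables):
            v = design[var.name]
            if var.is_numeric:
                out[i] = (float(v) - var.lower) / var.range
            else:
                out[i] = var.levels.index(v)
        return out

    def decode(self, vector: np.ndarray) -> StudyDesign:
        """Inverse of :meth:`encode`; numeric coordinates are clipped to
        [0, 1] and integers rounded to the nearest admissible value."""
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.d,):
            raise DesignError(f"encoded vector must have shape ({self.d},)")
        values = {}
        for i, var in enumerate(self.variables):
            z = vector[i]
            if var.is_numeric:
                raw = var.lower + np.clip(z, 0.0, 1.0) * var.range
                values[var.name] = int(round(raw)) if var.vartype == INTEGER else float(raw)
            else:
                idx = int(round(z))
                if not 0 <= idx < len(var.levels):
                    raise DesignError(f"{var.name}: level index {z} out of range")
                values[var.name] = var.levels[idx]
        return StudyDesign(values)

    def encode_matrix(self, designs: Sequence[StudyDesign], *, check: bool = True) -> np.ndarray:
        return np.vstack([self.encode(x, check=check) for x in designs]) if designs else np.empty((0, self.d))

    # index arrays into encoded vectors
    @property
    def numeric_idx(self) -> np.ndarray:
        return np.array([i for i, v in enumerate(self.variables) if v.is_numeric], dtype=int)

    @property
    def level_idx(self) -> np.ndarray:
        return np.array([i for i, v in enumerate(self.variables) if not v.is_numeric], dtype=int)

    @property
    def continuous_idx(self) -> np.ndarray:
        return np.array(
            [i for i, v in enumerate(self.variables) if v.vartype == CONTINUOUS], dtype=int
        )

    # -- distance ---------------------------------------------------------
    def distance(self, x1: StudyDesign, x2: StudyDesign) -> float:
        """Mixed distance: Euclidean on encoded numeric coordinates combined
        with a unit contribution per differing categorical/boolean variable,
        d = sqrt(Σ Δz_i² + #mismatches).  All categorical levels are thereby
        mutually equidistant."""
        e1, e2 = self.encode(x1), self.encode(x2)
        return self.encoded_distance(e1, e2)

    def encoded_distance(self, e1: np.ndarray, e2: np.ndarray) -> float:
        if e1.shape != e2.shape or e1.shape != (self.d,):
            raise DesignError("encoded dimension mismatch")
        num = self.numeric_idx
        lev = self.level_idx
        sq = 0.0
        if num.size:
            diff = e1[num] - e2[num]
            sq += float(diff @ diff)
        if lev.size:
            sq += float(np.sum(e1[lev] != e2[lev]))
        return float(np.sqrt(sq))

    def pairwise_distances(self, encoded: np.ndarray) -> np.ndarray:
        """Full mixed-distance matrix for an (n, d) encoded matrix."""
        num, lev = self.numeric_idx, self.level_idx
        n = encoded.shape[0]
        sq = np.zeros((n, n))
        if num.size:
            a = encoded[:, num]
            sq += np.sum((a[:, None, :] - a[None, :, :]) ** 2, axis=-1)
        if lev.size:
            b = encoded[:, lev]
            sq += np.sum(b[:, None, :] != b[None, :, :], axis=-1)
        return np.sqrt(sq)


def validate_design(space: DesignSpace, design: StudyDesign) -> ValidationReport:
    """Functional alias for :meth:`DesignSpace.validate`."""
    return space.validate(design)


def encode_design(space: DesignSpace, design: StudyDesign) -> np.ndarray:
    return space.encode(design)


def mixed_distance(space: DesignSpace, x1: StudyDesign, x2: StudyDesign) -> float:
    return space.distance(x1, x2)
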