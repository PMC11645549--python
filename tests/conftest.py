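import numpy as np
import pytest

from studyopt.space import (
    BOOLEAN,
    CATEGORICAL,
    CONTINUOUS,
    INTEGER,
    DesignSpace,
    StudyDesign,
    VariableSpec,
)


@pytest.fixture
def mixed_space() -> DesignSpace:
    """Small mixed space exercising all four variable types."""
    return DesignSpace(
        [
            VariableSpec("coverage", INTEGER, 1, 100),
            VariableSpec("error_rate", CONTINUOUS, 0.0, 0.1),
            VariableSpec("paired", BOOLEAN),
            VariableSpec("informatics", CATEGORICAL, levels=("callerA", "callerB", "callerC")),
        ]
    )


@pytest.fixture
def continuous_space() -> DesignSpace:
    return DesignSpace(
        [
            VariableSpec("x1", CONTINUOUS, 0.0, 1.0),
            VariableSpec("x2", CONTINUOUS, 0.0, 1.0),
        ]
    )


def random_design(space: DesignSpace, rng: np.random.Generator) -> StudyDesign:
    values = {}
    for var in space.variables:
        if var.vartype == CONTINUOUS:
            values[var.name] = float(rng.uniform(var.lower, var.upper))
        elif var.vartype == INTEGER:
            values[var.name] = int(rng.integers(var.lower, var.upper + 1))
        else:
            values[var.name] = var.levels[int(rng.integers(len(var.levels)))]
    return StudyDesign(values)
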