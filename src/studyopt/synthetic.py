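"""Seedable synthetic somatic-evolution evaluator.

A fast stand-in for read-level tumor simulation plus variant-calling
pipelines: each evaluation draws a stochastic tumor instance (Poisson SNV
and SV counts distributed over a subclone tree with cell fractions), then
converts a study design into variant calls through a monotone saturating
detection model — detection probability rises with coverage, read length
(SVs), samples and single cells, false calls rise with the error rate,
whole-exome designs mask most of the genome, and callers fail outright
with a small probability.  Only the monotone *structure* of the response
is asserted anywhere; the numeric constants are configuration with
documented defaults, not ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .objectives import (
    CohortData,
    MultiplicativeCostSpec,
    VariantSets,
    biopsy_cost,
    mutation_discovery_loss,
    multiplicative_cost,
    poisson_threshold_loss,
    subsample_recall_loss,
    sv_rate_loss,
)
from .optimizer import EvaluationRecord, ScoreConfig
from .space import (
    BOOLEAN,
    CATEGORICAL,
    CONTINUOUS,
    INTEGER,
    DesignSpace,
    StudyDesign,
    VariableSpec,
)

QUERIES = (
    "mutation_discovery",
    "costed_discovery",
    "sv_rate",
    "power_threshold",
    "cohort_recall",
)


def default_design_space(informatics_levels: Sequence[str] = ("callerA", "callerB")) -> DesignSpace:
    """The standard somatic study-design space: samples, single cells, read
    and fragment length, coverage, error rate, paired/genome flags and the
    informatics pipeline choice."""
    return DesignSpace(
        [
            VariableSpec("samples", INTEGER, 1, 3),
            VariableSpec("single_cells", INTEGER, 0, 10),
            VariableSpec("read_length", INTEGER, 100, 10000),
            VariableSpec("fragment_length", INTEGER, 200, 20000),
            VariableSpec("coverage", INTEGER, 1, 100),
            VariableSpec("error_rate", CONTINUOUS, 0.0, 0.1),
            VariableSpec("paired", BOOLEAN),
            VariableSpec("whole_genome", BOOLEAN),
            VariableSpec("informatics", CATEGORICAL, levels=tuple(informatics_levels)),
        ]
    )


# ---------------------------------------------------------------------------
# tumor instances
# ---------------------------------------------------------------------------

@dataclass
class TumorParams:
    """Stochastic tumor generator settings (configuration, not literature
    ground truth): Poisson means for SNV/SV counts, subclone count, genome
    size, and the chromosome set SV intervals are placed on."""

    snv_mean: float = 100.0
    sv_mean: float = 30.0
    n_subclones: int = 5
    genome_size: int = 3_000_000_000
    n_chromosomes: int = 5
    sv_len_min: int = 1_000
    sv_len_max: int = 100_000


@dataclass
class TumorInstance:
    """One realization q ~ Q(t): truth variants with cell fractions."""

    seed: int
    n_subclones: int
    snv_truth: dict[str, float]  # identifier -> cell fraction
    sv_truth: list[tuple[str, int, int, float]]  # (chrom, start, end, fraction)
    genome_size: int

    def sv_intervals(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, a, b, _ in self.sv_truth:
            out.setdefault(chrom, []).append((a, b))
        return out


def _subclone_fractions(rng: np.random.Generator, n_subclones: int) -> np.ndarray:
    """Cell fractions down a random branching subclone tree; the root clone
    is clonal (fraction 1), each child carries a random share of its
    parent's fraction."""
    fracs = [1.0]
    for _ in range(1, n_subclones):
        parent = fracs[int(rng.integers(len(fracs)))]
        fracs.append(parent * float(rng.uniform(0.2, 0.8)))
    return np.array(fracs)


def generate_tumor(params: TumorParams, seed: int) -> TumorInstance:
    """Draw one tumor instance; reproducible under seed."""
    rng = np.random.default_rng(seed)
    fracs = _subclone_fractions(rng, params.n_subclones)
    n_snv = int(rng.poisson(params.snv_mean))
    n_sv = int(rng.poisson(params.sv_mean))
    chrom_len = params.genome_size // params.n_chromosomes

    snv_truth: dict[str, float] = {}
    for i in range(n_snv):
        sub = 0 if i == 0 else int(rng.integers(params.n_subclones))
        chrom = f"chr{int(rng.integers(params.n_chromosomes)) + 1}"
        pos = int(rng.integers(1, chrom_len))
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        snv_truth[f"{chrom}:{pos}:{ref}:{alt}"] = float(fracs[sub])

    sv_truth: list[tuple[str, int, int, float]] = []
    for i in range(n_sv):
        sub = 0 if (i == 0 and n_snv == 0) else int(rng.integers(params.n_subclones))
        chrom = f"chr{int(rng.integers(params.n_chromosomes)) + 1}"
        length = int(rng.integers(params.sv_len_min, params.sv_len_max))
        start = int(rng.integers(0, max(1, chrom_len - length)))
        sv_truth.append((chrom, start, start + length, float(fracs[sub])))
    return TumorInstance(
        seed=seed,
        n_subclones=params.n_subclones,
        snv_truth=snv_truth,
        sv_truth=sv_truth,
        genome_size=params.genome_size,
    )


# ---------------------------------------------------------------------------
# detection model
# ---------------------------------------------------------------------------

def _saturate(u: float, half: float) -> float:
    """u/(u+half), with the half=0 limit = 1 for any positive u."""
    if half <= 0:
        return 1.0 if u > 0 else 0.0
    return u / (u + half)

@dataclass
class DetectionModel:
    """Design-conditioned variant detection.

    Per-variant single-sample detection probability

        p = p_max · u / (u + coverage_half),   u = c·φ·(1 + sc_boost·n_sc)

    with φ the variant's cell fraction; SVs are additionally scaled by
    rl/(rl + read_length_half) and a paired-end multiplier.  s samples
    combine as 1 − (1 − p)^s.  False calls arrive Poisson with mean
    proportional to the error rate; whole-exome designs restrict calling
    to ``exome_fraction`` of variants; a caller fails outright with
    probability ``caller_fail_prob``.
    """

    p_max: float = 0.95
    coverage_half: float = 20.0
    read_length_half: float = 500.0
    single_cell_boost: float = 0.05
    paired_sv_boost: float = 1.1
    error_fp_snv: float = 50.0
    error_fp_sv: float = 10.0
    exome_fraction: float = 0.02
    caller_fail_prob: float = 0.0
    informatics_p_max: dict[str, float] = field(
        default_factory=lambda: {"callerA": 1.0, "callerB": 0.85}
    )

    def _design_fields(self, x: StudyDesign) -> dict:
        v = x.values
        return {
            "coverage": float(v.get("coverage", 30)),
            "samples": int(v.get("samples", 1)),
            "single_cells": int(v.get("single_cells", 0)),
            "read_length": float(v.get("read_length", 150)),
            "error_rate": float(v.get("error_rate", 0.0)),
            "paired": bool(v.get("paired", True)),
            "whole_genome": bool(v.get("whole_genome", True)),
            "informatics": v.get("informatics"),
        }

    def detection_prob(self, x: StudyDesign, cell_fraction: float, is_sv: bool) -> float:
        d = self._design_fields(x)
        adj = self.informatics_p_max.get(d["informatics"], 1.0)
        u = d["coverage"] * cell_fraction * (1.0 + self.single_cell_boost * d["single_cells"])
        p = self.p_max * adj * _saturate(u, self.coverage_half)
        if is_sv:
            p *= _saturate(d["read_length"], self.read_length_half)
            if d["paired"]:
                p = min(1.0, p * self.paired_sv_boost)
        p_all = 1.0 - (1.0 - min(p, 1.0)) ** max(d["samples"], 1)
        return float(min(p_all, 1.0))


def simulate_calls(
    tumor: TumorInstance, x: StudyDesign, model: DetectionModel, seed: int
) -> VariantSets:
    """Variant calls for one design on one tumor instance."""
    rng = np.random.default_rng(seed)
    d = model._design_fields(x)
    caller_failed = bool(rng.random() < model.caller_fail_prob)
    exome_keep = 1.0 if d["whole_genome"] else model.exome_fraction

    snv_called: set[str] = set()
    for ident, frac in tumor.snv_truth.items():
        p = model.detection_prob(x, frac, is_sv=False) * exome_keep
        if rng.random() < p:
            snv_called.add(ident)
    # false positives scale with error rate (and exome masking)
    n_fp = int(rng.poisson(model.error_fp_snv * d["error_rate"] * exome_keep))
    chrom_len = tumor.genome_size // 5
    for i in range(n_fp):
        snv_called.add(f"chr{int(rng.integers(5)) + 1}:fp{int(rng.integers(chrom_len))}:N:N")

    sv_called: dict[str, list[tuple[int, int]]] = {}
    for chrom, a, b, frac in tumor.sv_truth:
        p = model.detection_prob(x, frac, is_sv=True) * exome_keep
        if rng.random() < p:
            sv_called.setdefault(chrom, []).append((a, b))
    n_fp_sv = int(rng.poisson(model.error_fp_sv * d["error_rate"] * exome_keep))
    for _ in range(n_fp_sv):
        chrom = f"chr{int(rng.integers(5)) + 1}"
        start = int(rng.integers(0, chrom_len - 10_000))
        sv_called.setdefault(chrom, []).append((start, start + int(rng.integers(1_000, 10_000))))

    return VariantSets(
        snv_truth=set(tumor.snv_truth),
        snv_called=snv_called,
        sv_truth=tumor.sv_intervals(),
        sv_called=sv_called,
        caller_failed=caller_failed,
    )


# ---------------------------------------------------------------------------
# liquid-biopsy cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Multi-patient multi-timepoint liquid-biopsy emulation: per-patient
    Poisson variant counts, three blood timepoints with variants persisting
    from a random origin timepoint, and a saturating coverage-detection
    curve for the subsampled calls."""

    variants_mean: float = 40.0
    n_timepoints: int = 3
    p_max: float = 0.98
    coverage_half: float = 5.0
    fraction_min: float = 0.05


@dataclass
class CohortTruth:
    """Per-patient variant catalogs: identifier -> (origin timepoint, φ)."""

    patients: list[dict[str, tuple[int, float]]]
    params: CohortParams

    def full_sets(self) -> list[set[str]]:
        return [set(p) for p in self.patients]


def generate_cohort(
    n_train: int, n_test: int, params: CohortParams, seed: int
) -> tuple[CohortTruth, CohortTruth]:
    """Train/test patient cohorts (defaults elsewhere: 10 train, 7 test)."""
    if n_train < 1 or n_test < 1:
        raise ValueError("cohort sizes must be at least 1")
    rng = np.random.default_rng(seed)

    def _patients(n: int) -> list[dict[str, tuple[int, float]]]:
        out = []
        for i in range(n):
            n_var = max(1, int(rng.poisson(params.variants_mean)))
            variants = {}
            for j in range(n_var):
                origin = int(rng.integers(params.n_timepoints))
                frac = float(rng.uniform(params.fraction_min, 1.0))
                variants[f"p{i}:v{j}"] = (origin, frac)
            out.append(variants)
        return out

    train = CohortTruth(patients=_patients(n_train), params=params)
    test = CohortTruth(patients=_patients(n_test), params=params)
    return train, test


def subsample_cohort(
    cohort: CohortTruth, x: StudyDesign, seed: int
) -> CohortData:
    """Emulate the subsampling protocol: pick ``samples`` of the available
    timepoints at random per patient, then call each variant present at a
    chosen timepoint with a coverage-saturating probability."""
    params = cohort.params
    rng = np.random.default_rng(seed)
    coverage = float(x.values.get("coverage", 30))
    s = int(x.values.get("samples", 1))
    s = max(1, min(s, params.n_timepoints))
    full, called = [], []
    for variants in cohort.patients:
        chosen = set(rng.choice(params.n_timepoints, size=s, replace=False).tolist())
        c_i = set()
        for ident, (origin, frac) in variants.items():
            present = [t for t in chosen if t >= origin]
            if not present:
                continue
            u = coverage * frac
            p = params.p_max * _saturate(u, params.coverage_half)
            p_any = 1.0 - (1.0 - p) ** len(present)
            if rng.random() < p_any:
                c_i.add(ident)
        full.append(set(variants))
        called.append(c_i)
    return CohortData(full=full, called=called)


# ---------------------------------------------------------------------------
# batch evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluatorConfig:
    """Everything the synthetic evaluator needs for one query."""

    tumor: TumorParams = field(default_factory=TumorParams)
    detection: DetectionModel = field(default_factory=DetectionModel)
    cohort: CohortParams = field(default_factory=CohortParams)
    cohort_n_train: int = 10
    cohort_n_test: int = 7
    cohort_seed: int = 20_240
    lam: float = 0.0
    threshold: float = 0.33
    oriented: bool = True
    cost_spec: MultiplicativeCostSpec = field(
        default_factory=lambda: MultiplicativeCostSpec(
            linear={"coverage": 0.004, "samples": 0.05, "single_cells": 0.01},
            interactions=[("coverage", "samples", 0.001)],
        )
    )


class SyntheticEvaluator:
    """Batch evaluator over one query; usable directly by the optimizer.

    Calling the instance with ``(designs, seeds)`` returns one loss per
    design; :meth:`records` returns full :class:`EvaluationRecord` rows.
    All randomness flows from the per-design seeds — no hidden state.
    """

    def __init__(self, query: str, config: EvaluatorConfig | None = None, n_jobs: int = 1):
        if query not in QUERIES:
            raise ValueError(f"unknown query {query!r}; choose from {QUERIES}")
        self.query = query
        self.config = config or EvaluatorConfig()
        self.n_jobs = n_jobs
        self._train_cohort: CohortTruth | None = None

    # -- cost/budget helpers ---------------------------------------------
    def cost_fn(self):
        cfg = self.config
        if self.query == "cohort_recall":
            return lambda x: biopsy_cost(
                float(x.values.get("coverage", 0)), int(x.values.get("samples", 1))
            )
        if self.query == "costed_discovery":
            return lambda x: multiplicative_cost(x, cfg.cost_spec)
        return None  # cost fixed at 0

    def score_config(self, budget_fn=None, budget=None) -> ScoreConfig:
        return ScoreConfig(
            lam=self.config.lam, cost_fn=self.cost_fn(),
            budget_fn=budget_fn, budget=budget,
        )

    # -- evaluation -------------------------------------------------------
    def _cohort(self) -> CohortTruth:
        if self._train_cohort is None:
            train, _ = generate_cohort(
                self.config.cohort_n_train, self.config.cohort_n_test,
                self.config.cohort, self.config.cohort_seed,
            )
            self._train_cohort = train
        return self._train_cohort

    def loss(self, x: StudyDesign, seed: int) -> float:
        cfg = self.config
        if self.query == "cohort_recall":
            data = subsample_cohort(self._cohort(), x, seed)
            return subsample_recall_loss(data, oriented=cfg.oriented)
        tumor = generate_tumor(cfg.tumor, seed)
        calls = simulate_calls(tumor, x, cfg.detection, seed + 1)
        if self.query in ("mutation_discovery", "costed_discovery"):
            return mutation_discovery_loss(calls, oriented=cfg.oriented)
        if self.query == "sv_rate":
            return sv_rate_loss(calls.sv_count_called, calls.sv_count_actual)
        if self.query == "power_threshold":
            return float(
                poisson_threshold_loss(
                    calls.sv_count_called, calls.sv_count_actual,
                    cfg.threshold, calls.caller_failed,
                )
            )
        raise AssertionError(self.query)

    def __call__(self, designs: Sequence[StudyDesign], seeds: Sequence[int]) -> list[float]:
        if len(designs) != len(seeds):
            raise ValueError("one seed per design required")
        if self.n_jobs != 1 and len(designs) > 1:
            # order-preserving; identical output to the sequential path
            # because every loss depends only on its per-design seed
            from joblib import Parallel, delayed

            self._cohort() if self.query == "cohort_recall" else None
            return Parallel(n_jobs=self.n_jobs)(
                delayed(self.loss)(x, int(s)) for x, s in zip(designs, seeds)
            )
        return [self.loss(x, int(s)) for x, s in zip(designs, seeds)]

    def records(
        self, designs: Sequence[StudyDesign], seeds: Sequence[int], round_idx: int = 0
    ) -> list[EvaluationRecord]:
        cost_fn = self.cost_fn()
        out = []
        for x, s in zip(designs, seeds):
            loss = self.loss(x, int(s))
            cost = float(cost_fn(x)) if cost_fn else 0.0
            out.append(
                EvaluationRecord(
                    design=x, loss=loss, cost=cost,
                    score=self.config.lam * cost + loss,
                    round=round_idx, instance_seed=int(s),
                )
            )
        return out


def evaluate_batch(
    designs: Sequence[StudyDesign],
    query: str,
    config: EvaluatorConfig | None = None,
    seeds: Sequence[int] | None = None,
) -> list[EvaluationRecord]:
    """One-shot batch evaluation: dispatches each design through the tumor
    or cohort generator, the detection model and the query's loss, with the
    query's matching cost attached."""
    ev = SyntheticEvaluator(query, config)
    if seeds is None:
        seeds = list(range(len(designs)))
    if len(seeds) != len(designs):
        raise ValueError("one seed per design required")
    return ev.records(designs, seeds)
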