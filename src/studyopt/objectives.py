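"""Loss and cost functions for somatic-variant study-design queries.

Five experimental queries are supported: mutation discovery (SNV recall
combined with an interval-overlap SV score), the same with a multiplicative
sequencing cost, SV rate estimation, a Poisson-power threshold test for SV
hypermutability screening, and liquid-biopsy cohort variant recall with the
coverage×samples cost.

The recall-like quantities are emitted as *oriented* losses 1 − recall by
default, so that the minimizing optimizer prefers designs that recover more
variants; the raw recall form is available via ``oriented=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import poisson

from .space import StudyDesign


class ObjectiveError(ValueError):
    pass


Interval = tuple[int, int]


@dataclass
class VariantSets:
    """Truth and called variant sets for one evaluated design.

    SNVs are opaque identifiers (conventionally CHROM:POS:REF:ALT); SVs are
    0-based half-open genomic intervals keyed by chromosome.
    """

    snv_truth: set[str] = field(default_factory=set)
    snv_called: set[str] = field(default_factory=set)
    sv_truth: dict[str, list[Interval]] = field(default_factory=dict)
    sv_called: dict[str, list[Interval]] = field(default_factory=dict)
    caller_failed: bool = False

    def __post_init__(self) -> None:
        for sets in (self.sv_truth, self.sv_called):
            for chrom, ivals in sets.items():
                for start, end in ivals:
                    if not start < end:
                        raise ObjectiveError(
                            f"{chrom}: interval [{start}, {end}) is empty or inverted"
                        )

    @property
    def sv_count_actual(self) -> int:
        return sum(len(v) for v in self.sv_truth.values())

    @property
    def sv_count_called(self) -> int:
        return sum(len(v) for v in self.sv_called.values())


@dataclass
class CohortData:
    """Per-patient full-data variant sets Z_i and subsample call sets C_i."""

    full: list[set[str]]
    called: list[set[str]]

    def __post_init__(self) -> None:
        if len(self.full) != len(self.called):
            raise ObjectiveError("full/called patient lists differ in length")

    @property
    def n_patients(self) -> int:
        return len(self.full)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def snv_recall(v: VariantSets) -> float:
    """Fraction of truth SNVs recovered by the calls."""
    if not v.snv_truth:
        raise ObjectiveError("SNV recall undefined: empty truth set")
    return len(v.snv_called & v.snv_truth) / len(v.snv_truth)


def sv_overlap_score(v: VariantSets) -> float:
    """Interval-overlap SV score in [0, 1].

    Per chromosome i, the fraction of truth intervals D_i overlapped by at
    least one called interval in C_i; chromosome fractions are combined as
    a weighted mean with weights |C_i| + |D_i|.
    """
    chroms = [c for c, ivals in v.sv_truth.items() if ivals]
    if not chroms:
        raise ObjectiveError("SV score undefined: no truth intervals")
    num = 0.0
    denom = 0.0
    for chrom in chroms:
        truth = v.sv_truth[chrom]
        called = v.sv_called.get(chrom, [])
        tree = IntervalTree.from_tuples(called) if called else IntervalTree()
        hits = sum(1 for (a, b) in truth if tree.overlap(a, b))
        frac = hits / len(truth)
        w = len(called) + len(truth)
        num += w * frac
        denom += w
    return num / denom


def mutation_discovery_loss(v: VariantSets, *, oriented: bool = True) -> float:
    """Mean of SNV recall and the SV overlap score; oriented as
    1 − (recall + SVscore)/2 so perfect calling scores 0."""
    raw = (snv_recall(v) + sv_overlap_score(v)) / 2.0
    return 1.0 - raw if oriented else raw


def sv_rate_loss(sv_called: int, sv_actual: int) -> float:
    """Relative error of the called SV count: |SV_C − SV_A| / SV_A."""
    if sv_actual <= 0:
        raise ObjectiveError("SV rate loss undefined: SV_A must be positive")
    if sv_called < 0:
        raise ObjectiveError("negative called SV count")
    return abs(sv_called - sv_actual) / sv_actual


def poisson_threshold_loss(
    sv_called: int,
    sv_actual: int,
    threshold: float,
    caller_failed: bool = False,
    *,
    mid_p: bool = False,
) -> int:
    """Thresholded power loss for an SV-count screening test.

    Modeling the called count as Poisson with mean SV_A, the quantile level
    u = PoissonCDF(SV_C; SV_A) of the observed count is compared against
    the median: the design passes (loss 0) when |u − 0.5| ≤ threshold,
    fails (loss 2) otherwise, and a caller failure is the sentinel loss 3.
    ``mid_p`` subtracts half the point mass at SV_C from u.
    """
    if caller_failed:
        return 3
    if sv_actual <= 0:
        raise ObjectiveError("SV_A must be positive")
    if sv_called < 0:
        raise ObjectiveError("negative called SV count")
    if not 0 < threshold < 0.5:
        raise ObjectiveError("threshold must lie in (0, 0.5)")
    u = float(poisson.cdf(sv_called, sv_actual))
    if mid_p:
        u -= 0.5 * float(poisson.pmf(sv_called, sv_actual))
    return 0 if abs(u - 0.5) <= threshold else 2


def subsample_recall_loss(c: CohortData, *, oriented: bool = True) -> float:
    """Cohort variant recall: mean over patients of |Z_i ∩ C_i| / |Z_i|,
    oriented as 1 − recall by default."""
    if c.n_patients < 1:
        raise ObjectiveError("cohort has no patients")
    recalls = []
    for i, (z, called) in enumerate(zip(c.full, c.called)):
        if not z:
            raise ObjectiveError(f"patient {i}: empty full-data variant set Z_i")
        recalls.append(len(z & called) / len(z))
    r = sum(recalls) / len(recalls)
    return 1.0 - r if oriented else r


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------

def biopsy_cost(coverage: float, samples: float) -> float:
    """Liquid-biopsy cost g = coverage·samples / 300, normalized to [0, 1]
    by the maxima of 100× coverage and three samples."""
    if not 0 <= coverage <= 100:
        raise ObjectiveError("coverage must lie in [0, 100]")
    if not 1 <= samples <= 3:
        raise ObjectiveError("samples must lie in [1, 3]")
    return coverage * samples / 300.0


@dataclass
class MultiplicativeCostSpec:
    """Linear + pairwise-product cost family over numeric design variables.

    ``linear`` maps variable name → coefficient; ``interactions`` lists
    (name_a, name_b, coefficient) product terms.  An example default models
    cost rising with depth and accuracy: per-unit coverage and sample terms
    plus a coverage×samples interaction.
    """

    linear: dict[str, float] = field(default_factory=dict)
    interactions: list[tuple[str, str, float]] = field(default_factory=list)


def multiplicative_cost(x: StudyDesign, spec: MultiplicativeCostSpec) -> float:
    """Evaluate the linear-plus-interaction cost at a design."""
    total = 0.0
    for name, w in spec.linear.items():
        total += w * _numeric_value(x, name)
    for a, b, w in spec.interactions:
        total += w * _numeric_value(x, a) * _numeric_value(x, b)
    return total


def _numeric_value(x: StudyDesign, name: str) -> float:
    v = x[name]
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise ObjectiveError(f"cost term references non-numeric variable {name!r}")
    return float(v)


# ---------------------------------------------------------------------------
# I/O: BED intervals, identifier lists, optional VCF
# ---------------------------------------------------------------------------

def read_bed(path) -> dict[str, list[Interval]]:
    """Read a 3+ column BED (0-based, half-open) into per-chromosome lists."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": int, "end": int},
    )
    out: dict[str, list[Interval]] = {}
    for rec in df.itertuples(index=False):
        out.setdefault(rec.chrom, []).append((int(rec.start), int(rec.end)))
    return out


def write_bed(intervals: Mapping[str, Sequence[Interval]], path) -> None:
    rows = [
        (chrom, a, b)
        for chrom in sorted(intervals)
        for (a, b) in sorted(intervals[chrom])
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_id_list(path) -> set[str]:
    """Newline-delimited variant identifiers (CHROM:POS:REF:ALT by
    convention); blank lines and #-comments ignored."""
    with open(path) as fh:
        return {
            line.strip()
            for line in fh
            if line.strip() and not line.startswith("#")
        }


def write_id_list(ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for ident in sorted(ids):
            fh.write(f"{ident}\n")


def read_vcf_ids(path) -> set[str]:
    """Variant identities (CHROM:POS:REF:ALT) from a VCF; genotypes ignored."""
    from cyvcf2 import VCF

    out = set()
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            out.add(f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}")
    return out
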