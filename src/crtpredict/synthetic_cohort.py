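"""Seeded synthetic cohorts with planted class-specific differential expression.

The generator emulates an RMA-style log2 expression matrix: per-gene baselines
drawn uniformly on the log2 scale, Gaussian within-gene noise, and two disjoint
planted gene sets whose means are shifted in the TO and MI samples
respectively.  A second module derives a distorted "other platform" dataset
(reduced gene set, affine intensity map, extra noise) so that cross-platform
harmonization can be exercised without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort_io import CohortDataset, DworakLabels, ExpressionMatrix, GRADES
from .errors import SpecError

#: Per-grade sample counts of the modeled study cohort (MI, MO, NT, TO).
DEFAULT_CLASS_SIZES = (10, 36, 13, 18)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic cohort draw."""

    seed: int = 0
    n_genes: int = 2000
    class_sizes: tuple[int, int, int, int] = DEFAULT_CLASS_SIZES
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    within_gene_sd: float = 1.0
    n_planted_to: int = 100
    delta_to: float = 1.0
    n_planted_mi: int = 100
    delta_mi: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise SpecError("n_genes must be positive")
        if len(self.class_sizes) != 4 or any(c <= 0 for c in self.class_sizes):
            raise SpecError("class_sizes must be four positive counts")
        if self.within_gene_sd <= 0:
            raise SpecError("within_gene_sd must be positive")
        if self.n_planted_to < 0 or self.n_planted_mi < 0:
            raise SpecError("planted counts must be non-negative")
        if self.n_planted_to + self.n_planted_mi > self.n_genes:
            raise SpecError(
                "planted TO and MI gene sets cannot be disjoint: "
                f"{self.n_planted_to} + {self.n_planted_mi} > {self.n_genes} genes"
            )
        lo, hi = self.baseline_mean_range
        if not lo < hi:
            raise SpecError("baseline_mean_range must be a non-empty interval")


@dataclass(frozen=True)
class PlantedTruth:
    """Which genes carry a planted shift, and by how much."""

    to_genes: frozenset[str]
    mi_genes: frozenset[str]
    deltas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.to_genes & self.mi_genes:
            raise SpecError("planted TO and MI gene sets overlap")


@dataclass(frozen=True)
class PlatformDistortionSpec:
    """Affine+noise distortion emulating a second array platform.

    Each retained value x becomes ``scale * x + offset + N(0, noise_sd)``,
    on a seeded random subset of ``ceil(keep_fraction * n_genes)`` genes.
    """

    seed: int = 0
    keep_fraction: float = 0.6
    scale: float = 0.8
    offset: float = 1.5
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.keep_fraction <= 1:
            raise SpecError("keep_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be non-negative")


def _gene_ids(n: int) -> tuple[str, ...]:
    width = max(4, len(str(n)))
    return tuple(f"G{i:0{width}d}" for i in range(1, n + 1))


def _sample_ids(n: int) -> tuple[str, ...]:
    return tuple(f"S{i:03d}" for i in range(1, n + 1))


def generate_cohort(spec: SyntheticSpec) -> tuple[CohortDataset, PlantedTruth]:
    """Draw one cohort: expression, grade labels, and the planted truth.

    The value for gene g in sample s is
    ``mu_g + delta * 1[g planted for s's grade] + eps`` with
    ``mu_g ~ U(baseline_mean_range)`` and ``eps ~ N(0, within_gene_sd)``.
    Labels carry exactly the requested per-grade counts; everything is a
    deterministic function of ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)

    n_samples = sum(spec.class_sizes)
    samples = _sample_ids(n_samples)
    grades: list[str] = []
    for grade, count in zip(GRADES, spec.class_sizes):
        grades.extend([grade] * count)
    labels = DworakLabels(samples, tuple(grades))

    mu = rng.uniform(*spec.baseline_mean_range, size=spec.n_genes)
    values = mu[:, None] + rng.normal(
        0.0, spec.within_gene_sd, size=(spec.n_genes, n_samples)
    )

    planted = rng.choice(
        spec.n_genes, size=spec.n_planted_to + spec.n_planted_mi, replace=False
    )
    to_idx = planted[: spec.n_planted_to]
    mi_idx = planted[spec.n_planted_to:]

    grade_arr = np.array(grades)
    to_cols = grade_arr == "TO"
    mi_cols = grade_arr == "MI"
    values[np.ix_(to_idx, to_cols)] += spec.delta_to
    values[np.ix_(mi_idx, mi_cols)] += spec.delta_mi

    expr = ExpressionMatrix(genes, samples, values)
    truth = PlantedTruth(
        to_genes=frozenset(genes[i] for i in to_idx),
        mi_genes=frozenset(genes[i] for i in mi_idx),
        deltas={"TO": spec.delta_to, "MI": spec.delta_mi},
    )
    return CohortDataset(expr, labels), truth


def distort_platform(
    expr: ExpressionMatrix, spec: PlatformDistortionSpec
) -> ExpressionMatrix:
    """Derive a "second platform" matrix from ``expr``.

    A seeded random subset of ``ceil(keep_fraction * n_genes)`` genes is
    retained (input gene order preserved); each value is mapped through
    ``scale * x + offset`` plus Gaussian noise.  Sample ids are unchanged.
    """
    rng = np.random.default_rng(spec.seed)
    n_keep = math.ceil(spec.keep_fraction * expr.n_genes)
    keep = np.sort(rng.choice(expr.n_genes, size=n_keep, replace=False))
    sub = expr.values[keep, :]
    noise = rng.normal(0.0, spec.noise_sd, size=sub.shape) if spec.noise_sd > 0 else 0.0
    distorted = spec.scale * sub + spec.offset + noise
    return ExpressionMatrix(
        tuple(expr.gene_ids[i] for i in keep), expr.sample_ids, distorted
    )


def write_truth(truth: PlantedTruth, path) -> None:
    """Write the planted-truth table as a two-column TSV (gene, contrast)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tcontrast\tdelta\n")
        for g in sorted(truth.to_genes):
            fh.write(f"{g}\tTO\t{truth.deltas.get('TO', '')!r}\n")
        for g in sorted(truth.mi_genes):
            fh.write(f"{g}\tMI\t{truth.deltas.get('MI', '')!r}\n")
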