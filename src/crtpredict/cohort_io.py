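"""Cohort data structures and text I/O.

The interchange formats are deliberately plain: tab-delimited UTF-8 text with a
header row.  An expression matrix has genes on rows (first column header
``gene``) and samples on columns; a label table has two columns
(``sample_id``, ``grade``).  Values are serialized with full ``repr``
precision so a write/read round trip is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    DuplicateGeneError,
    LabelError,
    ParseError,
)

#: The four tumor-regression grades modeled by the pipeline.  Grade 0
#: ("no regression") exists in the Dworak scale but is absent from the
#: cohort definition and rejected on input.
GRADES = ("MI", "MO", "NT", "TO")

# Accepted spellings for each grade on input (case-insensitive).
_GRADE_SYNONYMS = {
    "MI": "MI", "1": "MI", "G1": "MI", "GRADE1": "MI", "GRADE 1": "MI",
    "MO": "MO", "2": "MO", "G2": "MO", "GRADE2": "MO", "GRADE 2": "MO",
    "NT": "NT", "3": "NT", "G3": "NT", "GRADE3": "NT", "GRADE 3": "NT",
    "TO": "TO", "4": "TO", "G4": "TO", "GRADE4": "TO", "GRADE 4": "TO",
}


def normalize_grade(raw: str) -> str:
    """Map a grade spelling ("1", "G1", "MI", ...) to its canonical symbol.

    Raises
    ------
    LabelError
        If the value is not a recognized grade, including grade 0.
    """
    key = raw.strip().upper()
    try:
        return _GRADE_SYNONYMS[key]
    except KeyError:
        raise LabelError(
            f"unrecognized Dworak grade {raw!r}; expected one of "
            f"{GRADES} or a numeric grade 1-4"
        ) from None


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression intensities.

    Attributes
    ----------
    gene_ids : tuple of str
        Unique, non-empty gene symbols, one per row.
    sample_ids : tuple of str
        Unique sample names, one per column.
    values : numpy.ndarray
        Finite float matrix of shape ``(len(gene_ids), len(sample_ids))``.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.gene_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "values", values)
        if not genes:
            raise ParseError("expression matrix has no genes")
        if any(g == "" for g in genes):
            raise ParseError("empty gene identifier")
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise DuplicateGeneError(f"duplicate gene identifiers: {dupes}")
        if len(set(samples)) != len(samples):
            raise ParseError("duplicate sample identifiers")
        if values.ndim != 2 or values.shape != (len(genes), len(samples)):
            raise ParseError(
                f"value shape {values.shape} inconsistent with "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        if not np.all(np.isfinite(values)):
            raise ParseError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices of ``genes``, raising ``KeyError`` on a miss."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(tuple(genes), self.sample_ids, self.values[idx, :])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in samples], dtype=int)
        return ExpressionMatrix(self.gene_ids, tuple(samples), self.values[:, idx])


@dataclass(frozen=True)
class DworakLabels:
    """Per-sample tumor-regression grade in ``{MI, MO, NT, TO}``."""

    sample_ids: tuple[str, ...]
    grades: tuple[str, ...]

    def __post_init__(self) -> None:
        samples = tuple(str(s) for s in self.sample_ids)
        grades = tuple(normalize_grade(g) for g in self.grades)
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "grades", grades)
        if len(samples) != len(grades):
            raise LabelError("sample_ids and grades differ in length")
        if len(set(samples)) != len(samples):
            dupes = sorted({s for s in samples if samples.count(s) > 1})
            raise LabelError(f"duplicate sample ids: {dupes}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.grades))

    def counts(self) -> dict[str, int]:
        """Number of samples per grade, keyed by canonical grade symbol."""
        out = {g: 0 for g in GRADES}
        for g in self.grades:
            out[g] += 1
        return out

    def reorder(self, sample_ids: Iterable[str]) -> "DworakLabels":
        mapping = self.as_dict()
        ordered = tuple(sample_ids)
        missing = [s for s in ordered if s not in mapping]
        if missing:
            raise AlignmentError(f"samples absent from labels: {missing}")
        return DworakLabels(ordered, tuple(mapping[s] for s in ordered))


@dataclass(frozen=True)
class CohortDataset:
    """An expression matrix bound to sample labels, aligned by sample id."""

    expression: ExpressionMatrix
    labels: DworakLabels

    def __post_init__(self) -> None:
        if self.labels.sample_ids != self.expression.sample_ids:
            raise AlignmentError(
                "labels are not aligned to expression sample order; "
                "use bind_cohort()"
            )

    @property
    def grades(self) -> tuple[str, ...]:
        return self.labels.grades

    def binary_response(self, target_class: str) -> np.ndarray:
        """Boolean vector: True where the sample's grade equals ``target_class``."""
        return np.array([g == target_class for g in self.grades], dtype=bool)


def read_expression_matrix(path: str | Path, fmt: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples TSV (first row sample ids, first column genes).

    Row and column order is preserved from the file.

    Raises
    ------
    DuplicateGeneError
        If a gene symbol occurs on two rows.
    ParseError
        On a non-numeric or missing cell, or a malformed table.
    """
    if fmt != "tsv":
        raise ParseError(f"unsupported format {fmt!r}")
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(sample_ids) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, "
                    f"got {len(cells)}"
                )
            genes.append(cells[0])
            try:
                rows.append([float(c) for c in cells[1:]])
            except ValueError:
                bad = next(c for c in cells[1:] if not _is_float(c))
                raise ParseError(
                    f"{path}:{lineno}: non-numeric cell {bad!r} for gene "
                    f"{cells[0]!r}"
                ) from None
    if not genes:
        raise ParseError(f"{path}: no data rows")
    values = np.array(rows, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ParseError(f"{path}: non-finite value in matrix")
    return ExpressionMatrix(tuple(genes), tuple(sample_ids), values)


def _is_float(cell: str) -> bool:
    try:
        float(cell)
    except ValueError:
        return False
    return True


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write a TSV readable by :func:`read_expression_matrix` (exact round trip)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(expr.sample_ids) + "\n")
        for g, row in zip(expr.gene_ids, expr.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_labels(path: str | Path) -> DworakLabels:
    """Read a two-column (sample_id, grade) TSV with a header row.

    Grade synonyms ("1", "G1", "MI", ...) are normalized to canonical
    symbols; grade 0 and unknown values raise :class:`LabelError`.
    """
    path = Path(path)
    samples: list[str] = []
    grades: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise LabelError(f"{path}: empty label file")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 2:
                raise LabelError(f"{path}:{lineno}: expected 2 columns")
            samples.append(cells[0])
            grades.append(cells[1])
    return DworakLabels(tuple(samples), tuple(grades))


def write_labels(labels: DworakLabels, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tgrade\n")
        for s, g in zip(labels.sample_ids, labels.grades):
            fh.write(f"{s}\t{g}\n")


def bind_cohort(expr: ExpressionMatrix, labels: DworakLabels) -> CohortDataset:
    """Align labels to the expression sample order and bind them.

    Samples are matched by id, not position.  A sample present in only one
    of the two inputs raises :class:`AlignmentError`.
    """
    expr_set = set(expr.sample_ids)
    label_set = set(labels.sample_ids)
    if expr_set != label_set:
        only_expr = sorted(expr_set - label_set)
        only_labels = sorted(label_set - expr_set)
        raise AlignmentError(
            f"sample id mismatch: {only_expr or '-'} only in expression, "
            f"{only_labels or '-'} only in labels"
        )
    return CohortDataset(expr, labels.reorder(expr.sample_ids))
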