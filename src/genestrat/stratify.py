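"""Per-cell-line classification of genes into expressed / non-expressed /
indeterminate, and cross-cell-line set intersections.

A gene is expressed in a cell line when its log2CPM exceeds the cutoff in
strictly more than the consistency fraction of that line's samples
(default: >0 in >95 %), non-expressed when it falls below the cutoff in
more than that fraction, and indeterminate otherwise.  Values exactly at
the cutoff count toward neither side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SampleMetadata
from .normalize import NormalizedMatrix

__all__ = [
    "CLASS_LABELS",
    "ClassificationParams",
    "ClassificationTable",
    "classify_gene",
    "classify_all",
    "class_intersections",
    "cross_class_counts",
]

CLASS_LABELS = ("expressed", "non_expressed", "indeterminate")


@dataclass
class ClassificationParams:
    log2cpm_cutoff: float = 0.0
    consistency: float = 0.95

    def __post_init__(self) -> None:
        if not (0.5 < self.consistency <= 1.0):
            raise ValueError("consistency must be in (0.5, 1]")


@dataclass
class ClassificationTable:
    """Gene x cell line class labels plus reactive flags and dip statistics.

    ``reactive`` may only be true where the class is indeterminate; dip
    statistics are NaN wherever the dip test was not run.
    """

    gene_ids: list[str]
    cell_lines: list[str]
    class_: np.ndarray
    reactive: np.ndarray
    dip_stat: np.ndarray
    dip_p: np.ndarray
    dip_p_adj: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.gene_ids), len(self.cell_lines))
        for name in ("class_", "reactive", "dip_stat", "dip_p", "dip_p_adj"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} has wrong shape")
        if np.any(self.reactive & (self.class_ != "indeterminate")):
            raise ValueError("reactive flags are only valid on indeterminate entries")

    def line_index(self, cell_line: str) -> int:
        try:
            return self.cell_lines.index(cell_line)
        except ValueError:
            raise KeyError(f"unknown cell line {cell_line!r}") from None

    def genes_with(self, label: str, cell_line: str) -> list[str]:
        c = self.line_index(cell_line)
        return [g for g, cls in zip(self.gene_ids, self.class_[:, c]) if cls == label]


def classify_gene(values, params: ClassificationParams | None = None) -> str:
    """Classify one gene's per-sample log2CPM vector in one cell line."""
    if params is None:
        params = ClassificationParams()
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot classify an empty expression vector")
    frac_above = np.count_nonzero(v > params.log2cpm_cutoff) / v.size
    frac_below = np.count_nonzero(v < params.log2cpm_cutoff) / v.size
    if frac_above > params.consistency:
        return "expressed"
    if frac_below > params.consistency:
        return "non_expressed"
    return "indeterminate"


def classify_all(
    norm: NormalizedMatrix,
    meta: list[SampleMetadata],
    params: ClassificationParams | None = None,
    gene_universe: list[str] | None = None,
) -> ClassificationTable:
    """Classify every gene per cell line (samples pooled across datasets).

    Cell-line grouping comes solely from the metadata.  Genes listed in
    ``gene_universe`` but absent from the normalized matrix are reported
    as ``"unclassified"`` — not measured is distinct from measured off.
    Reactive flags start false; :func:`genestrat.dip.flag_reactive` sets
    them.
    """
    if params is None:
        params = ClassificationParams()
    meta_ids = {m.sample_id for m in meta}
    unknown = [s for s in norm.sample_ids if s not in meta_ids]
    if unknown:
        raise ValueError(f"samples without metadata: {unknown[:5]}")
    by_line: dict[str, list[str]] = {}
    for m in meta:
        if m.sample_id in norm.sample_ids:
            by_line.setdefault(m.cell_line, []).append(m.sample_id)
    cell_lines = sorted(by_line)
    for line, ids in by_line.items():
        if len(ids) < 2:
            raise ValueError(f"cell line {line!r} has fewer than 2 samples")

    gene_ids = list(gene_universe) if gene_universe is not None else list(norm.gene_ids)
    norm_index = {g: i for i, g in enumerate(norm.gene_ids)}
    n, k = len(gene_ids), len(cell_lines)
    class_ = np.full((n, k), "unclassified", dtype=object)
    for c, line in enumerate(cell_lines):
        cols = norm.sample_columns(by_line[line])
        for i, g in enumerate(gene_ids):
            if g in norm_index:
                class_[i, c] = classify_gene(cols[norm_index[g]], params)
    return ClassificationTable(
        gene_ids, cell_lines, class_,
        reactive=np.zeros((n, k), dtype=bool),
        dip_stat=np.full((n, k), np.nan),
        dip_p=np.full((n, k), np.nan),
        dip_p_adj=np.full((n, k), np.nan),
    )


def class_intersections(
    table: ClassificationTable, which: str
) -> dict[tuple[str, ...], int]:
    """Distinct (exclusive) intersection counts for one class label.

    Each gene carrying the label in at least one cell line is assigned to
    exactly one subset: the full set of cell lines in which it carries
    the label.  The subsets therefore partition those genes, as in the
    distinct-mode intersections of an upset plot.
    """
    if which not in CLASS_LABELS and which != "reactive":
        raise ValueError(f"unknown class label {which!r}")
    counts: dict[tuple[str, ...], int] = {}
    for i in range(len(table.gene_ids)):
        if which == "reactive":
            members = tuple(
                line for c, line in enumerate(table.cell_lines) if table.reactive[i, c]
            )
        else:
            members = tuple(
                line for c, line in enumerate(table.cell_lines)
                if table.class_[i, c] == which
            )
        if members:
            counts[members] = counts.get(members, 0) + 1
    return counts


def cross_class_counts(
    table: ClassificationTable, line_a: str, line_b: str
) -> int:
    """Number of genes expressed in ``line_a`` AND non-expressed in
    ``line_b`` (asymmetric; the two orders are independent counts)."""
    if line_a == line_b:
        raise ValueError("cross-class comparison of a cell line with itself is undefined")
    a = table.line_index(line_a)
    b = table.line_index(line_b)
    return int(np.count_nonzero(
        (table.class_[:, a] == "expressed") & (table.class_[:, b] == "non_expressed")
    ))
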