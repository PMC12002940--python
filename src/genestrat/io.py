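"""Readers and writers for the tabular formats the pipeline touches.

Formats handled here:

* featureCounts gene-level count tables (with or without the annotation
  columns ``Chr``/``Start``/``End``/``Strand``/``Length`` and the leading
  ``# Program`` comment line),
* GTF gene models (GFF2 dialect with ``gene_id`` / ``transcript_id`` /
  ``gene_biotype`` attributes),
* per-chromosome chromatin-state posterior tables and hard segmentation
  BED files,
* sample metadata tables and the per-gene classification output.

Coordinate conventions: GTF records are 1-based inclusive and are stored
as such on :class:`GeneModel`.  Everything downstream that does interval
arithmetic (see :mod:`genestrat.enrich`) converts to 0-based half-open at
the module boundary.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleMetadata",
    "GeneModel",
    "StatePosteriorTrack",
    "FormatError",
    "read_featurecounts",
    "read_gene_models",
    "longest_transcript_length",
    "read_state_posteriors",
    "read_segmentation_bed",
    "read_metadata",
    "write_classification",
    "read_classification",
]

#: featureCounts annotation columns that are skipped when building the
#: count matrix.
FEATURECOUNTS_ANNOTATION_COLUMNS = ("Chr", "Start", "End", "Strand", "Length")

LIBRARY_PREPS = ("polyA", "rRNA_depletion")
READ_LAYOUTS = ("single", "paired")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class CountMatrix:
    """Raw gene x sample integer counts.

    Attributes
    ----------
    gene_ids
        Ordered, unique gene identifiers (rows).
    sample_ids
        Ordered, unique sample identifiers (columns).
    counts
        Non-negative integer matrix of shape ``(len(gene_ids), len(sample_ids))``.
    lengths
        Optional per-gene length side table (populated when the source
        featureCounts file carried a ``Length`` column).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotation: originating dataset, cell line and protocol."""

    sample_id: str
    dataset: str
    cell_line: str
    library_prep: str = "polyA"
    read_layout: str = "paired"

    def __post_init__(self) -> None:
        if self.library_prep not in LIBRARY_PREPS:
            raise ValueError(f"unknown library_prep {self.library_prep!r}")
        if self.read_layout not in READ_LAYOUTS:
            raise ValueError(f"unknown read_layout {self.read_layout!r}")


@dataclass
class GeneModel:
    """Gene coordinates plus exon structure of each transcript.

    Coordinates are 1-based inclusive (GTF convention); ``strand`` is
    ``'+'`` or ``'-'`` and start/end are genomic (never swapped for minus
    strand genes).
    """

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    transcripts: list[tuple[str, list[tuple[int, int]]]] = field(default_factory=list)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for gene {self.gene_id}")
        if self.gene_start > self.gene_end:
            raise ValueError(f"gene_start > gene_end for gene {self.gene_id}")
        for _, exons in self.transcripts:
            for s, e in exons:
                if s > e:
                    raise ValueError(f"exon start > end in gene {self.gene_id}")
                if s < self.gene_start or e > self.gene_end:
                    raise ValueError(
                        f"exon [{s},{e}] outside gene bounds in {self.gene_id}"
                    )


@dataclass
class StatePosteriorTrack:
    """Chromatin state posteriors for one chromosome, one row per bin.

    Each row sums to 1; hard segmentations are represented as one-hot
    rows.  ``chrom_length`` defaults to ``n_bins * bin_size``; a shorter
    value marks the final bin as partial.
    """

    chrom: str
    bin_size: int
    states: list[str]
    posteriors: np.ndarray
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        if self.posteriors.ndim != 2 or self.posteriors.shape[1] != len(self.states):
            raise ValueError("posteriors must be (bins x states)")
        sums = self.posteriors.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("posterior rows must sum to 1 within 1e-6")
        n_bins = self.posteriors.shape[0]
        if self.chrom_length is None:
            self.chrom_length = n_bins * self.bin_size
        if not (self.bin_size * (n_bins - 1) < self.chrom_length <= self.bin_size * n_bins):
            raise ValueError("bins must cover the chromosome length (last bin may be partial)")

    @property
    def n_bins(self) -> int:
        return self.posteriors.shape[0]

    def bin_lengths(self) -> np.ndarray:
        """Base-pair span of every bin (last may be partial)."""
        lens = np.full(self.n_bins, self.bin_size, dtype=float)
        lens[-1] = self.chrom_length - self.bin_size * (self.n_bins - 1)
        return lens


# ---------------------------------------------------------------------------
# featureCounts
# ---------------------------------------------------------------------------

def read_featurecounts(path, id_column: str = "Geneid") -> CountMatrix:
    """Read a featureCounts-style tab-separated count table.

    The optional ``# Program`` comment line and the annotation columns
    (``Chr``, ``Start``, ``End``, ``Strand``, ``Length``) are skipped;
    every remaining non-id column becomes exactly one sample, preserving
    file order.  A ``Length`` column, when present, is retained on the
    returned matrix as :attr:`CountMatrix.lengths`.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if id_column not in df.columns:
        raise FormatError(f"id column {id_column!r} not found in {path}")
    gene_ids = df[id_column].tolist()
    if len(set(gene_ids)) != len(gene_ids):
        dup = df[id_column][df[id_column].duplicated()].iloc[0]
        raise FormatError(f"duplicate gene id {dup!r} in {path}")

    lengths = None
    if "Length" in df.columns:
        lengths = pd.Series(
            pd.to_numeric(df["Length"]).to_numpy(), index=gene_ids, name="length"
        )

    sample_cols = [
        c for c in df.columns
        if c != id_column and c not in FEATURECOUNTS_ANNOTATION_COLUMNS
    ]
    counts = np.empty((len(gene_ids), len(sample_cols)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise FormatError(
                f"non-numeric count in column {col!r}, row {row} "
                f"(gene {gene_ids[row]!r})"
            )
        arr = vals.to_numpy()
        if np.any(arr != np.floor(arr)):
            row = int(np.nonzero(arr != np.floor(arr))[0][0])
            raise FormatError(
                f"non-integer count {arr[row]!r} in column {col!r}, row {row} "
                f"(gene {gene_ids[row]!r})"
            )
        counts[:, j] = arr.astype(np.int64)
    return CountMatrix(gene_ids, sample_cols, counts, lengths=lengths)


def write_featurecounts(cm: CountMatrix, path, lengths: pd.Series | None = None) -> None:
    """Write a count matrix in featureCounts layout (Geneid [+Length] + samples)."""
    df = pd.DataFrame({"Geneid": cm.gene_ids})
    if lengths is None:
        lengths = cm.lengths
    if lengths is not None:
        df["Length"] = lengths.reindex(cm.gene_ids).to_numpy()
    for j, sid in enumerate(cm.sample_ids):
        df[sid] = cm.counts[:, j]
    with open(path, "w") as fh:
        fh.write("# genestrat featureCounts-style count table\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------

def read_gene_models(gtf_path, biotype_filter: str | None = None) -> list[GeneModel]:
    """Parse a GTF into one :class:`GeneModel` per gene.

    Exon records are grouped by ``transcript_id``; the gene span is the
    envelope of its ``gene`` record if present, else of its exons.  When
    ``biotype_filter`` is given (e.g. ``"protein_coding"``), genes of any
    other ``gene_biotype`` are dropped.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    genes: dict[str, dict] = {}

    def _entry(gid: str) -> dict:
        return genes.setdefault(
            gid,
            {"chrom": None, "strand": None, "start": None, "end": None,
             "biotype": None, "transcripts": {}, "order": len(genes)},
        )

    for feat in db.all_features(order_by=("seqid", "start")):
        ftype = feat.featuretype
        if ftype not in ("gene", "transcript", "exon"):
            continue
        gid_list = feat.attributes.get("gene_id")
        if not gid_list:
            raise FormatError(f"{ftype} record without gene_id in {gtf_path}")
        gid = gid_list[0]
        entry = _entry(gid)
        if feat.strand not in ("+", "-"):
            raise FormatError(f"unknown strand {feat.strand!r} for gene {gid}")
        if entry["strand"] is None:
            entry["strand"] = feat.strand
            entry["chrom"] = feat.seqid
        bt = feat.attributes.get("gene_biotype")
        if bt and entry["biotype"] is None:
            entry["biotype"] = bt[0]
        if ftype == "gene":
            entry["start"], entry["end"] = feat.start, feat.end
        elif ftype == "exon":
            tid_list = feat.attributes.get("transcript_id")
            if not tid_list:
                raise FormatError(f"exon without transcript_id for gene {gid}")
            entry["transcripts"].setdefault(tid_list[0], []).append((feat.start, feat.end))

    models = []
    for gid, entry in sorted(genes.items(), key=lambda kv: kv[1]["order"]):
        biotype = entry["biotype"] or "unknown"
        if biotype_filter is not None and biotype != biotype_filter:
            continue
        exon_spans = [iv for ivs in entry["transcripts"].values() for iv in ivs]
        start = entry["start"]
        end = entry["end"]
        if start is None:
            if not exon_spans:
                raise FormatError(f"gene {gid} has neither a gene record nor exons")
            start = min(s for s, _ in exon_spans)
            end = max(e for _, e in exon_spans)
        transcripts = [
            (tid, sorted(ivs)) for tid, ivs in sorted(entry["transcripts"].items())
        ]
        models.append(
            GeneModel(gid, entry["chrom"], entry["strand"], start, end,
                      transcripts=transcripts, biotype=biotype)
        )
    return models


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended 1-based inclusive intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def longest_transcript_length(model: GeneModel) -> int:
    """Sum of exon lengths of the gene's longest transcript.

    Exons within a transcript are merged before summation so malformed
    annotations with overlapping exon records are not double-counted.
    Lengths use inclusive coordinates (``end - start + 1`` per exon).
    """
    if not model.transcripts:
        raise ValueError(f"gene {model.gene_id} has no transcripts")
    best = 0
    for _, exons in model.transcripts:
        if not exons:
            raise ValueError(f"transcript without exons in gene {model.gene_id}")
        length = sum(e - s + 1 for s, e in merge_intervals(exons))
        best = max(best, length)
    return best


def gene_length_table(models: list[GeneModel]) -> pd.Series:
    """Per-gene longest-transcript length as a Series indexed by gene id."""
    return pd.Series(
        {m.gene_id: longest_transcript_length(m) for m in models}, name="length"
    )


def read_gene_lengths(path) -> pd.Series:
    """Read a two-column (gene_id, length) TSV."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"gene length table {path} needs gene_id and length columns")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].tolist(), name="length")


def write_gene_lengths(lengths: pd.Series, path) -> None:
    pd.DataFrame({"gene_id": lengths.index, "length": lengths.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# chromatin state posteriors
# ---------------------------------------------------------------------------

def read_state_posteriors(
    path, bin_size: int = 200, chrom: str | None = None,
    chrom_length: int | None = None,
) -> StatePosteriorTrack:
    """Read one chromosome's posterior table (header of state labels, one
    row per 200 bp bin).

    Rows whose sum deviates from 1 by at most 1e-4 are renormalized
    (text-file rounding); larger deviations raise :class:`FormatError`.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"empty posterior file {path}")
    states = lines[0].split("\t")
    rows = []
    for i, ln in enumerate(lines[1:], start=1):
        cells = ln.split("\t")
        if len(cells) != len(states):
            raise FormatError(f"ragged row {i} in {path}: {len(cells)} cells, "
                              f"expected {len(states)}")
        rows.append([float(c) for c in cells])
    post = np.array(rows, dtype=float)
    sums = post.sum(axis=1)
    bad = np.abs(sums - 1.0) > 1e-4
    if np.any(bad):
        i = int(np.nonzero(bad)[0][0])
        raise FormatError(f"row {i + 1} of {path} sums to {sums[i]:.6g}, not 1")
    post = post / sums[:, None]
    if chrom is None:
        chrom = str(path)
    return StatePosteriorTrack(chrom, bin_size, states, post, chrom_length=chrom_length)


def write_state_posteriors(track: StatePosteriorTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(track.states) + "\n")
        np.savetxt(fh, track.posteriors, delimiter="\t", fmt="%.6f")


def read_segmentation_bed(
    path, states: list[str] | None = None, bin_size: int = 200,
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, StatePosteriorTrack]:
    """Read a hard segmentation BED (chrom, start, end, state; 0-based
    half-open) into one-hot posterior tracks, one per chromosome."""
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "state"], comment="#")
    if states is None:
        states = sorted(bed["state"].unique())
    state_index = {s: i for i, s in enumerate(states)}
    tracks = {}
    for chrom, sub in bed.groupby("chrom", sort=False):
        length = int(sub["end"].max())
        if chrom_lengths and chrom in chrom_lengths:
            length = chrom_lengths[chrom]
        n_bins = -(-length // bin_size)
        post = np.zeros((n_bins, len(states)))
        for _, row in sub.iterrows():
            s, e = int(row["start"]), int(row["end"])
            if s % bin_size or (e % bin_size and e != length):
                raise FormatError(
                    f"segment [{s},{e}) in {path} not aligned to {bin_size} bp bins")
            post[s // bin_size: -(-e // bin_size), state_index[row["state"]]] = 1.0
        if np.any(post.sum(axis=1) != 1.0):
            raise FormatError(f"segmentation of {chrom} in {path} leaves gaps")
        tracks[chrom] = StatePosteriorTrack(chrom, bin_size, list(states), post,
                                            chrom_length=length)
    return tracks


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "dataset", "cell_line"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata {path} lacks columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate sample_id {dup!r} in {path}")
    out = []
    for _, row in df.iterrows():
        out.append(SampleMetadata(
            sample_id=row["sample_id"], dataset=row["dataset"],
            cell_line=row["cell_line"],
            library_prep=row.get("library_prep", "polyA"),
            read_layout=row.get("read_layout", "paired"),
        ))
    return out


def write_metadata(meta: list[SampleMetadata], path) -> None:
    pd.DataFrame([m.__dict__ for m in meta]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# classification table round trip
# ---------------------------------------------------------------------------

def write_classification(table, path) -> None:
    """Write a ClassificationTable as TSV.

    One row per gene; per cell line a class / reactive / dip / p / p_adj
    column group.  Dip statistics that were never computed (classes other
    than indeterminate) are written as empty fields, not zeros, so that
    ``read_classification`` round-trips missingness faithfully.
    """
    cols: dict[str, object] = {"gene_id": table.gene_ids}
    for c, line in enumerate(table.cell_lines):
        cols[f"{line}.class"] = table.class_[:, c]
        cols[f"{line}.reactive"] = table.reactive[:, c].astype(int)
        for name, mat in (("dip", table.dip_stat), ("p", table.dip_p),
                          ("p_adj", table.dip_p_adj)):
            cols[f"{line}.{name}"] = [
                "" if np.isnan(v) else repr(float(v)) for v in mat[:, c]
            ]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_classification(path):
    """Inverse of :func:`write_classification`."""
    from .stratify import ClassificationTable

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    gene_ids = df["gene_id"].tolist()
    cell_lines = [c[:-len(".class")] for c in df.columns if c.endswith(".class")]
    n, k = len(gene_ids), len(cell_lines)
    class_ = np.empty((n, k), dtype=object)
    reactive = np.zeros((n, k), dtype=bool)
    dip_stat = np.full((n, k), np.nan)
    dip_p = np.full((n, k), np.nan)
    dip_p_adj = np.full((n, k), np.nan)
    for c, line in enumerate(cell_lines):
        class_[:, c] = df[f"{line}.class"].to_numpy()
        reactive[:, c] = df[f"{line}.reactive"].astype(int).to_numpy().astype(bool)
        for name, mat in (("dip", dip_stat), ("p", dip_p), ("p_adj", dip_p_adj)):
            raw = df[f"{line}.{name}"].to_numpy()
            filled = raw != ""
            mat[filled, c] = [float(v) for v in raw[filled]]
    return ClassificationTable(gene_ids, cell_lines, class_, reactive,
                               dip_stat, dip_p, dip_p_adj)
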