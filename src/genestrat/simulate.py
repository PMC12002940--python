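"""Synthetic fixture data with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
several datasets per cell line with heterogeneous library sizes,
negative-binomial gene counts, planted gene classes (constitutively
expressed, silent, threshold-hovering, bimodal/reactive plus a small set
of high-abundance background genes that absorb the remaining CPM mass so
planted log2CPM values are realized on the CPM scale), log-normal gene
lengths, and chromatin-state posterior tracks correlated with expression
class.  Everything is driven by a single seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    GeneModel,
    SampleMetadata,
    StatePosteriorTrack,
)

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "simulate_counts",
    "simulate_gene_models",
    "simulate_posteriors",
    "DEFAULT_STATES",
]

DEFAULT_STATES = [
    "ActivePromoter",
    "StrongTranscription",
    "WeakGenicEnhancer",
    "Heterochromatin",
    "PolycombRepressed",
    "Quiescent",
]


@dataclass
class SimulationDesign:
    """Parameters of one synthetic experiment.

    ``cell_lines`` maps cell line name to ``(n_datasets, samples_per_dataset)``.
    ``n_genes`` maps planted class (``expressed``, ``silent``, ``hovering``,
    ``reactive``) to gene count.  ``n_background`` high-abundance filler
    genes absorb the CPM mass not taken by planted genes; ``n_discordant``
    genes are expressed in the first cell line and silent elsewhere.
    """

    cell_lines: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"LINE_A": (4, 10), "LINE_B": (4, 10)})
    n_genes: dict[str, int] = field(
        default_factory=lambda: {"expressed": 100, "silent": 100,
                                 "hovering": 100, "reactive": 100})
    n_background: int = 200
    n_discordant: int = 0
    expressed_mean_log2cpm: float = 5.0
    expressed_sd: float = 0.5
    hovering_sd: float = 0.4
    reactive_separation: float = 6.0
    reactive_mixing: float = 0.5
    # fraction of the mode separation that sits below the cutoff; the low
    # mode needs enough counts to form a tight second mode, so the split
    # is asymmetric by default
    reactive_low_fraction: float = 0.25
    library_size_range: tuple[float, float] = (10e6, 60e6)
    nb_dispersion: float = 0.05
    length_log_mean: float = 8.0
    length_log_sd: float = 0.6
    silent_zero_prob: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cell_lines:
            raise ValueError("need at least one cell line")
        for line, (nd, ns) in self.cell_lines.items():
            if nd < 1 or ns < 1:
                raise ValueError(f"cell line {line!r} needs >=1 dataset and sample")
        if any(v < 0 for v in self.n_genes.values()):
            raise ValueError("gene counts must be >= 0")
        if not (0 < self.reactive_mixing < 1):
            raise ValueError("reactive_mixing must be in (0, 1)")
        if self.reactive_separation <= 0:
            raise ValueError("reactive_separation must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("bad library size range")


@dataclass
class GroundTruth:
    """Planted truth: class per gene x cell line, reactivity flags and the
    per-sample latent high/low state of reactive genes."""

    classes: pd.DataFrame            # genes x cell lines, planted label
    reactive: pd.DataFrame           # genes x cell lines, bool
    latent_high: pd.DataFrame        # genes x samples, bool (reactive only)

    def to_frame(self) -> pd.DataFrame:
        df = self.classes.copy()
        df.columns = [f"{c}.class" for c in df.columns]
        for c in self.reactive.columns:
            df[f"{c}.reactive"] = self.reactive[c].astype(int)
        return df


def _sample_table(design: SimulationDesign) -> list[SampleMetadata]:
    meta = []
    preps = ("polyA", "rRNA_depletion")
    layouts = ("paired", "single")
    for line, (n_ds, n_per) in design.cell_lines.items():
        for d in range(n_ds):
            ds = f"{line}_ds{d + 1}"
            for s in range(n_per):
                meta.append(SampleMetadata(
                    sample_id=f"{ds}_s{s + 1}", dataset=ds, cell_line=line,
                    library_prep=preps[d % 2], read_layout=layouts[d % 2]))
    return meta


def simulate_counts(
    design: SimulationDesign,
) -> tuple[CountMatrix, list[SampleMetadata], pd.Series, GroundTruth]:
    """Generate a count matrix with planted gene classes.

    Per sample, a target library size is drawn from the design range
    (shrunk by a 5 % margin on each side so negative-binomial noise on
    the realized totals stays inside the range) and each gene's expected
    count is its planted CPM times gene length (kb) scaled to that
    depth.  Silent genes are zero with high probability and otherwise
    get 1-2 stray reads.  Reactive genes switch a latent high/low state
    per dataset block, with at least one block in each state per cell
    line so every reactive gene genuinely switches.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    meta = _sample_table(design)
    sample_ids = [m.sample_id for m in meta]
    lines = list(design.cell_lines)

    classes = ["expressed", "silent", "hovering", "reactive"]
    gene_ids: list[str] = []
    gene_class: list[str] = []
    for cls in classes:
        for i in range(design.n_genes.get(cls, 0)):
            gene_ids.append(f"{cls}_{i + 1:04d}")
            gene_class.append(cls)
    for i in range(design.n_discordant):
        gene_ids.append(f"discordant_{i + 1:04d}")
        gene_class.append("discordant")
    for i in range(design.n_background):
        gene_ids.append(f"background_{i + 1:04d}")
        gene_class.append("background")
    n_genes = len(gene_ids)
    if n_genes == 0 or not sample_ids:
        raise ValueError("infeasible design: zero genes or zero samples")

    lengths = np.round(
        np.exp(rng.normal(design.length_log_mean, design.length_log_sd, n_genes))
    ).astype(np.int64)
    lengths = np.maximum(lengths, 200)
    length_series = pd.Series(lengths, index=gene_ids, name="length")

    # Planted per-gene log2CPM levels (cutoff-relative; cutoff is 0).
    m_expr = rng.normal(design.expressed_mean_log2cpm, design.expressed_sd, n_genes)
    m_hover = rng.normal(0.0, design.hovering_sd, n_genes)
    cls_arr = np.array(gene_class)

    # Background genes absorb the CPM mass so that sum(2^m) ~= 1e6 and the
    # planted log2CPM scale is realized after normalization.
    m_react_high = design.reactive_separation * (1.0 - design.reactive_low_fraction)
    m_react_low = -design.reactive_separation * design.reactive_low_fraction
    planted_mass = 0.0
    for i in range(n_genes):
        if cls_arr[i] in ("expressed", "discordant"):
            planted_mass += 2.0 ** m_expr[i]
        elif cls_arr[i] == "hovering":
            planted_mass += 2.0 ** m_hover[i]
        elif cls_arr[i] == "reactive":
            planted_mass += 2.0 ** m_react_high
    n_bg = max(1, design.n_background)
    m_background = np.log2(max(1e6 - planted_mass, 1e5) / n_bg)

    # Latent high/low per reactive gene x dataset block, conditioned on
    # both states being present within each cell line.
    datasets = sorted({m.dataset for m in meta})
    ds_of_sample = {m.sample_id: m.dataset for m in meta}
    line_of_ds = {m.dataset: m.cell_line for m in meta}
    latent_ds = pd.DataFrame(False, index=gene_ids, columns=datasets)
    for i, g in enumerate(gene_ids):
        if cls_arr[i] != "reactive":
            continue
        for line in lines:
            ds_line = [d for d in datasets if line_of_ds[d] == line]
            if len(ds_line) == 1:
                latent_ds.loc[g, ds_line[0]] = bool(rng.random() < design.reactive_mixing)
                continue
            while True:
                states = rng.random(len(ds_line)) < design.reactive_mixing
                if states.any() and not states.all():
                    break
            latent_ds.loc[g, ds_line] = states

    # Per-sample expected log2CPM matrix.
    m_mat = np.zeros((n_genes, len(sample_ids)))
    silent_mask = np.zeros((n_genes, len(sample_ids)), dtype=bool)
    for j, sid in enumerate(sample_ids):
        ds = ds_of_sample[sid]
        line = line_of_ds[ds]
        for i in range(n_genes):
            cls = cls_arr[i]
            if cls == "expressed":
                m_mat[i, j] = m_expr[i]
            elif cls == "background":
                m_mat[i, j] = m_background
            elif cls == "hovering":
                m_mat[i, j] = m_hover[i]
            elif cls == "reactive":
                m_mat[i, j] = (m_react_high if latent_ds.at[gene_ids[i], ds]
                               else m_react_low)
            elif cls == "discordant":
                if line == lines[0]:
                    m_mat[i, j] = m_expr[i]
                else:
                    silent_mask[i, j] = True
            if cls == "silent":
                silent_mask[i, j] = True

    lo, hi = design.library_size_range
    margin = 0.05 * (hi - lo)
    targets = rng.uniform(lo + margin, hi - margin, len(sample_ids))
    if hi - lo == 0:
        targets = np.full(len(sample_ids), lo)

    rel = 2.0 ** m_mat * (lengths[:, None] / 1000.0)
    rel[silent_mask] = 0.0
    scale = targets / rel.sum(axis=0)
    mu = rel * scale[None, :]
    size = 1.0 / design.nb_dispersion
    counts = rng.negative_binomial(size, size / (size + np.maximum(mu, 1e-12)))
    # silent genes: mostly exact zeros, occasionally 1-2 stray reads
    stray = rng.random(silent_mask.shape) >= design.silent_zero_prob
    counts[silent_mask] = 0
    stray &= silent_mask
    counts[stray] = rng.integers(1, 3, int(stray.sum()))

    cm = CountMatrix(gene_ids, sample_ids, counts.astype(np.int64),
                     lengths=length_series)

    truth_classes = pd.DataFrame(index=gene_ids, columns=lines, dtype=object)
    truth_reactive = pd.DataFrame(False, index=gene_ids, columns=lines)
    for i, g in enumerate(gene_ids):
        cls = cls_arr[i]
        for line in lines:
            if cls == "discordant":
                truth_classes.at[g, line] = "expressed" if line == lines[0] else "silent"
            else:
                truth_classes.at[g, line] = cls
        if cls == "reactive":
            truth_reactive.loc[g] = True
    latent_high = pd.DataFrame(
        {sid: latent_ds[ds_of_sample[sid]] for sid in sample_ids})
    truth = GroundTruth(truth_classes, truth_reactive, latent_high)
    return cm, meta, length_series, truth


def simulate_gene_models(
    n_genes: int, seed: int = 0, chrom_count: int = 2, intergenic_mean: float = 20000.0,
) -> list[GeneModel]:
    """Random gene models: sequential placement on ``chrom_count``
    chromosomes, 1-5 transcripts per gene sharing an exon chain, strand
    50/50.  Coordinates are 1-based inclusive."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    models = []
    cursors = {f"chr{c + 1}": 1 for c in range(chrom_count)}
    for i in range(n_genes):
        chrom = f"chr{(i % chrom_count) + 1}"
        start = cursors[chrom] + int(rng.exponential(intergenic_mean)) + 1
        n_exons = int(rng.integers(1, 8))
        exon_lens = np.maximum(
            np.round(np.exp(rng.normal(6.0, 0.8, n_exons))).astype(int), 20)
        intron_lens = np.maximum(
            np.round(np.exp(rng.normal(6.5, 0.8, max(n_exons - 1, 0)))).astype(int), 30)
        exons = []
        pos = start
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k]) - 1))
            pos = exons[-1][1] + 1
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        gene_end = exons[-1][1]
        n_tx = int(rng.integers(1, 6))
        transcripts = []
        for t in range(n_tx):
            if n_exons == 1 or t == 0:
                sub = exons  # first transcript carries the full chain
            else:
                a = int(rng.integers(0, n_exons))
                b = int(rng.integers(a, n_exons))
                sub = exons[a:b + 1]
            transcripts.append((f"g{i + 1:05d}.t{t + 1}", list(sub)))
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GeneModel(
            gene_id=f"g{i + 1:05d}", chrom=chrom, strand=strand,
            gene_start=start, gene_end=gene_end,
            transcripts=transcripts, biotype="protein_coding"))
        cursors[chrom] = gene_end + 1
    return models


def simulate_posteriors(
    models: list[GeneModel],
    gene_classes: dict[str, str],
    seed: int = 0,
    bin_size: int = 200,
    states: list[str] | None = None,
    background_quiescent: float = 0.77,
    promoter_halfwidth: int = 400,
) -> dict[str, StatePosteriorTrack]:
    """Posterior tracks correlated with planted expression class.

    Bins over expressed gene bodies are biased toward strong
    transcription (active promoter around the TSS), silent genes toward
    heterochromatin/Polycomb, reactive genes get a mixture of both, and
    the intergenic background is tuned so the genome-wide quiescent
    posterior mass equals ``background_quiescent``.
    """
    if states is None:
        states = list(DEFAULT_STATES)
    s_idx = {s: i for i, s in enumerate(states)}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))

    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)

    profiles = {
        "expressed": {"StrongTranscription": 0.60, "WeakGenicEnhancer": 0.20,
                      "ActivePromoter": 0.05, "Quiescent": 0.15},
        "silent": {"Heterochromatin": 0.45, "PolycombRepressed": 0.40,
                   "Quiescent": 0.15},
        "reactive": {"StrongTranscription": 0.25, "ActivePromoter": 0.10,
                     "Heterochromatin": 0.20, "PolycombRepressed": 0.20,
                     "Quiescent": 0.25},
        "hovering": {"StrongTranscription": 0.20, "WeakGenicEnhancer": 0.15,
                     "Quiescent": 0.65},
    }
    promoter_profile = {"ActivePromoter": 0.75, "WeakGenicEnhancer": 0.10,
                        "Quiescent": 0.15}

    def _row(profile: dict[str, float]) -> np.ndarray:
        row = np.zeros(len(states))
        for s, v in profile.items():
            row[s_idx[s]] = v
        return row / row.sum()

    # Plan every bin first (gene bodies, then promoter windows on top),
    # then solve the background quiescent level so the genome-wide
    # quiescent mass hits the target exactly.
    planned: dict[str, np.ndarray] = {}
    for chrom, ms in by_chrom.items():
        length = max(m.gene_end for m in ms) + 2000
        n_bins = -(-length // bin_size)
        plan = np.full((n_bins, len(states)), np.nan)
        for m in ms:
            cls = gene_classes.get(m.gene_id, "hovering")
            cls = "expressed" if cls in ("background", "discordant") else cls
            if cls == "silent":
                row = profiles["silent"]
            else:
                row = profiles.get(cls, profiles["hovering"])
            b0 = (m.gene_start - 1) // bin_size
            b1 = (m.gene_end - 1) // bin_size
            plan[b0:b1 + 1] = _row(row)
            if cls in ("expressed", "reactive"):
                tss = (m.gene_start - 1) if m.strand == "+" else (m.gene_end - 1)
                p0 = max(0, (tss - promoter_halfwidth) // bin_size)
                p1 = min(n_bins - 1, (tss + promoter_halfwidth) // bin_size)
                plan[p0:p1 + 1] = _row(promoter_profile)
        planned[chrom] = plan

    total_bins = sum(p.shape[0] for p in planned.values())
    genic = {c: ~np.isnan(p[:, 0]) for c, p in planned.items()}
    genic_bins = sum(int(g.sum()) for g in genic.values())
    genic_quiescent = sum(
        float(np.nansum(p[:, s_idx["Quiescent"]])) for p in planned.values())
    bg_bins = total_bins - genic_bins
    if bg_bins <= 0:
        raise ValueError("genome too dense for a background fraction")
    q_bg = (background_quiescent * total_bins - genic_quiescent) / bg_bins
    q_bg = float(np.clip(q_bg, 0.0, 0.98))
    bg_row = np.zeros(len(states))
    bg_row[s_idx["Quiescent"]] = q_bg
    leftover = (1.0 - q_bg)
    bg_row[s_idx["Heterochromatin"]] = leftover * 0.5
    bg_row[s_idx["PolycombRepressed"]] = leftover * 0.3
    bg_row[s_idx["WeakGenicEnhancer"]] = leftover * 0.2

    tracks: dict[str, StatePosteriorTrack] = {}
    for chrom, plan in planned.items():
        n_bins = plan.shape[0]
        post = plan.copy()
        post[~genic[chrom]] = bg_row
        # small dirichlet wobble keeps rows stochastic but sums exactly 1
        noise = rng.dirichlet(np.full(len(states), 200.0), size=n_bins) - 1.0 / len(states)
        post = np.clip(post + 0.02 * noise, 1e-6, None)
        post /= post.sum(axis=1, keepdims=True)
        tracks[chrom] = StatePosteriorTrack(chrom, bin_size, list(states), post)
    return tracks


def design_with_paper_library_span(design: SimulationDesign) -> SimulationDesign:
    """Convenience: the design with the library-size span reported for the
    real meta-analysis (9.24 M to 106 M reads)."""
    return replace(design, library_size_range=(9.24e6, 106e6))
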