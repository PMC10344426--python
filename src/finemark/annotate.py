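"""Peak-to-gene annotation and expression-class statistics.

Gene classes come from a differential-expression contrast between a stem
cell population (neuroblasts) and its immediate progeny (immature INPs):
a gene is differentially expressed iff |fold change| > 2 and adjusted
p < 0.05 (the sign choosing ``nb_enriched`` vs ``immINP_enriched``),
invariant iff |fold change| < 2, and unclassified otherwise (|FC| >= 2
without significance, or |FC| exactly 2).

Peaks are annotated HOMER-style: the category of the summit position by
precedence promoter > tts > exonic > intronic > intergenic, with the
promoter window (-1000, +100) bp around the TSS in gene orientation and
the TTS window mirrored at the transcript end; every peak is assigned to
the gene with the nearest TSS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneAnnotation, make_intervals, overlaps_any
from .peaks import PeakSet

GENE_CLASSES = ("nb_enriched", "immINP_enriched", "invariant", "unclassified")
CATEGORIES = ("promoter", "tts", "exonic", "intronic", "intergenic")


def classify_genes(de_table: pd.DataFrame) -> pd.DataFrame:
    """Apply the |FC| > 2 & padj < 0.05 classification rule.

    *de_table* needs columns gene_id, log2fc, padj.  Returns the table with
    a ``gene_class`` column; every gene lands in exactly one class.
    """
    for col in ("gene_id", "log2fc", "padj"):
        if col not in de_table.columns:
            raise ValueError(f"DE table lacks column {col!r}")
    log2fc = de_table["log2fc"].to_numpy(dtype=float)
    padj = de_table["padj"].to_numpy(dtype=float)
    if not np.isfinite(log2fc).all():
        raise ValueError("non-finite log2fc")
    if ((padj < 0) | (padj > 1) | ~np.isfinite(padj)).any():
        raise ValueError("padj outside [0, 1]")
    fc = 2.0 ** np.abs(log2fc)
    de = (fc > 2.0) & (padj < 0.05)
    cls = np.where(
        de & (log2fc > 0),
        "nb_enriched",
        np.where(de, "immINP_enriched", np.where(fc < 2.0, "invariant", "unclassified")),
    )
    out = de_table.copy()
    out["gene_class"] = cls
    return out


def overestim_var_ttest(
    expr_a: np.ndarray, expr_b: np.ndarray
) -> tuple[float, float]:
    """Welch-style t-test with overestimated variance.

    The comparison group's variance term is divided by the focal group's
    size (not its own), inflating the standard error whenever the focal
    group is the smaller — a deliberately conservative convention for
    marker-gene testing.  Inputs are log-scale expression values; returns
    (log2fc = mean(a) − mean(b), two-sided p).
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    log2fc = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return log2fc, 1.0
    # both variance terms scaled by the focal group's size
    res = stats.ttest_ind_from_stats(
        a.mean(), np.sqrt(va), len(a), b.mean(), np.sqrt(vb), len(a), equal_var=False
    )
    return log2fc, float(res.pvalue)


# ---------------------------------------------------------------------------
# peak annotation
# ---------------------------------------------------------------------------


def _directional_window(
    tss: np.ndarray, strand: np.ndarray, upstream: int, downstream: int
) -> tuple[np.ndarray, np.ndarray]:
    """Half-open interval covering [−upstream, +downstream] around an
    anchor position in gene orientation."""
    plus = strand == "+"
    start = np.where(plus, tss - upstream, tss - downstream)
    end = np.where(plus, tss + downstream + 1, tss + upstream + 1)
    return np.maximum(start, 0).astype(np.int64), end.astype(np.int64)


def annotate_peaks(
    peakset: PeakSet | pd.DataFrame,
    annotation: GeneAnnotation,
    promoter_window: tuple[int, int] = (1_000, 100),
    tts_window: tuple[int, int] = (100, 1_000),
) -> pd.DataFrame:
    """Categorize each peak at its summit and assign the nearest-TSS gene.

    *promoter_window* is (upstream, downstream) bp around the TSS in gene
    orientation; *tts_window* likewise around the transcript end.  Returns
    peak coordinates plus ``category`` and ``assigned_gene``.
    """
    peaks = peakset.peaks if isinstance(peakset, PeakSet) else peakset
    genes = annotation.genes
    if len(genes) == 0:
        raise ValueError("empty gene annotation")
    if "summit" in peaks.columns and peaks["summit"].notna().all():
        summit = peaks["summit"].to_numpy(dtype=np.int64)
    else:
        summit = ((peaks["start"] + peaks["end"]) // 2).to_numpy(dtype=np.int64)
    points = make_intervals(peaks["chrom"], summit, summit + 1)

    tss = genes["tss"].to_numpy()
    strand = genes["strand"].to_numpy()
    ps, pe = _directional_window(tss, strand, *promoter_window)
    promoters = make_intervals(genes["chrom"], ps, pe)
    tes = np.where(strand == "+", genes["end"].to_numpy() - 1, genes["start"].to_numpy())
    ts, te = _directional_window(tes, strand, *tts_window)
    tts = make_intervals(genes["chrom"], ts, te)
    bodies = genes[["chrom", "start", "end"]]
    exons = annotation.exons[["chrom", "start", "end"]] if len(annotation.exons) else None

    in_prom = overlaps_any(points, promoters)
    in_tts = overlaps_any(points, tts)
    in_exon = overlaps_any(points, exons) if exons is not None and len(exons) else np.zeros(len(points), bool)
    in_body = overlaps_any(points, bodies)
    category = np.where(
        in_prom,
        "promoter",
        np.where(in_tts, "tts", np.where(in_exon, "exonic", np.where(in_body, "intronic", "intergenic"))),
    )

    assigned = np.empty(len(peaks), dtype=object)
    gene_by_chrom = {
        c: sub.sort_values("tss").reset_index(drop=True) for c, sub in genes.groupby("chrom", sort=False)
    }
    chrom_arr = peaks["chrom"].to_numpy()
    for i in range(len(peaks)):
        sub = gene_by_chrom.get(chrom_arr[i])
        if sub is None:
            raise ValueError(f"no annotated gene on chromosome {chrom_arr[i]!r}")
        t = sub["tss"].to_numpy()
        j = int(np.argmin(np.abs(t - summit[i])))  # nearest TSS; leftmost on ties
        assigned[i] = sub["gene_id"].iloc[j]

    out = peaks[["chrom", "start", "end"]].copy().reset_index(drop=True)
    out["summit"] = summit
    out["category"] = category
    out["assigned_gene"] = assigned
    return out


def category_distribution(annotations: pd.DataFrame) -> pd.DataFrame:
    """Fraction of peaks per genomic category."""
    counts = annotations["category"].value_counts()
    rows = [(cat, int(counts.get(cat, 0))) for cat in CATEGORIES]
    df = pd.DataFrame(rows, columns=["category", "count"])
    total = df["count"].sum()
    df["fraction"] = df["count"] / total if total else 0.0
    return df


def bound_gene_fraction(
    peak_annotations: pd.DataFrame, gene_class_table: pd.DataFrame, gene_class: str
) -> float:
    """Percent of genes of *gene_class* with at least one assigned peak."""
    genes = gene_class_table.loc[gene_class_table["gene_class"] == gene_class, "gene_id"]
    if len(genes) == 0:
        raise ValueError(f"no genes of class {gene_class!r}")
    bound = set(peak_annotations["assigned_gene"])
    return 100.0 * genes.isin(bound).mean()


def peakset_overlap_fraction(
    set_a: PeakSet | pd.DataFrame,
    set_b: PeakSet | pd.DataFrame,
    categories_a: pd.Series | None = None,
) -> float | dict[str, float]:
    """Percent of A peaks overlapping any B peak by >= 1 bp; stratified per
    A category when *categories_a* is given."""
    a = set_a.peaks if isinstance(set_a, PeakSet) else set_a
    b = set_b.peaks if isinstance(set_b, PeakSet) else set_b
    if len(a) == 0:
        raise ValueError("empty query peak set")
    hits = overlaps_any(a, b)
    if categories_a is None:
        return 100.0 * hits.mean()
    cats = np.asarray(categories_a)
    return {
        cat: 100.0 * hits[cats == cat].mean()
        for cat in pd.unique(cats)
        if (cats == cat).any()
    }
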