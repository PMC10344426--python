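"""Synthetic CUT&RUN-like data with planted, recorded ground truth.

Emulates the structure of the study design this package quantifies: two
conditions (control and a mutant in which a transcription factor is lost)
x two replicates of histone-mark fragments, one deeply enriched
transcription-factor sample with sub-120-bp fragments, depth and
composition differences between samples, and a differential-expression
gene table with planted neuroblast-enriched / immature-INP-enriched /
invariant classes.

Three kinds of truth region are planted:

``tf_peak``
    narrow (~500 bp) strongly enriched TF binding sites, placed
    preferentially in the promoter windows of NB-class genes;
``low_level_mark``
    modest histone-mark enrichment coinciding with a subset of TF peaks,
    with a condition-specific decrease in the mutant for most of them;
``broad_domain``
    multi-kb strongly enriched repressive domains away from TF peaks,
    stable across conditions.

Fragment start counts per bp are negative binomial with mean
``mu = background_rate * depth * prod(enrichment * condition_fc)`` and
variance ``mu * (1 + phi * mu)``; ``phi = 0`` reduces to Poisson.  One seed
governs a whole experiment; each sample draws from a substream keyed by a
CRC32 hash of its sample id, so adding a sample never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    FragmentSet,
    GeneAnnotation,
    GenomeLayout,
    make_intervals,
    merge_intervals,
    overlaps_any,
    write_bed,
)

TRUTH_KINDS = ("tf_peak", "low_level_mark", "broad_domain")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic experiment.

    Defaults give a toy genome (2 x 2.5 Mb) dense enough that every
    downstream stage has power, at a scale that simulates in seconds.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_500_000
    background_rate: float = 0.02  # fragments per bp at depth 1
    conditions: tuple[str, ...] = ("control", "mutant")
    replicates_per_condition: int = 2
    # per-sample depth multipliers, cycled by sample order: deliberate
    # depth/composition differences for the normalization stages to absorb
    depth_multipliers: tuple[float, ...] = (1.0, 1.3, 0.8, 1.15)
    tf_depth_multiplier: float = 2.0
    dispersion: float = 0.1  # NB phi; 0 -> Poisson
    tf_fragment_range: tuple[int, int] = (50, 119)
    histone_fragment_range: tuple[int, int] = (150, 400)
    # gene annotation
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    class_fractions: tuple[float, float, float] = (0.35, 0.25, 0.40)  # nb, immINP, invariant
    # planted regions
    n_tf_peaks: int = 100
    tf_peak_width: int = 500
    tf_enrichment: float = 25.0
    fraction_near_nb: float = 0.74
    n_broad_domains: int = 12
    domain_width_range: tuple[int, int] = (5_000, 50_000)
    domain_enrichment: float = 8.0
    # domains merged within 10 kb downstream are indistinguishable; planted
    # ones keep a larger separation so truth regions stay resolvable
    domain_min_separation: int = 12_000
    lowlevel_fraction_of_peaks: float = 0.5
    lowlevel_enrichment: float = 3.0
    # nucleosomal marks spread beyond the factor footprint: the planted mark
    # region is the TF peak extended this many bp on each side
    lowlevel_extension: int = 750
    lowlevel_down_fraction: float = 0.8
    lowlevel_mutant_fc: float = 0.4  # 2.5-fold decrease in the mutant
    # DE table jitter
    de_log2fc_location: float = 2.0
    de_log2fc_scale: float = 0.4

    def __post_init__(self) -> None:
        if self.background_rate < 0 or self.dispersion < 0:
            raise ValueError("rates and dispersion must be non-negative")
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise ValueError("genome dimensions must be positive")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")

    def layout(self) -> GenomeLayout:
        return GenomeLayout({f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)})

    def sample_specs(self, target: str = "H3K27me3") -> list[tuple[str, str, int]]:
        """(sample_id, condition, replicate) for every histone sample."""
        specs = []
        for ci, cond in enumerate(self.conditions):
            for rep in range(1, self.replicates_per_condition + 1):
                specs.append((f"{target}_{cond}_rep{rep}", cond, rep))
        return specs

    def depth_for(self, condition: str, replicate: int) -> float:
        idx = self.conditions.index(condition) * self.replicates_per_condition + (replicate - 1)
        return self.depth_multipliers[idx % len(self.depth_multipliers)]


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-label RNG substream of the experiment seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


# ---------------------------------------------------------------------------
# truth placement
# ---------------------------------------------------------------------------


def _place_genes(config: SimulationConfig, rng: np.random.Generator) -> GeneAnnotation:
    layout = config.layout()
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    rows = []
    gi = 0
    for chrom in layout.chroms:
        L = layout[chrom]
        slots = np.linspace(0, L, per_chrom + 1)[:-1]
        for anchor in slots:
            if gi >= config.n_genes:
                break
            length = int(rng.integers(*config.gene_length_range, endpoint=True))
            start = int(min(max(anchor + rng.integers(0, 2000), 0), L - length - 1))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"gene{gi:04d}", chrom, start, start + length, strand))
            gi += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    genes["start"] = genes["start"].astype(np.int64)
    genes["end"] = genes["end"].astype(np.int64)
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    return GeneAnnotation(genes)


def _assign_classes(config: SimulationConfig, genes: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    n = len(genes)
    f_nb, f_imm, _ = config.class_fractions
    n_nb = int(round(n * f_nb))
    n_imm = int(round(n * f_imm))
    labels = np.array(
        ["nb_enriched"] * n_nb + ["immINP_enriched"] * n_imm + ["invariant"] * (n - n_nb - n_imm)
    )
    rng.shuffle(labels)
    return pd.DataFrame({"gene_id": genes["gene_id"].to_numpy(), "true_class": labels})


def _place_nonoverlapping(
    rng: np.random.Generator,
    layout: GenomeLayout,
    widths: list[int],
    forbidden: pd.DataFrame,
    margin: int = 0,
    max_retries: int = 1000,
) -> pd.DataFrame:
    """Uniformly place intervals of the given widths avoiding *forbidden*
    (grown by *margin*) and one another."""
    chroms = layout.chroms
    weights = np.array([layout[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: list[tuple[str, int, int]] = []
    for width in widths:
        blocked = forbidden
        if placed:
            blocked = pd.concat(
                [forbidden, pd.DataFrame(placed, columns=["chrom", "start", "end"])],
                ignore_index=True,
            )
        for attempt in range(max_retries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            hi = layout[chrom] - width
            if hi <= 0:
                continue
            start = int(rng.integers(0, hi))
            cand = make_intervals([chrom], [max(0, start - margin)], [start + width + margin])
            if not overlaps_any(cand, blocked)[0]:
                placed.append((chrom, start, start + width))
                break
        else:
            raise RuntimeError(f"could not place a {width} bp region after {max_retries} tries")
    df = pd.DataFrame(placed, columns=["chrom", "start", "end"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def simulate_truth(
    config: SimulationConfig,
) -> tuple[GenomeLayout, GeneAnnotation, pd.DataFrame, pd.DataFrame]:
    """Generate layout, gene models, planted truth regions and gene classes.

    Returns
    -------
    layout, annotation, truth, gene_truth
        *truth* has columns chrom, start, end, kind, base_enrichment and
        one ``fc_<condition>`` column per condition; same-kind regions are
        non-overlapping.  *gene_truth* maps gene_id to its planted class.
    """
    layout = config.layout()
    rng = _substream(config.seed, "truth")
    annotation = _place_genes(config, rng)
    gene_truth = _assign_classes(config, annotation.genes, rng)

    nb_tss = annotation.genes.merge(gene_truth, on="gene_id")
    nb_tss = nb_tss[nb_tss["true_class"] == "nb_enriched"]

    # TF peaks: a configurable fraction sits inside NB-gene promoter windows
    n_near = int(round(config.n_tf_peaks * config.fraction_near_nb))
    rows: list[tuple[str, int, int]] = []
    if n_near > 0 and len(nb_tss) == 0:
        raise RuntimeError("fraction_near_nb > 0 requires NB-class genes")
    if n_near > 0:
        chosen = nb_tss.iloc[
            rng.choice(len(nb_tss), size=n_near, replace=n_near > len(nb_tss))
        ]
        for row in chosen.itertuples(index=False):
            # peak centred just upstream of the TSS so the summit falls in
            # the (-1000, +100) promoter window regardless of strand
            if row.strand == "+":
                start = int(row.tss) - config.tf_peak_width + 150
            else:
                start = int(row.tss) - 150
            start = max(0, min(start, layout[row.chrom] - config.tf_peak_width))
            rows.append((row.chrom, start, start + config.tf_peak_width))
    seeded = pd.DataFrame(rows, columns=["chrom", "start", "end"]) if rows else make_intervals([], [], [])
    n_far = config.n_tf_peaks - n_near
    far = _place_nonoverlapping(
        rng, layout, [config.tf_peak_width] * n_far, forbidden=seeded, margin=500
    )
    tf_peaks = pd.concat([seeded, far], ignore_index=True) if len(far) else seeded
    tf_peaks = tf_peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    # overlapping promoter-seeded peaks collapse to keep same-kind regions disjoint
    tf_peaks = merge_intervals(tf_peaks)

    widths = [
        int(rng.integers(*config.domain_width_range, endpoint=True))
        for _ in range(config.n_broad_domains)
    ]
    domains = _place_nonoverlapping(
        rng, layout, widths, forbidden=tf_peaks, margin=config.domain_min_separation
    )

    # low-level mark enrichment around a subset of TF peaks; the mark region
    # is the peak extended on both sides, clipped to the chromosome and
    # merged where extensions collide (keeps same-kind regions disjoint)
    n_low = int(round(len(tf_peaks) * config.lowlevel_fraction_of_peaks))
    low_idx = np.sort(rng.choice(len(tf_peaks), size=n_low, replace=False)) if n_low else np.array([], int)
    low = tf_peaks.iloc[low_idx].reset_index(drop=True).copy()
    if n_low:
        ext = config.lowlevel_extension
        low["start"] = np.maximum(low["start"] - ext, 0)
        low["end"] = np.minimum(
            low["end"] + ext, low["chrom"].map(dict(layout.lengths)).to_numpy()
        )
        low = merge_intervals(low)
    n_low = len(low)
    n_down = int(round(n_low * config.lowlevel_down_fraction))
    down_mask = np.zeros(n_low, dtype=bool)
    if n_low:
        down_mask[rng.choice(n_low, size=n_down, replace=False)] = True

    def block(df: pd.DataFrame, kind: str, enrich: float, fc: dict[str, np.ndarray]) -> pd.DataFrame:
        out = df[["chrom", "start", "end"]].copy()
        out["kind"] = kind
        out["base_enrichment"] = enrich
        for cond in config.conditions:
            out[f"fc_{cond}"] = fc.get(cond, np.ones(len(df)))
        return out

    ones = {c: np.ones(len(tf_peaks)) for c in config.conditions}
    low_fc = {c: np.ones(n_low) for c in config.conditions}
    if len(config.conditions) > 1:
        mutant = config.conditions[1]
        low_fc[mutant] = np.where(down_mask, config.lowlevel_mutant_fc, 1.0)
    truth = pd.concat(
        [
            block(tf_peaks, "tf_peak", config.tf_enrichment, ones),
            block(low, "low_level_mark", config.lowlevel_enrichment, low_fc),
            block(domains, "broad_domain", config.domain_enrichment, {}),
        ],
        ignore_index=True,
    )
    truth["start"] = truth["start"].astype(np.int64)
    truth["end"] = truth["end"].astype(np.int64)
    return layout, annotation, truth, gene_truth


# ---------------------------------------------------------------------------
# fragment simulation
# ---------------------------------------------------------------------------


def _rate_array(
    truth: pd.DataFrame, layout: GenomeLayout, chrom: str, condition: str, target: str, base: float
) -> np.ndarray:
    """Per-bp fragment-start rate on one chromosome for one sample."""
    mu = np.full(layout[chrom], base, dtype=np.float64)
    if target.lower() in {"tf", "factor"}:
        kinds = {"tf_peak"}
    else:
        kinds = {"low_level_mark", "broad_domain"}
    sub = truth[(truth["chrom"] == chrom) & truth["kind"].isin(kinds)]
    fc_col = f"fc_{condition}"
    for row in sub.itertuples(index=False):
        factor = float(row.base_enrichment) * float(getattr(row, fc_col, 1.0))
        mu[row.start : row.end] *= factor
    return mu


def expected_fragment_count(
    truth: pd.DataFrame, config: SimulationConfig, condition: str, target: str, depth: float
) -> float:
    """Analytic expectation of the total fragment count for one sample."""
    layout = config.layout()
    total = 0.0
    for chrom in layout.chroms:
        total += _rate_array(truth, layout, chrom, condition, target, config.background_rate * depth).sum()
    return total


def simulate_fragments(
    truth: pd.DataFrame,
    config: SimulationConfig,
    condition: str,
    replicate: int,
    target: str,
    depth: float | None = None,
) -> FragmentSet:
    """Draw one sample's fragments from the planted truth.

    Start counts per bp are NB(mu, phi); lengths follow the target's
    uniform length model; fragments overrunning the chromosome end have
    their length redrawn (start resampled when no admissible length exists).
    """
    layout = config.layout()
    sample_id = f"{target}_{condition}_rep{replicate}"
    rng = _substream(config.seed, f"fragments/{sample_id}")
    if depth is None:
        depth = (
            config.tf_depth_multiplier
            if target.lower() in {"tf", "factor"}
            else config.depth_for(condition, replicate)
        )
    lo, hi = (
        config.tf_fragment_range
        if target.lower() in {"tf", "factor"}
        else config.histone_fragment_range
    )
    phi = config.dispersion
    chroms, starts = [], []
    for chrom in layout.chroms:
        mu = _rate_array(truth, layout, chrom, condition, target, config.background_rate * depth)
        if phi > 0:
            lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        else:
            lam = mu
        counts = rng.poisson(lam)
        pos = np.repeat(np.arange(layout[chrom], dtype=np.int64), counts)
        chroms.append(np.full(len(pos), chrom, dtype=object))
        starts.append(pos)
    chrom_arr = np.concatenate(chroms) if chroms else np.array([], dtype=object)
    start_arr = np.concatenate(starts) if starts else np.array([], dtype=np.int64)
    n = len(start_arr)
    lengths = rng.integers(lo, hi, size=n, endpoint=True)
    limits = np.array([layout[c] for c in chrom_arr], dtype=np.int64) if n else np.array([], np.int64)
    # redraw lengths of fragments that would overrun the chromosome end
    for _ in range(20):
        over = start_arr + lengths > limits
        if not over.any():
            break
        lengths[over] = rng.integers(lo, hi, size=int(over.sum()), endpoint=True)
    over = start_arr + lengths > limits
    if over.any():  # start too close to the end for any admissible length
        start_arr = start_arr.copy()
        for i in np.flatnonzero(over):
            start_arr[i] = rng.integers(0, limits[i] - lengths[i])
    frags = pd.DataFrame({"chrom": chrom_arr, "start": start_arr, "end": start_arr + lengths})
    frags = frags.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    frags["start"] = frags["start"].astype(np.int64)
    frags["end"] = frags["end"].astype(np.int64)
    return FragmentSet(sample_id, condition, replicate, target, frags)


def simulate_experiment(
    config: SimulationConfig, histone_target: str = "H3K27me3", tf_target: str = "tf"
) -> dict[str, FragmentSet]:
    """All histone samples (conditions x replicates) plus one TF sample."""
    out: dict[str, FragmentSet] = {}
    _layout, _annotation, truth, _gene_truth = simulate_truth(config)
    for sample_id, cond, rep in config.sample_specs(histone_target):
        out[sample_id] = simulate_fragments(truth, config, cond, rep, histone_target)
    tf_cond = config.conditions[0]
    out[f"{tf_target}_{tf_cond}_rep1"] = simulate_fragments(truth, config, tf_cond, 1, tf_target)
    return out


# ---------------------------------------------------------------------------
# DE table
# ---------------------------------------------------------------------------


def simulate_de_table(gene_truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Differential-expression table (gene_id, log2fc, padj) whose planted
    classes are recoverable by the |FC| > 2 & padj < 0.05 rule.

    NB-enriched genes get positive log2 fold changes with magnitude > 1 and
    padj < 0.05; immature-INP-enriched the mirrored negative; invariant
    genes get |log2fc| < 1 with uninformative padj.
    """
    rng = _substream(config.seed, "de_table")
    n = len(gene_truth)
    log2fc = np.empty(n)
    padj = np.empty(n)
    cls = gene_truth["true_class"].to_numpy()
    for i, c in enumerate(cls):
        if c in ("nb_enriched", "immINP_enriched"):
            mag = max(1.1, rng.normal(config.de_log2fc_location, config.de_log2fc_scale))
            log2fc[i] = mag if c == "nb_enriched" else -mag
            padj[i] = rng.uniform(1e-6, 0.049)
        else:
            log2fc[i] = np.clip(rng.normal(0.0, 0.25), -0.95, 0.95)
            padj[i] = rng.uniform(0.0, 1.0)
    return pd.DataFrame({"gene_id": gene_truth["gene_id"].to_numpy(), "log2fc": log2fc, "padj": padj})


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_truth(
    outdir: str | Path,
    layout: GenomeLayout,
    annotation: GeneAnnotation,
    truth: pd.DataFrame,
    gene_truth: pd.DataFrame,
) -> None:
    """Serialize truth as chrom-sizes + BED + TSV, valid genome_io inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout.to_file(outdir / "genome.chrom.sizes")
    genes = annotation.genes.rename(columns={"gene_id": "name"})
    genes = genes.assign(score=0.0)[["chrom", "start", "end", "name", "score", "strand"]]
    write_bed(genes, outdir / "genes.bed")
    bed = truth.rename(columns={"kind": "name"}).assign(score=truth["base_enrichment"])
    write_bed(bed[["chrom", "start", "end", "name", "score"]], outdir / "truth_regions.bed")
    truth.to_csv(outdir / "truth_regions.tsv", sep="\t", index=False)
    gene_truth.to_csv(outdir / "gene_classes_truth.tsv", sep="\t", index=False)
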