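"""End-to-end orchestration on synthetic data: simulate -> filter ->
call/normalize -> differential -> domains -> density -> annotate.

Every stage is a pure function of (inputs, config, seed): a rerun with the
same config writes byte-identical tables.  All intermediates are
serialized as BED/bedGraph/TSV under the output directory, and a
``report.json`` collects the headline quantities: peak counts and genomic
distribution, bound-gene fractions per expression class (real vs shuffled
control), peak-set overlap, the differential kb summary, domain count and
the domain:peak coverage ratio, and bin-density summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, coverage, density, diffwin, domains, peaks, synth
from .genome import GenomeLayout, write_bed
from .synth import SimulationConfig

logger = logging.getLogger("finemark")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All tunable parameters, with defaults matching the analysis they
    reproduce (window 500 / step 100, q < 0.05, 2-fold cut, peak
    confidence 100, blacklist merge gap 3000, island w=500 g=2000 egf=0.7,
    domain filters score>500 length>3000 merge 10000, fragment cap 120)."""

    outdir: str = "finemark_out"
    seed: int = 0
    # differential windows
    window: int = 500
    step: int = 100
    q_cut: float = 0.05
    fc_cut: float = 2.0
    min_window_count: float = 10.0
    # TF peaks
    peak_confidence: float = 100.0
    peak_window: int = 150
    fragment_cap: int = 120
    blacklist_gap: int = 3_000
    # islands / domains
    island_w: int = 500
    island_gap: int = 2_000
    island_egf: float = 0.7
    island_window_p: float = 0.2
    domain_min_score: float = 500.0
    domain_min_length: int = 3_000
    domain_merge_gap: int = 10_000
    # bin density
    density_bin: int = 500
    subsample_n: int | None = None  # default: smallest condition depth
    # track export
    track_bin: int = 10
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown simulation keys: {sorted(sim_unknown)}")
            for key in ("conditions", "depth_multipliers", "tf_fragment_range",
                        "histone_fragment_range", "gene_length_range",
                        "class_fractions", "domain_width_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulation"] = SimulationConfig(**sim)
        return cls(**raw)


def _stage(name: str, **params):
    logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in params.items()))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on freshly simulated data and write the report.

    Returns the report dict (also written to ``<outdir>/report.json``).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    report: dict = {"seed": config.seed, "warnings": []}

    # ---- simulate -------------------------------------------------------
    try:
        _stage("simulate", seed=sim.seed, n_chroms=sim.n_chroms, chrom_length=sim.chrom_length)
        layout, annotation, truth, gene_truth = synth.simulate_truth(sim)
        synth.write_truth(out / "truth", layout, annotation, truth, gene_truth)
        histone = {
            sid: synth.simulate_fragments(truth, sim, cond, rep, "H3K27me3")
            for sid, cond, rep in sim.sample_specs("H3K27me3")
        }
        tf_fs = synth.simulate_fragments(truth, sim, sim.conditions[0], 1, "tf")
        for fs in [*histone.values(), tf_fs]:
            write_bed(fs.fragments, out / f"fragments_{fs.sample_id}.bed")
        de_table = synth.simulate_de_table(gene_truth, sim)
        de_table.to_csv(out / "de_table.tsv", sep="\t", index=False)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("simulate", exc) from exc

    control, mutant = sim.conditions[0], sim.conditions[1]

    # ---- TF peaks -------------------------------------------------------
    try:
        _stage("callpeaks", fragment_cap=config.fragment_cap,
               peak_window=config.peak_window, confidence=config.peak_confidence)
        tf_small = peaks.filter_fragment_size(tf_fs, config.fragment_cap)
        called = peaks.call_peaks_poisson(tf_small, layout, window=config.peak_window)
        confident = peaks.filter_high_confidence(called, config.peak_confidence)
        blacklist = peaks.build_blacklist(
            peaks.PeakSet("H3K9me3", peaks._empty_peaks()), merge_gap=config.blacklist_gap
        )
        tf_peaks = peaks.apply_blacklist(confident, blacklist)
        write_bed(
            tf_peaks.peaks.assign(name="peak", score=tf_peaks.peaks["neglog10_q"])[
                ["chrom", "start", "end", "name", "score"]
            ],
            out / "tf_peaks.bed",
        )
        shuffled = peaks.shuffle_peaks(
            tf_peaks, layout, exclude_regions=tf_peaks.peaks, seed=_derive_seed(config.seed, "shuffle")
        )
        write_bed(shuffled.peaks[["chrom", "start", "end"]], out / "tf_peaks_shuffled.bed")
        report["n_tf_peaks"] = len(tf_peaks)
    except Exception as exc:
        raise PipelineError("callpeaks", exc) from exc

    # ---- annotation + gene classes -------------------------------------
    try:
        _stage("annotate")
        gene_classes = annotate.classify_genes(de_table)
        gene_classes.to_csv(out / "gene_classes.tsv", sep="\t", index=False)
        anno = annotate.annotate_peaks(tf_peaks, annotation)
        anno.to_csv(out / "tf_peak_annotation.tsv", sep="\t", index=False)
        dist = annotate.category_distribution(anno)
        dist.to_csv(out / "genomic_distribution.tsv", sep="\t", index=False)
        anno_shuf = annotate.annotate_peaks(shuffled, annotation)
        report["genomic_distribution"] = dict(zip(dist["category"], dist["fraction"]))
        report["bound_gene_fraction"] = {}
        report["bound_gene_fraction_shuffled"] = {}
        for cls in ("nb_enriched", "immINP_enriched", "invariant"):
            if (gene_classes["gene_class"] == cls).any():
                report["bound_gene_fraction"][cls] = annotate.bound_gene_fraction(
                    anno, gene_classes, cls
                )
                report["bound_gene_fraction_shuffled"][cls] = annotate.bound_gene_fraction(
                    anno_shuf, gene_classes, cls
                )
        report["shuffled_overlap_with_real_pct"] = annotate.peakset_overlap_fraction(
            shuffled, tf_peaks
        )
    except Exception as exc:
        raise PipelineError("annotate", exc) from exc

    # ---- normalization --------------------------------------------------
    try:
        _stage("normalize", island_w=config.island_w, island_gap=config.island_gap,
               egf=config.island_egf)
        control_ids = [sid for sid, cond, _ in sim.sample_specs("H3K27me3") if cond == control]
        pooled_control = pd.concat(
            [histone[sid].fragments for sid in control_ids], ignore_index=True
        ).sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        islands_pooled = domains.call_islands(
            pooled_control, layout, w=config.island_w, gap=config.island_gap,
            egf=config.island_egf, window_p=config.island_window_p,
        )
        # reads-in-peaks regions: the broad enriched domains, where the mark's
        # signal mass sits and which a peak caller on the control would report;
        # sub-threshold low-level enrichment stays out of the normalization set
        norm_regions = domains.filter_domains(
            islands_pooled, config.domain_min_score, config.domain_min_length
        )[["chrom", "start", "end"]]
        counts = pd.DataFrame(
            {sid: coverage.count_in_regions(fs, norm_regions) for sid, fs in histone.items()}
        )
        counts.insert(0, "region", [f"r{i}" for i in range(len(norm_regions))])
        counts.to_csv(out / "reads_in_peaks_counts.tsv", sep="\t", index=False)
        norms = coverage.normalize_samples(counts.drop(columns="region"))
        scale_of = {n.sample_id: n.final_scale for n in norms}
        pd.DataFrame(
            [(n.sample_id, n.tmm_factor, n.reads_in_peaks, n.final_scale) for n in norms],
            columns=["sample_id", "tmm_factor", "reads_in_peaks", "final_scale"],
        ).to_csv(out / "normalization.tsv", sep="\t", index=False)
        report["tmm_factors"] = {n.sample_id: n.tmm_factor for n in norms}

        # scaled + z-scored merged track for the control condition
        tracks = [
            coverage.apply_scale(
                coverage.compute_coverage(histone[sid], layout, config.track_bin), scale_of[sid]
            )
            for sid in control_ids
        ]
        merged_track = coverage.merge_replicates(tracks)
        z = coverage.zscore_normalize(merged_track)
        coverage.write_bedgraph(z, out / f"H3K27me3_{control}_zscore.bedgraph")
    except Exception as exc:
        raise PipelineError("normalize", exc) from exc

    # ---- differential windows ------------------------------------------
    try:
        _stage("diffwindows", window=config.window, step=config.step, q_cut=config.q_cut)
        windows = diffwin.window_scan(list(histone.values()), layout, config.window, config.step)
        sample_triples = [
            (sid, fs.condition, scale_of[sid]) for sid, fs in histone.items()
        ]
        table = diffwin.test_windows(
            windows, sample_triples, (control, mutant),
            alpha=config.q_cut, min_count=config.min_window_count,
        )
        table = diffwin.mark_bound(table, tf_peaks.peaks)
        table.to_csv(out / "diff_windows.tsv", sep="\t", index=False)
        diffwin.volcano_table(table, out / "volcano.tsv")
        summary = diffwin.summarize_fc(table, config.fc_cut, config.q_cut)
        pd.DataFrame([summary.as_dict()]).to_csv(out / "diff_summary.tsv", sep="\t", index=False)
        report["diff_summary"] = summary.as_dict()
    except Exception as exc:
        raise PipelineError("diffwindows", exc) from exc

    # ---- broad domains + coverage ratio --------------------------------
    try:
        _stage("domains", min_score=config.domain_min_score,
               min_length=config.domain_min_length, merge_gap=config.domain_merge_gap)
        per_rep = []
        for sid in control_ids:
            islands = domains.call_islands(
                histone[sid], layout, w=config.island_w, gap=config.island_gap,
                egf=config.island_egf, window_p=config.island_window_p,
            )
            per_rep.append(domains.filter_domains(
                islands, config.domain_min_score, config.domain_min_length
            ))
        pc_domains = domains.merge_domains(per_rep[0], per_rep[1] if len(per_rep) > 1 else per_rep[0].iloc[:0],
                                           config.domain_merge_gap)
        write_bed(
            pc_domains.assign(name="domain")[["chrom", "start", "end", "name", "score"]],
            out / "pc_domains.bed",
        )
        report["n_pc_domains"] = len(pc_domains)
        control_frags = [histone[sid] for sid in control_ids]
        outside = domains.peaks_outside_domains(tf_peaks.peaks, pc_domains)
        peak_cov = domains.region_coverage(control_frags, outside)
        dom_cov = domains.region_coverage(control_frags, pc_domains)
        peak_cov.to_csv(out / "peak_coverage.tsv", sep="\t", index=False)
        dom_cov.to_csv(out / "domain_coverage.tsv", sep="\t", index=False)
        report["coverage_ratio_domain_over_peak"] = domains.coverage_ratio(peak_cov, dom_cov)
    except Exception as exc:
        raise PipelineError("domains", exc) from exc

    # ---- bin density ----------------------------------------------------
    try:
        _stage("density", bin=config.density_bin)
        pooled = {}
        for cond in (control, mutant):
            ids = [sid for sid, c, _ in sim.sample_specs("H3K27me3") if c == cond]
            frags = pd.concat([histone[sid].fragments for sid in ids], ignore_index=True)
            frags = frags.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
            pooled[cond] = synth.FragmentSet(f"H3K27me3_{cond}_pooled", cond, 1, "H3K27me3", frags)
        n = config.subsample_n or min(len(fs) for fs in pooled.values())
        matched = {
            cond: density.subsample_fragments(fs, n, seed=_derive_seed(config.seed, f"subsample/{cond}"))
            for cond, fs in pooled.items()
        }
        table, dsummary = density.bin_density(matched, layout, tf_peaks.peaks, config.density_bin)
        table.to_csv(out / "bin_density.tsv", sep="\t", index=False)
        dsummary.to_csv(out / "bin_density_summary.tsv", sep="\t", index=False)
        density.density_histograms(table, list(matched)).to_csv(
            out / "bin_density_histograms.tsv", sep="\t", index=False
        )
        report["bin_density_n"] = int(n)
        report["bin_density_summary"] = dsummary.to_dict(orient="records")
    except Exception as exc:
        raise PipelineError("density", exc) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _derive_seed(seed: int, label: str) -> int:
    import zlib

    return (seed * 1_000_003 + zlib.crc32(label.encode())) % (2**31)
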