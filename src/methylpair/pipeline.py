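"""End-to-end orchestration: simulate (or read) -> filter -> call -> annotate
-> integrate, with standard-format outputs and a structured summary."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import core, dmr, integration, io
from .errors import ConfigError
from .simulate import SimConfig, SimTruth, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_outputs"]


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Exactly one input mode is active: ``sim`` set (simulate mode) or real
    input paths set (``counts`` sample sheet + annotation). Thresholds hold
    the published defaults: depth > 10, |delta| >= 0.03, q < 0.05 for DMRs;
    FC > 2 or < 0.5 at FDR < 0.05 for DEGs.
    """

    seed: int = 0
    sim: SimConfig | None = None
    # real-input mode
    counts: list[dict] | None = None  # rows: path, sample, animal, group
    genome_path: str | None = None
    genes_path: str | None = None
    expression_path: str | None = None
    gmt_path: str | None = None
    tf_path: str | None = None
    # analysis parameters
    window: dmr.WindowSpec = field(default_factory=dmr.WindowSpec)
    groups: tuple[str, str] = ("adipogenic", "myogenic")
    min_depth: int = 10
    delta_min: float = 0.03
    q_max: float = 0.05
    fc_up: float = 2.0
    fc_down: float = 0.5
    fdr_max: float = 0.05
    autosomes: tuple[str, ...] = core.PIG_AUTOSOMES
    test_mode: str = "level"

    def __post_init__(self) -> None:
        simulate = self.sim is not None
        real = self.counts is not None
        if simulate == real:
            raise ConfigError("exactly one of simulate/real-input modes must be active")
        if not (self.fc_down < 1.0 < self.fc_up):
            raise ConfigError("DEG thresholds must satisfy fc_down < 1 < fc_up")
        for name in ("min_depth", "delta_min", "q_max", "fdr_max"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if simulate and self.sim.seed != self.seed:
            self.sim = replace(self.sim, seed=self.seed)


@dataclass
class PipelineResult:
    config: PipelineConfig
    matrix: core.CpGCountMatrix          # filtered sites
    conversion: pd.Series | None
    size_factors: pd.Series
    window_table: dmr.MethylWindowTable
    dmrset: dmr.DMRSet
    cgis: list[ann.CGIRecord]
    shores: list[tuple[str, int, int]]
    annotations: pd.DataFrame            # per called DMR: category, gene link
    feature_dist: pd.DataFrame
    degs: pd.DataFrame
    codiff: integration.CoDifferentResult | None
    fc_by_category: pd.DataFrame | None
    ora: pd.DataFrame | None
    tf_tables: tuple[pd.DataFrame, pd.DataFrame] | None
    genome: dict[str, str] | None
    gene_models: pd.DataFrame
    truth: SimTruth | None
    confusion: dict | None
    summary: dict

    def summary_text(self) -> str:
        lines = ["methylpair pipeline summary", "=" * 28]
        for key, val in self.summary.items():
            if isinstance(val, float):
                lines.append(f"{key}: {val:.4g}")
            else:
                lines.append(f"{key}: {val}")
        lines.append("")
        lines.append("DMR feature distribution:")
        for r in self.feature_dist.itertuples():
            lines.append(f"  {r.category}: {r.count} ({r.percent:.2f}%)")
        if self.confusion is not None:
            lines.append("")
            lines.append("truth vs called (tested windows):")
            for key in ("tp", "fp", "fn", "tn"):
                lines.append(f"  {key}: {self.confusion[key]}")
            lines.append(f"  sensitivity: {self.confusion['sensitivity']:.4g}")
            lines.append(f"  empirical_fdr: {self.confusion['empirical_fdr']:.4g}")
        return "\n".join(lines) + "\n"


def _truth_confusion(tested: pd.DataFrame, called: pd.DataFrame,
                     truth: SimTruth) -> dict:
    truth_keys = {(c, s) for c, s, _e, _d in truth.dmr_intervals}
    tested_keys = list(zip(tested["chrom"], tested["start"]))
    called_keys = set(zip(called["chrom"], called["start"]))
    tp = fp = fn = tn = 0
    for key in tested_keys:
        is_true = key in truth_keys
        is_called = key in called_keys
        tp += is_true and is_called
        fp += (not is_true) and is_called
        fn += is_true and (not is_called)
        tn += (not is_true) and (not is_called)
    n_called = tp + fp
    n_true_tested = tp + fn
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "n_tested": len(tested_keys),
        "sensitivity": tp / n_true_tested if n_true_tested else float("nan"),
        "empirical_fdr": fp / n_called if n_called else 0.0,
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and return the full result bundle."""
    simulate_mode = config.sim is not None
    truth = None
    controls = None
    tf_names = None
    gene_sets = None

    if simulate_mode:
        ds = simulate_dataset(config.sim)
        raw = ds.counts
        genome = ds.genome
        gene_models = ds.gene_models
        expression = ds.expression
        truth = ds.truth
        controls = ds.controls
    else:
        mats = [
            core.read_cpg_report(row["path"], sample=row["sample"],
                                 animal=row["animal"], group=row["group"])
            for row in config.counts
        ]
        raw = core.merge_samples(mats)
        ctrl = [core.read_noncpg_controls(row["path"], sample=row["sample"])
                for row in config.counts]
        if any(len(c.sites) for c in ctrl):
            from .simulate import NonCpGControls
            n = max(len(c.sites) for c in ctrl)
            meth = np.zeros((n, len(ctrl)), dtype=np.int64)
            total = np.zeros((n, len(ctrl)), dtype=np.int64)
            for j, c in enumerate(ctrl):
                meth[: len(c.sites), j] = c.meth[:, 0]
                total[: len(c.sites), j] = c.total[:, 0]
            controls = NonCpGControls(
                sites=ctrl[0].sites, samples=[c.samples[0] for c in ctrl],
                meth=meth, total=total,
            )
        genome = io.load_genome(config.genome_path) if config.genome_path else None
        gene_models = io.read_gene_models(config.genes_path)
        expression = (io.read_expression(config.expression_path)
                      if config.expression_path else None)
    if config.gmt_path:
        gene_sets = io.read_gmt(config.gmt_path)
    if config.tf_path:
        tf_names = io.read_tf_list(config.tf_path)

    logger.info("sites read: %d", raw.n_sites)
    matrix = core.filter_sites(raw, min_depth=config.min_depth,
                               autosomes=config.autosomes)
    logger.info("sites surviving depth/autosome filter: %d", matrix.n_sites)
    conversion = (core.estimate_conversion_rate(controls)
                  if controls is not None and len(controls.sites) else None)
    sf = core.size_factors(matrix)

    table = dmr.tile_windows(matrix, config.window)
    tested = dmr.test_windows(
        table, groups=config.groups, mode=config.test_mode,
        size_factors=sf if config.test_mode == "normalized_counts" else None,
    )
    logger.info("windows tested: %d", len(tested))
    dmrset = dmr.call_dmrs(tested, table, delta_min=config.delta_min,
                           q_max=config.q_max)
    logger.info("DMRs called: %d", dmrset.n_dmrs)

    cgis = ann.find_cgis(genome) if genome else []
    chrom_lengths = {c: len(s) for c, s in genome.items()} if genome else None
    shores = ann.define_shores(cgis, chrom_lengths=chrom_lengths) if cgis else []
    model = ann.build_feature_model(gene_models, cgis=cgis, shores=shores)

    records = dmrset.records
    annotations = records[["chrom", "start", "end", "delta", "q_value",
                           "direction"]].copy()
    annotations["category"] = ann.annotate_dmrs(records, model) \
        if len(records) else pd.Series(dtype=str)
    links = ann.closest_genes(records, model.genes) if len(records) else \
        pd.DataFrame(columns=["gene_id", "distance"])
    annotations[["gene_id", "distance"]] = links
    feature_dist = ann.feature_distribution(annotations["category"])

    degs = pd.DataFrame(columns=["gene_id", "fc", "fdr", "direction"])
    codiff = fc_by_cat = ora = tf_tables = None
    if expression is not None:
        degs = integration.call_degs(
            expression, fc_up=config.fc_up, fc_down=config.fc_down,
            fdr_max=config.fdr_max, groups=config.groups,
        )
        codiff = integration.co_different(degs, annotations)
        if len(annotations):
            fc_by_cat = integration.fold_change_by_category(
                annotations, expression, groups=config.groups)
        if tf_names:
            tf_tables = integration.tf_subset(expression, tf_names, degs)
        if gene_sets:
            universe = set(expression["gene_id"])
            query = set(degs["gene_id"]) & universe
            ora = integration.ora_enrichment(query, gene_sets, universe)

    confusion = None
    if simulate_mode:
        confusion = _truth_confusion(tested, records, truth)

    summary = {
        "mode": "simulate" if simulate_mode else "real",
        "seed": config.seed,
        "n_sites_read": raw.n_sites,
        "n_sites_filtered": matrix.n_sites,
        "n_windows_tested": len(tested),
        **dmrset.summary(),
        "n_cgis": len(cgis),
        "n_genes": len(gene_models),
        "n_degs": len(degs),
        "n_co_different": len(codiff.genes) if codiff else 0,
    }
    if conversion is not None:
        summary["conversion_rate_pooled"] = float(conversion["pooled"])
    if codiff:
        summary.update(
            {f"quadrant_{k}": v for k, v in codiff.quadrant_counts.items()})

    return PipelineResult(
        config=config, matrix=matrix, conversion=conversion, size_factors=sf,
        window_table=table, dmrset=dmrset, cgis=cgis, shores=shores,
        annotations=annotations, feature_dist=feature_dist, degs=degs,
        codiff=codiff, fc_by_category=fc_by_cat, ora=ora, tf_tables=tf_tables,
        genome=genome, gene_models=gene_models, truth=truth,
        confusion=confusion, summary=summary,
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> list[Path]:
    """Write every stage output; returns the list of files written.

    DMRs and CGIs go out as BED6 (score = -log10 q for DMRs, clipped to
    [0, 1000]); tables as TSV with headers; DMR sequences as multi-FASTA when
    a genome is available; the summary as structured text.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _path(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    records = result.dmrset.records
    bed = records[["chrom", "start", "end"]].copy() if len(records) else \
        pd.DataFrame(columns=["chrom", "start", "end"])
    if len(records):
        bed["name"] = [f"DMR_{d}_{i:05d}" for i, d in
                       enumerate(records["direction"], start=1)]
        bed["score"] = io.dmr_score(records["q_value"].to_numpy())
    io.write_bed6(bed, _path("dmrs.bed"))

    cgi_bed = pd.DataFrame(
        [(r.chrom, r.start, r.end, f"CGI_{i:04d}", 0)
         for i, r in enumerate(result.cgis, start=1)],
        columns=["chrom", "start", "end", "name", "score"],
    )
    io.write_bed6(cgi_bed, _path("cgis.bed"))
    shore_bed = pd.DataFrame(
        [(c, s, e, f"shore_{i:04d}", 0)
         for i, (c, s, e) in enumerate(result.shores, start=1)],
        columns=["chrom", "start", "end", "name", "score"],
    )
    io.write_bed6(shore_bed, _path("shores.bed"))

    result.dmrset.tested.to_csv(_path("windows.tsv"), sep="\t", index=False,
                                float_format="%.6g")
    result.annotations.to_csv(_path("annotations.tsv"), sep="\t", index=False,
                              float_format="%.6g")
    result.feature_dist.to_csv(_path("feature_distribution.tsv"), sep="\t",
                               index=False, float_format="%.6g")
    result.degs.to_csv(_path("degs.tsv"), sep="\t", index=False,
                       float_format="%.6g")
    if result.codiff is not None:
        result.codiff.genes.to_csv(_path("co_different.tsv"), sep="\t",
                                   index=False, float_format="%.6g")
    if result.fc_by_category is not None:
        result.fc_by_category.to_csv(_path("fc_by_category.tsv"), sep="\t",
                                     index=False, float_format="%.6g")
    if result.ora is not None:
        result.ora.to_csv(_path("ora.tsv"), sep="\t", index=False,
                          float_format="%.6g")
    if result.genome is not None and len(records):
        ann.export_dmr_fasta(records, result.genome, _path("dmrs.fasta"))
    with open(_path("summary.txt"), "w") as fh:
        fh.write(result.summary_text())
    return written


def export_simulated_inputs(result: PipelineResult, outdir: str | Path
                            ) -> list[Path]:
    """Write simulate-mode inputs (genome FASTA, gene GTF, per-sample
    cytosine reports, expression TSV, truth tables) so a real-input run can
    reproduce the analysis from files."""
    if result.truth is None:
        raise ConfigError("export_simulated_inputs requires simulate mode")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    io.write_fasta(result.genome, outdir / "genome.fa")
    written.append(outdir / "genome.fa")
    io.write_gtf(result.gene_models, outdir / "genes.gtf")
    written.append(outdir / "genes.gtf")
    # full (unfiltered) per-sample reports would need the raw matrix; the
    # filtered one is sufficient for round-tripping the DMR analysis
    for name in result.matrix.samples["name"]:
        p = outdir / f"{name}.cov.tsv"
        core.write_cpg_report(result.matrix, p, sample=name)
        written.append(p)
    result.truth.dmr_frame().to_csv(outdir / "truth_dmrs.tsv", sep="\t",
                                    index=False)
    written.append(outdir / "truth_dmrs.tsv")
    return written
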