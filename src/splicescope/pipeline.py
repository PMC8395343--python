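"""End-to-end orchestration of the splicing analysis stages.

A :class:`RunConfig` names every input file and threshold; ``run_pipeline``
executes the stages in order (quantify -> consequence -> microexon -> SNPs
-> motifs -> miRNA -> expression), writes TSV/JSON artifacts into the
output directory, and records a manifest with row counts, stage status and
the exact configuration used.  Stages with missing optional inputs (e.g. no
VCF) are skipped with an explicit manifest note; a stage failure stops the
run but keeps the partial outputs and marks the failure point.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    consequence as cq,
    core_io,
    diffexp_stats as dx,
    microexon as mx,
    mirna_target as mt,
    rbp_motif as rm,
    snp_context as sc,
    splice_quant as sq,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run.

    Thresholds default to the event filter (|dPSI| > 0.1, probability >
    0.9), the strong/moderate boundary at 0.5, 15-nt splice-site windows
    with intronic windows out to 500 nt, 250-nt motif flanks, microexons of
    3-30 nt, and alpha = 0.05 on BH-adjusted p-values.
    """

    annotation: str
    genome: str
    junctions: str
    samples: str
    outdir: str
    vcf: str | None = None
    gene_expression: str | None = None
    mirna_expression: str | None = None
    mirna_fasta: str | None = None
    utr_fasta: str | None = None
    motifs: str | None = None
    targets: str | None = None
    gwas_genes: str | None = None
    ortholog_map: str | None = None
    factor_gene: str = "Srrm4"
    seed: int = 0
    dpsi_cutoff: float = 0.1
    prob_cutoff: float = 0.9
    strong_cutoff: float = 0.5
    prob_threshold: float = 0.0
    n_draws: int = 10_000
    ss_window: int = 15
    intron_window: tuple[int, int] = (15, 500)
    flank_nt: int = 250
    microexon_range: tuple[int, int] = (3, 30)
    alpha: float = 0.05

    def validate(self) -> None:
        if not 0 <= self.dpsi_cutoff <= 1 or not 0 <= self.prob_cutoff <= 1:
            raise ValueError("cutoffs must lie in [0, 1]")
        if self.intron_window[0] >= self.intron_window[1]:
            raise ValueError("intron window must be (min, max) with min < max")
        if self.microexon_range[0] > self.microexon_range[1]:
            raise ValueError("bad microexon length range")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        for key in ("intron_window", "microexon_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def for_bundle(cls, bundle_dir: str | Path, outdir: str | Path, seed: int = 0) -> "RunConfig":
        """Configuration pointing at a synthetic-study bundle directory."""
        b = Path(bundle_dir)

        def opt(name: str) -> str | None:
            p = b / name
            return str(p) if p.exists() else None

        return cls(
            annotation=str(b / "annotation.gtf"),
            genome=str(b / "genome.fa"),
            junctions=str(b / "junctions.tsv"),
            samples=str(b / "samples.tsv"),
            outdir=str(outdir),
            vcf=opt("snps.vcf"),
            gene_expression=opt("gene_expression.tsv"),
            mirna_expression=opt("mirna_expression.tsv"),
            mirna_fasta=opt("mirna.fa"),
            utr_fasta=opt("utr.fa"),
            motifs=opt("motifs.tsv"),
            targets=opt("microexon_targets.tsv"),
            gwas_genes=opt("gwas_genes.txt"),
            ortholog_map=opt("ortholog_map.tsv"),
            seed=seed,
        )

    @property
    def snp_windows(self) -> sc.SnpWindows:
        return sc.SnpWindows(
            ss_intronic=self.ss_window,
            ss_exonic=self.ss_window,
            intron_min=self.intron_window[0],
            intron_max=self.intron_window[1],
        )


class PipelineResult:
    """Handle on a finished (or partially finished) run."""

    def __init__(self, outdir: Path, manifest: dict):
        self.outdir = outdir
        self.manifest = manifest

    def table(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.outdir / name, sep="\t")

    def json(self, name: str) -> dict:
        with open(self.outdir / name) as fh:
            return json.load(fh)


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return len(df)


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)


def run_pipeline(config: RunConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}, "outputs": {}}

    def record(stage: str, status: str, note: str = "") -> None:
        manifest["stages"][stage] = {"status": status, "note": note}

    def emit(name: str, df: pd.DataFrame) -> None:
        manifest["outputs"][name] = _write_tsv(df, outdir / name)

    try:
        # ---- load shared inputs -----------------------------------------
        ann = core_io.read_annotation(config.annotation, fasta_path=config.genome)
        events = sq.infer_events(ann)
        counts, samples = core_io.read_junction_counts(config.junctions)
        groups = core_io.read_samples(config.samples)
        group_names: list[str] = []
        for s in samples:
            if groups[s] not in group_names:
                group_names.append(groups[s])
        record("load", "ok", f"{len(events)} events, {len(samples)} samples")

        # ---- quantify ----------------------------------------------------
        events = sq.quantify_events(
            events, counts, samples, groups,
            seed=config.seed, n_draws=config.n_draws,
            dpsi_cutoff=config.dpsi_cutoff, prob_cutoff=config.prob_cutoff,
            strong_cutoff=config.strong_cutoff, prob_threshold=config.prob_threshold,
        )
        emit("events.tsv", sq.events_table(events))
        record("quantify", "ok")

        # ---- consequence -------------------------------------------------
        consequences = cq.annotate_consequences(events, ann)
        emit("consequences.tsv", cq.consequence_table(consequences))
        _write_json(cq.frame_summary(events, consequences, ann), outdir / "frame_summary.json")
        manifest["outputs"]["frame_summary.json"] = 1
        record("consequence", "ok")

        # ---- microexons --------------------------------------------------
        micro = mx.detect_microexons(ann, *config.microexon_range)
        emit(
            "microexons.tsv",
            pd.DataFrame(
                [
                    {"exon_id": m.exon_id, "gene": m.gene_id, "chrom": m.chrom,
                     "start": m.start, "end": m.end, "length": m.length}
                    for m in micro
                ],
                columns=["exon_id", "gene", "chrom", "start", "end", "length"],
            ),
        )
        micro_summary: dict = {"n_microexons": len(micro)}
        if config.targets:
            targets = mx.read_target_list(config.targets)
            t_summary, t_table = mx.summarize_target_inclusion(events, targets)
            micro_summary["targets"] = t_summary
            emit("target_inclusion.tsv", t_table)
            if config.gene_expression:
                expr = core_io.read_expression(config.gene_expression, groups)
                if config.factor_gene in expr.values.index:
                    psi = mx.per_sample_target_psi(events, targets, samples, counts)
                    factor = expr.values.loc[config.factor_gene, samples].to_numpy(dtype=float)
                    mask = ~np.isnan(psi.to_numpy())
                    if mask.sum() >= 4:
                        rho, p = mx.expression_inclusion_correlation(
                            factor[mask], psi.to_numpy()[mask], seed=config.seed
                        )
                        micro_summary["factor_inclusion_correlation"] = {
                            "factor": config.factor_gene, "rho": rho, "p": p,
                        }
        _write_json(micro_summary, outdir / "microexon_summary.json")
        manifest["outputs"]["microexon_summary.json"] = 1
        record("microexon", "ok")

        # ---- SNP context -------------------------------------------------
        snps: list[core_io.SnpRecord] = []
        if config.vcf:
            windows = config.snp_windows
            snps = core_io.read_vcf(config.vcf)
            emit("snp_counts.tsv", sc.snp_count_table(snps, events, windows))
            genome_length = sum(ann.contig_lengths().values())
            _write_json(
                sc.density_summary(snps, events, genome_length, windows),
                outdir / "snp_enrichment.json",
            )
            manifest["outputs"]["snp_enrichment.json"] = 1
            ss_genes = sc.flag_splice_site_snp_genes(snps, events, windows)
            emit("splice_site_snp_genes.tsv", pd.DataFrame({"gene": ss_genes}))
            cpg = sc.count_cpg_loss(snps, ann, events, windows)
            emit(
                "cpg_loss.tsv",
                pd.DataFrame(
                    [{"gene": g, "n_cpg_lost": n} for g, n in cpg.items()],
                    columns=["gene", "n_cpg_lost"],
                ),
            )
            record("snps", "ok", f"{len(snps)} SNPs")
        else:
            record("snps", "skipped", "no VCF supplied")

        # ---- RBP motifs --------------------------------------------------
        if config.motifs:
            motifs = rm.read_motifs(config.motifs)
            sig_up = [e for e in events if e.significant and (e.delta_psi or 0) > 0]
            sig_down = [e for e in events if e.significant and (e.delta_psi or 0) < 0]
            background = [e for e in events if e.quantifiable and not e.significant]
            tables = []
            for fg, direction in ((sig_up, "inclusion_up"), (sig_down, "inclusion_down")):
                if fg and background:
                    tables.append(
                        rm.enrichment_table(
                            motifs, fg, background, ann,
                            flank_nt=config.flank_nt, direction=direction,
                        )
                    )
            enr = (
                pd.concat(tables, ignore_index=True)
                if tables
                else pd.DataFrame(
                    columns=["motif", "region", "direction", "fg_hits", "fg_n",
                             "bg_hits", "bg_n", "log2_enrichment", "p", "p_adj"]
                )
            )
            emit("motif_enrichment.tsv", enr)
            if snps:
                effects = rm.event_snp_motif_effects(
                    events, snps, motifs, ann,
                    flank_nt=config.flank_nt, windows=config.snp_windows,
                )
                emit("motif_effects.tsv", effects)
                _write_json(
                    {"n_affected_events": rm.count_affected_events(effects)},
                    outdir / "motif_affected.json",
                )
                manifest["outputs"]["motif_affected.json"] = 1
            record("motifs", "ok")
        else:
            record("motifs", "skipped", "no motif file supplied")

        # ---- miRNA targeting ----------------------------------------------
        if config.mirna_expression and config.mirna_fasta and config.utr_fasta:
            mirna_expr = core_io.read_expression(config.mirna_expression, groups)
            diff = mt.differential_mirnas(mirna_expr, alpha=config.alpha, full=True)
            emit("mirna_diffexp.tsv", diff)
            mirna_seqs = core_io.read_fasta(config.mirna_fasta)
            utr = next(iter(core_io.read_fasta(config.utr_fasta).values()))
            candidates = mt.candidate_regulators(
                diff[diff["significant"]], mirna_seqs, utr, required_direction=1
            )
            emit("mirna_candidates.tsv", candidates)
            record("mirna", "ok")
        else:
            record("mirna", "skipped", "miRNA inputs not supplied")

        # ---- differential expression / GWAS overlap ----------------------
        if config.gene_expression:
            expr = core_io.read_expression(config.gene_expression, groups)
            diffexp = dx.differential_expression(expr, alpha=config.alpha)
            emit("diffexp.tsv", diffexp)
            sig_features = diffexp.loc[diffexp["significant"], "feature"].tolist()
            if sig_features:
                scaled = dx.scale_heatmap_matrix(expr, sig_features)
                scaled.to_csv(outdir / "heatmap_matrix.tsv", sep="\t",
                              float_format=FLOAT_FORMAT, index_label="feature")
                manifest["outputs"]["heatmap_matrix.tsv"] = len(scaled)
            if config.gwas_genes and config.ortholog_map:
                spliced_genes = sorted(
                    {ann.genes[e.gene_id].symbol for e in events if e.significant}
                )
                overlap = dx.intersect_gene_lists(
                    spliced_genes,
                    core_io.read_gene_list(config.gwas_genes),
                    core_io.read_ortholog_map(config.ortholog_map),
                )
                emit("gwas_overlap.tsv", overlap)
            record("diffexp", "ok")
        else:
            record("diffexp", "skipped", "no expression matrix supplied")

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_json(manifest, outdir / "manifest.json")
        raise

    _write_json(manifest, outdir / "manifest.json")
    return PipelineResult(outdir, manifest)
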