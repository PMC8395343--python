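"""Microexon detection, target-exon inclusion summaries, and the
inclusion-vs-splicing-factor-expression correlation.

Microexons are internal exons of 3-30 nt; their inclusion is typically
frame-preserving and driven by dedicated factors (SRRM4 in neurons and
neuron-like secretory cells).  A supplied target-exon list (coordinates)
marks exons whose inclusion should track the factor's expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenomeAnnotation
from .splice_quant import SpliceEvent

logger = logging.getLogger(__name__)

MICROEXON_MIN = 3
MICROEXON_MAX = 30


@dataclass(frozen=True)
class MicroexonRecord:
    exon_id: str
    gene_id: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def detect_microexons(
    ann: GenomeAnnotation,
    min_len: int = MICROEXON_MIN,
    max_len: int = MICROEXON_MAX,
) -> list[MicroexonRecord]:
    """All internal exons with min_len <= length <= max_len, deduplicated
    by coordinates; invariant to transcript order in the input."""
    seen: dict[tuple[str, int, int], MicroexonRecord] = {}
    for gene_id in sorted(ann.genes):
        gene = ann.genes[gene_id]
        for tx in sorted(gene.transcripts, key=lambda t: t.id):
            exons = tx.exons_genomic
            for s, e in exons[1:-1]:
                if min_len <= e - s <= max_len:
                    key = (gene.chrom, s, e)
                    if key not in seen:
                        seen[key] = MicroexonRecord(
                            f"{gene.chrom}:{s}-{e}", gene_id, gene.chrom, s, e
                        )
    return [seen[k] for k in sorted(seen)]


def read_target_list(path) -> set[tuple[str, int, int]]:
    """Target-exon coordinates: TSV with chrom, start, end (0-based
    half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: int, 2: int})
    return {(r.iloc[0], int(r.iloc[1]), int(r.iloc[2])) for _, r in df.iterrows()}


def summarize_target_inclusion(
    events: Sequence[SpliceEvent],
    targets: set[tuple[str, int, int]],
) -> tuple[dict, pd.DataFrame]:
    """Mean PSI per group over target exons plus per-event skip calls.

    An event is 'preferentially skipped' in the group whose PSI is lower,
    provided the event passed the significance filter.  Returns
    ``(summary, per_event_table)``; an empty intersection yields an empty
    summary with a warning.
    """
    matched = [
        e
        for e in events
        if (e.chrom, e.start, e.end) in targets and e.quantifiable
    ]
    if not matched:
        logger.warning("summarize_target_inclusion: no quantifiable target events")
        return {"n_targets": 0, "mean_psi_g1": None, "mean_psi_g2": None}, pd.DataFrame(
            columns=["event_id", "gene", "psi_g1", "psi_g2", "delta_psi", "skipped_in"]
        )
    rows = []
    for e in matched:
        if e.significant and e.delta_psi is not None and e.delta_psi != 0:
            skipped_in = "group1" if e.delta_psi < 0 else "group2"
        else:
            skipped_in = ""
        rows.append(
            {
                "event_id": e.event_id,
                "gene": e.gene_id,
                "psi_g1": e.psi_g1,
                "psi_g2": e.psi_g2,
                "delta_psi": e.delta_psi,
                "skipped_in": skipped_in,
            }
        )
    table = pd.DataFrame(rows)
    summary = {
        "n_targets": len(matched),
        "mean_psi_g1": float(np.mean([e.psi_g1 for e in matched])),
        "mean_psi_g2": float(np.mean([e.psi_g2 for e in matched])),
        "n_skipped_in_group1": int((table["skipped_in"] == "group1").sum()),
        "n_skipped_in_group2": int((table["skipped_in"] == "group2").sum()),
    }
    return summary, table


def per_sample_target_psi(
    events: Sequence[SpliceEvent],
    targets: set[tuple[str, int, int]],
    samples: Sequence[str],
    counts: dict[str, list[tuple[int, int]]],
) -> pd.Series:
    """Per-sample mean PSI across target events (per-sample counts, not
    pooled); samples where an event has zero coverage are averaged over the
    remaining events."""
    matched = [e for e in events if (e.chrom, e.start, e.end) in targets]
    per_sample: list[float] = []
    for j, _sample in enumerate(samples):
        vals = []
        for e in matched:
            if e.event_id not in counts:
                continue
            inc, exc = counts[e.event_id][j]
            if inc + exc > 0:
                vals.append(inc / (inc + exc))
        per_sample.append(float(np.mean(vals)) if vals else np.nan)
    return pd.Series(per_sample, index=list(samples), name="target_mean_psi")


def expression_inclusion_correlation(
    factor_expression: Sequence[float],
    psi: Sequence[float],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation between per-sample factor expression and
    per-sample mean target PSI, with a two-sided permutation p-value.

    Constant inputs have no defined rank correlation and return
    ``(nan, nan)`` with a warning.
    """
    x = np.asarray(factor_expression, dtype=float)
    y = np.asarray(psi, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 paired samples")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        logger.warning("expression_inclusion_correlation: constant input vector")
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        if abs(float(stats.spearmanr(x, perm).statistic)) >= abs(rho) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return rho, float(p)
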