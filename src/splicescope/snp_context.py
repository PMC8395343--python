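"""Positional classification of SNPs around alternative exons.

Windows (transcript orientation, distances in nucleotides):

* splice-site adjacent: within 15 nt of a splice site, counted on both the
  intronic and the exonic side of the exon boundary;
* intronic upstream/downstream: 15 < distance <= 500 into the flanking
  intron;
* exonic: inside the exon, more than 15 nt away from both edges;
* outside: everything farther away (or on another chromosome).

Densities are normalized per 1000 nt, and local densities are compared
against a genome-wide baseline with a 2x2 chi-square test (1 df, no
continuity correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .core_io import GenomeAnnotation, Interval, SnpRecord
from .splice_quant import SpliceEvent

logger = logging.getLogger(__name__)

CAT_INTRONIC_UP = "intronic_upstream"
CAT_SS3 = "ss3_adjacent"
CAT_EXONIC = "exonic"
CAT_SS5 = "ss5_adjacent"
CAT_INTRONIC_DOWN = "intronic_downstream"
CAT_OUTSIDE = "outside"

CATEGORIES = (CAT_INTRONIC_UP, CAT_SS3, CAT_EXONIC, CAT_SS5, CAT_INTRONIC_DOWN)


@dataclass(frozen=True)
class SnpWindows:
    """Window widths; ``ss_intronic``/``ss_exonic`` are the splice-site
    adjacency widths on either side of the exon boundary."""

    ss_intronic: int = 15
    ss_exonic: int = 15
    intron_min: int = 15
    intron_max: int = 500


DEFAULT_WINDOWS = SnpWindows()


def classify_snp_position(
    snp: SnpRecord,
    exon: Interval,
    strand: str,
    chrom: str | None = None,
    windows: SnpWindows = DEFAULT_WINDOWS,
) -> str:
    """Positional category of a SNP relative to one alternative exon.

    Distances are 1-based from the exon boundary (the first intronic base
    and the outermost exonic base both have distance 1).  Upstream /
    downstream and the acceptor (3'ss) / donor (5'ss) sides follow
    transcript orientation.
    """
    if chrom is not None and snp.chrom != chrom:
        return CAT_OUTSIDE
    p = snp.pos0
    start, end = exon
    if start <= p < end:
        d_left = p - start + 1
        d_right = end - p
        if d_left <= windows.ss_exonic or d_right <= windows.ss_exonic:
            side = "left" if d_left <= d_right else "right"
        else:
            return CAT_EXONIC
    else:
        if p < start:
            d = start - p
            side = "left"
        else:
            d = p - (end - 1)
            side = "right"
        if d <= windows.ss_intronic:
            pass  # splice-site adjacent, resolved below
        elif d <= windows.intron_max:
            upstream = (side == "left") == (strand == "+")
            return CAT_INTRONIC_UP if upstream else CAT_INTRONIC_DOWN
        else:
            return CAT_OUTSIDE
    # splice-site adjacency: genomic-left edge is the acceptor (3'ss) on
    # '+' and the donor (5'ss) on '-'
    acceptor_side = "left" if strand == "+" else "right"
    return CAT_SS3 if side == acceptor_side else CAT_SS5


def per_event_snp_counts(
    snps: Iterable[SnpRecord],
    event: SpliceEvent,
    windows: SnpWindows = DEFAULT_WINDOWS,
) -> tuple[int, int, int, int, int, int]:
    """Counts ``(intronic_up, ss3, exonic, ss5, intronic_down, total)`` of
    SNPs around one event's alternative exon."""
    counts = dict.fromkeys(CATEGORIES, 0)
    for snp in snps:
        cat = classify_snp_position(
            snp, event.segment, event.strand, chrom=event.chrom, windows=windows
        )
        if cat in counts:
            counts[cat] += 1
    ordered = tuple(counts[c] for c in CATEGORIES)
    return ordered + (sum(ordered),)


def snp_density_per_kb(n_snps: int, region_length_nt: int) -> float:
    """SNPs per 1000 nt."""
    if region_length_nt < 1:
        raise ValueError("region length must be >= 1 nt")
    if n_snps < 0:
        raise ValueError("negative SNP count")
    return n_snps / region_length_nt * 1000.0


def enrichment_chi2(
    n_near: int, len_near_nt: int, n_global: int, len_global_nt: int
) -> tuple[float, float]:
    """2x2 chi-square (1 df, no continuity correction) comparing the SNP
    density near alternative exons against the genome-wide density.

    Rows are near/global, columns are SNP vs non-SNP positions.  A warning
    is logged when an expected cell drops below 1, but the statistic is
    still returned.
    """
    if min(n_near, n_global) < 0 or min(len_near_nt, len_global_nt) <= 0:
        raise ValueError("counts must be non-negative and lengths positive")
    if n_near > len_near_nt or n_global > len_global_nt:
        raise ValueError("SNP count exceeds region length")
    table = [
        [n_near, len_near_nt - n_near],
        [n_global, len_global_nt - n_global],
    ]
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 1).any():
        logger.warning("enrichment_chi2: expected cell below 1 (%s)", expected.tolist())
    return float(chi2), float(p)


def event_window_span(event: SpliceEvent, windows: SnpWindows = DEFAULT_WINDOWS) -> Interval:
    """Genomic interval covered by the exon plus both intronic windows."""
    return (max(0, event.start - windows.intron_max), event.end + windows.intron_max)


def flag_splice_site_snp_genes(
    snps: Iterable[SnpRecord],
    events: Sequence[SpliceEvent],
    windows: SnpWindows = DEFAULT_WINDOWS,
    significant_only: bool = True,
) -> list[str]:
    """Genes with >= 1 splice-site-adjacent SNP on a (significant) event."""
    snps = list(snps)
    flagged: set[str] = set()
    for event in events:
        if significant_only and not event.significant:
            continue
        for snp in snps:
            cat = classify_snp_position(
                snp, event.segment, event.strand, chrom=event.chrom, windows=windows
            )
            if cat in (CAT_SS3, CAT_SS5):
                flagged.add(event.gene_id)
                break
    return sorted(flagged)


def _destroys_cpg(ref_context: str, ref: str, alt: str) -> bool:
    """``ref_context`` is the 3-mer (prev, snp, next) on the genome forward
    strand.  True iff a CpG dinucleotide covering the SNP exists with the
    reference allele but none exists with the alternative allele."""
    prev, mid, nxt = ref_context
    if mid != ref:
        raise ValueError(f"reference allele {ref!r} does not match context {ref_context!r}")
    def has_cpg(base: str) -> bool:
        return (base == "C" and nxt == "G") or (base == "G" and prev == "C")
    return has_cpg(ref) and not has_cpg(alt)


def count_cpg_loss(
    snps: Iterable[SnpRecord],
    ann: GenomeAnnotation,
    events: Sequence[SpliceEvent],
    windows: SnpWindows = DEFAULT_WINDOWS,
) -> dict[str, int]:
    """Per-gene count of CpG dinucleotides destroyed by SNPs within the
    event windows (CpG is strand-symmetric; the forward strand is used)."""
    spans: dict[str, list[tuple[str, Interval]]] = {}
    for event in events:
        spans.setdefault(event.chrom, []).append((event.gene_id, event_window_span(event, windows)))

    losses: dict[str, set[tuple[str, int]]] = {}
    for snp in snps:
        for gene_id, (w_start, w_end) in spans.get(snp.chrom, []):
            if not (w_start <= snp.pos0 < w_end):
                continue
            try:
                context = ann.sequence(snp.chrom, snp.pos0 - 1, snp.pos0 + 2, "+")
            except (ValueError, KeyError):
                context = ""
            if len(context) != 3:
                logger.warning(
                    "count_cpg_loss: SNP at %s:%d too close to contig edge, skipped",
                    snp.chrom, snp.pos,
                )
                continue
            if _destroys_cpg(context, snp.ref, snp.alt):
                losses.setdefault(gene_id, set()).add((snp.chrom, snp.pos))
    return {gene: len(sites) for gene, sites in sorted(losses.items())}


def snp_count_table(
    snps: Iterable[SnpRecord],
    events: Sequence[SpliceEvent],
    windows: SnpWindows = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Per-event table mirroring the five positional columns plus total."""
    snps = list(snps)
    rows = []
    for event in events:
        c = per_event_snp_counts(snps, event, windows)
        rows.append(
            {
                "event_id": event.event_id,
                "gene": event.gene_id,
                "n_intronic_upstream": c[0],
                "n_ss3_adjacent": c[1],
                "n_exonic": c[2],
                "n_ss5_adjacent": c[3],
                "n_intronic_downstream": c[4],
                "n_total": c[5],
            }
        )
    return pd.DataFrame(rows)


def density_summary(
    snps: Iterable[SnpRecord],
    events: Sequence[SpliceEvent],
    genome_length: int,
    windows: SnpWindows = DEFAULT_WINDOWS,
) -> dict:
    """Near-exon SNP density per kb, the global baseline, and the 2x2
    chi-square comparison."""
    snps = list(snps)
    spans_by_chrom: dict[str, list[Interval]] = {}
    for event in events:
        spans_by_chrom.setdefault(event.chrom, []).append(event_window_span(event, windows))

    # merge overlapping windows so positions are not double-counted
    near_len = 0
    merged: dict[str, list[Interval]] = {}
    for chrom, spans in spans_by_chrom.items():
        spans = sorted(spans)
        acc: list[Interval] = []
        for s, e in spans:
            if acc and s <= acc[-1][1]:
                acc[-1] = (acc[-1][0], max(acc[-1][1], e))
            else:
                acc.append((s, e))
        merged[chrom] = acc
        near_len += sum(e - s for s, e in acc)

    n_near = sum(
        1
        for snp in snps
        if any(s <= snp.pos0 < e for s, e in merged.get(snp.chrom, []))
    )
    n_global = len(snps)
    chi2, p = enrichment_chi2(n_near, near_len, n_global, genome_length)
    return {
        "n_near": n_near,
        "near_length_nt": near_len,
        "density_near_per_kb": snp_density_per_kb(n_near, near_len) if near_len else 0.0,
        "n_global": n_global,
        "genome_length_nt": genome_length,
        "density_global_per_kb": snp_density_per_kb(n_global, genome_length),
        "chi2": chi2,
        "p": p,
    }
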