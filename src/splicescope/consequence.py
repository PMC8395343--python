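"""Reading-frame consequences of exon skipping.

Cassette exons in the coding sequence either preserve the downstream frame
when skipped (length divisible by 3) or shift it.  Several frameshifting
exons of one gene skipped together in the same direction can rescue the
frame when their summed length is divisible by 3.  The observed frameshift
rate is compared against the rate expected under random skipping of
internal coding exons of the supplied annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .core_io import GenomeAnnotation
from .splice_quant import SpliceEvent

REGION_5UTR = "5UTR"
REGION_CDS = "CDS"
REGION_3UTR = "3UTR"
REGION_NA = "NA"

FRAME_PRESERVED = "preserved"
FRAME_SHIFT = "shift"
FRAME_RESCUE = "rescue-group"
FRAME_NA = "NA"


@dataclass
class EventConsequence:
    event_id: str
    region: str
    frame: str = FRAME_NA
    rescue_group_id: str | None = None


def map_event_region(event: SpliceEvent, ann: GenomeAnnotation) -> str:
    """Locate the alternative segment in 5'UTR / CDS / 3'UTR.

    Uses the longest-CDS transcript of the gene; a segment overlapping both
    UTR and CDS counts as CDS.  Non-coding genes (or genes missing from the
    annotation) map to NA.
    """
    gene = ann.genes.get(event.gene_id)
    if gene is None:
        return REGION_NA
    coding = [t for t in gene.transcripts if t.cds_start is not None]
    if not coding:
        return REGION_NA
    tx = max(coding, key=lambda t: (t.cds_end - t.cds_start, t.id))
    if event.start < tx.cds_end and tx.cds_start < event.end:
        return REGION_CDS
    genomic_left_of_cds = event.end <= tx.cds_start
    if gene.strand == "+":
        return REGION_5UTR if genomic_left_of_cds else REGION_3UTR
    return REGION_3UTR if genomic_left_of_cds else REGION_5UTR


def frame_consequence(exon_length: int) -> str:
    """``preserved`` iff skipping the exon keeps the frame (length % 3 == 0)."""
    if exon_length < 1:
        raise ValueError(f"exon length must be >= 1, got {exon_length}")
    return FRAME_PRESERVED if exon_length % 3 == 0 else FRAME_SHIFT


def find_rescue_groups(events: Sequence[SpliceEvent]) -> dict[str, str]:
    """Group frameshifting cassette exons of one gene that rescue the frame
    if co-skipped.

    Candidates must share the dPSI sign (co-regulated direction); a group's
    summed length must be divisible by 3.  Grouping is greedy
    smallest-group-first: residue-1 exons are paired with residue-2 exons in
    genomic order, then leftovers of a single residue are grouped in
    threes.  Each event joins at most one group.  Returns
    ``{event_id: group_id}``.
    """
    by_gene_sign: dict[tuple[str, int], list[SpliceEvent]] = {}
    for e in events:
        if e.length % 3 == 0 or e.delta_psi is None:
            continue
        sign = 1 if e.delta_psi > 0 else -1
        by_gene_sign.setdefault((e.gene_id, sign), []).append(e)

    assignment: dict[str, str] = {}
    counters: dict[str, int] = {}
    for (gene_id, _sign), members in sorted(by_gene_sign.items()):
        members = sorted(members, key=lambda e: (e.start, e.end))
        r1 = [e for e in members if e.length % 3 == 1]
        r2 = [e for e in members if e.length % 3 == 2]

        def new_group(group_events: list[SpliceEvent]) -> None:
            counters[gene_id] = counters.get(gene_id, 0) + 1
            gid = f"{gene_id}.rescue{counters[gene_id]}"
            for ev in group_events:
                assignment[ev.event_id] = gid

        n_pairs = min(len(r1), len(r2))
        for i in range(n_pairs):
            new_group([r1[i], r2[i]])
        for rest in (r1[n_pairs:], r2[n_pairs:]):
            for i in range(0, len(rest) - 2, 3):
                new_group(rest[i : i + 3])
    return assignment


def annotate_consequences(
    events: Sequence[SpliceEvent], ann: GenomeAnnotation
) -> list[EventConsequence]:
    """Region + frame call per event; frame is defined only for CDS cassette
    exons, and rescue groups are searched among significant frameshifters."""
    out: list[EventConsequence] = []
    frame_candidates: list[SpliceEvent] = []
    records: dict[str, EventConsequence] = {}
    for e in events:
        region = map_event_region(e, ann)
        cons = EventConsequence(e.event_id, region)
        if e.etype == "CE" and region == REGION_CDS:
            cons.frame = frame_consequence(e.length)
            if cons.frame == FRAME_SHIFT and e.significant:
                frame_candidates.append(e)
        out.append(cons)
        records[e.event_id] = cons
    for event_id, group_id in find_rescue_groups(frame_candidates).items():
        records[event_id].frame = FRAME_RESCUE
        records[event_id].rescue_group_id = group_id
    return out


def consequence_table(consequences: Sequence[EventConsequence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": c.event_id,
                "region": c.region,
                "frame": c.frame,
                "rescue_group_id": c.rescue_group_id or "",
            }
            for c in consequences
        ],
        columns=["event_id", "region", "frame", "rescue_group_id"],
    )


def summarize_frame_counts(
    n_preserved: int, n_shift: int, n_rescue: int
) -> dict[str, float]:
    """Percent breakdown of frame consequences (rounded to whole percent)."""
    total = n_preserved + n_shift + n_rescue
    if total == 0:
        raise ValueError("no frame-classified events to summarize")
    return {
        "n_preserved": n_preserved,
        "n_shift": n_shift,
        "n_rescue": n_rescue,
        "n_total": total,
        "pct_preserved": round(100 * n_preserved / total),
        "pct_shift": round(100 * n_shift / total),
        "pct_rescue": round(100 * n_rescue / total),
    }


def random_skipping_null(ann: GenomeAnnotation) -> float:
    """Expected frameshift rate under random skipping of one internal coding
    exon: the fraction of internal CDS exons (deduplicated by coordinates)
    whose length is not a multiple of 3."""
    seen: set[tuple[str, int, int]] = set()
    for gene in ann.genes.values():
        for tx in gene.transcripts:
            if tx.cds_start is None:
                continue
            exons = tx.exons_genomic
            for s, e in exons[1:-1]:
                if tx.cds_start <= s and e <= tx.cds_end:
                    seen.add((gene.chrom, s, e))
    if not seen:
        raise ValueError("annotation has no internal CDS exons")
    n_shift = sum(1 for _, s, e in seen if (e - s) % 3 != 0)
    return n_shift / len(seen)


def frameshift_enrichment_test(n_shift: int, n_total: int, p_null: float) -> float:
    """Two-sided exact binomial p-value (minimum-likelihood convention) for
    observing ``n_shift`` frameshifters among ``n_total`` skipped exons when
    the null frameshift probability is ``p_null``."""
    if not 0 <= n_shift <= n_total:
        raise ValueError("need 0 <= n_shift <= n_total")
    if not 0 < p_null < 1:
        raise ValueError("p_null must lie strictly between 0 and 1")
    return float(stats.binomtest(n_shift, n_total, p_null, alternative="two-sided").pvalue)


def frame_summary(
    events: Sequence[SpliceEvent],
    consequences: Sequence[EventConsequence],
    ann: GenomeAnnotation,
) -> dict:
    """Event- and gene-level frame statistics plus the random-skipping null
    and its exact binomial comparison."""
    by_id = {c.event_id: c for c in consequences}
    genes_by_frame: dict[str, set[str]] = {
        FRAME_PRESERVED: set(),
        FRAME_SHIFT: set(),
        FRAME_RESCUE: set(),
    }
    counts = {FRAME_PRESERVED: 0, FRAME_SHIFT: 0, FRAME_RESCUE: 0}
    # frame statistics are reported over the significant CDS cassette exons
    for e in events:
        cons = by_id.get(e.event_id)
        if cons is None or cons.frame == FRAME_NA or not e.significant:
            continue
        counts[cons.frame] += 1
        genes_by_frame[cons.frame].add(e.gene_id)

    summary: dict = {
        "event_level": summarize_frame_counts(
            counts[FRAME_PRESERVED], counts[FRAME_SHIFT], counts[FRAME_RESCUE]
        )
        if sum(counts.values())
        else None,
        "gene_level": {k: len(v) for k, v in genes_by_frame.items()},
    }
    try:
        p_null = random_skipping_null(ann)
        summary["random_skipping_null"] = p_null
        n_shift = counts[FRAME_SHIFT]
        n_total = sum(counts.values())
        if n_total and 0 < p_null < 1:
            summary["frameshift_vs_null_p"] = frameshift_enrichment_test(
                n_shift, n_total, p_null
            )
    except ValueError:
        summary["random_skipping_null"] = None
    return summary
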