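"""PSI/dPSI quantification of alternative-splicing events.

An event is one alternative segment (cassette exon, retained intron, or the
differential piece of an alternative 5'/3' splice site) with per-sample
inclusion/exclusion junction counts.  Group PSI is estimated from counts
pooled across the samples of a group; the confidence that the two groups
differ is a Monte-Carlo posterior probability under independent per-group
Beta posteriors with a Jeffreys prior.  Events pass the significance filter
when |dPSI| exceeds ``dpsi_cutoff`` and the posterior probability exceeds
``prob_cutoff``; significant events are then labelled
strong/moderate inclusion/exclusion around the ``strong_cutoff`` boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GenomeAnnotation, Interval, Transcript

EVENT_TYPES = ("CE", "IR", "alt5ss", "alt3ss")

CATEGORY_NONE = "none"


@dataclass
class SpliceEvent:
    """One alternative-splicing unit.

    ``start``/``end`` delimit the alternative segment (0-based half-open,
    genomic).  For CE events the segment is the cassette exon itself; for IR
    the retained intron; for alt5ss/alt3ss the differential extension.
    """

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    etype: str
    counts_g1: list[tuple[int, int]] = field(default_factory=list)
    counts_g2: list[tuple[int, int]] = field(default_factory=list)
    psi_g1: float | None = None
    psi_g2: float | None = None
    delta_psi: float | None = None
    probability: float | None = None
    significant: bool = False
    category: str = CATEGORY_NONE

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def segment(self) -> Interval:
        return (self.start, self.end)

    @property
    def quantifiable(self) -> bool:
        return self.psi_g1 is not None and self.psi_g2 is not None


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def estimate_psi(samples: Sequence[tuple[int, int]]) -> float | None:
    """Pooled-count PSI: sum(inc) / (sum(inc) + sum(exc)) across samples.

    Returns ``None`` (unquantifiable) when every count is zero.
    """
    inc = sum(i for i, _ in samples)
    exc = sum(e for _, e in samples)
    if inc + exc == 0:
        return None
    return inc / (inc + exc)


def delta_psi(psi_g1: float, psi_g2: float, decimals: int = 3) -> float:
    """Group-1 minus group-2 PSI, rounded for reporting (3 decimals)."""
    return round(psi_g1 - psi_g2, decimals)


def dpsi_probability(
    counts_g1: Sequence[tuple[int, int]],
    counts_g2: Sequence[tuple[int, int]],
    n_draws: int = 10_000,
    seed: int | None = None,
    threshold: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Posterior probability that the group PSI difference is real.

    Counts are pooled per group and given independent
    ``Beta(sum_inc + 1/2, sum_exc + 1/2)`` posteriors (Jeffreys prior).  The
    returned value is the fraction of Monte-Carlo draws in which
    ``psi1 - psi2`` has the same sign as the point estimate and exceeds
    ``threshold`` in magnitude (default 0).
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    inc1 = sum(i for i, _ in counts_g1)
    exc1 = sum(e for _, e in counts_g1)
    inc2 = sum(i for i, _ in counts_g2)
    exc2 = sum(e for _, e in counts_g2)
    if inc1 + exc1 == 0 or inc2 + exc2 == 0:
        raise ValueError("both groups must be quantifiable (non-zero counts)")
    if rng is None:
        rng = np.random.default_rng(seed)
    d1 = rng.beta(inc1 + 0.5, exc1 + 0.5, size=n_draws)
    d2 = rng.beta(inc2 + 0.5, exc2 + 0.5, size=n_draws)
    diff = d1 - d2
    point = inc1 / (inc1 + exc1) - inc2 / (inc2 + exc2)
    if point >= 0:
        return float(np.mean(diff > threshold))
    return float(np.mean(-diff > threshold))


def classify_event(
    dpsi: float,
    probability: float,
    dpsi_cutoff: float = 0.1,
    prob_cutoff: float = 0.9,
    strong_cutoff: float = 0.5,
) -> tuple[bool, str]:
    """Significance filter plus strength/direction category.

    Significant iff |dPSI| > ``dpsi_cutoff`` and probability >
    ``prob_cutoff``; categories are strong/moderate (|dPSI| >=
    ``strong_cutoff`` or not) x inclusion/exclusion (sign of dPSI).
    """
    significant = abs(dpsi) > dpsi_cutoff and probability > prob_cutoff
    if not significant:
        return False, CATEGORY_NONE
    strength = "strong" if abs(dpsi) >= strong_cutoff else "moderate"
    direction = "inclusion" if dpsi > 0 else "exclusion"
    return True, f"{strength} {direction}"


# ---------------------------------------------------------------------------
# Event discovery / typing against the annotation
# ---------------------------------------------------------------------------

def _pair_segments(a: Transcript, b: Transcript, strand: str) -> list[tuple[int, int, str]]:
    """Alternative segments between two isoforms of one gene."""
    out: list[tuple[int, int, str]] = []
    ex_a, ex_b = a.exons_genomic, b.exons_genomic
    introns_a, introns_b = a.introns_genomic(), b.introns_genomic()

    def covers(exons: list[Interval], seg: Interval) -> bool:
        return any(s <= seg[0] and seg[1] <= e for s, e in exons)

    def overlaps_any(exons: list[Interval], seg: Interval) -> bool:
        return any(s < seg[1] and seg[0] < e for s, e in exons)

    # cassette exons: internal exon of one isoform absent from the other,
    # with both flanking exons shared
    for first, second in ((ex_a, ex_b), (ex_b, ex_a)):
        for i in range(1, len(first) - 1):
            exon = first[i]
            if overlaps_any(second, exon):
                continue
            if first[i - 1] in second and first[i + 1] in second:
                out.append((exon[0], exon[1], "CE"))

    # intron retention: intron of one isoform fully inside an exon of the other
    retained: set[Interval] = set()
    for introns, other in ((introns_a, ex_b), (introns_b, ex_a)):
        for intron in introns:
            if covers(other, intron):
                out.append((intron[0], intron[1], "IR"))
                retained.add(intron)

    # alternative donor/acceptor: overlapping exons sharing one boundary
    all_introns = introns_a + introns_b
    for exon_a, exon_b in itertools.product(ex_a, ex_b):
        if exon_a == exon_b or not (exon_a[0] < exon_b[1] and exon_b[0] < exon_a[1]):
            continue
        seg = None
        side = None
        if exon_a[0] == exon_b[0] and exon_a[1] != exon_b[1]:
            seg = (min(exon_a[1], exon_b[1]), max(exon_a[1], exon_b[1]))
            side = "right"
        elif exon_a[1] == exon_b[1] and exon_a[0] != exon_b[0]:
            seg = (min(exon_a[0], exon_b[0]), max(exon_a[0], exon_b[0]))
            side = "left"
        if seg is None:
            continue
        # a boundary shift that swallows a whole intron is an IR/complex
        # case, not a simple alternative splice site
        if any(seg[0] <= i0 and i1 <= seg[1] for i0, i1 in all_introns):
            continue
        # genomic right edge is the donor (5'ss) on '+', acceptor (3'ss) on '-'
        if side == "right":
            etype = "alt5ss" if strand == "+" else "alt3ss"
        else:
            etype = "alt3ss" if strand == "+" else "alt5ss"
        out.append((seg[0], seg[1], etype))
    return out


def infer_events(ann: GenomeAnnotation) -> list[SpliceEvent]:
    """Enumerate alternative segments between all isoform pairs per gene.

    Event ids are deterministic: ``<gene>.e<i>`` in genomic order.
    """
    events: list[SpliceEvent] = []
    for gene_id in sorted(ann.genes):
        gene = ann.genes[gene_id]
        segs: set[tuple[int, int, str]] = set()
        for a, b in itertools.combinations(gene.transcripts, 2):
            segs.update(_pair_segments(a, b, gene.strand))
        for i, (start, end, etype) in enumerate(sorted(segs), start=1):
            events.append(
                SpliceEvent(
                    event_id=f"{gene_id}.e{i}",
                    gene_id=gene_id,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    start=start,
                    end=end,
                    etype=etype,
                )
            )
    return events


def classify_event_type(event: SpliceEvent, ann: GenomeAnnotation) -> str:
    """Re-derive the event type of a segment from the isoform topology.

    Returns ``"NA"`` when the segment matches no pairwise isoform
    difference of its gene.
    """
    gene = ann.genes.get(event.gene_id)
    if gene is None:
        return "NA"
    for a, b in itertools.combinations(gene.transcripts, 2):
        for start, end, etype in _pair_segments(a, b, gene.strand):
            if (start, end) == (event.start, event.end):
                return etype
    return "NA"


# ---------------------------------------------------------------------------
# Batch quantification and the events table
# ---------------------------------------------------------------------------

EVENTS_TABLE_COLUMNS = [
    "event_id",
    "gene",
    "type",
    "psi_g1",
    "psi_g2",
    "delta_psi",
    "probability",
    "significant",
    "category",
]


def quantify_events(
    events: Sequence[SpliceEvent],
    counts: Mapping[str, Sequence[tuple[int, int]]],
    samples: Sequence[str],
    groups: Mapping[str, str],
    seed: int = 0,
    n_draws: int = 10_000,
    dpsi_cutoff: float = 0.1,
    prob_cutoff: float = 0.9,
    strong_cutoff: float = 0.5,
    prob_threshold: float = 0.0,
) -> list[SpliceEvent]:
    """Fill PSI/dPSI/probability/category on every event with counts.

    Per-event RNG streams are derived from ``seed`` and the event index so
    results are independent of how many events precede a given one.
    """
    group_names: list[str] = []
    for s in samples:
        g = groups[s]
        if g not in group_names:
            group_names.append(g)
    if len(group_names) != 2:
        raise ValueError(f"expected exactly two groups, got {group_names}")
    g1_idx = [i for i, s in enumerate(samples) if groups[s] == group_names[0]]
    g2_idx = [i for i, s in enumerate(samples) if groups[s] == group_names[1]]

    out: list[SpliceEvent] = []
    for idx, event in enumerate(sorted(events, key=lambda e: e.event_id)):
        if event.event_id not in counts:
            out.append(event)
            continue
        pairs = counts[event.event_id]
        event.counts_g1 = [pairs[i] for i in g1_idx]
        event.counts_g2 = [pairs[i] for i in g2_idx]
        p1 = estimate_psi(event.counts_g1)
        p2 = estimate_psi(event.counts_g2)
        event.psi_g1 = None if p1 is None else round(p1, 3)
        event.psi_g2 = None if p2 is None else round(p2, 3)
        if p1 is None or p2 is None:
            out.append(event)
            continue
        event.delta_psi = delta_psi(p1, p2)
        rng = np.random.default_rng([seed, idx])
        event.probability = dpsi_probability(
            event.counts_g1,
            event.counts_g2,
            n_draws=n_draws,
            threshold=prob_threshold,
            rng=rng,
        )
        event.significant, event.category = classify_event(
            event.delta_psi,
            event.probability,
            dpsi_cutoff=dpsi_cutoff,
            prob_cutoff=prob_cutoff,
            strong_cutoff=strong_cutoff,
        )
        out.append(event)
    return out


def events_table(events: Sequence[SpliceEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "event_id": e.event_id,
                "gene": e.gene_id,
                "type": e.etype,
                "psi_g1": e.psi_g1,
                "psi_g2": e.psi_g2,
                "delta_psi": e.delta_psi,
                "probability": e.probability,
                "significant": e.significant,
                "category": e.category,
            }
        )
    return pd.DataFrame(rows, columns=EVENTS_TABLE_COLUMNS)
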