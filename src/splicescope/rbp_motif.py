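"""RBP motif scanning around alternative exons and SNP-induced motif changes.

Motifs are small sets of degenerate IUPAC k-mers (5-8 nt) with region
semantics: each motif is scanned in the exon and/or the flanking intronic
windows (default 250 nt), always on the sense strand.  Event-level
presence/absence between an inclusion-up foreground and a background event
set is compared with Fisher's exact test, BH-adjusted across all
(motif, region) pairs.  A SNP disrupts a motif when some match covers the
SNP with the reference allele but none does with the alternative allele
(and creates one in the reverse case).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GenomeAnnotation, SnpRecord, complement_base
from .snp_context import SnpWindows, classify_snp_position, DEFAULT_WINDOWS
from .splice_quant import SpliceEvent

REGION_UP = "upstream_intron"
REGION_EXON = "exon"
REGION_DOWN = "downstream_intron"
REGIONS = (REGION_UP, REGION_EXON, REGION_DOWN)

# log2 enrichment sentinel used when one fraction is exactly zero
LOG2_CAP = 20.0

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}


@dataclass(frozen=True)
class MotifModel:
    """Named RBP motif: degenerate IUPAC patterns + regions it is scanned in."""

    name: str
    patterns: tuple[str, ...]
    regions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"motif {self.name}: empty pattern set")
        for pat in self.patterns:
            bad = set(pat.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"motif {self.name}: non-IUPAC symbols {sorted(bad)}")
        for region in self.regions:
            if region not in REGIONS:
                raise ValueError(f"motif {self.name}: unknown region {region!r}")

    @property
    def max_k(self) -> int:
        return max(len(p) for p in self.patterns)


@dataclass(frozen=True)
class MotifHit:
    motif: str
    offset: int
    matched: str
    pattern: str


DEMO_MOTIFS: tuple[MotifModel, ...] = (
    # SR-protein-like purine-rich exonic/downstream enhancer
    MotifModel("SRSF1", ("GGAGGA", "GGACGGA"), (REGION_EXON, REGION_DOWN)),
    # poly-pyrimidine / C-rich hnRNP-like silencer
    MotifModel("PCBP1", ("CCTCCC", "CCCTCC"), (REGION_UP, REGION_EXON)),
    # (U)GCAUG-class downstream-intron motif
    MotifModel("RBFOX", ("TGCATG",), (REGION_DOWN,)),
    # degenerate demonstration motif
    MotifModel("SRSF7", ("GAYGAC",), (REGION_UP, REGION_DOWN)),
)


def _matches_at(seq: str, pattern: str, offset: int) -> bool:
    return all(seq[offset + i] in IUPAC[sym] for i, sym in enumerate(pattern))


def scan_motif(sequence: str, motif: MotifModel) -> list[MotifHit]:
    """All offsets (overlaps included) where any pattern matches under IUPAC
    expansion.  The sequence must be sense-strand A/C/G/T/N."""
    seq = sequence.upper()
    for i, base in enumerate(seq):
        if base not in "ACGTN":
            raise ValueError(f"non-ACGTN base {base!r} at position {i}")
    hits: dict[int, MotifHit] = {}
    for pattern in motif.patterns:
        pat = pattern.upper()
        k = len(pat)
        for offset in range(len(seq) - k + 1):
            if offset in hits:
                continue
            if _matches_at(seq, pat, offset):
                hits[offset] = MotifHit(motif.name, offset, seq[offset : offset + k], pat)
    return [hits[o] for o in sorted(hits)]


# ---------------------------------------------------------------------------
# Regions around an event
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSeq:
    """A scanned region in genomic coordinates plus its sense-strand
    sequence; offsets in the sequence run 5'->3' in transcript orientation."""

    region: str
    chrom: str
    start: int
    end: int
    strand: str
    seq: str

    def genomic_to_offset(self, pos0: int) -> int | None:
        if not (self.start <= pos0 < self.end):
            return None
        return pos0 - self.start if self.strand == "+" else self.end - 1 - pos0


def event_regions(
    event: SpliceEvent, ann: GenomeAnnotation, flank_nt: int = 250
) -> dict[str, RegionSeq]:
    """Sense-strand sequences of the exon and both intronic flanks."""
    chrom, strand = event.chrom, event.strand
    contig_len = ann.contig_length(chrom)
    left = (max(0, event.start - flank_nt), event.start)
    right = (event.end, min(contig_len, event.end + flank_nt))
    if strand == "+":
        coords = {REGION_UP: left, REGION_EXON: event.segment, REGION_DOWN: right}
    else:
        coords = {REGION_UP: right, REGION_EXON: event.segment, REGION_DOWN: left}
    out: dict[str, RegionSeq] = {}
    for region, (s, e) in coords.items():
        out[region] = RegionSeq(region, chrom, s, e, strand, ann.sequence(chrom, s, e, strand))
    return out


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def presence_fraction(motif: MotifModel, sequences: Sequence[str]) -> tuple[int, int]:
    """(number of sequences with >= 1 hit, number scanned)."""
    n_hit = sum(1 for seq in sequences if scan_motif(seq, motif))
    return n_hit, len(sequences)


def regional_enrichment(
    motif: MotifModel,
    fg_seqs: Sequence[str],
    bg_seqs: Sequence[str],
) -> tuple[float, float, int, int]:
    """Fisher exact test of event-level motif presence, foreground vs
    background.  Returns ``(log2_enrichment, p, fg_hits, bg_hits)``; a zero
    fraction on one side caps the log2 enrichment at +/-20."""
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background must be non-empty")
    fg_hit, fg_n = presence_fraction(motif, fg_seqs)
    bg_hit, bg_n = presence_fraction(motif, bg_seqs)
    table = [[fg_hit, fg_n - fg_hit], [bg_hit, bg_n - bg_hit]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    fg_frac = fg_hit / fg_n
    bg_frac = bg_hit / bg_n
    if fg_frac == 0 and bg_frac == 0:
        log2e = 0.0
    elif bg_frac == 0:
        log2e = LOG2_CAP
    elif fg_frac == 0:
        log2e = -LOG2_CAP
    else:
        import math

        log2e = math.log2(fg_frac / bg_frac)
    return log2e, float(p), fg_hit, bg_hit


def enrichment_table(
    motifs: Sequence[MotifModel],
    fg_events: Sequence[SpliceEvent],
    bg_events: Sequence[SpliceEvent],
    ann: GenomeAnnotation,
    flank_nt: int = 250,
    direction: str = "inclusion_up",
) -> pd.DataFrame:
    """Per-(motif, region) Fisher enrichment with BH adjustment."""
    fg_regions = [event_regions(e, ann, flank_nt) for e in fg_events]
    bg_regions = [event_regions(e, ann, flank_nt) for e in bg_events]
    rows = []
    for motif in motifs:
        for region in motif.regions:
            fg_seqs = [r[region].seq for r in fg_regions if r[region].seq]
            bg_seqs = [r[region].seq for r in bg_regions if r[region].seq]
            if not fg_seqs or not bg_seqs:
                continue
            log2e, p, fg_hit, bg_hit = regional_enrichment(motif, fg_seqs, bg_seqs)
            rows.append(
                {
                    "motif": motif.name,
                    "region": region,
                    "direction": direction,
                    "fg_hits": fg_hit,
                    "fg_n": len(fg_seqs),
                    "bg_hits": bg_hit,
                    "bg_n": len(bg_seqs),
                    "log2_enrichment": log2e,
                    "p": p,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "motif", "region", "direction", "fg_hits", "fg_n",
            "bg_hits", "bg_n", "log2_enrichment", "p",
        ],
    )
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_adj"] = pd.Series(dtype=float)
    return df


def hit_profile(
    motif: MotifModel, sequences: Sequence[str], bin_nt: int = 25
) -> pd.DataFrame:
    """Positional hit density per offset bin (for plotting/export)."""
    counts: dict[int, int] = {}
    for seq in sequences:
        for hit in scan_motif(seq, motif):
            counts[hit.offset // bin_nt] = counts.get(hit.offset // bin_nt, 0) + 1
    rows = [
        {"bin_start": b * bin_nt, "bin_end": (b + 1) * bin_nt, "n_hits": n}
        for b, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["bin_start", "bin_end", "n_hits"])


# ---------------------------------------------------------------------------
# SNP effects on motifs
# ---------------------------------------------------------------------------

EFFECT_DISRUPT = "disrupt"
EFFECT_CREATE = "create"
EFFECT_NONE = "none"


def snp_motif_effect(
    motif: MotifModel,
    sequence: str,
    snp_offset: int,
    ref: str,
    alt: str,
) -> str:
    """Effect of substituting ``ref -> alt`` at ``snp_offset`` of a
    sense-strand sequence on matches of ``motif`` covering that position.

    ``disrupt``: a covering match exists with ref but none with alt;
    ``create``: the reverse; ``none`` otherwise.  The sequence should extend
    at least k-1 bases beyond the SNP on both sides where possible.
    """
    seq = sequence.upper()
    ref, alt = ref.upper(), alt.upper()
    if not (0 <= snp_offset < len(seq)):
        raise ValueError("SNP offset outside the sequence window")
    if seq[snp_offset] != ref:
        raise ValueError(
            f"reference allele {ref!r} does not match sequence base "
            f"{seq[snp_offset]!r} at offset {snp_offset}"
        )
    alt_seq = seq[:snp_offset] + alt + seq[snp_offset + 1 :]

    def covering_match(s: str) -> bool:
        for pattern in motif.patterns:
            k = len(pattern)
            lo = max(0, snp_offset - k + 1)
            hi = min(len(s) - k, snp_offset)
            for offset in range(lo, hi + 1):
                if _matches_at(s, pattern.upper(), offset):
                    return True
        return False

    ref_cov = covering_match(seq)
    alt_cov = covering_match(alt_seq)
    if ref_cov and not alt_cov:
        return EFFECT_DISRUPT
    if alt_cov and not ref_cov:
        return EFFECT_CREATE
    return EFFECT_NONE


def event_snp_motif_effects(
    events: Sequence[SpliceEvent],
    snps: Iterable[SnpRecord],
    motifs: Sequence[MotifModel],
    ann: GenomeAnnotation,
    flank_nt: int = 250,
    windows: SnpWindows = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Per-(event, SNP, motif) effect report.

    SNPs are mapped into each event's scanned regions; alleles are
    complemented for minus-strand genes so the comparison runs on the sense
    strand.  Motifs are only tested in the regions they are scanned in.
    """
    snps = list(snps)
    rows = []
    for event in events:
        regions = event_regions(event, ann, flank_nt)
        for snp in snps:
            if snp.chrom != event.chrom:
                continue
            for region_name, rseq in regions.items():
                offset = rseq.genomic_to_offset(snp.pos0)
                if offset is None:
                    continue
                if event.strand == "+":
                    ref, alt = snp.ref, snp.alt
                else:
                    ref, alt = complement_base(snp.ref), complement_base(snp.alt)
                category = classify_snp_position(
                    snp, event.segment, event.strand, chrom=event.chrom, windows=windows
                )
                for motif in motifs:
                    if region_name not in motif.regions:
                        continue
                    effect = snp_motif_effect(motif, rseq.seq, offset, ref, alt)
                    if effect != EFFECT_NONE:
                        rows.append(
                            {
                                "event_id": event.event_id,
                                "gene": event.gene_id,
                                "snp": f"{snp.chrom}:{snp.pos}:{snp.ref}>{snp.alt}",
                                "motif": motif.name,
                                "region": region_name,
                                "snp_category": category,
                                "effect": effect,
                            }
                        )
    return pd.DataFrame(
        rows,
        columns=["event_id", "gene", "snp", "motif", "region", "snp_category", "effect"],
    )


def count_affected_events(effects: pd.DataFrame) -> int:
    """Number of distinct events with >= 1 disrupt/create call."""
    if effects.empty:
        return 0
    hit = effects[effects["effect"].isin([EFFECT_DISRUPT, EFFECT_CREATE])]
    return int(hit["event_id"].nunique())


# ---------------------------------------------------------------------------
# Motif file I/O:  TSV (name, regions, patterns), comma-separated lists
# ---------------------------------------------------------------------------

def read_motifs(path) -> list[MotifModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        out.append(
            MotifModel(
                name=row["name"],
                patterns=tuple(p.strip().upper() for p in row["patterns"].split(",")),
                regions=tuple(r.strip() for r in row["regions"].split(",")),
            )
        )
    return out


def write_motifs(motifs: Sequence[MotifModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tregions\tpatterns\n")
        for m in motifs:
            fh.write(f"{m.name}\t{','.join(m.regions)}\t{','.join(m.patterns)}\n")
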