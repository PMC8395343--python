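"""Self-contained synthetic two-group splicing study with known ground truth.

The generator emulates the design of a two-strain islet RNA-seq comparison:
two groups of five samples, alternative-splicing events of four types
(cassette exon, intron retention, alternative 5'/3' splice site) with
planted per-group PSI values, junction counts sampled binomially at a
Poisson per-sample depth, SNPs planted in defined positional windows,
RBP-motif occurrences with and without allele disruption, CpG sites
destroyed by planted substitutions, and log-normal expression matrices with
configured group effects.  Everything is written in the exact formats
``core_io`` reads, alongside truth tables recording every planted value.

The toy genome is i.i.d. uniform over {A,C,G,T} except where motifs and
CpG sites are planted, which gives a neutral background for motif
statistics.  One gene lives on one contig.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import rbp_motif
from .core_io import (
    Gene,
    GenomeAnnotation,
    SnpRecord,
    Transcript,
    complement_base,
    reverse_complement,
    write_annotation,
    write_fasta,
    write_junction_counts,
    write_samples,
    write_vcf,
)
from .rbp_motif import DEMO_MOTIFS, IUPAC, MotifModel
from .snp_context import (
    CAT_EXONIC,
    CAT_INTRONIC_DOWN,
    CAT_INTRONIC_UP,
    CAT_OUTSIDE,
    CAT_SS3,
    CAT_SS5,
    DEFAULT_WINDOWS,
)
from .splice_quant import infer_events

BASES = np.frombuffer(b"ACGT", dtype="S1")

PAD = 1200  # contig padding on both sides of a gene


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic bundle.

    Defaults mirror the emulated study: two groups of five animals, mean
    junction coverage 200 per sample, an event-type mix dominated by
    cassette exons, and microexons of 3-30 nt.
    """

    seed: int = 0
    n_genes: int = 40
    n_samples_per_group: int = 5
    depth: float = 200.0
    event_mix: dict[str, float] = field(
        default_factory=lambda: {"CE": 0.56, "IR": 0.23, "alt3ss": 0.11, "alt5ss": 0.10}
    )
    frac_differential: float = 0.5
    n_microexon: int = 6
    n_targets: int = 4
    n_rescue_genes: int = 2
    n_noncoding: int = 2
    n_utr_genes: int = 1
    psi_table: dict[str, tuple[float, float]] | None = None
    snp_placement: list[tuple[str, str]] | None = None
    motif_plants: list[tuple[str, str, str, str]] | None = None
    expression_effects: dict[str, float] | None = None
    mirna_effects: dict[str, float] | None = None
    n_mirnas: int = 8
    mirna_len: int = 22
    utr_len: int = 600
    expression_sigma: float = 0.25
    factor_gene: str = "Srrm4"
    flank_nt: int = 250
    group_names: tuple[str, str] = ("group1", "group2")

    def validate(self) -> None:
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if self.n_samples_per_group < 2:
            raise ConfigError("need at least two samples per group")
        if self.psi_table:
            for event_id, (p1, p2) in self.psi_table.items():
                if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
                    raise ConfigError(f"psi for {event_id} outside [0, 1]")
        if self.n_genes < self.n_rescue_genes + self.n_noncoding + self.n_utr_genes + 4:
            raise ConfigError("n_genes too small for the configured special genes")


# ---------------------------------------------------------------------------
# Gene plans and structures
# ---------------------------------------------------------------------------

@dataclass
class _GenePlan:
    gene_id: str
    symbol: str
    strand: str
    etype: str                      # CE / IR / alt5ss / alt3ss / CE2
    alt_len: int
    psi: tuple[float, float]        # psi for every event of the gene
    differential: bool
    microexon: bool = False
    is_target: bool = False
    coding: str = "cds"             # cds / utr3 / noncoding


@dataclass
class _GeneStructure:
    plan: _GenePlan
    gene: Gene
    segments: list[tuple[int, int]]  # alternative segments, genomic order
    contig_len: int


def _largest_remainder(mix: dict[str, float], n: int) -> dict[str, int]:
    raw = {k: v * n for k, v in mix.items()}
    counts = {k: int(v) for k, v in raw.items()}
    rest = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:rest]:
        counts[k] += 1
    return counts


def _plan_genes(config: SimulationConfig, rng: np.random.Generator) -> list[_GenePlan]:
    counts = _largest_remainder(config.event_mix, config.n_genes - config.n_rescue_genes)
    etypes: list[str] = []
    for etype in ("CE", "IR", "alt3ss", "alt5ss"):
        etypes.extend([etype] * counts.get(etype, 0))
    etypes.extend(["CE2"] * config.n_rescue_genes)

    plans: list[_GenePlan] = []
    micro_assigned = 0
    special_pool: list[str] = []  # CE gene ids eligible for noncoding/utr3
    for i, etype in enumerate(etypes):
        gene_id = f"g{i + 1:03d}"
        plan = _GenePlan(
            gene_id=gene_id,
            symbol=f"Gene{i + 1:03d}",
            strand="+" if rng.random() < 0.5 else "-",
            etype=etype,
            alt_len=0,
            psi=(0.0, 0.0),
            differential=False,
        )
        if etype == "CE" and micro_assigned < config.n_microexon:
            plan.microexon = True
            plan.is_target = micro_assigned < config.n_targets
            # keep >= 4 so both frame residues occur among microexons
            plan.alt_len = int(rng.integers(4, 31))
            micro_assigned += 1
        elif etype in ("CE", "CE2"):
            # alternate frame-preserving / frameshifting cassette exons
            base = int(rng.integers(20, 60))
            plan.alt_len = base * 3 if i % 2 == 0 else base * 3 + int(rng.integers(1, 3))
        else:
            plan.alt_len = int(rng.integers(45, 91))
        plans.append(plan)
        if etype == "CE" and not plan.microexon:
            special_pool.append(gene_id)

    # differential assignment: targets are always differential (skipped in
    # group 1); rescue genes are always differential; the rest alternate
    n_diff_needed = round(config.frac_differential * len(plans))
    for plan in plans:
        if plan.is_target or plan.etype == "CE2":
            plan.differential = True
    remaining = [p for p in plans if not p.differential]
    still = n_diff_needed - sum(p.differential for p in plans)
    # spread differential events across types (and leave null CE genes for
    # the background/UTR/noncoding roles) by taking every other candidate
    for plan in (remaining[::2] + remaining[1::2])[: max(0, still)]:
        plan.differential = True

    for plan in plans:
        if plan.is_target or plan.etype == "CE2":
            plan.psi = (0.15, 0.9)
        elif plan.differential:
            base = float(rng.uniform(0.15, 0.5))
            delta = float(rng.uniform(0.3, 0.45))
            if rng.random() < 0.5:
                plan.psi = (base + delta, base)
            else:
                plan.psi = (base, base + delta)
        else:
            p = float(rng.uniform(0.2, 0.8))
            plan.psi = (p, p)

    # region variety: a few null CE genes become noncoding / 3'UTR cases
    null_ce = [p for p in plans if p.gene_id in special_pool and not p.differential]
    for plan in null_ce[: config.n_noncoding]:
        plan.coding = "noncoding"
    for plan in null_ce[config.n_noncoding : config.n_noncoding + config.n_utr_genes]:
        plan.coding = "utr3"

    # apply explicit PSI overrides (keyed by gene id)
    if config.psi_table:
        by_id = {p.gene_id: p for p in plans}
        for gene_id, psi in config.psi_table.items():
            if gene_id not in by_id:
                raise ConfigError(f"psi_table references unknown gene {gene_id}")
            by_id[gene_id].psi = psi
            by_id[gene_id].differential = abs(psi[0] - psi[1]) > 0.1
    return plans


def _build_structure(plan: _GenePlan, rng: np.random.Generator) -> _GeneStructure:
    n_exons = 6 if plan.etype == "CE2" else 5
    lengths = [int(rng.integers(90, 211)) for _ in range(n_exons)]
    if plan.etype == "CE":
        lengths[2] = plan.alt_len
    elif plan.etype == "CE2":
        # two frameshifting exons with complementary residues (sum % 3 == 0)
        r = int(rng.integers(20, 40))
        lengths[2] = 3 * r + 1
        lengths[3] = 3 * r + 2
    introns = [int(rng.integers(1100, 1501)) for _ in range(n_exons - 1)]

    exons: list[tuple[int, int]] = []
    pos = PAD
    for i, length in enumerate(lengths):
        exons.append((pos, pos + length))
        pos += length
        if i < n_exons - 1:
            pos += introns[i]
    gene_end = exons[-1][1]
    contig_len = gene_end + PAD

    chrom = plan.gene_id
    strand = plan.strand
    segments: list[tuple[int, int]] = []

    def tx(tx_id: str, ex: list[tuple[int, int]], cds: tuple[int, int] | None) -> Transcript:
        ordered = sorted(ex)
        if strand == "-":
            ordered = ordered[::-1]
        cs, ce = cds if cds else (None, None)
        return Transcript(tx_id, plan.gene_id, ordered, cs, ce)

    # CDS placement by coding mode (transcript orientation aware)
    if plan.coding == "cds":
        cds = (exons[0][0] + 30, exons[-1][1] - 30)
    elif plan.coding == "utr3":
        if strand == "+":
            cds = (exons[0][0] + 30, exons[1][1] - 30)
        else:
            cds = (exons[-2][0] + 30, exons[-1][1] - 30)
    else:
        cds = None

    transcripts: list[Transcript] = []
    if plan.etype in ("CE",):
        segments.append(exons[2])
        transcripts.append(tx(f"{plan.gene_id}.t1", exons, cds))
        transcripts.append(tx(f"{plan.gene_id}.t2", exons[:2] + exons[3:], cds))
    elif plan.etype == "CE2":
        segments.extend([exons[2], exons[3]])
        transcripts.append(tx(f"{plan.gene_id}.t1", exons, cds))
        transcripts.append(tx(f"{plan.gene_id}.t2", exons[:2] + exons[3:], cds))
        transcripts.append(tx(f"{plan.gene_id}.t3", exons[:3] + exons[4:], cds))
    elif plan.etype == "IR":
        intron = (exons[2][1], exons[3][0])
        segments.append(intron)
        merged = exons[:2] + [(exons[2][0], exons[3][1])] + exons[4:]
        transcripts.append(tx(f"{plan.gene_id}.t1", exons, cds))
        transcripts.append(tx(f"{plan.gene_id}.t2", merged, cds))
    else:  # alternative splice sites
        d = plan.alt_len
        s, e = exons[2]
        donor_right = strand == "+"
        extend_right = (plan.etype == "alt5ss") == donor_right
        if extend_right:
            long_exon = (s, e + d)
            segments.append((e, e + d))
        else:
            long_exon = (s - d, e)
            segments.append((s - d, s))
        long_exons = exons[:2] + [long_exon] + exons[3:]
        transcripts.append(tx(f"{plan.gene_id}.t1", exons, cds))
        transcripts.append(tx(f"{plan.gene_id}.t2", long_exons, cds))

    gene = Gene(plan.gene_id, plan.symbol, chrom, strand, transcripts)
    return _GeneStructure(plan, gene, sorted(segments), contig_len)


# ---------------------------------------------------------------------------
# Sequence planting
# ---------------------------------------------------------------------------

class _Contig:
    """Mutable contig sequence with an occupancy map for planted features."""

    def __init__(self, length: int, rng: np.random.Generator):
        self.arr = rng.choice(BASES, size=length)
        self.occupied: set[int] = set()

    def free(self, start: int, end: int) -> bool:
        return not any(p in self.occupied for p in range(start, end))

    def reserve(self, start: int, end: int) -> None:
        self.occupied.update(range(start, end))

    def write(self, start: int, seq: str) -> None:
        for i, base in enumerate(seq):
            self.arr[start + i] = base.encode()

    def base(self, pos: int) -> str:
        return self.arr[pos].decode()

    def seq(self, start: int, end: int, strand: str = "+") -> str:
        s = b"".join(self.arr[max(0, start) : end]).decode()
        return reverse_complement(s) if strand == "-" else s

    def __str__(self) -> str:
        return b"".join(self.arr).decode()


def _region_coords(
    segment: tuple[int, int], strand: str, contig_len: int, flank: int
) -> dict[str, tuple[int, int]]:
    left = (max(0, segment[0] - flank), segment[0])
    right = (segment[1], min(contig_len, segment[1] + flank))
    if strand == "+":
        return {rbp_motif.REGION_UP: left, rbp_motif.REGION_EXON: segment, rbp_motif.REGION_DOWN: right}
    return {rbp_motif.REGION_UP: right, rbp_motif.REGION_EXON: segment, rbp_motif.REGION_DOWN: left}


def _category_position(
    segment: tuple[int, int], strand: str, category: str, rng: np.random.Generator
) -> int:
    """A genomic 0-based position whose positional class is ``category``."""
    s, e = segment
    w = DEFAULT_WINDOWS
    if category == CAT_EXONIC:
        if e - s <= 2 * (w.ss_exonic + 1):
            raise ValueError("segment too short for an exonic-interior SNP")
        return int(rng.integers(s + w.ss_exonic + 1, e - w.ss_exonic))
    if category == CAT_OUTSIDE:
        d = int(rng.integers(w.intron_max + 50, w.intron_max + 400))
        return s - d if strand == "+" else e - 1 + d
    if category in (CAT_SS3, CAT_SS5):
        d = int(rng.integers(1, w.ss_intronic + 1))
    elif category in (CAT_INTRONIC_UP, CAT_INTRONIC_DOWN):
        d = int(rng.integers(w.intron_min + 1, w.intron_max + 1))
    else:
        raise ValueError(f"unknown category {category}")
    upstream_is_left = strand == "+"
    acceptor_cats = (CAT_SS3, CAT_INTRONIC_UP)
    on_left = (category in acceptor_cats) == upstream_is_left
    return s - d if on_left else e - 1 + d


def _context_is_cpg(contig: _Contig, pos: int) -> bool:
    prev = contig.base(pos - 1) if pos > 0 else "N"
    nxt = contig.base(pos + 1) if pos + 1 < len(contig.arr) else "N"
    mid = contig.base(pos)
    return (mid == "C" and nxt == "G") or (mid == "G" and prev == "C")


def _motif_effect_here(
    contig: _Contig,
    structure: _GeneStructure,
    pos: int,
    ref: str,
    alt: str,
    motifs: Sequence[MotifModel],
    flank: int,
) -> str:
    """Effect of a candidate SNP on any scanned motif of any event of its
    gene (genes can carry two cassette exons)."""
    strand = structure.gene.strand
    region_list = [
        (region, coords)
        for segment in structure.segments
        for region, coords in _region_coords(
            segment, strand, structure.contig_len, flank
        ).items()
    ]
    for region, (rs, re) in region_list:
        if not (rs <= pos < re):
            continue
        seq = contig.seq(rs, re, strand)
        offset = pos - rs if strand == "+" else re - 1 - pos
        sref = ref if strand == "+" else complement_base(ref)
        salt = alt if strand == "+" else complement_base(alt)
        for motif in motifs:
            if region not in motif.regions:
                continue
            effect = rbp_motif.snp_motif_effect(motif, seq, offset, sref, salt)
            if effect != rbp_motif.EFFECT_NONE:
                return effect
    return rbp_motif.EFFECT_NONE


def _plant_motif(
    contig: _Contig,
    structure: _GeneStructure,
    segment: tuple[int, int],
    region: str,
    motif: MotifModel,
    effect: str,
    rng: np.random.Generator,
    flank: int,
    other_motifs: Sequence[MotifModel] = (),
) -> SnpRecord | None:
    """Write one motif instance into a region; for disrupt/create also plant
    the SNP and verify the classifier recovers the requested effect."""
    strand = structure.gene.strand
    coords = _region_coords(segment, strand, structure.contig_len, flank)
    rs, re = coords[region]
    pattern = motif.patterns[int(rng.integers(len(motif.patterns)))]
    k = len(pattern)
    if re - rs < k + 20:
        raise ValueError(f"region {region} too short for motif {motif.name}")

    s0, s1 = segment
    for _attempt in range(60):
        off = int(rng.integers(10, re - rs - k - 10))
        g_start = rs + off if strand == "+" else re - off - k
        if not contig.free(g_start - 1, g_start + k + 1):
            continue
        # keep motif SNPs out of the 15-nt splice-site windows so their
        # positional category stays intronic (or exon-interior)
        w = DEFAULT_WINDOWS
        if region == rbp_motif.REGION_EXON:
            if not (s0 + w.ss_exonic + 1 <= g_start and g_start + k <= s1 - w.ss_exonic):
                continue
        elif not (g_start + k <= s0 - w.ss_intronic - 1 or g_start >= s1 + w.ss_intronic):
            continue
        instance = "".join(
            sorted(IUPAC[sym] - {"N"})[int(rng.integers(len(IUPAC[sym] - {"N"})))]
            for sym in pattern
        )
        snp: SnpRecord | None = None
        if effect in (rbp_motif.EFFECT_DISRUPT, rbp_motif.EFFECT_CREATE):
            slot = int(rng.integers(k))
            allowed = IUPAC[pattern[slot]] - {"N"}
            blocked = sorted(set("ACGT") - allowed)
            if not blocked:
                slot = min(range(k), key=lambda j: len(IUPAC[pattern[j]]))
                allowed = IUPAC[pattern[slot]] - {"N"}
                blocked = sorted(set("ACGT") - allowed)
            matching = instance[slot]
            breaking = blocked[int(rng.integers(len(blocked)))]
            if effect == rbp_motif.EFFECT_DISRUPT:
                sense_ref, sense_alt = matching, breaking
            else:
                sense_ref, sense_alt = breaking, matching
                instance = instance[:slot] + sense_ref + instance[slot + 1 :]
            sense_pos = off + slot
            g_pos = rs + sense_pos if strand == "+" else re - 1 - sense_pos
            ref = sense_ref if strand == "+" else complement_base(sense_ref)
            alt = sense_alt if strand == "+" else complement_base(sense_alt)
            snp = SnpRecord(structure.gene.chrom, g_pos + 1, ref, alt)

        sense_instance = instance if strand == "+" else reverse_complement(instance)
        saved = contig.seq(g_start, g_start + k)
        contig.write(g_start, sense_instance)

        ok = True
        region_seq = contig.seq(rs, re, strand)
        if effect == rbp_motif.EFFECT_NONE:
            ok = bool(rbp_motif.scan_motif(region_seq, motif))
        else:
            offset = snp.pos0 - rs if strand == "+" else re - 1 - snp.pos0
            sref = snp.ref if strand == "+" else complement_base(snp.ref)
            salt = snp.alt if strand == "+" else complement_base(snp.alt)
            got = rbp_motif.snp_motif_effect(motif, region_seq, offset, sref, salt)
            ok = got == effect and not _context_is_cpg(contig, snp.pos0)
            # the SNP must not touch any *other* scanned motif
            if ok and other_motifs:
                ok = (
                    _motif_effect_here(
                        contig, structure, snp.pos0, snp.ref, snp.alt,
                        other_motifs, flank,
                    )
                    == rbp_motif.EFFECT_NONE
                )
        if ok:
            contig.reserve(g_start - 1, g_start + k + 1)
            return snp
        contig.write(g_start, saved)  # undo and retry elsewhere
    raise RuntimeError(
        f"could not plant motif {motif.name} ({effect}) in {region} of "
        f"{structure.gene.id} after 60 attempts"
    )


def _plant_category_snp(
    contig: _Contig,
    structure: _GeneStructure,
    segment: tuple[int, int],
    category: str,
    rng: np.random.Generator,
    motifs: Sequence[MotifModel],
    flank: int,
) -> SnpRecord:
    """Plant a SNP whose positional class is ``category`` and which neither
    destroys a CpG nor touches any scanned motif."""
    for _attempt in range(200):
        pos = _category_position(segment, structure.gene.strand, category, rng)
        if pos < 1 or pos + 1 >= structure.contig_len:
            continue
        if not contig.free(pos, pos + 1):
            continue
        if _context_is_cpg(contig, pos):
            continue
        ref = contig.base(pos)
        alts = [b for b in "ACGT" if b != ref]
        alt = alts[int(rng.integers(3))]
        if (
            _motif_effect_here(contig, structure, pos, ref, alt, motifs, flank)
            != rbp_motif.EFFECT_NONE
        ):
            continue
        contig.reserve(pos, pos + 1)
        return SnpRecord(structure.gene.chrom, pos + 1, ref, alt)
    raise RuntimeError(
        f"could not place a {category} SNP on {structure.gene.id} after 200 attempts"
    )


def _plant_cpg_loss(
    contig: _Contig,
    structure: _GeneStructure,
    segment: tuple[int, int],
    rng: np.random.Generator,
    motifs: Sequence[MotifModel],
    flank: int,
) -> SnpRecord:
    """Plant a CG dinucleotide in the upstream intron and a C->T SNP that
    destroys it."""
    strand = structure.gene.strand
    w = DEFAULT_WINDOWS
    s, e = segment
    for _attempt in range(200):
        d = int(rng.integers(w.intron_min + 5, w.intron_max - 5))
        pos = s - d if strand == "+" else e - 1 + d
        if pos < 2 or pos + 2 >= structure.contig_len:
            continue
        if not contig.free(pos - 1, pos + 3):
            continue
        saved = contig.seq(pos - 1, pos + 3)
        # avoid an accidental second CpG around the plant: clamp neighbours
        contig.write(pos - 1, "ACGA")  # prev=A, C, G, next=A
        if (
            _motif_effect_here(contig, structure, pos, "C", "T", motifs, flank)
            != rbp_motif.EFFECT_NONE
        ):
            contig.write(pos - 1, saved)
            continue
        contig.reserve(pos - 1, pos + 3)
        return SnpRecord(structure.gene.chrom, pos + 1, "C", "T")
    raise RuntimeError(f"could not plant a CpG-loss SNP on {structure.gene.id}")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _sample_names(config: SimulationConfig) -> tuple[list[str], dict[str, str]]:
    g1, g2 = config.group_names
    samples_g1 = [f"{g1}_s{i + 1}" for i in range(config.n_samples_per_group)]
    samples_g2 = [f"{g2}_s{i + 1}" for i in range(config.n_samples_per_group)]
    groups = {s: g1 for s in samples_g1} | {s: g2 for s in samples_g2}
    return samples_g1 + samples_g2, groups


def generate_expression(
    config: SimulationConfig,
    features: Sequence[str] | None = None,
    effects: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Log-normal expression for ``features`` with per-feature group
    log2 fold-changes ``effects`` (group 1 relative to group 2)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if features is None:
        features = [f"Gene{i + 1:03d}" for i in range(config.n_genes)]
    effects = effects or {}
    samples, groups = _sample_names(config)
    g1 = config.group_names[0]
    base = rng.uniform(3.0, 8.0, size=len(features))
    rows = []
    for i, feature in enumerate(features):
        lfc = effects.get(feature, 0.0)
        values = []
        for s in samples:
            mu = base[i] + (lfc / 2 if groups[s] == g1 else -lfc / 2)
            log2x = rng.normal(mu, config.expression_sigma)
            values.append(round(float(2.0 ** log2x), 4))
        rows.append(values)
    return pd.DataFrame(rows, index=list(features), columns=samples)


# ---------------------------------------------------------------------------
# Bundle assembly
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """Paths of a generated study plus in-memory truth tables."""

    root: Path
    config: SimulationConfig

    @property
    def genome(self) -> Path:
        return self.root / "genome.fa"

    @property
    def annotation(self) -> Path:
        return self.root / "annotation.gtf"

    @property
    def junctions(self) -> Path:
        return self.root / "junctions.tsv"

    @property
    def samples(self) -> Path:
        return self.root / "samples.tsv"

    @property
    def vcf(self) -> Path:
        return self.root / "snps.vcf"

    @property
    def gene_expression(self) -> Path:
        return self.root / "gene_expression.tsv"

    @property
    def mirna_expression(self) -> Path:
        return self.root / "mirna_expression.tsv"

    @property
    def mirna_fasta(self) -> Path:
        return self.root / "mirna.fa"

    @property
    def utr_fasta(self) -> Path:
        return self.root / "utr.fa"

    @property
    def motifs(self) -> Path:
        return self.root / "motifs.tsv"

    @property
    def targets(self) -> Path:
        return self.root / "microexon_targets.tsv"

    @property
    def gwas_genes(self) -> Path:
        return self.root / "gwas_genes.txt"

    @property
    def ortholog_map(self) -> Path:
        return self.root / "ortholog_map.tsv"

    @property
    def truth_dir(self) -> Path:
        return self.root / "truth"

    def truth(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.truth_dir / f"{name}.tsv", sep="\t")

    def truth_summary(self) -> dict:
        with open(self.truth_dir / "summary.json") as fh:
            return json.load(fh)


def generate_study(config: SimulationConfig, outdir: str | Path) -> StudyBundle:
    """Generate the full synthetic study bundle under ``outdir``.

    Deterministic: a fixed seed yields byte-identical outputs.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_plan, rng_seq, rng_counts, rng_snp, rng_motif, rng_expr, rng_mirna = (
        np.random.default_rng(s) for s in streams
    )

    plans = _plan_genes(config, rng_plan)
    structures = [_build_structure(p, rng_plan) for p in plans]
    by_gene = {s.plan.gene_id: s for s in structures}

    ann = GenomeAnnotation([s.gene for s in structures])
    events = infer_events(ann)
    seg_to_event = {(e.gene_id, e.start, e.end): e for e in events}
    for s in structures:
        for seg in s.segments:
            key = (s.plan.gene_id, seg[0], seg[1])
            if key not in seg_to_event:
                raise RuntimeError(f"planted segment {key} not recovered as an event")
        planted = {(e.start, e.end) for e in events if e.gene_id == s.plan.gene_id}
        if planted != {tuple(seg) for seg in s.segments}:
            raise RuntimeError(f"extra events inferred for {s.plan.gene_id}: {planted}")

    contigs = {s.plan.gene_id: _Contig(s.contig_len, rng_seq) for s in structures}

    # --- motif plants ----------------------------------------------------
    motifs = list(DEMO_MOTIFS)
    motif_by_name = {m.name: m for m in motifs}
    snps: list[SnpRecord] = []
    motif_truth_rows: list[dict] = []

    if config.motif_plants is None:
        plants: list[tuple[str, str, str, str]] = []
        # enrichment signal: SRSF1 downstream of every inclusion-up event
        up_genes = [p.gene_id for p in plans if p.differential and p.psi[0] > p.psi[1]]
        down_genes = [
            p.gene_id
            for p in plans
            if p.differential and p.psi[0] < p.psi[1] and p.etype != "CE2"
        ]
        for gene_id in up_genes:
            plants.append((gene_id, rbp_motif.REGION_DOWN, "SRSF1", rbp_motif.EFFECT_NONE))
        for gene_id in down_genes[:6]:
            plants.append((gene_id, rbp_motif.REGION_DOWN, "SRSF1", rbp_motif.EFFECT_DISRUPT))
        for gene_id in down_genes[6:8]:
            plants.append((gene_id, rbp_motif.REGION_UP, "PCBP1", rbp_motif.EFFECT_CREATE))
    else:
        plants = list(config.motif_plants)

    for gene_id, region, motif_name, effect in plants:
        structure = by_gene[gene_id]
        segment = structure.segments[0]
        snp = _plant_motif(
            contigs[gene_id], structure, segment, region,
            motif_by_name[motif_name], effect, rng_motif, config.flank_nt,
            other_motifs=[m for m in motifs if m.name != motif_name],
        )
        if snp is not None:
            snps.append(snp)
            event = seg_to_event[(gene_id, segment[0], segment[1])]
            motif_truth_rows.append(
                {
                    "event_id": event.event_id,
                    "gene": gene_id,
                    "motif": motif_name,
                    "region": region,
                    "effect": effect,
                    "chrom": snp.chrom,
                    "pos": snp.pos,
                    "ref": snp.ref,
                    "alt": snp.alt,
                }
            )

    # --- CpG-loss plants -------------------------------------------------
    cpg_rows: list[dict] = []
    diff_plans = [p for p in plans if p.differential and p.etype != "CE2"]
    for i, plan in enumerate(diff_plans[:4]):
        structure = by_gene[plan.gene_id]
        segment = structure.segments[0]
        for _ in range(i + 1):  # 1..4 destroyed CpG sites per gene
            snp = _plant_cpg_loss(
                contigs[plan.gene_id], structure, segment, rng_snp, motifs, config.flank_nt
            )
            snps.append(snp)
            cpg_rows.append({"gene": plan.gene_id, "chrom": snp.chrom, "pos": snp.pos})

    # --- positional-category SNPs ---------------------------------------
    snp_truth_rows: list[dict] = []
    if config.snp_placement is None:
        cycle = [CAT_INTRONIC_UP, CAT_SS3, CAT_EXONIC, CAT_SS5, CAT_INTRONIC_DOWN, CAT_OUTSIDE]
        placement = []
        for i, event in enumerate(events):
            for j in range(2):
                category = cycle[(i + j) % len(cycle)]
                if category == CAT_EXONIC and event.length <= 2 * (DEFAULT_WINDOWS.ss_exonic + 1):
                    category = CAT_INTRONIC_UP
                placement.append((event.event_id, category))
    else:
        by_event = {e.event_id: e for e in events}
        placement = []
        for gene_or_event, category in config.snp_placement:
            if gene_or_event in by_event:
                placement.append((gene_or_event, category))
            else:
                raise ConfigError(f"snp_placement references unknown event {gene_or_event}")

    by_event_id = {e.event_id: e for e in events}
    for event_id, category in placement:
        event = by_event_id[event_id]
        structure = by_gene[event.gene_id]
        snp = _plant_category_snp(
            contigs[event.gene_id], structure, (event.start, event.end),
            category, rng_snp, motifs, config.flank_nt,
        )
        snps.append(snp)
        snp_truth_rows.append(
            {
                "event_id": event_id,
                "gene": event.gene_id,
                "chrom": snp.chrom,
                "pos": snp.pos,
                "ref": snp.ref,
                "alt": snp.alt,
                "category": category,
            }
        )

    # --- junction counts -------------------------------------------------
    samples, groups = _sample_names(config)
    psi_by_event: dict[str, tuple[float, float]] = {}
    for s in structures:
        for seg in s.segments:
            event = seg_to_event[(s.plan.gene_id, seg[0], seg[1])]
            psi_by_event[event.event_id] = s.plan.psi
    counts: dict[str, list[tuple[int, int]]] = {}
    g1 = config.group_names[0]
    for event in events:
        p1, p2 = psi_by_event[event.event_id]
        pairs = []
        for sample in samples:
            psi = p1 if groups[sample] == g1 else p2
            n = int(rng_counts.poisson(config.depth))
            inc = int(rng_counts.binomial(n, psi)) if n > 0 else 0
            pairs.append((inc, n - inc))
        counts[event.event_id] = pairs

    # --- expression -------------------------------------------------------
    gene_symbols = [p.symbol for p in plans] + [config.factor_gene]
    if config.expression_effects is None:
        effects = {config.factor_gene: -2.5}
        candidates = [p.symbol for p in plans if not p.differential][:6]
        for i, symbol in enumerate(candidates):
            effects[symbol] = 2.0 if i % 2 == 0 else -2.0
    else:
        effects = dict(config.expression_effects)
    gene_expr = generate_expression(config, gene_symbols, effects, rng_expr)

    # --- miRNAs -----------------------------------------------------------
    mirna_ids = [f"miR-sim-{i + 1:02d}" for i in range(config.n_mirnas)]
    if config.mirna_effects is None:
        mirna_effects = {
            "miR-sim-01": 2.5,
            "miR-sim-02": 2.5,
            "miR-sim-04": 2.5,
            "miR-sim-05": -2.5,
        }
    else:
        mirna_effects = dict(config.mirna_effects)
    mirna_seqs = {
        mid: "".join(
            "ACGT"[int(rng_mirna.integers(4))] for _ in range(config.mirna_len)
        )
        for mid in mirna_ids
    }
    utr = ["ACGT"[int(rng_mirna.integers(4))] for _ in range(config.utr_len)]
    # planted seed sites: 8mer for miR-01, 7mer-m8 for miR-02/03/05
    site_plan = [("miR-sim-01", 60, "8mer"), ("miR-sim-02", 160, "7mer-m8"),
                 ("miR-sim-03", 260, "7mer-m8"), ("miR-sim-05", 360, "7mer-m8")]
    for mid, offset, stype in site_plan:
        m = mirna_seqs[mid]
        site = reverse_complement(m[1:8])
        if stype == "8mer":
            site += "A"
        utr[offset : offset + len(site)] = list(site)
    utr_seq = "".join(utr)
    # miR-04 is differential but must have no 6mer core in the UTR
    for _ in range(100):
        core = reverse_complement(mirna_seqs["miR-sim-04"][1:7])
        if core not in utr_seq:
            break
        mirna_seqs["miR-sim-04"] = "".join(
            "ACGT"[int(rng_mirna.integers(4))] for _ in range(config.mirna_len)
        )
    mirna_expr = generate_expression(config, mirna_ids, mirna_effects, rng_mirna)

    # --- GWAS overlap inputs ---------------------------------------------
    overlap_symbols = [p.symbol for p in plans][:5]
    external = [s.upper() for s in overlap_symbols] + [f"GWASONLY{i}" for i in range(1, 6)]
    ortho_rows = [(s.upper(), s) for s in overlap_symbols] + [
        (f"GWASONLY{i}", f"Absent{i}") for i in range(1, 6)
    ]

    # --- write the bundle -------------------------------------------------
    write_fasta({s.plan.gene_id: str(contigs[s.plan.gene_id]) for s in structures},
                outdir / "genome.fa")
    write_annotation(ann, outdir / "annotation.gtf")
    write_junction_counts(counts, samples, outdir / "junctions.tsv")
    write_samples(groups, outdir / "samples.tsv")
    write_vcf(snps, outdir / "snps.vcf",
              {s.plan.gene_id: s.contig_len for s in structures})
    gene_expr.to_csv(outdir / "gene_expression.tsv", sep="\t", index_label="feature")
    mirna_expr.to_csv(outdir / "mirna_expression.tsv", sep="\t", index_label="feature")
    write_fasta(mirna_seqs, outdir / "mirna.fa")
    write_fasta({f"{config.factor_gene}_3UTR": utr_seq}, outdir / "utr.fa")
    rbp_motif.write_motifs(motifs, outdir / "motifs.tsv")
    with open(outdir / "gwas_genes.txt", "w") as fh:
        fh.write("\n".join(external) + "\n")
    with open(outdir / "ortholog_map.tsv", "w") as fh:
        fh.write("external_symbol\tgene\n")
        for ext, nat in ortho_rows:
            fh.write(f"{ext}\t{nat}\n")

    target_rows = []
    for s in structures:
        if s.plan.is_target:
            seg = s.segments[0]
            target_rows.append((s.gene.chrom, seg[0], seg[1]))
    with open(outdir / "microexon_targets.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\n")
        for chrom, s0, e0 in target_rows:
            fh.write(f"{chrom}\t{s0}\t{e0}\n")

    # --- truth tables -----------------------------------------------------
    event_truth = []
    for event in events:
        s = by_gene[event.gene_id]
        p1, p2 = psi_by_event[event.event_id]
        event_truth.append(
            {
                "event_id": event.event_id,
                "gene": event.gene_id,
                "type": event.etype,
                "length": event.length,
                "psi_g1": p1,
                "psi_g2": p2,
                "differential": s.plan.differential,
                "microexon": s.plan.microexon,
                "is_target": s.plan.is_target,
                "coding": s.plan.coding,
            }
        )
    pd.DataFrame(event_truth).to_csv(outdir / "truth" / "events.tsv", sep="\t", index=False)
    pd.DataFrame(snp_truth_rows).to_csv(outdir / "truth" / "snps.tsv", sep="\t", index=False)
    pd.DataFrame(motif_truth_rows).to_csv(outdir / "truth" / "motifs.tsv", sep="\t", index=False)
    pd.DataFrame(cpg_rows).to_csv(outdir / "truth" / "cpg.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"feature": k, "log2fc": v} for k, v in sorted(effects.items())]
    ).to_csv(outdir / "truth" / "expression.tsv", sep="\t", index=False)

    cpg_by_gene: dict[str, int] = {}
    for row in cpg_rows:
        cpg_by_gene[row["gene"]] = cpg_by_gene.get(row["gene"], 0) + 1
    ss_genes = sorted(
        {
            row["gene"]
            for row in snp_truth_rows
            if row["category"] in (CAT_SS3, CAT_SS5)
            and by_gene[row["gene"]].plan.differential
        }
    )
    n_affected = len({r["event_id"] for r in motif_truth_rows
                      if r["effect"] in (rbp_motif.EFFECT_DISRUPT, rbp_motif.EFFECT_CREATE)})
    summary = {
        "n_events": len(events),
        "n_differential": sum(
            1 for e in events if by_gene[e.gene_id].plan.differential
        ),
        "events_by_type": {
            t: sum(1 for e in events if e.etype == t) for t in ("CE", "IR", "alt3ss", "alt5ss")
        },
        "n_motif_affected_events": n_affected,
        "splice_site_snp_genes": ss_genes,
        "cpg_loss_by_gene": cpg_by_gene,
        "expected_candidate_mirnas": ["miR-sim-01", "miR-sim-02"],
        "n_gwas_overlap": len(overlap_symbols),
        "target_events": [
            seg_to_event[(s.plan.gene_id, s.segments[0][0], s.segments[0][1])].event_id
            for s in structures
            if s.plan.is_target
        ],
        "factor_gene": config.factor_gene,
        "group_names": list(config.group_names),
    }
    with open(outdir / "truth" / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    return StudyBundle(outdir, config)


# ---------------------------------------------------------------------------
# Frame-null annotation (no sequence needed)
# ---------------------------------------------------------------------------

def make_frame_null_annotation(
    n_internal_exons: int = 12_000,
    min_len: int = 30,
    max_len: int = 329,
    seed: int | None = None,
    mode: str = "uniform",
) -> GenomeAnnotation:
    """Annotation whose internal CDS exon lengths are uniform over
    ``{min_len..max_len}`` — for calibrating the random-skipping null.

    ``mode="cycle"`` uses every length equally often (the null rate is then
    an exact count); ``mode="uniform"`` samples lengths with ``seed``.
    """
    if mode == "uniform":
        rng = np.random.default_rng(seed)
        lengths = rng.integers(min_len, max_len + 1, size=n_internal_exons)
    elif mode == "cycle":
        span = max_len - min_len + 1
        lengths = [(min_len + i % span) for i in range(n_internal_exons)]
    else:
        raise ValueError("mode must be 'uniform' or 'cycle'")

    genes = []
    per_gene = 10
    pos = 100
    chrom = "null_chr"
    idx = 0
    gene_no = 0
    while idx < len(lengths):
        chunk = [int(x) for x in lengths[idx : idx + per_gene]]
        idx += per_gene
        gene_no += 1
        exons = [(pos, pos + 60)]
        pos += 60 + 100
        for L in chunk:
            exons.append((pos, pos + L))
            pos += L + 100
        exons.append((pos, pos + 60))
        pos += 60 + 500
        gid = f"null_g{gene_no:05d}"
        tx = Transcript(f"{gid}.t1", gid, exons, exons[0][0], exons[-1][1])
        genes.append(Gene(gid, gid, chrom, "+", [tx]))
    return GenomeAnnotation(genes)
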