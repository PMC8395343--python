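"""Genomic data model and file I/O.

All coordinate conversions between external formats and the internal
convention live in this module:

* internal coordinates are 0-based half-open intervals ``[start, end)``;
* GTF/GFF exon coordinates are 1-based closed and are converted on read;
* VCF positions stay 1-based in :class:`SnpRecord` (as printed in the file)
  and are converted by consumers.

"Upstream"/"downstream" throughout the package means transcript (5'->3')
orientation: genomic order is flipped for minus-strand genes.  Sequence
access on the minus strand returns the reverse complement so that motif
scanning always operates on the sense strand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from gffutils.feature import feature_from_line
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


class AnnotationError(ValueError):
    """Malformed or inconsistent gene annotation."""


class VcfFormatError(ValueError):
    """Malformed VCF input."""


class JunctionTableError(ValueError):
    """Malformed junction-count table."""


@dataclass
class Transcript:
    """One isoform: exons ordered 5'->3' in transcript orientation.

    ``cds_start``/``cds_end`` are genomic (0-based half-open) and optional;
    non-coding transcripts leave them as ``None``.
    """

    id: str
    gene_id: str
    exons: list[Interval]
    cds_start: int | None = None
    cds_end: int | None = None

    @property
    def exons_genomic(self) -> list[Interval]:
        """Exons sorted by genomic coordinate (ascending)."""
        return sorted(self.exons)

    @property
    def span(self) -> Interval:
        ex = self.exons_genomic
        return ex[0][0], ex[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns_genomic(self) -> list[Interval]:
        ex = self.exons_genomic
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]


@dataclass
class Gene:
    id: str
    symbol: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass(frozen=True)
class SnpRecord:
    """A bi-allelic single-nucleotide variant; ``pos`` is 1-based (VCF)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    strain_id: str = "query"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"SNP at {self.chrom}:{self.pos} has ref == alt")
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(
                f"SNP at {self.chrom}:{self.pos} has non-ACGT alleles "
                f"{self.ref}>{self.alt}"
            )

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1


class GenomeAnnotation:
    """Genes -> transcripts -> exons, with optional FASTA-backed sequence."""

    def __init__(self, genes: Iterable[Gene], fasta_path: str | Path | None = None):
        self.genes: dict[str, Gene] = {}
        for g in genes:
            if g.id in self.genes:
                raise AnnotationError(f"duplicate gene id {g.id}")
            self.genes[g.id] = g
        self._fasta_path = Path(fasta_path) if fasta_path else None
        self._fasta: Fasta | None = None
        self.validate()

    # -- sequence access -------------------------------------------------
    @property
    def has_sequence(self) -> bool:
        return self._fasta_path is not None

    def _get_fasta(self) -> Fasta:
        if self._fasta is None:
            if self._fasta_path is None:
                raise AnnotationError("no genome FASTA attached to this annotation")
            self._fasta = Fasta(str(self._fasta_path), as_raw=True, sequence_always_upper=True)
        return self._fasta

    def contig_length(self, chrom: str) -> int:
        return len(self._get_fasta()[chrom])

    def contig_lengths(self) -> dict[str, int]:
        fa = self._get_fasta()
        return {name: len(fa[name]) for name in fa.keys()}

    def sequence(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)``; minus strand returns the reverse complement."""
        if start < 0 or end < start:
            raise ValueError(f"invalid interval [{start}, {end})")
        seq = str(self._get_fasta()[chrom][start:end])
        return reverse_complement(seq) if strand == "-" else seq

    def spliced_sequence(self, transcript: Transcript) -> str:
        gene = self.genes[transcript.gene_id]
        parts = [self.sequence(gene.chrom, s, e, gene.strand) for s, e in transcript.exons]
        return "".join(parts)

    # -- structure -------------------------------------------------------
    def transcripts(self) -> Iterable[Transcript]:
        for gene in self.genes.values():
            yield from gene.transcripts

    def validate(self) -> None:
        for gene in self.genes.values():
            if gene.strand not in "+-":
                raise AnnotationError(f"gene {gene.id}: bad strand {gene.strand!r}")
            for tx in gene.transcripts:
                if not tx.exons:
                    raise AnnotationError(f"transcript {tx.id} has zero exons")
                ex = tx.exons_genomic
                for s, e in ex:
                    if s < 0 or e <= s:
                        raise AnnotationError(
                            f"transcript {tx.id}: invalid exon [{s}, {e})"
                        )
                for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
                    if s2 < e1:
                        raise AnnotationError(
                            f"transcript {tx.id}: overlapping exons "
                            f"[{s1},{e1}) and [{s2},{e2})"
                        )
                # transcript-orientation ordering
                expect = ex if gene.strand == "+" else ex[::-1]
                if tx.exons != expect:
                    raise AnnotationError(
                        f"transcript {tx.id}: exons not ordered 5'->3'"
                    )
                if (tx.cds_start is None) != (tx.cds_end is None):
                    raise AnnotationError(f"transcript {tx.id}: half-defined CDS")
                if tx.cds_start is not None:
                    span = tx.span
                    if not (span[0] <= tx.cds_start < tx.cds_end <= span[1]):
                        raise AnnotationError(
                            f"transcript {tx.id}: CDS [{tx.cds_start},{tx.cds_end}) "
                            f"outside exonic span [{span[0]},{span[1]})"
                        )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path, fasta_path: str | Path | None = None) -> GenomeAnnotation:
    """Read an ENSEMBL-dialect GTF into a :class:`GenomeAnnotation`.

    Only ``exon`` and ``CDS`` features are used; exons are grouped per
    transcript and ordered 5'->3' in transcript orientation.
    """
    path = Path(path)
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    tx_meta: dict[str, tuple[str, str, str, str]] = {}  # tx -> (gene, symbol, chrom, strand)
    seen_tx: set[str] = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            ftype = fields[2]
            if ftype not in ("exon", "CDS", "transcript"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise AnnotationError(f"{path}:{lineno}: unparseable row ({exc})") from exc
            attrs = feat.attributes
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise AnnotationError(
                    f"{path}:{lineno}: row lacks gene_id/transcript_id attributes"
                )
            gene_id = attrs["gene_id"][0]
            tx_id = attrs["transcript_id"][0]
            symbol = attrs["gene_name"][0] if "gene_name" in attrs else gene_id
            tx_meta.setdefault(tx_id, (gene_id, symbol, feat.seqid, feat.strand))
            seen_tx.add(tx_id)
            interval = (feat.start - 1, feat.end)  # 1-based closed -> 0-based half-open
            if ftype == "exon":
                exons.setdefault(tx_id, []).append(interval)
            elif ftype == "CDS":
                cds.setdefault(tx_id, []).append(interval)

    no_exon = sorted(t for t in seen_tx if t not in exons)
    if no_exon:
        raise AnnotationError(f"transcripts with zero exons: {', '.join(no_exon)}")

    genes: dict[str, Gene] = {}
    for tx_id in sorted(exons):
        gene_id, symbol, chrom, strand = tx_meta[tx_id]
        ex = sorted(exons[tx_id])
        if strand == "-":
            ex = ex[::-1]
        cs = ce = None
        if tx_id in cds:
            segs = cds[tx_id]
            cs = min(s for s, _ in segs)
            ce = max(e for _, e in segs)
        gene = genes.setdefault(gene_id, Gene(gene_id, symbol, chrom, strand))
        gene.transcripts.append(Transcript(tx_id, gene_id, ex, cs, ce))

    return GenomeAnnotation(genes.values(), fasta_path=fasta_path)


def write_annotation(ann: GenomeAnnotation, path: str | Path, source: str = "splicescope") -> None:
    """Write the annotation back to GTF (exon + per-exon CDS features)."""
    with open(path, "w") as out:
        for gene_id in sorted(ann.genes):
            gene = ann.genes[gene_id]
            for tx in gene.transcripts:
                attrs = (
                    f'gene_id "{gene.id}"; transcript_id "{tx.id}"; '
                    f'gene_name "{gene.symbol}";'
                )
                for s, e in tx.exons_genomic:
                    out.write(
                        f"{gene.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )
                    if tx.cds_start is not None:
                        cs, ce = max(s, tx.cds_start), min(e, tx.cds_end)
                        if cs < ce:
                            out.write(
                                f"{gene.chrom}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t"
                                f"{gene.strand}\t.\t{attrs}\n"
                            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    strain_id: str = "query",
    stats: dict | None = None,
) -> list[SnpRecord]:
    """Read a VCF into SNP records, one per (row, alt allele).

    Indels and other non-SNV alleles are skipped; the skip count is logged
    and, if ``stats`` is given, stored under ``stats["skipped"]``.
    """
    from cyvcf2 import VCF

    try:
        reader = VCF(str(path))
    except Exception as exc:
        raise VcfFormatError(f"{path}: not a readable VCF ({exc})") from exc

    records: list[SnpRecord] = []
    skipped = 0
    try:
        for variant in reader:
            ref = variant.REF.upper()
            for alt in variant.ALT:
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES or alt not in VALID_BASES:
                    skipped += 1
                    continue
                records.append(SnpRecord(variant.CHROM, variant.POS, ref, alt, strain_id))
    except Exception as exc:
        if isinstance(exc, VcfFormatError):
            raise
        raise VcfFormatError(f"{path}: malformed VCF body ({exc})") from exc
    finally:
        reader.close()

    if skipped:
        logger.info("read_vcf(%s): skipped %d non-SNV alleles", path, skipped)
    if stats is not None:
        stats["skipped"] = skipped
        stats["n_records"] = len(records)
    return records


def write_vcf(records: Sequence[SnpRecord], path: str | Path,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                out.write(f"##contig=<ID={name},length={length}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, rec in enumerate(sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)), 1):
            out.write(
                f"{rec.chrom}\t{rec.pos}\tsnp{i:05d}\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\n"
            )


# ---------------------------------------------------------------------------
# Junction-count tables
# ---------------------------------------------------------------------------

def read_junction_counts(path: str | Path) -> tuple[dict[str, list[tuple[int, int]]], list[str]]:
    """Read a per-event junction-count TSV.

    Layout: first column ``event_id``, one column per sample, each cell
    ``"<inclusion>,<exclusion>"``.  Missing cells become ``(0, 0)`` with a
    warning; duplicate event ids and negative counts are errors.
    Returns ``(counts, sample_names)``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and df.columns.size == 0:
        return {}, []
    samples = list(df.columns[1:])
    counts: dict[str, list[tuple[int, int]]] = {}
    for _, row in df.iterrows():
        event_id = row.iloc[0]
        if event_id in counts:
            raise JunctionTableError(f"duplicate event id {event_id!r}")
        pairs: list[tuple[int, int]] = []
        for sample in samples:
            cell = row[sample]
            if pd.isna(cell) or str(cell).strip() == "":
                warnings.warn(
                    f"missing junction counts for {event_id}/{sample}; using (0,0)",
                    stacklevel=2,
                )
                pairs.append((0, 0))
                continue
            try:
                inc_s, exc_s = str(cell).split(",")
                inc, exc = int(inc_s), int(exc_s)
            except ValueError as exc:
                raise JunctionTableError(
                    f"cell {cell!r} for {event_id}/{sample} is not 'inc,exc'"
                ) from exc
            if inc < 0 or exc < 0:
                raise JunctionTableError(
                    f"negative count in {event_id}/{sample}: {cell!r}"
                )
            pairs.append((inc, exc))
        counts[event_id] = pairs
    return counts, samples


def write_junction_counts(
    counts: Mapping[str, Sequence[tuple[int, int]]],
    samples: Sequence[str],
    path: str | Path,
) -> None:
    with open(path, "w") as out:
        out.write("event_id\t" + "\t".join(samples) + "\n")
        for event_id, pairs in counts.items():
            cells = [f"{inc},{exc}" for inc, exc in pairs]
            out.write(event_id + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Sample sheets, expression matrices, gene lists
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Features x samples matrix of non-negative FPKM-like values with a
    two-group sample assignment."""

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression matrix contains negative values")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        if len(set(self.groups[s] for s in self.values.columns)) != 2:
            raise ValueError("expression matrix must span exactly two groups")

    @property
    def group_names(self) -> tuple[str, str]:
        seen: list[str] = []
        for s in self.values.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen[0], seen[1]

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def group_values(self, feature: str, group: str):
        return self.values.loc[feature, self.group_columns(group)].to_numpy(dtype=float)


def read_samples(path: str | Path) -> dict[str, str]:
    """Read a two-column sample sheet (sample, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_samples(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("sample\tgroup\n")
        for sample, group in groups.items():
            out.write(f"{sample}\t{group}\n")


def read_expression(path: str | Path, groups: Mapping[str, str]) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, dict(groups))


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_ortholog_map(path: str | Path) -> dict[str, list[str]]:
    """TSV (external_symbol, native_symbol); one external symbol may map to
    several native genes."""
    mapping: dict[str, list[str]] = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    for ext, nat in zip(df.iloc[:, 0], df.iloc[:, 1]):
        mapping.setdefault(ext, []).append(nat)
    return mapping


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}
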