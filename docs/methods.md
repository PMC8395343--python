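# Methods

This note documents the models, estimators, windows and design choices
behind splicescope, and what the synthetic study does and does not
emulate.

## Coordinates, strand and sequence

Internal coordinates are 0-based half-open; GTF (1-based closed) and VCF
(1-based positions) are converted only in `core_io`, so no other module
performs coordinate arithmetic across conventions.  "Upstream" and
"downstream" always mean transcript (5′→3′) orientation: genomic order is
flipped for minus-strand genes, and sequence access on the minus strand
returns the reverse complement so motif and seed scanning always run on
the sense strand.  CpG calls are the one deliberate exception: CpG is
strand-symmetric, so they use the genome forward strand.

## Event model and PSI estimation

An event is one alternative segment derived from pairwise isoform
comparison: a cassette exon (internal exon absent from one isoform with
both flanking exons shared), a retained intron (intron of one isoform
contained in an exon of the other), or the differential extension of a
shared exon boundary (alternative donor/acceptor, assigned 5′ss/3′ss by
strand).  Boundary shifts that swallow a whole intron are treated as
IR/complex and excluded from the alt-ss class.

Group PSI pools counts across the samples of a group,
Ψ = Σinc / (Σinc + Σexc).  Pooling (rather than averaging per-sample
ratios) was chosen for stability at low per-sample depth; the per-sample
ratio is still used where the question is per-sample (the
inclusion–expression correlation).  Events with all-zero counts are marked
unquantifiable and excluded downstream.

The confidence that the two groups differ is a Monte-Carlo posterior
probability: independent Beta(Σinc + ½, Σexc + ½) posteriors per group
(Jeffreys prior), 10 000 draws by default, reporting the fraction of draws
in which Ψ₁ − Ψ₂ shares the sign of the point estimate and exceeds a
threshold (default 0; the threshold is exposed because "difference
exceeds 0" vs "exceeds the filter cutoff" are both defensible readings).
This deliberately replaces a full splice-graph EM and its exact posterior
with a specifiable estimator that preserves the filter semantics
(|ΔΨ| cutoff + posterior-probability cutoff).  The Monte-Carlo error at
10 000 draws is ≤ 0.005, well inside the 0.9 filter margin for the effect
sizes of interest; tests compare the estimator against numerical
integration of the Beta-difference probability.

Significance: |ΔΨ| > 0.1 (strict) and probability > 0.9 (strict).
Categories: strong at |ΔΨ| ≥ 0.5, else moderate; inclusion/exclusion by
the sign of ΔΨ (group 1 − group 2).  The 0.5 boundary is an inference
from published per-event tables (0.510 → strong, 0.410 → moderate) rather
than a stated rule, and is configurable.  PSI/ΔΨ are reported rounded to
3 decimals.

## Frame consequences

Frame is defined only for significant CDS cassette exons.  Region calls
use the longest-CDS transcript of the gene; a segment overlapping both UTR
and CDS counts as CDS; genes without CDS give NA.  Skipping preserves the
frame iff exon length ≡ 0 (mod 3).

Rescue groups — several frameshifting exons of one gene whose joint
skipping restores the frame — are underdetermined in general, so grouping
is deterministic and auditable: within a gene and ΔΨ direction, residue-1
exons are paired with residue-2 exons in genomic order (smallest groups
first), then leftovers of a single residue class are grouped in threes.
An exon whose own length ≡ 0 (mod 3) never joins a group.

The random-skipping null is the fraction of internal (non-first,
non-last) CDS exons, deduplicated by coordinates, with length ≢ 0 (mod 3),
recomputed from whatever annotation is supplied rather than hard-coded.
For exon lengths uniform over {30..329} this is exactly 2/3;
`make_frame_null_annotation` builds such an annotation for calibration.
The observed frameshift count is compared with an exact two-sided binomial
test (minimum-likelihood convention).  Both event-level and gene-level
summaries are emitted because published per-event and per-gene counts are
not always distinguishable.

## SNP windows

Relative to one alternative exon (transcript orientation):

| category            | definition                                   |
|---------------------|----------------------------------------------|
| ss3/ss5 adjacent    | ≤ 15 nt from the acceptor/donor, counted on **both** the intronic and the exonic side of the boundary |
| intronic up/down    | 15 < distance ≤ 500 into the flanking intron |
| exonic              | inside the exon, > 15 nt from both edges     |
| outside             | farther away, or another chromosome          |

Distances are 1-based from the boundary (first intronic base and outermost
exonic base both have distance 1).  The symmetric exonic-side splice-site
window is one reading of "within 15 nucleotides up- or downstream of
splice sites"; its width is a config knob (`ss_window`) because the
wording is ambiguous, as is whether intronic windows start at the exon
edge (they do here).  Densities are per 1000 nt; the enrichment test is a
2×2 χ² (SNP vs non-SNP positions × near-exon vs genome-wide) with 1 df and
no continuity correction.  The genome-wide baseline is total SNPs over
total genome length from the FASTA — the simplest defensible
normalisation, since no baseline is standard.  Overlapping event windows
are merged before counting so positions are not double-counted.

A SNP destroys a CpG iff a CpG dinucleotide covering the position exists
with the reference allele and none exists with the alternative allele;
counts are per gene within the event windows.

## RBP motifs

Motifs are user-supplied sets of degenerate IUPAC k-mers (5–8 nt) with
region semantics (upstream intron / exon / downstream intron); the repo
ships a small demonstration set (SRSF1-like purine-rich, PCBP1-like C-rich,
an RBFOX-like TGCATG, and a degenerate SRSF7-like pattern) because no
canonical 47-motif collection is printed anywhere reusable.  The scanner
reports every matching offset (overlaps included) by direct per-position
IUPAC set membership; tests verify equivalence against a regular-expression
oracle.

Enrichment is event-level presence/absence of ≥ 1 hit in a region
(default flank 250 nt), foreground = significant inclusion-up (or -down)
events, background = quantifiable non-significant events, Fisher exact
test with BH adjustment across all (motif, region, direction) rows and a
log2 ratio of hit fractions (±20 as the capped sentinel when a fraction is
zero).  This replaces positional sliding-window statistics with a simpler,
fully specified test; a positional hit-density profile is still exported
for plotting but carries no test.  The background choice (non-significant
events of the same study rather than all alternative exons genome-wide) is
a documented deviation forced by desk-scale inputs.

A SNP **disrupts** a motif when some match covers the SNP with the
reference allele and no covering match survives with the alternative
allele; **creates** in the reverse case.  Alleles are complemented for
minus-strand genes before the sense-strand comparison.  Affected events
are counted deduplicated.

## miRNA targeting

Canonical seed classes: the 6mer core is the reverse complement of miRNA
positions 2–7; 7mer-m8 adds complementarity to position 8; 7mer-A1 adds an
adenosine opposite position 1; 8mer has both.  One (highest-priority) type
is reported per core locus.  Differential miRNAs use a Welch t-test on
log2(x + 1) with BH adjustment; candidate regulators of a gene must be
significant in the required direction and carry at least one site of class
7mer-m8 or better (configurable) in the gene's 3′UTR, ranked by site class
then adjusted p.  Seed-class rules stand in for an unspecified external
prediction framework and are labelled as such.

## Group statistics

Welch's unequal-variance t-test (Welch–Satterthwaite df) is the
differential-expression surface, applied to FPKM-like values after
log2(x + 1); count-model re-estimation (negative binomial) is out of
scope, and externally computed fold-changes/p-values are treated as
pass-through annotation.  Degenerate inputs follow fixed conventions:
both groups constant and equal → p = 1; constant with different means →
p = 0, flagged.  Heatmap matrices are log2(x + 1), then row-centred and
scaled to unit sample variance (ddof = 1, the convention of R's `scale`);
constant rows become zero.  Gene-list intersections map external symbols
through an explicit ortholog table (case-insensitive), flagging one-to-many
mappings as ambiguous — the mapping is an input because no mapping method
is canonical.

## Synthetic study

The generator mirrors the study design the package targets: two groups × five
samples, ~40 genes (one per contig) with an event mix dominated by
cassette exons (56 % CE, 23 % IR, 11 % alt3′ss, 10 % alt5′ss), half the
events differential with planted |ΔΨ| ≥ 0.3, microexons of 3–30 nt
including four factor-target exons skipped in group 1, two genes with two
complementary-residue frameshifting exons (joint-skip rescue), plus
noncoding and 3′UTR-event genes for region variety.  Junction counts are
n ~ Poisson(depth = 200) per sample with inclusion ~ Binomial(n, Ψ) —
the simplest generative model consistent with junction-count PSI
estimation.  Contig sequences are i.i.d. uniform over {A,C,G,T} (a neutral
background for motif statistics) except where features are planted:

* motif instances in scanned regions, with disrupt/create SNPs whose
  effect is verified at plant time against the scanner itself (and against
  all *other* motifs, which must be untouched);
* CG dinucleotides with C→T SNPs for CpG loss, with clamped neighbours so
  exactly one CpG is destroyed;
* positional-category SNPs sampled inside the window definitions, rejected
  and resampled if they would touch a CpG context or any scanned motif.

Expression is log-normal (σ = 0.25 on the log2 scale) with planted group
log2 fold-changes, including a lowered splicing-factor gene whose
expression co-varies with target-exon inclusion across samples; miRNAs
include two elevated species with planted ≥7mer seed sites in the factor
3′UTR and negative controls (elevated without a site, sited without
elevation, elevated in the wrong direction).  All randomness flows from
one seed through per-stage generators, so a fixed configuration is
byte-reproducible.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: overdispersed biological replicate variation
beyond binomial/log-normal noise, correlated events within a gene,
realistic base composition and repeat structure, mapping ambiguity in
junction counts, batch effects, and genome-scale multiple-testing burdens.
Recovery rates near 100 % reflect planted effect sizes chosen to be
detectable at depth 200 with five samples per group, not expected
real-data performance.

## Problem sizes and numerics

Default problem sizes (40 genes / ~42 events, depth 200, 10 000 posterior
draws, 10 000 permutations, 12 000 exons in the frame-null annotation)
keep the full test suite and the acceptance script in the tens of seconds
on one CPU while leaving Monte-Carlo errors an order of magnitude below
every decision boundary.  Ties and degenerate cases are fixed by
convention and tested: strict inequalities at both filter cutoffs,
ss-adjacency resolved to the nearer exon edge (left on ties), rescue
grouping in genomic order, capped log2 enrichment sentinels, and
permutation p-values of the form (k + 1)/(N + 1).
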