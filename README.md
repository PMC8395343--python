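# splicescope

Downstream alternative-splicing analysis for two-group bulk RNA-seq, built
around the comparison of pancreatic-islet transcriptomes from two obese
mouse strains that differ in diabetes susceptibility (five animals per
group).  Starting from per-event inclusion/exclusion junction counts, a
gene annotation, a genome, a strain VCF and expression matrices, the
package quantifies splicing changes and annotates their likely causes and
consequences:

* **PSI/ΔPSI event calling.**  For each alternative segment (cassette exon
  CE, retained intron IR, alternative 5′/3′ splice site) the percent
  spliced in is the pooled-count ratio Ψ = Σinc / (Σinc + Σexc) per group,
  ΔΨ = Ψ₁ − Ψ₂.  Confidence comes from a Monte-Carlo posterior under
  independent per-group Beta(Σinc + ½, Σexc + ½) posteriors (Jeffreys
  prior): the probability that Ψ₁ − Ψ₂ has the sign of the point estimate.
  Events pass the filter when |ΔΨ| > 0.1 and probability > 0.9, and are
  labelled strong/moderate inclusion/exclusion around |ΔΨ| = 0.5.
* **Frame consequences.**  CDS cassette exons preserve the reading frame
  when skipped iff length ≡ 0 (mod 3); frameshifting exons of one gene can
  rescue the frame when co-skipped in the same direction with summed
  length ≡ 0 (mod 3).  The observed frameshift rate is tested (exact
  binomial) against the random-skipping null — the fraction of internal
  CDS exons with length ≢ 0 (mod 3), ≈ 66 % for a typical annotation.
* **Microexons** (internal exons of 3–30 nt) and the inclusion of a
  supplied target-exon list, correlated per sample with the expression of
  a splicing factor (SRRM4-like) via Spearman rank correlation with a
  permutation p-value.
* **Splice-regulatory SNPs.**  Each SNP is positionally classified
  relative to an alternative exon (splice-site-adjacent within 15 nt,
  intronic 15–500 nt up/downstream in transcript orientation, exonic
  interior, outside), densities are normalised per 1000 nt and compared
  with the genome-wide density by a 2×2 χ² test; splice-site SNP genes are
  flagged and CpG-destroying substitutions counted.
* **RBP motifs.**  Degenerate IUPAC k-mer motifs are scanned in exons and
  250-nt intronic flanks (sense strand); event-level presence is compared
  between inclusion-up and background events (Fisher exact, BH-adjusted),
  and SNPs are called as motif-disrupting or motif-creating.
* **miRNA targeting.**  Differential miRNAs (Welch t-test on log2 values)
  are matched against a 3′UTR by canonical seed classes (6mer, 7mer-A1,
  7mer-m8, 8mer) to rank candidate silencers of a splicing factor.

Because a study like this cannot be reproduced at desk scale without the
raw sequencing data, the package ships a first-class synthetic-study
generator (`splicescope.synthetic_data`) that emits a toy genome,
annotation, junction counts, VCF, expression matrices and motif file in
exactly the formats the pipeline reads — with truth tables recording every
planted PSI value, SNP category, motif effect and expression effect, so
every stage is testable end to end.

## Worked example

Quantify one cassette exon from junction counts of five samples per group
(`(inclusion, exclusion)` pairs):

```python
from splicescope import delta_psi, classify_event, dpsi_probability, estimate_psi

g1 = [(123, 77), (98, 102), (110, 90), (131, 69), (102, 98)]
g2 = [(41, 159), (38, 162), (52, 148), (44, 156), (49, 151)]
psi1, psi2 = estimate_psi(g1), estimate_psi(g2)
d = delta_psi(psi1, psi2)
prob = dpsi_probability(g1, g2, seed=0)
sig, cat = classify_event(d, prob)
print(f"PSI group1 = {psi1:.3f}, PSI group2 = {psi2:.3f}")
print(f"dPSI = {d:+.3f}, probability = {prob:.3f}")
print(f"significant = {sig}, category = {cat!r}")
```

prints

```
PSI group1 = 0.564, PSI group2 = 0.224
dPSI = +0.340, probability = 1.000
significant = True, category = 'moderate inclusion'
```

i.e. the exon is included in 56 % of transcripts in group 1 but only 22 %
in group 2; the +0.34 shift clears both filter cutoffs and lands in the
moderate-inclusion band (|ΔΨ| < 0.5).

The same analysis end to end on a synthetic study:

```bash
splicescope simulate --seed 11 demo_bundle
splicescope run-all --bundle demo_bundle --seed 11 demo_out
```

```
load: ok (42 events, 10 samples)
quantify: ok
consequence: ok
microexon: ok
snps: ok (102 SNPs)
motifs: ok
mirna: ok
diffexp: ok
```

`demo_out/events.tsv` then holds one row per event:

```
event_id  gene  type  psi_g1  psi_g2  delta_psi  probability  significant  category
g001.e1   g001  CE    0.14    0.901   -0.761     1            True         strong exclusion
g002.e1   g002  CE    0.151   0.902   -0.751     1            True         strong exclusion
```

and `demo_out/frame_summary.json` reports the frame breakdown of the
significant CDS cassette exons together with the annotation's
random-skipping null (0.669 here) and the exact binomial p-value of the
departure from it.  Further outputs: per-event SNP counts mirroring the
five positional categories, the SNP-density χ² enrichment, splice-site SNP
gene and CpG-loss tables, motif enrichment/effect tables, differential
miRNAs with seed-site classes, and the GWAS-gene overlap — all listed with
row counts in `demo_out/manifest.json`.

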