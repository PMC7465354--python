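# sdrscan

Toolkit for mapping and characterising the **sex-determination region (SDR)**
of a dioecious plant genome from population resequencing data, and for dating
and describing the repeat structures found inside it.

It is aimed at population/evolutionary genomicists who have (i) a VCF of
biallelic SNPs for a sexed cohort, (ii) per-sex pooled coverage tables, and
(iii) contig sequences, and who want a tested, scriptable version of the
classic SDR-mapping recipe:

1. **Sex association** — GATK-style hard filtering
   (`AF < 0.01 || AF > 0.99 || QD < 10 || ExcessHet > 20 || FS > 10 || MQ < 58`),
   a minor-allele-frequency floor (MAF > 0.05), a two-sided Fisher exact test
   on the 2×2 sex × allele table of each SNP (the plink allelic convention:
   each called diploid genotype contributes two allele observations), and a
   Bonferroni familywise cutoff α/n. For n = 4,586,112 tests at α = 0.05 the
   cutoff is 1.09×10⁻⁸. Significant SNPs are clustered into candidate SDR
   intervals.
2. **Hemizygosity scan** — median read depth of 1-kb windows per sex cohort;
   windows with total median depth ≥ 400 are classified by
   log₂((F+1)/(M+1)): < −1 male-biased (Y-hemizygous under XY), > +1
   female-biased; runs of biased windows become sex-specific regions.
3. **Genotype configurations & heterogamety** — each sex-associated marker is
   classed as XY-linked (females homozygous, males uniformly heterozygous),
   ZW-linked (mirror), female-null (hemizygous male-specific sequence: the
   marker fails to genotype in females), male-null, or unlinked; a majority
   vote infers XY vs ZW and the marker span estimates the SDR.
4. **LTR insertion dating** — the 5′ and 3′ terminal repeats of a
   retrotransposon are globally aligned; the substitution proportion d over
   ungapped columns, with a 1000-replicate column bootstrap SE, converts to
   insertion age t = d/μ (default μ = 2.5×10⁻⁹ site⁻¹ yr⁻¹; the independent
   two-lineage convention t = d/2μ is a flag). 33.95 substitutions/kb dates
   an insertion at 13.6 Myr.
5. **Repeat structure** — telomeric arrays: maximal (TTTAGGG)ₙ/(CCCTAAA)ₙ
   chains with ≥ 1000 bp of motif; inverted repeats: shared k-mer
   self-dotplot (k = 15), anti-diagonal chaining of reverse-complement
   matches into arm pairs, global re-alignment, percent identity over all
   alignment columns.
6. **Divergence & phylogeny** — Nei–Gojobori (NG86) dS/dN with
   Jukes–Cantor correction and a dS > 0.5 ortholog filter; Kimura
   2-parameter distances d = −½·ln((1−2P−Q)√(1−2Q)), optionally with
   Γ-distributed rate variation; Saitou–Nei neighbor-joining with
   column-bootstrap supports.

A seeded synthetic-data module generates every input with the statistical
structure the analysis assumes (balanced 100♀+100♂ cohorts at ~11× per
sample, a 115-kb XY-configured SDR containing a 45-kb male-specific core,
Hardy–Weinberg autosomal background, diverged LTR pairs, telomere arrays, a
five-arm inverted-repeat cluster), so the whole pipeline is testable
end-to-end against known ground truth.

## Worked example

```bash
sdrscan run --out run1 --seed 1
```

runs simulation → association → depth scan → genotype configuration → LTR
dating → telomere/IR scan → dS/dN → phylogeny and prints `run1/report.txt`:

```
Inferred heterogamety system: XY
Marker class counts: {'unlinked': 5020, 'xy_linked': 175, 'female_null': 112}
SDR span estimate: chrSDR:40201-154601

Association: 175 significant SNPs of 4101 tested (Bonferroni 1.22e-05)
  candidate SDR cluster chrSDR:40201-154601: 175 SNPs, min p = 2.52e-39

Depth scan: 45 male-biased windows of 200
  male_biased region chrSDR:60001-105000 (45 windows, mean log2 ratio -5.596)

Oldest LTR insertion: 14.96 ± 0.75 (SE) Myr

Telomeric array ir_contig:20579-28376: 1114 x TTTAGGG (7798 bp)
Inverted-repeat arm pairs: 6 (identity % [92.9, 93.2, 93.2, 93.8, 93.3, 92.3])

Ground-truth comparison:
  system_correct: True
  sdr_start_error_bp: 200
  sdr_end_error_bp: 399
  core_start_error_bp: 0
  core_end_error_bp: 0
```

Reading: the 175 fully sex-linked markers (females homozygous, males
heterozygous) plus 112 female-null markers vote for an XY system; their span
recovers the planted 115-kb SDR to within 400 bp, and the depth scan recovers
the planted 45-kb male-specific core exactly to the window. The Bonferroni
cutoff is α divided by the 4101 SNPs actually tested at this simulation
scale. The oldest simulated LTR (planted at 13.58 Myr under t = d/μ) is dated
at 14.96 ± 0.75 Myr, within two bootstrap SEs of truth. The five planted
inverted-repeat arms are recovered in six arm pairs (partial homologies
between non-adjacent arms are real pairs, as in published IR clusters) at
≈ 93.3 % identity.

Each stage is also available separately (`sdrscan simulate / assoc /
depthscan / config / ltrage / telomere / irscan / dnds / phylo`) on standard
formats (VCF v4.2, samtools-depth TSV, FASTA, BED, newick). Report tables
are 1-based inclusive; BED output is 0-based half-open.

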