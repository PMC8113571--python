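# ssrscape

Genome-wide discovery of **polymorphic SSR (microsatellite) markers** from a
reference genome plus whole-genome resequencing of multiple accessions —
the in-silico alternative to wet-lab polymorphism screening used in crop
marker development (the motivating system is spinach, *Spinacia oleracea*,
with its six-chromosome Sp75 reference and a 21-accession 30× panel).

The pipeline:

1. **Mine** perfect di- to hexanucleotide SSRs from the reference under
   minimum repeat counts (6, 5, 4, 4, 4 for unit lengths 2–6).
2. **Filter** candidates: primer-designable flanks (product 100–400 bp,
   Tm 60 °C in 59–61 °C, GC ≥ 40%, primer 18–25 nt), drop A/T-only motifs,
   drop loci less than 100 bp apart; extract 250 bp flanks.
3. **Genotype in silico**: for every locus and accession, spanning reads are
   reduced to an observed repeat count by CIGAR arithmetic, and a diploid
   genotype (a₁, a₂) is called by maximum a-posteriori under a symmetric
   geometric stutter model

   P(k | a) = 1 − pₛ if k = a, else pₛ(1 − ρ)ρ^{|k−a|−1}/2,

   with per-read mixture P(k | a₁, a₂) = ½P(k|a₁) + ½P(k|a₂). Calls are
   screened with `min-call-qual 0.9`, `max-call-flank-indel 0.15`,
   `max-call-stutter 0.15`.
4. **Screen** the panel: drop loci monomorphic or missing in all accessions
   and loci whose non-reference allele appears in fewer than two accessions;
   keep the rest as polymorphic markers; annotate genic/intergenic against a
   GFF3; write a stage-by-stage filter ledger.
5. **Characterize** markers from binary (1/0) band scores: number of alleles
   Na, expected heterozygosity He = 1 − Σpᵢ², polymorphism information
   content PIC = 1 − Σpᵢ² − Σᵢ<ⱼ2pᵢ²pⱼ², PCA, Jaccard distances, a
   neighbor-joining tree (Newick) and a STRUCTURE-format export.

A fully deterministic **synthetic-data generator** (`ssrscape.simdata`)
plants known SSR loci, diploid genotypes and stutter-noised pre-aligned
reads, so every stage is verified against ground truth at desk scale.

## Worked example

Run the whole pipeline on a small simulated panel (1 × 20 kb chromosome,
5 planted loci, 4 accessions, 60% of loci polymorphic):

```bash
cat > demo.yaml <<'EOF'
seed: 0
sim:
  n_chrom: 1
  chrom_len: 20000
  n_loci_per_chrom: 5
  n_accessions: 4
  polymorphic_fraction: 0.6
EOF
ssrscape all --config demo.yaml --out demo_run
```

which logs one line per stage:

```
[ssrscape] stage=simulate loci=5 accessions=4
[ssrscape] stage=mine mined=5
[ssrscape] stage=design input=5 kept=5
[ssrscape] stage=at_filter input=5 kept=5 removed=0
[ssrscape] stage=proximity input=5 kept=5 removed=0
[ssrscape] stage=genotype loci=5 called=5
[ssrscape] stage=screen input=5 kept=4 mono_or_missing=1 low_nonref=0
[ssrscape] stage=annotate genic_fraction=0.25
[ssrscape] stage=stats loci=4 mean_he=0.5472 mean_pic=0.4564
```

All five planted loci are mined and primer-designable; one locus happened to
be drawn monomorphic and is removed by the screen; the four polymorphic
markers get Na/He/PIC statistics (`demo_run/marker_stats.tsv`):

```
locus	Na	He	PIC
chr01_3_4264	3.0	0.65	0.58
chr01_6_8264	2.0	0.44	0.35
chr01_2_12261	2.0	0.48	0.36
chr01_2_16294	3.0	0.61	0.54
Mean	2.5	0.55	0.46
```

`demo_run/` also contains the mined and pursued BED files, the per-call VCF
(`calls.vcf`, full-tract REF/ALT alleles), the conservation-checked
`ledger.tsv`, the marker catalog with primers and flanks, a neighbor-joining
tree (`nj.nwk`) and a STRUCTURE input file.

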