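# Methods

This note documents the models, conventions and numerical choices behind
`ssrscape`, and what the synthetic-data tests do and do not demonstrate.

## SSR mining

A locus is a **maximal perfect tandem repeat** of a primitive motif of
length 2–6 (a motif is primitive when it is not itself a tandem of a
shorter word; this is what prevents (AT)₆ from also being reported as
(ATAT)₃, and excludes mononucleotide runs entirely). Minimum repeat counts
are 6 (di), 5 (tri) and 4 (tetra/penta/hexa); all are configurable.

*Maximality convention.* Detection works on the character-level periodicity
track `s[i] == s[i+u]`: a run is a maximal interval of period `u`, and the
reported tract is the **leftmost whole-unit tiling**, `floor(len/u)` units
from the interval's left edge. This resolves an ambiguity of unit-level
maximality: in `GTATATATAC` the phase-shifted candidates (TA)₄ at offset 1
and (AT)₃ at offset 2 lie in one periodic interval, and only the leftmost
tiling is reported. Runs touching an `N` are broken at the `N`. The rare
case of overlapping candidates at *different* unit lengths (possible in
principle, made unlikely by the thresholds) is resolved greedily by
`(start, unit_len)`. The unit tests and the acceptance suite compare the
production detector against an independently written quadratic scanner on
repeat-salted random sequences.

*Filters.* The A/T-only filter removes loci whose motif alphabet is a
subset of {A, T} (hard to score on gels). The proximity filter removes
**both** members of every same-chromosome pair separated by less than
`min_gap` (default 100 bp), evaluated on the original locus list, so a
locus with any close neighbor is removed. Whether only one member of a
close pair should survive is genuinely underdetermined by the marker-
development practice this mirrors; removing both is the conservative
choice and is configurable.

*Summaries.* Densities are loci per megabase rounded half-up to 1 decimal;
motif-class shares are percentages rounded half-up to 2 decimals. Full
precision is kept internally.

## Primer feasibility

The designer is a deterministic feasibility oracle, not a thermodynamic
simulator. Melting temperature uses the composition formula
`Tm = 64.9 + 41(nGC − 16.4)/N`, which is monotone in GC count at fixed
length — sufficient to rank candidates and to reproduce the *decision
structure* (designable vs not) that drives the locus cascade. Constraints:
product 100–400 bp spanning the full tract, Tm within 59–61 °C (optimum
60), GC ≥ 0.40, length 18–25 nt (optimum 20). Two cheap secondary-structure
guards reject primers with a homopolymer run ≥ 5 and pairs whose 3′-terminal
4-mers are mutually complementary (M13-tailed primers are prone to such
artifacts). Among admissible pairs the scan minimizes summed |Tm − 60|,
then summed |len − 20|, then product length, then positions — so identical
inputs always return the identical pair. The M13 tail
`CACGACGTTGTAAAACGAC` is prepended to forward primers for fluorescent
genotyping.

## Stutter model and genotype calling

Per-read repeat counts come from CIGAR arithmetic: observed tract length =
reference tract span + (inserted − deleted bases whose reference position
falls inside the tract); a change that is not a whole-unit multiple marks
the read off-frame. A read is *spanning* when its alignment covers the
tract plus `anchor_bp` (default 10) on both sides; any indel touching the
two anchor windows flags the read `flank_indel`.

The stutter likelihood is a global symmetric geometric model with per-read
stutter probability `p_s` (default 0.05) and decay `rho` (default 0.8):
`P(k|a) = 1 − p_s` for `k = a`, else `p_s(1 − rho)rho^{|k−a|−1}/2`. The
defaults are in the range reported for Illumina STR stutter and are
deliberately a *stand-in* for locus-specific learned models: the goal is a
fully specified, reproducible decision procedure with the same filter
structure, not a re-estimate of any particular dataset's error profile.

Calling: candidate alleles are the distinct in-frame observed counts plus
the reference count; the genotype space is all unordered pairs under a
uniform prior; quality is the posterior of the MAP genotype (the test suite
checks the MAP against full enumeration and that posteriors sum to 1).
Ties break toward the pair containing the reference allele, then
lexicographically. A call is MISSING with a reason when spanning reads < 5
(`no_reads`; the threshold is mild at 30× and configurable), posterior <
0.9 (`low_qual`), flank-indel fraction > 0.15 (`flank_indel`), or the
fraction of usable reads not matching either called allele (off-frame
reads included) > 0.15 (`stutter`). Reasons are evaluated in that order.
Reads are taken at face value; no local realignment is attempted.

## Polymorphism screen and ledger

A locus is removed as `mono_or_missing` when every non-missing call is
homozygous reference or every call is missing ("missing in all
accessions" is the operational reading; a stricter missing-rate cut can be
layered on). Otherwise it is removed as `low_nonref` when fewer than
`min_nonref_accessions` (default 2) accessions carry at least one
non-reference allele — a heterozygous (ref, alt) call counts as carrying.
The remainder is the polymorphic catalog (allele count ≥ 2 is asserted at
catalog build). The FilterLedger enforces `kept + removed = input` at every
stage and stage-chaining on **every** pipeline run, not only in tests.
Genic annotation converts GFF3 1-based inclusive intervals to 0-based
half-open and flags any ≥ 1 bp overlap.

## Diversity statistics

Dominant 1/0 band scores cannot distinguish heterozygotes from homozygotes,
so allele frequencies are **band-share frequencies**: carriers of allele i
divided by total carrier count at the locus. On these, He = 1 − Σpᵢ² and
PIC = 1 − Σpᵢ² − Σᵢ<ⱼ2pᵢ²pⱼ² (the Botstein convention); 0 ≤ PIC ≤ He < 1
with equality only for monomorphic loci (property-tested on 10⁴ simplex
draws). Report tables round half-up to 2 decimals; computation is full
precision. PCA mean-imputes missing marks per column, centres, and uses
SVD with a deterministic sign convention (largest-magnitude loading
positive). Accession distances are Jaccard on the binary scores — a
nucleotide-substitution model is not applicable to band data, so no
sequence-evolution distance is offered. The neighbor-joining implementation
is standard Saitou–Nei with smallest-index tie-breaking and negative branch
lengths clamped to zero; it recovers additive matrices exactly and is
cross-checked against scikit-bio's implementation in the tests. STRUCTURE
export writes one row per accession with −9 for missing.

## Synthetic data generator

The generator emulates the study design the pipeline targets: a
multi-chromosome uniform-ACGT background with planted primitive,
non-A/T-only SSR tracts (unit-length mix weighted 41/31/14/9/5% for di–hexa,
like a plant genome survey), 21 diploid accessions, ~31% of loci
polymorphic (alt alleles at ref ± 1–3 units, at least two carrier
accessions guaranteed by redraw), 30× single-end 150 nt reads, stutter
`p_s = 0.05, rho = 0.8`, substitution rate 10⁻³ outside the tract-plus-
anchor window. Everything derives from one `numpy` Generator seed;
outputs are byte-identical across runs.

Design choices that make truth exact:

- the background is **rejection-screened**: any mined locus that was not
  planted has its (non-planted) bases re-randomized until mining returns
  exactly the planted set, so planted-recovery tests assert equality, not
  approximation;
- planted tract boundaries are fixed so the repeat cannot extend by one
  base in either direction;
- reads are emitted **pre-aligned** with correct POS/CIGAR (the tract
  length change appears as one I/D placed one unit into the tract), which
  keeps external aligners out of the test loop while still exercising the
  genotyper's CIGAR arithmetic; reads whose placement would require
  clipping inside a length-changed tract are not emitted (they would be
  non-spanning and uninformative);
- reads are single-end with FLAG 0; mates are not simulated because only
  spanning reads inform repeat-count genotyping.

*What passing tests show — and don't.* The simulator demonstrates correct
bookkeeping and calibrated behavior of the calling machinery under its own
noise model (concordance ≥ 99% at 30×/p_s 0.05 over ≥ 1000 locus×accession
cells; exact recovery with noise off; monotone degradation in p_s). Real
data add locus-specific stutter, alignment artifacts, coverage bias,
duplicates and imperfect repeats, none of which are modeled; results on
real panels depend on the upstream aligner and on how well the global
stutter parameters match the instrument.

## Problem sizes and published-surface checks

The bundled survey tables (per-chromosome counts, the per-motif-class
filter cascade, the 36-marker validation panel) let the accounting and
diversity arithmetic be checked against a real published surface: densities
(e.g. 5,200 loci on a 50.66 Mb chromosome → 102.6/Mb), the cascade
endpoints 19,397 pursued and 5,986 polymorphic, the 94.4% amplification
rate and the panel means He 0.40 / PIC 0.25. The genome-scale counts
themselves are not desk-reproducible (they require the full reference and
read set), so synthetic runs use 2 × 80 kb chromosomes with 50 planted
loci and 21 accessions — large enough for ≥ 1000 genotype cells and stable
rate estimates, small enough to run in seconds. The cascade table's
called-locus total (16,179) is used where the running text of the source
survey disagrees with its own table, because only the table value is
consistent with the downstream arithmetic.
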