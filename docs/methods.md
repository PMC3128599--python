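# Methods

## Consensus-homozygosity scan

The scan targets recessive loci shared identically by descent among
affected relatives. For each SNP the affected group's genotype classes
(homA / het / homB / no-call) are tallied; frequencies divide by the called
count only, so missing genotypes never dilute the signal. A SNP is
**consensus homozygous** when the top genotype frequency equals exactly 1
and the top genotype is a homozygote. The run finder then extracts maximal
stretches of consecutive consensus SNPs along the contiguous map index and
keeps those whose informative-SNP count clears the threshold.

Conventions where the procedure is underdetermined:

- **Threshold semantics.** The default is *strict*: a run needs more than
  `min_snps` (default 10) informative SNPs, i.e. at least 11. A `strict`
  flag switches to at-least semantics, since "at least 10 consecutive
  SNPs" is the other defensible reading of the same rule of thumb; both
  are exposed in the library and the CLI.
- **Uninformative SNPs** (no calls at all in the group) neither break a
  run nor count toward the threshold: a locus with no data cannot refute
  homozygosity. Run boundaries are trimmed to informative SNPs, so
  boundary SNPs are always consensus calls.
- **Allele switches** (consensus homA at one SNP, homB at the next) do not
  break a run: the criterion is per-SNP homozygosity of the group, not a
  shared allele along a haplotype. A/B coding is taken as-is; the
  algorithm never needs strand or allele identity, only
  homozygous/heterozygous state.
- **Carrier filter** is region-level: a run fails only when the carrier
  group is consensus-homozygous for the *identical* allele at every
  informative SNP of the run. Runs failing the check are reported with
  `carrier_pass=False` rather than silently discarded; with no carriers the
  verdict is undetermined. The normal group is never used by the scan.
- **Ordering.** "Largest" means SNP count first, then bp span, then
  genomic order.
- **QC.** SNPs survive chip QC when call rate is strictly above 0.80 and
  the GenTrain cluster-quality score is at least 0.25 (both configurable);
  no minor-allele-frequency filter is applied, since fixed autozygous
  regions are precisely the low-MAF signal of interest. Contiguity is
  defined over the retained, re-indexed SNPs, the only reading under which
  "consecutive" is well defined after filtering. Whether QC metrics are
  computed per-cohort or taken from vendor plate-level summaries is left
  to the caller: `SnpQc` is supplied externally (or read from a GenTrain
  column of the report, with call rate computed from the cohort).

## Region reporting

Coordinates are 1-based inclusive throughout; BED input is converted from
0-based half-open on read. Spans are `(end − start + 1)/10⁶` rounded
half-up to two decimals. Gene overlap means at least one shared base pair —
no minimum-fraction rule. Separations between regions are computed from
boundary coordinates, never taken from any summary figure.

## Variant effects, digest and concordance

Translation uses the standard genetic code from position 1 and stops at the
first stop codon; a stop at the final codon is normal termination. Variant
classification maps (exon, offset) → transcript → CDS coordinate, so codon
number = ⌈cds_position / 3⌉; labels use one-letter amino acids with `X` for
a gained stop and `=` for synonymous changes.

The digest model cuts after base 4 of every `CATG` occurrence on the given
strand (NlaIII leaves 3′ overhangs at a palindromic site, so single-strand
scanning gives the same fragment lengths). Occurrences may overlap; all
are cut. Fragment lengths always sum to the amplicon length and number one
more than the cut sites — a cut flush with a sequence end contributes a
zero-length fragment to keep that invariant, a case engineered fixtures
never produce. A *band* is a distinct fragment length (equal lengths
co-migrate), so heterozygote bands are the union over the two allele
digests. The transcript-level (RT-PCR) digest is the same computation on
the spliced sequence; because the diagnostic amplicon lies entirely within
one exon, the two amplicons coincide here.

Concordance scores a genotype table against the fully penetrant recessive
model with risk allele T: affected ⇒ TT, obligate carrier ⇒ CT,
phenotypically normal (related or control) ⇒ not TT. Per-group rates are
reported separately (`None` for absent groups); the pooled rate divides by
every individual in the table.

## Two-locus LD

Haplotype frequencies come from the standard EM over the 3×3 genotype
grid: all cells except the double heterozygote contribute gametes
deterministically; the double heterozygote splits between cis (AB/ab) and
trans (Ab/aB) phase in proportion to current haplotype-frequency products.
Initialization is at linkage equilibrium from the observed allele
frequencies, making the estimate deterministic; convergence is a maximum
frequency change below 1e-8 (default, capped at 1000 iterations). D′ and
r² follow the usual definitions; monomorphic loci yield an explicitly
undefined result (NaN, flagged) rather than 0. Individuals missing either
locus of a pair are dropped pairwise, matching common Haploview behaviour —
a convention, not a requirement of the estimator. Text output rounds D′/r²
to two decimals.

## Synthetic cohort generator

The generator emulates the study design rather than a generic population:

- **Map**: 54,241 SNPs over 27 chromosomes with approximately realistic
  length proportions, spacing jittered uniform around the mean (the real
  chip's spacing distribution is not modelled).
- **Pedigree**: a carrier ram outcrossed to unrelated ewes (F1) and F1
  daughters backcrossed to the ram (F2). Affected animals are F2 backcross
  offspring; the genotyped carrier group is the ram plus carrier F1
  daughters. The 24 phenotypically normal relatives (F1 lambs and non-TT
  F2 lambs) and the 46 unrelated controls exist only as causal-locus
  genotypes for the concordance table — they were not array-genotyped in
  the study either. Unconstrained backcross draws that come out TT are
  recorded (for segregation checks, which confirm ≈50% carriers among F2)
  and reclassified as affected rather than kept as "normal".
- **Genotypes** arise by gene-dropping founder haplotypes (per-SNP
  Bernoulli at a MAF drawn uniform on (0.05, 0.5), minor allele assigned
  to A or B at random) with Poisson crossovers at 0.01 Morgan/Mb. On
  causal-lineage meioses the gamete is constrained to copy the
  causal-haplotype-bearing parental chromosome exactly over each planted
  segment, with the implied breakpoints in the flanking inter-SNP gaps.
  Every transmitted haplotype is therefore a genuine mosaic of its
  parent's two chromosomes (Mendelian consistency is a tested invariant)
  while the planted segments are exact at the haplotype level.
- **Planted truth**: three segments of 125, 19 and 11 SNPs (two on
  chromosome 6, one on 15), anchored at the study's coordinates; the
  causal SNP sits inside the largest at ~112.2 Mb, risk allele private to
  the ram's haplotype. Carriers carry exactly one causal-haplotype copy
  across segment 1; their state in segments 2–3 is left to inheritance.
- **Noise**: per-cell no-calls at 1%; per-SNP QC metadata with ~1% forced
  GenTrain failures placed outside the planted segments (and a 2-SNP
  flank) so the planted truth is invariant under QC filtering.
- **Determinism**: one master generator seeded from `SimConfig.seed`
  drives every stream; identical seeds give byte-identical cohorts.

What the generator does **not** reproduce: coalescent-realistic background
LD (off-segment SNPs are exchangeable given the pedigree), X-linked
inheritance, genotype-intensity artefacts, and the real chip's allele
frequency spectrum. Consequently, recovery tests demonstrate correctness of
the scan's logic under the study design, not its false-positive behaviour
on populations with strong background LD.

A consequence of finite case groups (in real data as much as here): a
recovered run can extend a SNP or two beyond the planted segment wherever
the flanking genotypes coincide by state, even with zero no-calls. The
recovery criterion therefore allows ±2 SNPs per boundary; across 50
full-scale replicates the three planted segments are recovered within that
slack in ≥95% of cohorts (no-calls, by contrast, can never shorten a run,
and that is asserted exactly).

## Gene and amplicon fixture

The six-exon gene fixture is built so that every published arithmetical
fact is mutually consistent: exons 1–5 contribute 183 coding nt and exon 6
the remaining 1,341 nt of the 1,524-nt ORF (87.99% ≈ 88% of the open
reading frame), so exon-6 offset 250 is CDS position 433 = codon 145,
which carries CGA (arginine); the C→T transition gives TGA, the R145X stop,
and a 144-residue product. Introns of ~2.9 kb put the locus above 16 kb.
The 250-bp amplicon lies within exon 6 and carries one constitutive CATG
plus the variant site, where codon 144 (GCA) followed by codon 145 (CGA)
means the T allele creates C-A-T-G across the codon boundary; background
codons are sampled stop-free per seed and any stray CATG (on either allele)
is repaired deterministically, keeping all fragment lengths distinct
(54/196 for the C allele, 54/67/129 for T ⇒ 2, 3 and 4 bands for CC, TT
and CT).

## Problem sizes

Default test and acceptance runs use the full study scale (54,241 SNPs, 20
chip samples, 50 replicate cohorts for recovery statistics); unit tests
use a 4,000-SNP cohort with proportionally placed segments, which exercises
identical code paths. Oracle checks run brute-force enumeration at small
n: exhaustive window enumeration for the run finder (sequences ≤ 60), a
1e-4 grid search over the cis-haplotype frequency for the EM, and direct
occurrence counting for the digest.
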