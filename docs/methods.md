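# Methods

## Scope and model

`bequant` quantifies the outcomes of CRISPR base editing in early embryos
and screens for off-target consequences at the whole-genome level. It
covers five stages:

1. **Editor and coordinate model.** A base editor is described by its
   chemistry (C→T for cytosine base editors, A→G for adenine base
   editors), a closed activity window in 1-based protospacer coordinates
   (position 1 is the PAM-distal spacer base), a degenerate IUPAC PAM
   pattern required 3′ of the spacer, and a spacer length. The registry
   ships BE3 and BE4-Gam (C→T, window 4–8, NGG, 20 nt), ABE7.10 (A→G,
   window 4–7, NGG, 20 nt) and SaKKH-BE3 (C→T, window 3–12). For
   SaKKH-BE3 we use the field-standard SaCas9-KKH parameters — PAM NNNRRT
   and a 21-nt spacer — as its own registry defaults; both are plain
   constructor arguments for user-defined editors. Substrate bases
   *outside* the window are tracked too (flagged out-of-window), because
   bystander conversions at flanking positions are a real and reported
   phenomenon; nothing about out-of-window scoring is guessed — in- and
   out-of-window conversions are simply both recorded.

2. **Clone genotyping.** Each sequenced clone is globally aligned to the
   reference amplicon (match +2, mismatch −3, gap open −8, gap extend
   −1, via Biopython's `PairwiseAligner`), gap runs are left-normalized
   to make indel coordinates deterministic, and the bases at all
   protospacer positions are read off — reverse-complemented for
   minus-strand sites so conversions always report on the protospacer
   strand as C→T / A→G. Categories: `indel` (any insertion/deletion
   overlapping the spacer ± a 5-bp margin; takes precedence) > `mixed` >
   `unintended` (any non-product substitution in the spacer) >
   `intended` (≥1 substrate→product conversion, nothing else) > `WT`.
   Substitutions outside the spacer ± margin never change the category;
   clones with more than `max_background_mismatches` (default 5) of
   them, or covering no spacer position, are uninformative and excluded
   from every denominator. Per-position frequencies use
   position-specific denominators (clones ungapped at that position);
   positions with no informative clone are reported as missing, never
   as 0. Indel clones count in the indel-frequency denominator (all
   informative clones) — a convention chosen explicitly because indel
   and conversion tallies are reported separately.

3. **Embryo and blastomere summaries.** An embryo is `edited` if any
   informative clone is non-WT, `fully_converted` if some in-window
   editable position has intended frequency 1.0, and `mosaic` if ≥2
   distinct allele strings coexist among its clones. Experiment
   summaries count edited embryos over analyzed (edited %), indels and
   intended conversions over edited embryos, 100 %-conversion embryos
   over intended-conversion embryos, multiplex tiers (number of sites
   with ≥1 intended conversion) over edited embryos, and "100 % tier-k"
   over the tier-k embryos themselves. These denominators were chosen to
   be internally consistent and are asserted against worked numeric
   examples in the tests. Percentages round to one decimal, half away
   from zero. Blastomere zygosity comes from clone counts, not read
   depth: hom-edited = all informative clones intended, het-edited =
   intended and WT clones both observed (≥1 each; the minimum clone
   count per allele is configurable), `uninformative` below `min_clones`
   (default 3) informative clones. With few clones, hom calls are upper
   bounds — an inherent limit of clone-count zygosity. Blastomere pie
   categories are exclusive with precedence multiplex > single-site >
   indel > unintended > WT.

4. **Trio de novo refinement.** Bi-allelic candidates (multi-allelic
   records are split; an allele belonging to a different alternate is
   kept as a sentinel so Mendelian logic still sees it) pass, in order:
   class-specific hard filters (SNVs: QD < 2.0, FS > 60, MQ < 40,
   MQRankSum < −12.5, ReadPosRankSum < −8.0, QUAL < 100; indels:
   QD < 2.0, FS > 200, ReadPosRankSum < −20, QUAL < 100 — all strict
   inequalities; a missing annotation never fails a clause by itself but
   is counted), a density filter removing every variant that shares any
   100-bp window with ≥4 others (applied after the hard filters; the
   alternative order is not documented upstream, so the implemented
   order is asserted by a test), a Mendelian rule (the fetus carries the
   focal alternate or the reference allele while neither parent does)
   gated on GQ ≥ 30 in all three samples, and a pileup refinement: raw
   read depth ≥ 20 in all samples (raw pileup counts govern, not
   FORMAT/DP), zero reads supporting the disallowed allele in either
   parent, and fetal allele balance in [0.3, 0.7] — bounds inclusive, a
   choice asserted by a boundary test. Only autosomes are expected; a
   chromosome allow-list enforces this when configured.

5. **Off-target scan and spectrum excess.** The scanner enumerates every
   position on both strands where the PAM pattern matches and the spacer
   Hamming distance is ≤ `max_mismatch`; no bulge modelling (documented
   scope — candidate lists from standard predictors are mismatch-only in
   their default modes). The expected substitution spectrum multiplies
   the total de novo SNV count by reference class fractions (an input
   TSV, never a download); the excess is observed − expected per class,
   with the cytosine-deamination-relevant summary being the C>T plus
   G>A excess. Classes default to all 12 reference-strand pairs because
   C>T and G>A must stay separate; a pyrimidine-collapsed 6-class view
   exists for comparison. (Reference catalogues are sometimes published
   with 9 substitution categories, which matches neither 12 unstranded
   nor 6 collapsed classes; the class set is therefore configurable
   rather than hard-coded, and the discrepancy is left documented.)

## Synthetic data: what it emulates, and what it does not

The generators produce every input with known ground truth:

- **Amplicons/sites**: random sequence with one planted spacer+PAM and a
  requested number of substrate bases forced into the window; placement
  is resampled until the protospacer is unique.
- **Embryo clones**: a zygotic pool of 2 alleles, each independently
  edited — per-position Bernoulli conversion at `intended_rate` in the
  window and `bystander_rate` outside it, plus unintended-substitution
  (`unintended_rate`) and deletion (`indel_rate`) events — then clones
  sampled from the pool with multiplicity noise and uniform sequencing
  errors (default 10⁻³/bp) to exercise the background-mismatch
  tolerance. The two-allele pool makes clone counts a *mixture* over
  allele states, which is the biology of a mosaic embryo but is not
  binomial in the editing rate; `allele_pool="per-clone"` draws an
  independent allele per clone for calibration studies where binomial
  sampling statistics are wanted (the parameter-recovery tests use this
  mode for exactly that reason).
- **Blastomeres**: a two-generation lineage (zygote → 2 cells); each
  branch carries its own allele pair, blastomeres alternate between
  branches, so sister blastomeres can share or differ in genotype —
  part-embryo editing and mosaicism emerge naturally. A
  `coediting_correlation` parameter couples editing across sites within
  an allele through a shared latent draw (1.0 = all-or-nothing multiplex
  editing, 0.0 = independent sites; the recovery test uses 0.0 because
  only there does a closed-form tier probability exist as an independent
  oracle).
- **Trios**: Mendelian-consistent inherited variants, planted de novos
  that pass every filter, and six artifact classes each violating
  exactly one filter (QUAL < 100, GQ < 30, pileup depth < 20, parental
  alternate reads, allele balance outside [0.3, 0.7], 5-in-100-bp
  clusters). Default table: 1,000 variants, 20 true de novos, 50
  artifacts. Positions are spaced ≥ 200 bp apart except inside planted
  clusters, so the density filter removes exactly its own artifacts.
- **Genomes**: planted off-target sites at specified mismatch counts and
  alternating strands, non-overlapping, PAMs realized from the
  degenerate pattern.

Everything is deterministic under `SimConfig.seed`, with independent
random streams per component (sequence, events, sampling, trio, genome).

What passing tests on these data do **not** show: performance on real
Sanger chromatograms (no trace noise or heterozygous peak calling), on
real WGS callsets (no mapping artefacts beyond the density model, no
systematic strand or context biases), or under PCR chimeras/allele
dropout in whole-genome-amplified single cells. The generators validate
the *accounting*, not the upstream measurement process.

## Numerical choices and degenerate inputs

- Alignment ties are resolved by left-normalizing gap runs (score-neutral
  shifts to the leftmost placement), making deletion coordinates
  deterministic; scores are verified against an independent affine-gap
  DP oracle in the tests.
- Frequencies with zero informative clones at a position are `None`
  (missing), and `site_frequencies` refuses clone sets with no
  informative clone at all.
- Percentage rounding is decimal-exact (half away from zero), not float
  `round`, to reproduce values like 19.4 and 94.9 stably.
- The exact binomial 99 % interval used in recovery tests is the central
  `[ppf(0.005), ppf(0.995)]` interval, which covers ≥ 99 % by
  construction; coverage thresholds are set at 98 %.
- Problem sizes in the test-suite and acceptance script (50-kb scan
  genomes, 1,000-variant trios over five seeds, 500 replicates of 50
  clones for rate recovery) were chosen as the smallest sizes at which
  the statistical properties are stable; all complete in a few minutes
  on one CPU.

## Known limitations

- Zygosity from clone counts saturates: with n clones, het alleles are
  missed with probability 2⁻ⁿ⁺¹ per site, so hom calls at low clone
  counts are soft.
- The Mendelian candidacy rule is the literal genotype + GQ ≥ 30 rule;
  posterior-probability-based "high confidence" de novo annotation from
  genotype-refinement workflows may differ at sites with marginal
  likelihoods.
- The density filter counts variants after hard filtering; counts from
  the raw callset would be slightly more aggressive.
- No bulge (gapped) off-target search, no specificity scoring; the
  scanner is exhaustive but purely mismatch-based.
- Clone pooling across independent PCRs of one embryo is treated as a
  single pool per embryo.
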