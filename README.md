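# bequant

Quantification of multiplex base-editing outcomes in embryos, and
trio-based screening for off-target mutations.

Base editors — cytosine base editors (CBE, C→T) and adenine base editors
(ABE, A→G) — install point mutations inside an editor-specific activity
window of the protospacer without double-strand breaks. Experiments that
inject editor mRNA and one or several sgRNAs into zygotes then need a
consistent accounting layer: which clones from a cloned PCR amplicon
carry intended conversions, unintended substitutions or indels; how
often each editable position converted; whether an embryo is fully
converted or mosaic; how many single blastomeres carry edits at all
targeted sites simultaneously (the single-cell multiplex efficiency);
and, genome-wide, which fetus variants are true de novo events and
whether they betray guide-dependent (off-target site overlap) or
guide-independent (C>T/G>A spectrum excess) editor activity. `bequant`
implements that accounting layer for analysts working in Python, plus
deterministic synthetic-data generators so every stage runs and is
testable without any external download.

## The statistics at the core

- Per-position conversion frequency: conversion-positive clones /
  informative clones at that position (position-specific denominators;
  indel frequency over all informative clones).
- Clone categories `WT / intended / unintended / mixed / indel` with
  indel precedence; embryo flags edited / fully-converted (some editable
  position at frequency 1.0) / mosaic (≥2 distinct allele strings).
- Multiplex tiers: number of sites with ≥1 intended conversion per
  embryo; blastomere zygosity from clone counts (hom = all clones
  edited, het = both alleles observed) and k-site single-cell editing
  rates.
- De novo cascade: class-specific hard filters (QD, FS, MQ, rank sums,
  QUAL) → 100-bp density filter (≥5 variants) → Mendelian rule with
  GQ ≥ 30 → pileup refinement (depth ≥ 20 everywhere, zero disallowed
  parental reads, fetal allele balance in [0.3, 0.7]).
- Off-target scan: exhaustive spacer-Hamming + degenerate-PAM search on
  both strands; spectrum excess: observed − expected class counts, with
  expected = total de novo SNVs × reference SNP class fraction.

## Worked example

```sh
python examples/single_site_editing.py
```

```
target FAH-sim: strand +, editable positions [(7, 'C'), (8, 'C')]
  E1|-|c1: intended  intended at (7, 8, 12, 13)
  E1|-|c2: intended  intended at (8, 13, 15)
  ...
per-position intended conversion frequency (edited / informative clones):
  C7: 0.33  (n=12)
  C8: 1.00  (n=12)
indel frequency: 0.00

embryo flags: edited=True, mosaic=True, fully_converted=True
```

Twelve simulated clones from one embryo, all carrying C→T conversions:
C8 converted in every clone (frequency 1.00 — the "100 % allele
frequency" outcome, so the embryo is flagged fully converted), C7 in a
third of them, with bystander conversions at out-of-window positions 12,
13 and 15 also recorded; two distinct allele strings coexist, so the
embryo is mosaic. The other examples cover blastomere genotyping and
multiplex rates (`multiplex_blastomeres.py`), the trio de novo cascade
with per-stage counts (`trio_denovo.py`), and off-target scanning plus
spectrum excess (`offtarget_scan.py`).

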