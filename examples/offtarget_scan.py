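"""Off-target site scanning and deaminase substitution-spectrum excess.

Plants mismatch off-target sites in a random genome, scans for them,
intersects them with a set of de novo calls, and estimates the
guide-independent cytosine-deaminase excess from an expected
substitution-class table.
"""

import bequant as bq

cfg = bq.SimConfig(seed=3, genome_len=100_000, planted_mismatches=(1, 1, 2, 2, 3, 3, 4))
genome, spacer, truth = bq.gen_genome_offtargets(cfg, "BE3")

sites = bq.scan_offtargets(genome, spacer, "NGG", max_mismatch=4)
print(f"scan found {len(sites)} candidate sites (planted: {len(truth)}):")
for s in sites:
    print(f"  {s.chrom}:{s.start}-{s.end} ({s.strand}) {s.n_mismatches} mismatches")

# intersect with the de novo calls of a synthetic trio (different genome,
# so use the trio's own chromosome space for a like-for-like example)
sim = bq.sim_trio(bq.SimConfig(seed=3, n_variants=300, n_true_denovo=10))
result = bq.run_denovo_pipeline(sim.records, sim.pileups)
predicted = [
    bq.OfftargetSite(chrom=c.record.chrom, start=c.record.pos + 99,
                     end=c.record.pos + 122, strand="+", n_mismatches=2,
                     matched_sequence="")
    for c in result.calls
]
pairs = bq.overlap_variants_sites(result.calls, predicted)
print(f"\nde novo calls overlapping predicted sites: {len(pairs)} "
      f"(of {len(result.calls)} calls vs {len(predicted)} sites)")

# expected substitution spectrum: fraction of each class in a reference
# SNP catalogue times the total number of de novo SNVs
fractions = {k: 1 / 12 for k in bq.offtarget.SUBSTITUTION_CLASSES}
reference = bq.SubstitutionSpectrum(fractions, "fractions")
observed = bq.spectrum_from_calls(result.calls)
expected = bq.expected_spectrum(int(observed.total), reference)
excess, deaminase = bq.excess_substitutions(observed, expected)
print(f"C>T excess: {excess['C>T']:.2f}, G>A excess: {excess['G>A']:.2f}, "
      f"summed deaminase excess: {deaminase:.2f}")
# A positive C>T + G>A excess beyond the reference spectrum would point to
# guide-independent cytosine deamination; near zero means none detected.
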