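"""Classify clones from one base-edited embryo and summarise the site.

Generates an amplicon with a planted BE3 protospacer, simulates Sanger
clones drawn from a mosaic two-allele pool, classifies each clone and
prints per-position conversion frequencies.
"""

import bequant as bq

be3 = bq.build_editor_spec("BE3")
cfg = bq.SimConfig(seed=1, intended_rate=0.6, indel_rate=0.1, clones_per_embryo=12)

amplicon, site = bq.gen_site(cfg, be3, locus="FAH-sim")
print(f"target {site.locus}: strand {site.strand}, "
      f"editable positions {bq.editable_positions(site, be3)}")

clones, truth = bq.sim_embryo_clones(site, be3, cfg, embryo_id="E1")
calls = bq.classify_clones(clones, site, be3)
for call in calls:
    print(f"  {call.clone_id}: {call.category}  intended at {call.intended_positions}")

freqs = bq.site_frequencies(calls, site, be3)
print("\nper-position intended conversion frequency (edited / informative clones):")
for p in freqs.editable_positions:
    print(f"  C{p}: {freqs.intended[p]:.2f}  (n={freqs.n_informative[p]})")
print(f"indel frequency: {freqs.indel_frequency:.2f}")

outcome = bq.embryo_outcome("E1", {site.locus: calls}, {site.locus: (site, be3)})
flags = outcome.flags[site.locus]
print(f"\nembryo flags: edited={flags.edited}, mosaic={flags.mosaic}, "
      f"fully_converted={flags.fully_converted}")
# A frequency of 1.00 at an editable C means every informative clone
# carried the C->T conversion there (the "100% allele frequency" case);
# mosaic=True means several distinct allele strings coexist in the embryo.
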