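"""Catalogue dispersed repeats in a simulated cotton-like mitogenome.

Builds a circular genome carrying the diploid-cotton large-repeat profile
(six families, 7.3-12.9 kb, two copies each), then detects maximal exact
repeats and tabulates them by size class.
"""

from mitocmp import classify_and_count, find_maximal_repeats, repeat_table
from mitocmp.simulate import indel_trio_scenario

res = indel_trio_scenario(seed=1).run()
genome = res.ancestor
print(f"genome: {genome.id}, {genome.length:,} bp, GC {genome.gc_content:.2%}")

families = find_maximal_repeats(genome, min_len=1000)
counts = classify_and_count(families)
print(f"large (>=1 kb) repeat families: {counts['large']}")
print(repeat_table([genome], min_len=1000).to_string(index=False))
# Each row is one repeat family; unit_length is the exact repeated unit in
# bp. Large dispersed repeats like these are the substrate of homologous
# recombination that rearranges plant mitochondrial genomes.
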