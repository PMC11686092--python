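"""The per-read genotype-likelihood model on hand-sized inputs.

Each read supports its own base with probability 1-eps and any specific
other base with eps/3; a diploid genotype averages its two alleles and the
site likelihood multiplies over reads, normalized over the three genotypes.
"""

from glpopgen.glcore import genotype_likelihood

print("one A read, eps=0, alleles A/C: ",
      genotype_likelihood([("A", 0.0)], "A", "C").round(4))
print("  -> (2/3, 1/3, 0): the het is half as likely as hom-A, hom-C impossible")

print("one A read, eps=0.2:           ",
      genotype_likelihood([("A", 0.2)], "A", "C").round(4))
print("  -> the het component is exactly 1/3 for ANY single read")

print("three A reads + one C, eps=0.01:",
      genotype_likelihood([("A", 0.01)] * 3 + [("C", 0.01)], "A", "C").round(4))
print("  -> both alleles seen: heterozygote now dominates")

print("zero reads:                     ",
      genotype_likelihood([], "A", "C").round(2))
print("  -> uninformative (0.33, 0.33, 0.33); downstream code treats this as missing")
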