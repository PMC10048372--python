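# SYNTHETIC mtDNA haplotype definition table.
# The D-loop variant sets that define the A2 and A22 haplotypes are not
# reproduced from any published nomenclature; these positions/alleles are a
# synthetic stand-in with the right structure (two haplogroup-A haplotypes
# sharing part of their defining profile) for exercising the assignment
# logic.  Replace with an authoritative table for real analyses.
A2:
  - {pos: 15627, allele: A}
  - {pos: 15639, allele: C}
  - {pos: 15800, allele: T}
A22:
  - {pos: 15627, allele: A}
  - {pos: 15665, allele: G}
  - {pos: 15815, allele: C}
  - {pos: 15931, allele: T}
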