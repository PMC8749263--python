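# Candidate amino-acid sites screened for cold-adaptation / high-altitude
# association in mitochondrially encoded OXPHOS subunits.
#
# Codons are 1-based within the reference protein of the named gene.  Where
# a site is conventionally quoted as a human mtDNA nucleotide position,
# that position is recorded too (human_position), but calling on non-human
# genomes always goes through the gene-relative codon.  reference_residue
# may be omitted; the caller's reference gene sequence then defines it.

sites:
  - gene: MT-ATP6
    codon: 59
    reference_residue: T
    variant_residues: [A]
    human_position: 8701
    phenotype: cold-adaptation (minimum habitat temperature)
  - gene: MT-ND3
    codon: 114
    reference_residue: T
    variant_residues: [A]
    human_position: 10398
    phenotype: cold-adaptation (minimum habitat temperature)
  - gene: MT-ND4
    codon: 29
    variant_residues: []
    phenotype: cold-adaptation (hare species, genus Lepus)
  - gene: MT-ND1
    codon: 30
    reference_residue: Y
    variant_residues: [C, H]
    phenotype: high-altitude adaptation
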