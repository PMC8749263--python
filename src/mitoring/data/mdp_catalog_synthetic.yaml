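# Synthetic human-like MDP locus catalog.
#
# Nine mitochondrial-derived-peptide (MDP) sORF loci hosted by the rRNA
# genes MT-RNR1 / MT-RNR2 and (antisense) the protein-coding gene MT-CO1.
# MDPs are transcribed inside the mitochondrion but translated in the
# cytoplasm under the standard (nuclear) genetic code; gau lacks an ATG
# under that code (its first codon is ATA) and only yields a peptide when
# the start repertoire is extended to the vertebrate-mitochondrial set.
#
# SYNTHETIC REFERENCE DATA: the nucleotide sequences below are not the
# human mitogenome sORFs.  MOTS-c and humanin carry the published human
# peptide sequences; the SHLP and gau peptides are synthetic stand-ins of
# the published lengths (SHLP1-6: 24/26/38/26/24/20 aa; gau dwarf sORF:
# 14 aa).  Every nucleotide sequence is a deterministic back-translation
# (one fixed codon per residue) plus a TAA stop, so each entry translates
# exactly to its stated peptide under its stated code/start policy.  Use a
# catalog compiled from real reference coordinates for work on natural
# genomes; this file exists so the pipeline is fully testable without
# downloads.
#
# Fields per locus:
#   host          MT-RNR1 | MT-RNR2 | MT-CO1
#   sense         host-sense | antisense (reading direction vs the host gene)
#   code          translation table for the peptide (standard unless overridden)
#   start_policy  require_listed_start | extended_starts
#   peptide       reference peptide (initial residue reported as M)
#   nt            reference sORF nucleotide sequence, sORF reading sense,
#                 including the stop codon

loci:
  - name: MOTS-c
    host: MT-RNR1
    sense: host-sense
    code: standard
    start_policy: require_listed_start
    peptide: MRWQEMGYIFYPRKLR
    nt: ATGCGCTGGCAGGAGATGGGCTACATCTTCTACCCCCGCAAGCTGCGCTAA
  - name: humanin
    host: MT-RNR2
    sense: host-sense
    code: standard
    start_policy: require_listed_start
    peptide: MAPRGFSCLLLLTSEIDLPVKRRA
    nt: ATGGCCCCCCGCGGCTTCAGCTGCCTGCTGCTGCTGACCAGCGAGATCGACCTGCCCGTGAAGCGCCGCGCCTAA
  - name: SHLP1
    host: MT-RNR2
    sense: host-sense
    code: standard
    start_policy: require_listed_start
    peptide: MVSKLWLAPFTRGVHSELIQNDRA
    nt: ATGGTGAGCAAGCTGTGGCTGGCCCCCTTCACCCGCGGCGTGCACAGCGAGCTGATCCAGAACGACCGCGCCTAA
  - name: SHLP2
    host: MT-RNR2
    sense: host-sense
    code: standard
    start_policy: require_listed_start
    peptide: MLPQGFRDSWTKVIANHESLVGYTRA
    nt: ATGCTGCCCCAGGGCTTCCGCGACAGCTGGACCAAGGTGATCGCCAACCACGAGAGCCTGGTGGGCTACACCCGCGCCTAA
  - name: SHLP3
    host: MT-RNR2
    sense: host-sense
    code: standard
    start_policy: require_listed_start
    peptide: MLGYNFSSLPCKVEHRTWIADQGLSNVFKETYRPWSIA
    nt: ATGCTGGGCTACAACTTCAGCAGCCTGCCCTGCAAGGTGGAGCACCGCACCTGGATCGCCGACCAGGGCCTGAGCAACGTGTTCAAGGAGACCTACCGCCCCTGGAGCATCGCCTAA
  - name: SHLP4
    host: MT-RNR2
    sense: host-sense
    code: standard
    start_policy: require_listed_start
    peptide: MLDFVESRTKWHANGIPYQSCVLRIA
    nt: ATGCTGGACTTCGTGGAGAGCCGCACCAAGTGGCACGCCAACGGCATCCCCTACCAGAGCTGCGTGCTGCGCATCGCCTAA
  - name: SHLP5
    host: MT-RNR2
    sense: host-sense
    code: standard
    start_policy: require_listed_start
    peptide: MFSRLTADHEWVGKQNIYPCLSVA
    nt: ATGTTCAGCCGCCTGACCGCCGACCACGAGTGGGTGGGCAAGCAGAACATCTACCCCTGCCTGAGCGTGGCCTAA
  - name: SHLP6
    host: MT-RNR2
    sense: host-sense
    code: standard
    start_policy: require_listed_start
    peptide: MVDLKSQWFNIRGTAHPEYC
    nt: ATGGTGGACCTGAAGAGCCAGTGGTTCAACATCCGCGGCACCGCCCACCCCGAGTACTGCTAA
  - name: gau
    host: MT-CO1
    sense: antisense
    code: standard
    start_policy: extended_starts
    peptide: MFLTSRWVKGHQDA
    nt: ATATTCCTGACCAGCCGCTGGGTGAAGGGCCACCAGGACGCCTAA
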