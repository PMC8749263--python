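# Methods

## Coordinate model

All sequences are uppercase IUPAC nucleotide strings. Coordinates are
0-based, half-open, plus-strand oriented. On a circular sequence of
length L a span may wrap the origin; it is stored with `end > start`
(possibly `end > L`) and normalized modulo L for display. GenBank's
1-based inclusive locations (including origin-spanning `join` pairs) are
converted once at the I/O boundary. Ambiguity codes compare by expansion
set everywhere (N matches anything), so an N in an assembly never counts
as a primer mismatch or a substitution.

Rotation normalization (`rotate_to_anchor`) rotates a ring to the first
exact plus-strand occurrence of an anchor motif, smallest position winning
on ties. Downstream results are rotation- and strand-convention-invariant
by construction: locus anchoring and primer scanning search a doubled
template on both strands, so the test suite asserts identical outputs
(modulo coordinate shift) for rotated and reverse-complemented inputs.

## In-silico PCR

A primer binding site is a semi-global alignment: the primer is consumed
in full, the template locally, under unit edit costs. Defaults are
`max_edits = 2` and an exactly matching 3'-terminal window of 3 bases.
The rationale is biochemical: polymerase extension requires a paired 3'
end, while mismatches and the single-base template insertion documented
for some species are tolerated in the footprint body; the exact tolerance
in vitro is unknown, so both knobs are exposed as parameters. Indels are
modelled at unit cost (no affine gaps) because single-base events are the
relevant class at primer scale.

The scanner computes, in one vectorized dynamic program over the doubled
template, the best edit distance of the full primer ending at every
template position (the within-row insertion recurrence is resolved with a
min-plus prefix scan). Candidate ends within the edit budget are traced
back (tie preference: diagonal, then template insertion, then template
deletion), filtered for the 3'-exact rule — the alignment must end in a
run of at least `three_prime_window` exact matches — and reduced to the
best placement per group of overlapping spans (fewest edits, then smallest
start). This canonical site definition is what the test oracle (exhaustive
per-offset prefix alignments via edlib, an independent implementation)
reproduces.

Back-to-back pairing is pure circle geometry. For a plus-strand site P and
a minus-strand site M, the 5'-adjacent boundaries are `P.start` and
`M.end`; `gap = (P.start − M.end) mod L`, the product runs the long way
round from `P.start` to `M.end`, and `product_length + gap = L` is an
invariant. Same-strand pairs are rejected outright; pairs whose 3' ends
face each other produce a near-L gap and fall to the `max_gap` filter
(default 50 nt). Multiple candidate pairs are ordered by total edits, then
gap, then position.

The inverse problem scores alignment windows by mean per-column distinct
symbol count (a gap in any row adds one variant; 1.0 = invariant) and
returns the lowest-degeneracy, non-overlapping windows. `design_back_to_back`
cuts a window at an internal junction (caller-specified; midpoint by
default): the reverse primer is the reverse complement of the block ending
at the junction, the forward primer the block starting there, so the 3'
ends face outward and re-scanning the source genome yields a zero-gap
amplicon.

## MDP prediction

Translation uses NCBI table 1 ("standard", start set {ATG} — the
TTG/CTG prokaryotic-style starts are deliberately excluded, since MDP
prediction models cytoplasmic translation) and NCBI table 2
("vertebrate_mito"), both derived from Biopython's codon tables and
cross-checked in the tests against independently hand-transcribed tables
over all 64 codons. The extended start repertoire {ATG, ATA, ATT, ATC,
GTG} is the vertebrate-mitochondrial start set; it is data, not code, and
can be overridden per call. Initial residues are reported as M whatever
the start codon; ambiguity-containing codons translate to X and cannot
serve as starts.

A locus call proceeds in three steps:

1. **Anchor** (`locate_locus`): best infix alignment of the catalog's
   reference sORF against both strands of the doubled genome (edlib);
   identity = 100·(1 − edits/|ref|). Below `min_identity` (default 60%)
   the locus is `not_locatable` — deliberately distinct from
   `absent_no_start`, which asserts a located window without a start. The
   hit is padded by a 30-nt flank on each side.
2. **Enumerate** (`scan_sorfs`): all start-to-stop ORFs in the three
   frames of the window's reading strand. ORFs shorter than 8 residues are
   `below_min_length` (8 is the conventional floor for an sORF call);
   ORFs longer than 40 residues fall outside the mitochondrial sORFome
   size range and are dropped; an ORF without an in-window stop is
   reported with a truncation flag.
3. **Classify** (`classify_mdp`) against the reference placement, in
   evidence order: a net non-multiple-of-3 length change inside the
   reference footprint ⇒ `frameshift`; a non-start codon at the position
   the reference start maps to ⇒ `absent_no_start`; an in-frame stop
   before the reference peptide length ⇒ `premature_stop`; otherwise
   `intact` with the observed length. Anchoring the classification at the
   mapped reference start (rather than at the 5'-most start in the
   window) prevents a downstream in-frame ATG — MOTS-c has one — from
   masking a lost primary start; such downstream starts are counted and
   reported separately.

The species × locus matrix has one explicit cell per (genome, locus) in
input/catalog order. Peptide conservation (`conserved_core`) builds a star
multiple alignment of the (≤ 40-residue) peptides around the longest one
using Biopython's pairwise aligner and returns the longest run of columns
identical and ungapped in every row — adequate and exact at micropeptide
scale, where a full progressive MSA would add nothing.

### Reference catalog

The shipped catalog (`data/mdp_catalog_synthetic.yaml`) is a synthetic
human-like stand-in, clearly labelled as such: MOTS-c and humanin carry
their published human peptides, the SHLP and gau entries synthetic
peptides of the published lengths (24/26/38/26/24/20 aa; gau 14 aa), each
back-translated with one fixed codon per residue plus a TAA stop. gau's
first codon is ATA, reproducing its defining property of being
untranslatable under the standard code. The catalog is plain YAML so real
reference coordinates can be dropped in without code changes; an optional
per-locus `code` field accommodates documented exceptions such as
mitochondrial-code translation of a locus in particular taxa.

## Divergence and candidate sites

Divergence is the uncorrected p-distance: substitutions over mutually
ungapped columns of a global pairwise alignment, gap columns excluded from
numerator and denominator, flagged as such in the result metadata.
The alignment is a banded Gotoh algorithm (integer costs 0/3 match/
mismatch, 12 + 2/base gaps; band 100 nt plus the length difference),
vectorized across the band with the same min-plus scan as the primer
scanner. The affine gap costs matter: under unit costs an optimal
alignment of two substitution-diverged genomes converts runs of
substitutions into spurious indel pairs and biases p downwards by ~10% of
its value at d ≈ 10%; with gaps expensive the planted divergence is
recovered exactly, and the tests cross-check the aligner against MAFFT on
an indel-carrying pair. The band presumes co-linear sequences, which holds
for conspecific mitogenomes; it is a parameter for anything more
distant.

Whole-mitogenome comparisons exclude the NCR by default — it is the
fastest-evolving, repeat-laden region and conventionally avoided in
phylogenetic comparisons — and a flag restores full-length comparison so
both values can be reported side by side. Gene-restricted comparisons
slice annotated features (or locate the gene by homology in an
unannotated genome) and are rotation-independent by construction. The
Genetic Species Concept helper flags `divergence > 11.0` (strict) on
*MT-CYB*; interpretation near the threshold is left to the caller.

Candidate amino-acid sites are stored gene-relative (1-based codon on the
reference protein), with the human mtDNA positions (8701, 10398) recorded
alongside where the site is conventionally quoted that way, so non-human
genomes remain callable. A call anchors the reference gene by best infix
alignment on either strand, maps the codon's three reference bases through
the banded global alignment, requires them to land on three consecutive
gap-free target bases (otherwise `uncallable`, reason recorded), and
translates under the vertebrate mitochondrial code. Group contrasts are
descriptive residue-count tables per (site, group); no inferential
statistics are attached, because with group sizes of a few dozen the
question — does any residue segregate cleanly with a phenotype group — is
read directly off the table.

## Synthetic data

`generate_mitogenome` lays out the canonical vertebrate gene order
(37 genes + NCR) with human-like nominal lengths scaled to the target
size, drawn uniformly from 14–20 kb when unspecified — the size range of
vertebrate mitogenomes. Background bases are i.i.d. with the light-strand
bias typical of vertebrate mtDNA (A 0.31, C 0.31, G 0.13, T 0.25), which
keeps spurious starts/stops at realistic rates. Planted content overrides
the background: the primer motif (reverse-complemented reverse primer
followed by the forward primer) inside *MT-RNR2* immediately downstream
of the SHLP6 sORF, so the padded SHLP6 locus window overlaps the primer
footprint as it does in real mitogenomes; one reference sORF per catalog
locus in its host gene (gau reverse-complemented into *MT-CO1*); and a
tandem-repeat array in the NCR (default 4 × 10 nt — NCR minisatellites
are an occasional, not universal, feature, and the default keeps one
present without dominating the region).

Primer lesions follow the documented event classes: `mismatch` plants
substitutions in the forward footprint interior, `insertion` a single
extra template base inside the reverse footprint, both away from the 3'
termini (the in vitro observation is that such sites still amplify, which
requires intact 3' ends). The insertion lengthens the genome by one base;
annotations and truth coordinates are shifted accordingly.
Pseudogenization modes: `absent_no_start` rewrites the start codon's
middle base to C, removing it from both start sets; `premature_stop`
replaces an internal codon in the first half of the peptide with TAA;
`frameshift` inserts or deletes one base mid-ORF. `mutate_haplotype`
substitutes exactly `round(L·d/100)` distinct positions (no indels), so
the planted p-distance is exact up to rounding; indel divergence is out
of scope for the generator's current version.

All generators are pure functions of (plan, seed) via
`numpy.random.default_rng`; per-locus lesion seeds are derived with CRC32
so results are independent of Python's randomized string hashing.

What the generator does **not** emulate: real sequence composition
(codon structure of protein genes, tRNA cloverleaves, strand-asymmetric
mutation spectra), NUMTs, heteroplasmy, indel divergence between
haplotypes, or read-level artefacts. Passing tests therefore demonstrate
the correctness of the algorithms on molecules with the right geometry
and planted signal — not performance on degraded, heteroplasmic or
NUMT-contaminated samples.

## Numerical and design choices

* Primer-site tie-breaks (edits, then position; traceback preference
  diagonal → insertion → deletion) and amplicon ordering (total edits,
  gap, position) make every report deterministic.
* The conserved-window score counts distinct symbols rather than entropy:
  primer design cares about any variant existing at a column, not its
  frequency.
* `classify_mdp` checks frameshift before start loss before premature
  stop; a compound lesion reports the first category in that order.
* Degenerate inputs: empty FASTA, missing ORIGIN, wrap requests on linear
  sequences, windows longer than alignments, empty peptides, unassigned
  genomes in group contrasts and out-of-range divergences all raise
  `ValueError` with the offending record named.
* Problem sizes in the acceptance script (50 2-kb rings for the scanner
  oracle, 40 genomes × 9 loci for status recovery, 16-kb rings for
  divergence) are chosen so the whole script completes in seconds while
  every rate is estimated from hundreds of independent events.

## Known limitations

* The banded aligner assumes co-linearity; genome rearrangements or very
  large indels need a wider band or an external aligner.
* Primer thermodynamics (melting temperature, hairpins, dimers) are out
  of scope; a window that scans perfectly may still be a poor oligo.
* The shipped MDP catalog is synthetic (see above); biological
  conclusions require a catalog built from real reference sORFs.
* p-distance is uncorrected by design; no multiple-hit correction
  (Jukes–Cantor etc.) is applied, matching its use for
  species-delimitation thresholds defined on raw divergence.
* tRNA structural annotation, read assembly and tree inference are
  deliberately not part of this package.
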