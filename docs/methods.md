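# Methods

This note documents the models, conventions and numerical choices behind
globinevo, and what the synthetic-data generators do and do not emulate.

## Coordinates and formats

All coordinates are 0-based half-open internally; GFF input/output converts
at the boundary (1-based closed), and human-facing reports are 1-based. Gene
models are normalised to transcript orientation: minus-strand exon and CDS
lists run 5′→3′ along the transcript. Promoter coordinates are anchored to
the translation initiation site (TIS): −1 is the base immediately upstream of
the ATG, +1 the A of the ATG, and there is no position 0. FASTA, newick and
JASPAR PFM parsing delegate to biopython/dendropy; PFM counts receive
background-proportional pseudocounts totalling 1.0 per column before
normalisation, so all-zero columns become the background and log-odds scores
stay finite.

## Orthology and synteny

BLAST-style proteome search is replaced by exact Smith–Waterman local
alignment (BLOSUM45, gap open 11, gap extend 1: a gap of length k costs
11 + (k−1)). At desk scale exactness is affordable and directly testable
against exhaustive path enumeration. Because no database size exists here to
calibrate E-values, the reporting threshold is a raw score floor
(`min_score`, default 50 matrix units). Reciprocal best hits require each
protein to be the other's strict best hit after deterministic tie-breaking
(lexicographically smallest subject id); one protein per gene is assumed.

Shared synteny: a focal (globin) gene shows shared synteny with another
species when, in both species, it lies adjacent — zero intervening annotated
genes on the same scaffold, orientation-insensitive — to an anchor gene
linked across the species by an RBH pair. Non-adjacent co-scaffold placement
is reported with the intervening gene count; a missing focal gene is a
flagged status, not an error.

## Intron helix-coordinate codes

An intron after CDS nucleotide n has phase n mod 3 and affects protein
residue ⌊n/3⌋ + 1. Phase-0 codes number the downstream codon (G7.0 = intron
immediately before helix-G codon 7), matching standard globin-literature
usage; phases 1/2 name the interrupted codon. Residues between annotated
helices X and Y are labelled "XY" with the codon index counted from the
linker start; residues before helix A are "NA", after helix H "HC".
Classification: B12.2 and G7.0 are "ancestral" (the two ancient globin
introns); any intron inside helix E or its flanking linkers (DE, EF) is
"central"; everything else "other". Codes are computed per gene from that
gene's own helix annotation — helices are never inferred from sequence.

The canonical fixture is a frozen 150-codon globin gene (fixed internal
seed, so every call returns identical bytes) with helix annotation
A=4–18, B=21–36, C=37–43, D=52–58, E=59–77, F=84–93, G=101–118, H=125–145
(protein residues, 1-based closed). The annotation is an invented but frozen
coordinate table chosen so that the classic worked examples land where the
nomenclature says they should: an intron after CDS nt 95 is B12.2, after
204 is E11.0, after 318 is G7.0.

In exon projection, a residue split by a phase-1/2 intron is assigned to the
exon containing the codon's first base.

## Ancestral reconstruction and Ka/Ks

Ancestors are reconstructed by nucleotide-level Fitch parsimony:
bottom-up state sets per site, top-down resolution with the parent state
when possible and an alphabetical tie-break ('A' < 'C' < 'G' < 'T' < '-';
gaps are a fifth state) otherwise. The parsimony score equals the number of
union events, verified against exhaustive enumeration of internal labelings
on small trees. Parsimony is deterministic and oracle-checkable; it replaces
likelihood-based reconstruction, and reconstructed sequences are reported as
parsimony-based. Because the reconstruction is nucleotide-wise it can
produce stop codons at internal nodes; branch-wise Ka/Ks masks codon pairs
containing stops (pairwise, like gap codons).

Ka/Ks uses Nei–Gojobori (1986) counting: per codon, the nine single-base
mutations are enumerated; position i contributes syn/(3 − stops) synonymous
sites, so N + S = 3 per compared codon (mutations to stop codons are
excluded from the denominator). Observed differences between codons
differing at 2–3 positions are averaged with equal weights over all
mutational pathways that avoid stop codons. Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p) is applied to both proportions; p ≥ 3/4 is an
error ("JC correction undefined"). Per branch, the statistic compares the
parent (reconstructed) and child sequences. Ks = 0 with Ka > 0 is flagged
"undefined"; no differences at all is "no change". Absolute values differ
slightly from implementations using the alternative stop-site convention
(N + S < 3L, e.g. biopython's NG86); the cross-check test allows a 10%
relative band for exactly that reason.

The missense profile counts, per 30-nt window stepping by 20 (windows
anchored at CDS position 1 of the reference; the final partial window is
retained and flagged), nucleotide differences from the ancestral reference
whose single-base substitution into the reference codon changes the amino
acid, summed over all compared sequences. Stop-creating or gapped codons are
skipped.

## Phylogenetic footprinting

The promoter region is 1000 bp upstream of the TSS plus the full 5′UTR plus
the first 20 bp of CDS (1020 bp + UTR; 1375 bp for the fixture's 355-bp
UTR). The 5′UTR is assumed contiguous — UTR introns are out of scope. Short
scaffolds truncate the region with a warning and the true length recorded.

PWM hits are thresholded on the min–max relative score
(raw − min)/(max − min) over the log-odds matrix, which makes "75–85%"
thresholds reproducible without proprietary score profiles. Both strands are
scanned; windows containing ambiguous bases are skipped. Flank pairing
compares the concatenated 5-bp left+right flanks of two hits (left flanks
right-justified against the hit); flanks truncated at region edges shrink
the denominator.

Positional conservation: the first taxon in configuration order is the
reference (the deviation is measured to the reference, not all-pairs). A
site is conserved when every taxon contributes a hit for the same PWM within
50 bp of the reference offset; when several qualify, the closest is
selected. Optional flank pairing applies between the reference and each
other taxon.

Substring parsimony (FootPrinter-style) finds all width-k motifs (default
k=8) explainable with ≤ 3 substitutions in total and ≤ 1 per branch, one
occurrence per taxon, positions unconstrained across taxa (the
position-shift penalty exists but defaults off, equivalent to a subregion
change cost of zero). The search is a Sankoff dynamic program over all 4^k
ancestral labels with unit-mutation relaxations per branch, followed by a
deterministic traceback per qualifying root label (processed in ascending
score order so deduplication of identical per-taxon instance sets keeps the
most parsimonious labelling). Note one subtlety the tests pin down: a leaf
instance 2 mutations from the rest is *not* excluded by the per-branch cap
alone — the program can route one change through the leaf's ancestor at the
cost of an extra change on the sister branch — so exclusion happens through
the total budget.

Consensus scanning matches IUPAC patterns exactly (default 0 mismatches) on
both strands of a ±5-kb window around the gene, with offsets reported
relative to the TSS in transcript orientation. The NRSE pattern set is
configuration data; the shipped default file carries the classic 21-bp
REST/NRSF consensus and a degenerate variant, and users are expected to
substitute their own consensi.

Motif-library matching stacks instances into a pseudocounted probability
matrix and scores each library PWM by the maximum, over ungapped offsets
with ≥ 4 overlapping columns and both orientations, of the mean per-column
Pearson correlation; zero-variance columns are skipped and a comparison with
no informative columns is flagged uninformative, with ties broken by name.

## Guide trees

Distances are uncorrected protein p-distances (mismatches over columns where
both sequences are ungapped; a pair with no comparable columns is an
error). Neighbor joining is the standard Saitou–Nei agglomeration with ties
in the Q-matrix broken by the lowest (i, j) index pair and negative branch
estimates clamped to zero with a warning; output is unrooted, serialized
with a trifurcating root. Bootstrap support resamples alignment columns with
replacement to the original length and reports, per internal edge of the
tree built on the original alignment, the percentage of replicate trees
containing the same leaf bipartition (bipartitions keyed by the side not
containing the lexicographically smallest taxon, independent of rotation).
This is backbone machinery only — p-distance NJ deliberately replaces
likelihood-based distance estimation, and any externally inferred tree can
be supplied as newick.

## Synthetic data: what it emulates, and what it does not

The codon simulator works at the nucleotide-attempt level: attempts are
Poisson(branch length × sequence length); the target base is drawn with
transition weight κ (default 2) against transversion weight 1; synonymous
changes are always accepted, nonsynonymous ones with probability min(1, ω),
and stop-creating changes are rejected. This is simpler than a codon-matrix
CTMC but yields the dN/dS signal the estimator must recover: at ω = 1, κ = 1
the accepted-nonsynonymous fraction matches the genetic code's neutral
expectation (tested against brute-force enumeration), and recovered NG86
ratios track simulated ω (the frozen calibration band for ω = 0.2, 500
codons, 2 × 0.3 substitutions/site is [0.1, 0.35] in ≥ 95% of seeds). Not
emulated: indels, rate heterogeneity across sites, empirical codon
frequencies, CpG effects. Passing tests therefore show estimator
correctness under the model, not robustness to alignment error or
compositional bias in real data.

Promoter families are i.i.d. background at a configurable GC content
(default 0.40, a typical vertebrate promoter neighbourhood) with motif
instances evolved down the tree (≤ `max_mutations_per_branch` substitutions
per branch, drawn uniformly, with an optional tree-wide total budget
consumed in preorder) and planted at the configured TIS offset ± uniform
jitter. Real promoters are not i.i.d. (CpG islands, repeats); the generator
validates recovery logic, not false-positive rates on genomic background.

Synthetic loci place evolved anchor-gene families (default 100 codons,
star-tree divergence 0.05 substitutions/site, strands alternating) and a
globin gene carrying the requested intron codes (default the vertebrate
B12.2/E11.0/G7.0 pattern, 355-bp 5′UTR so the default promoter region is
1375 bp) in the configured order with 400-bp spacers. "Scrambled" species
additionally get filler genes flanking the globin: with a three-gene
neighbourhood, permutation alone cannot break adjacency, so displacement is
what makes the negative control negative.

All generators are pure functions of (configuration, seed); per-stage seeds
derive from the master seed by hashing, and every CLI stage logs its
effective parameters.

## Problem sizes in the test suite

Oracle suites run at the sizes where exhaustive enumeration is exact and
fast: local alignment on peptides of length ≤ 6, Fitch on ≤ 5 leaves × 5–6
sites, substring parsimony on 3 taxa × ~14 bp × k = 3, NG86 on all 61 sense
codons and random codon pairs. Parameter-recovery runs use 150–500 codons,
4–6 taxa and 20 seeds per ω ∈ {0.1, 0.5, 1.0}. These sizes are the
package's chosen trade-off between statistical resolution and a test suite
that stays fast enough to run habitually.

## Known limitations

* Ka/Ks absolute values depend on the counting convention (documented
  above); comparisons across tools should use the same estimator.
* Fitch parsimony underestimates changes on long branches; branch Ka/Ks on
  deep trees inherits that bias.
* The substring-parsimony search is exponential in k through the 4^k label
  space; k ≤ 10 is practical, the default is 8.
* The positional-conservation filter anchors on the first configured taxon;
  a different reference can change the reported site set when hits are
  near the 50-bp boundary.
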