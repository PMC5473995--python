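# Methods

This note documents the models and procedures behind each pipeline stage,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions.

## Coordinates and containers

External formats (FASTA, GFF3, alignments) use 1-based inclusive
coordinates; all internal interval arithmetic is 0-based half-open, with
conversion confined to the I/O boundary.  Minus-strand gene models are
normalized into transcript orientation at load
(`GeneModel.to_transcript_orientation`), so every downstream computation
assumes plus-strand transcripts.  Multiple alignments are consumed as
inputs (aligned FASTA or Clustal), never computed: progressive MSA is a
solved problem outside this package's scope, and the pairwise
Needleman–Wunsch/Gotoh aligner covers all pairwise needs.

## Pairwise alignment and scoring

Alignment dynamic programming is delegated to Biopython's
`PairwiseAligner`, wrapped so that a gap of length L costs
`gap_open + gap_extend · L` and the unknown residue X scores 0 against
everything (and never matches a motif).  Two scoring regimes coexist:

* **global** (`AlignmentParams` defaults): BLOSUM62, open 10 / extend 0.1 —
  the clustal-style costs used for full-length protein comparisons and
  percent-identity figures.  Percent identity counts identical aligned
  pairs over all columns except terminal-gap overhangs, so a full-length
  alignment of unequal sequences is not penalized for its ends.
* **local, window-vs-reference** (`blast_local_params()`): BLOSUM62,
  open 11 / extend 1.  The 10/0.1 costs make gaps nearly free in local
  mode, which drives random local scores into the linear growth regime
  where Karlin–Altschul statistics do not hold; with the blastp-style 11/1
  costs, the standard gapped-BLOSUM62 constants λ = 0.267, K = 0.041 give
  well-behaved E-values (E = K·m·n·e^(−λS)).  Only the ordering and
  thresholding of E matter to the analysis, so these constants are used
  as-is rather than re-derived.

Both regimes are verified in the test suite against independent oracles:
plain recursion enumerating every alignment (sequences ≤ 7–8 aa, where the
alignment graph is small enough to walk exhaustively), an exhaustive
max-over-substring-pairs local oracle (≤ 6 aa), and hand-written quadratic
Gotoh / Smith–Waterman DPs up to 200 aa.

## Sliding-window dot plot and collinear chaining

The query is cut into 120-residue windows at a step of 5; when the last
full window stops short of the C-terminus one extra window anchored to end
exactly at L is appended, so terminal motifs are always scanned.  Each
window is Smith–Waterman-aligned to the reference; up to
`max_hits_per_window` non-overlapping hits are extracted by masking each
found reference interval with X and re-aligning.  Hits with E ≤ `e_cutoff`
(default 1e-3; the legacy genome-screen cutoff 1e-4 is kept as a named
provenance constant) enter a weighted longest-increasing-subsequence
chain, strictly monotone in both query and reference starts, maximizing
total hit score.  Consecutive chain hits whose diagonal offset
(ref_start − q_start) differs by more than `gap_tolerance` (30 residues)
split the chain into segments; the reported gap magnitude is the
difference of adjacent segments' *mean* offsets, which is robust against
occasional junction-spanning hits whose local alignment bridges a
breakpoint with an internal gap.  The −log10(E) heat-map binning
({0,1,2,4,8,16,∞}) is purely presentational.

## Domain segmentation and classification

Ca²⁺-binding linker motifs are matched degenerately: DXNDN as
D-x-[NDE]-D-N requiring ≥ 4 of 5 positions (the wildcard always counts),
DXD as D-x-D, XPXF as x-P-x-F; overlapping same-class hits collapse to the
best-scoring, most N-terminal one.  EC repeats are delimited by a chain of
DXNDN hits selected by dynamic programming (maximize EC count, then total
motif score, then the most N-terminal layout) in which consecutive chosen
hits must be 85–140 aa apart; degenerate spurious hits inside a repeat are
thereby skipped.  A post-pass bridges unsegmented spans *between two
called ECs* whose length is within k × [85, 140] (k ≤ 2) into k evenly
split repeats — this recovers junctions that lack a motif (the Ca²⁺-free
linker of type IVa cadherins) while two stray motifs with nothing called
around them are never bridged.  Because no printed boundary convention
exists for EC starts/ends, all boundary assertions in the tests allow
±3 residues.

The TM helix is the best mean Kyte–Doolittle window of width 19–23 above
threshold 1.6 in the C-terminal half; CP is everything after it.  De novo
CE domains are cysteine clusters (≥ 5 C within 40 aa) between the EC array
and the TM; LG domains are 150–210 aa spans between consecutive CEs (or
the last CE and the TM); NC is the region from the EC array to the first
CE.  When a reference annotation is supplied, domains are instead
transferred through a global alignment (segments wholly absorbed by query
gaps are reported absent) — reference transfer overrides de novo calls,
mirroring how type III domain positions are anchored on the spider pair.

Type calls, in rule order: full CE2+LG2+CE3 block present → III if the EC
count is 14–17, else non-categorized; block absent → IVa at exactly 7 ECs,
IVb at exactly 9; all else non-categorized (the 8-EC case is explicitly
undefined and warned about).

## Exon–intron inference and intron-position homology

`infer_gene_structure` reconstructs a gene model by walking the transcript
against the genome with maximal exact matches; at each splice point the
next exon is located with a 20-nt seed and the boundary adjusted within
±10 nt so the intron starts GT and ends AG (minimum length 30 nt);
remaining ambiguity resolves to the leftmost donor.  The concatenated
exons must reproduce the transcript exactly (the mismatch tolerance is 0
for synthetic data; real data would need a configurable tolerance, which
is out of scope here).  The CDS is taken as the longest ATG→stop open
reading frame.  Incomplete models are only accepted when explicitly
flagged `partial`, since no convention exists for coordinating partial
5'/3' gene models.

Each intron maps to protein coordinates as position = ⌊offset/3⌋ + 1 and
phase = offset mod 3, where offset is the number of coding bases 5' of the
intron — i.e. a phase-1/2 intron is assigned to the codon it interrupts,
and a phase-0 intron to the codon it precedes.  Sites from different genes
are homologous iff they occupy the same alignment column *with the same
phase*; phase identity is the standard strictness and is required even
though column identity alone would usually suffice.

Conservation categories are assigned per homologized site from the
taxon-group roles of its carriers (spider / other-arthropod-type-III /
arthropod-type-IV / non-arthropod), in precedence order: broadly shared
(spider + other arthropod + non-arthropod); spider + non-arthropod only;
type III/IV shared (non-spider arthropod III and IV, absent elsewhere);
arthropod-specific (spider + other arthropod, no non-arthropod);
non-arthropod-shared (≥ 2 non-arthropods only); otherwise unshared, with a
note when a site is shared only within one lineage (e.g. the two spider
genes).  A site found in ≥ 2 arthropods but no spider and only one type is
deliberately *unshared*: "arthropod-specific" is reserved for sites whose
distribution spans spiders and other arthropods.  The shared-by-≥ k
summary (k defaults to 4) is computed over an arbitrary caller-stated gene
subset.

## Cysteine profiling

Cysteines are grouped greedily left to right: adjacent pairs (CC) first,
then single-spaced pairs (CXC) among the remainder, then solitaries — so
"CCC" is a CC run plus a solitary.  Occupancy is the per-column fraction
of sequences in each taxon group carrying C (zero-C columns omitted).
Column calls with `stable_threshold` 0.8: stable (≥ threshold everywhere),
lineage_loss (≥ threshold in all groups but one, exactly 0 there),
lineage_gain (the mirror image), sporadic otherwise.  "Highly conserved"
has no printed numeric criterion, so the threshold is a parameter and is
echoed into output metadata.  The C-terminal motif E-[S/A]-W-C counts as
present when its cysteine falls among the last three residues, so both
terminal and near-terminal variants match.

## The synthetic generator

`CadherinBlueprint` fixes an architecture; `generate_protein` instantiates
it deterministically under a seed.  Defaults encode the study
architectures: type III = Nt(90) + 17 × EC(112) + NC(170) + CE1(45) +
LG1(180) + CE2(45) + LG2(180) + CE3(45) + TM(21) + CP(305) = 2985 aa, the
scale of the spider type III proteins; IVa/IVb = 7/9 × EC with the reduced
NC–CE–LG–TM–CP block (1405/1629 aa), IVa with a Ca²⁺-free linker at its
EC2/EC3 junction.  Background residues are uniform over the 19 standard
amino acids *minus cysteine*, and two hard generator guarantees keep the
planted truth exact: cysteines occur only where the cysteine plan puts
them, and DXNDN-class windows (score ≥ 4) occur only at planted junctions
— background draws and mutations are resampled otherwise ("mutations never
create novel linker motifs"; windows inherited unchanged from the parent
always pass through).  Both choices trade a little compositional realism
for exact scorability.

`build_gene` reverse-translates with uniformly random synonymous codons,
adds ATG-free UTRs (50 nt), and inserts GT…AG introns of 60–200 nt at the
planted (position, phase) sites; planted sites are kept ≥ 10 codons apart
so splice inference always has a clean exact-match seed.  `derive_variant`
applies BLOSUM62-biased substitutions (never creating C) to a target
divergence (realized divergence is exact up to the indel contribution) and
rare indels (1 per 500 substituted residues, geometric lengths of mean 3,
capped at 10), returning an exact child→parent homology map.  Preserved
landmarks — linker motifs, planted cysteines, the C-terminal motif, the TM
span, and the initiator methionine — are never substituted or deleted; the
TM and start codon go beyond the obvious motif set because a degraded
anchor or lost start codon would silently change the architecture or the
inferred ORF rather than test the pipeline.

`generate_family` derives all members from one type III ancestor: IVb
members keep ancestral EC6–EC14 (nine repeats, the two extra N-terminal
ones being the primitive character) and IVa members EC8–EC14 (seven),
both losing CE2–LG2–CE3 — which makes the IVa-EC1 ↔ III-EC8
correspondence an emergent property of the fixture.  Planted intron sites
carry an explicit carrier list; placement is sampled from the positions
retained by every carrier, spaced ≥ 25 codons in each carrier's
post-deletion coordinates, with a 7-codon indel-exclusion margin so child
exons never shrink below the inference minimum.  The true multiple
alignment is built on the ancestor's coordinate scaffold (child-specific
insertions get extra left-aligned columns), so planted site and cysteine
columns are known exactly.

What the generator does **not** emulate: realistic residue composition or
site-rate heterogeneity, repeat homogenization/concerted evolution between
EC units (each EC is drawn independently), non-canonical splice sites,
alternative isoforms, sequencing error, and alignment error (downstream
stages are scored against the *true* alignment).  Tests passing on this
fixture therefore demonstrate algorithmic correctness against planted
truth, not robustness to aligner mistakes or compositional bias in real
proteomes.

## Problem sizes and determinism

Every stochastic component takes an explicit integer seed and is
bit-reproducible; the pipeline itself is deterministic given its inputs.
The packaged checks use: exhaustive alignment enumeration at ≤ 7–8 aa and
quadratic DP oracles at ≤ 200 aa; window arithmetic over all lengths
120–4000; 20 replicates each for the planted 240-residue deletion, the
34 %-divergence paralog identity (66 ± 3), and the two-cysteine lineage
loss; 50 genes × 5–40 introns for splice round-trips; 1000 random presence
matrices against the rule oracle; and an 11-gene panel (two spider type
III paralogs, 34 shared coding introns, nine non-chelicerate relatives)
for the conservation tallies.  These sizes keep the whole suite at a few
minutes on one CPU while exercising every rule branch.

## Known limitations

* Splice inference requires exact transcript/genome agreement and
  canonical GT-AG introns; it is a verification tool for curated or
  simulated data, not a spliced aligner for noisy genome assemblies.
* De novo CE/LG detection presumes cysteine-dense CE domains and
  150–210 aa inter-CE spacing; unusual spacings need reference transfer.
* E-values use fixed gapped-BLOSUM62 constants; scores from other
  matrices or gap costs would need re-estimated λ/K for absolute (rather
  than relative) significance.
* The dot-plot is quadratic per window pair and intended for single
  proteins, not proteome-scale sweeps.
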