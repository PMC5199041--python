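# Methods

`rapphr` reimplements, as a tested desk-scale pipeline, the computational
analysis of the Rap-Phr quorum-sensing family in *Bacillus*: mining of
receptor–propeptide cassettes from genome assemblies, autoinducer calling
and repeat detection, monophyletic peptide clustering on a receptor tree,
GC-based horizontal-transfer classification, presence/absence population
statistics, and gain/loss parsimony of target regulation. A synthetic-genome
generator with full ground truth makes every stage exercisable and testable
without external downloads.

## Cassette mining

The search is tblastn-style: protein seed queries against the six-frame
translation (NCBI table 11; codons containing N translate to X, stops to
`*`) of every contig. Exact amino-acid 4-mer seeds are grouped on diagonals,
candidate regions are extended by Smith–Waterman local alignment (BLOSUM62,
affine gaps −11/−1, via Biopython's `PairwiseAligner`), and significance is
assessed with Karlin–Altschul e-values (λ = 0.267, K = 0.041, the standard
gapped BLOSUM62 parameters; database size = total translated residues).
Pre-merge hits are discarded above e = 10⁻³ so seed noise cannot distort
locus boundaries; hits on the same contig and strand within 100 nt are then
merged, summing member aligned lengths, so a frameshifted receptor split
across two frames still reports its full homology length. A locus is kept
when its merged e-value is ≤ 10⁻²⁰ against any query and the homology spans
≥ 300 aa (the NprR profile differs only in e ≤ 10⁻³⁰ and its window).
Externally computed BLAST tabular hits (outfmt 6) can be imported for exact
parity with a reference search.

Each hit is extended in frame to a complete ORF: downstream to the nearest
stop, upstream to the 5′-most ATG/GTG/TTG start not preceded by an in-frame
stop. Hits running off a contig edge are reported as partial and excluded.
When the single-frame ORF is shorter than the homology evidence the
receptor is flagged as a candidate frameshift — the automated counterpart
of browsing short high-homology hits by hand.

The propeptide scan covers a window from 100 nt before to 600 nt after the
receptor stop (receptor orientation, configurable; −100..+500 for NprR).
Same-strand ORFs of 35–120 aa whose start codon lies inside the window are
scored by the signal-peptide PWM; candidates scoring ≥ 0.3 are ranked by
score, then proximity, then coordinate, and pruned to a non-overlapping
set. A receptor with no passing candidate is an orphan cassette; two or
more accepted candidates mark a phr gene duplication. Coordinates are
0-based half-open internally and 1-based inclusive in written tables.

## Signal-peptide scoring

Secretion-signal detection uses a fixed-anchor position weight matrix over
the first 30 residues encoding the canonical Sec tripartite architecture:
initiator methionine, a positively charged n-region (K/R), a hydrophobic
h-region (L/I/V/F/A/M), and a small-residue c-region before a mildly polar
early-mature segment. Scores are normalized so the matrix consensus scores
exactly 1.0; residues beyond position 45 can never influence the score. The
weights were designed for a sharp margin at the 0.3 acceptance threshold:
uniform-random 45-mers score 0.13 ± 0.05 (≈0.1–0.2 % exceed 0.3), while
signal regions sampled from the matrix score ≥ 0.45. The scorer is a
self-contained component of the package; its threshold semantics (0.3 for
positive identification) follow the mining protocol.

Because even a ~0.1 % per-ORF false-positive rate yields an occasional
spurious propeptide over hundreds of scan windows, the pipeline adds a
conservation screen — the automated analog of manually screening candidates
by conservation pattern: a propeptide is rejected when its receptor has
relatives within tree distance 0.2 and none of them carries a propeptide
ending in the same C-terminal pentamer. Receptors without close relatives
(e.g. single-strain mobile cassettes) are never screened out.

## Autoinducer calling and repeats

The mature Phr autoinducer is a penta- or hexapeptide, usually at the
propeptide C-terminus. For a group of aligned propeptides, every 5- and
6-column window is scored by 0.5 × mean per-column majority fraction +
0.5 × best identity to a known-peptide library (conservation alone when no
library is given; library identity alone for singletons). The best window
wins; ties prefer the most C-terminal, then the longer window. Confidence
below 0.5 flags a low-confidence call. A pentapeptide and its hexapeptide
extension are distinct peptides: peptide equality is exact string equality
throughout.

The pipeline assigns per-cassette peptides in two passes: a provisional
C-terminal pentamer (a suffix of the mature peptide under either length)
groups leaves into provisional monophyletic clusters; each group is then
realigned and called jointly, and leaves are reclustered on the final
calls. Group-level conservation decides penta vs hexa; for singleton
clusters the hexamer is preferred at ties, a documented ambiguity.

Intragenic repeats are maximal sets of ≥ 2 non-overlapping windows within a
mismatch budget of a common consensus. Every window serves as provisional
consensus, compatible windows are collected greedily left to right, the
per-column consensus of the chosen copies is recomputed, and a degenerate
bracket pattern (e.g. `E[R/K]PVGT`) is emitted with residues in order of
first appearance. Analyses scan only the mature region (the N-terminal
signal is trimmed first): the compositionally biased signal region —
poly-hydrophobic h-region, small-residue c-region — otherwise produces
trivial approximate matches. Whole-phr-gene duplication is ≥ 2 accepted
propeptides on one cassette; divergence is the normalized Hamming distance
of their C-terminal hexamer windows.

## Trees, clusters and diversity

Maximum-likelihood inference is deliberately out of scope; trees are
imported as newick or built with neighbor joining (scikit-bio) on
p-distances with pairwise deletion of gap sites, negative NJ branch lengths
clamped to zero. Bootstrap supports count bipartition recovery over column
resamples. Multiple alignment is progressive (biotite, BLOSUM62, gaps
−10/−1); externally computed alignments import from FASTA.

Peptide clusters are maximal clades whose leaves all encode the same
peptide string; every leaf belongs to exactly one cluster. Orphan leaves
form singleton clusters unless orphan merging is enabled (default distance
0.2), in which case monophyletic orphan groups whose tip-depth diameter
bound (twice the maximal depth from the clade base) is within the threshold
merge — this reproduces named orphan clusters rather than per-strain
singletons. Phylogenetic diversity of a leaf subset is Faith-style: the
summed length of branches on the union of root-to-leaf paths of the subset,
divided by the same quantity for all leaves (so a single leaf on a star of
n equal branches spans 1/n, and the full set spans 1.0; the convention is
rooted, pendant branches always count).

## Mobility and population statistics

A cassette's mobility call is a one-sided z-test of its gene GC below the
strain's gene-GC distribution (α = 0.05 by default); degenerate sd = 0
distributions are labeled by strict inequality with an undefined p-value.
When no annotation is available the strain background is the GC of all
complete ORFs ≥ 300 nt — a documented difference from using annotated
genes. Cluster-level labels are majority votes over member cassettes.
Neighborhood GC uses the window 1000–300 nt upstream of the receptor start;
the gene-vs-neighborhood regression is least squares through the origin,
reporting the uncentered R² (1 − SSres/Σy², clamped at 0) — documented
because centered and uncentered definitions differ for origin-constrained
fits.

The association matrix marks each cluster present/absent per strain;
(strain, cluster) pairs with ≥ 2 members are duplicate cases, with orphan
duplicates counted separately. Per-species frequencies average presence
within species, then across the species where the cluster occurs at all.
Rarefaction draws random strain permutations (500 by default) and averages
distinct clusters over prefixes; nested prefixes make the curve monotone by
construction with its endpoint equal to the observed cluster count. The
tail slope is the least-squares slope over the last `tail_window` sizes
(20 by default; the pipeline caps it at n−1 strains and uses 10 at the
default 20-strain scale).

## Gain/loss parsimony of target regulation

Measured phenotypes (sporulation efficiency for the Spo0A pathway, srfA
reporter expression for ComA) are binarized by configured cutoffs; the
thresholds are required configuration, not code constants, values exactly
at a cutoff count as not repressing, and missing measurements leave the tip
unconstrained. Ancestral states and per-branch gain/loss events come from
Sankoff dynamic programming with unit gain and loss costs; the root can be
fixed (the family's ancestral state is Spo0A-pathway control) or free, and
a fixed root can only increase the event count. Among equally parsimonious
child states the default resolution keeps the parent state (delayed
transformation); accelerated resolution is selectable and ties are
reported. Correctness is checked against exhaustive enumeration on all
4–5-leaf topologies (and sampled 6-leaf ones) and against an independent
Fitch-set implementation on random trees.

Interface-residue conservation is per-column 1 − H/ln 20 (Shannon entropy
over non-gap residues, all-gap columns undefined), with modal-residue
consensus strings for Target and OFF-Target groups at user-supplied
alignment columns; structures are never parsed.

## Synthetic study conditions

The generator's defaults describe a *B. subtilis*-group-like population:
20 strains in 4 species on a rooted tree (interspecies branches 0.5–1.5,
within-species 0.01–0.05 substitutions/site); 7 core clusters per species
of which 3 are orphan (matching the three orphan raps of strain 168, giving
≈ 3 orphan cassettes per strain); a pool of 40 mobile clusters evolving by
a reversible two-state jump process whose stationary frequency is set so
the mean repertoire is 11 cassettes/strain (the typical subtilis-group
mean; the cereus-like profile uses 6 cassettes/strain, no orphans and
background GC 0.35); background GC 0.435 with mobile cassettes embedded in
islands (cassette ± 500 bp) at GC depressed by 0.05 — there is no canonical
numeric GC delta for mobile elements, so the default is a free parameter
chosen to give clear but not trivial separation (≈ 3–4 strain-sd); 5
planted same-cluster duplicate cases plus 3 orphan duplicates (counts of
the size observed in real subtilis-group association matrices, used here
as the planted condition); receptors of 360 aa diverged 15–35 % from a family ancestor per
cluster and ~4 % within clusters; propeptides of 40–60 aa with a
PWM-sampled signal region, filler diverged 25 % within clusters, and 1–3
autoinducer repeats (the C-terminal copy always exact, additional copies
carrying up to 2 planned mismatches); 70 % hexapeptides; 20 % of core
clusters reuse another species' core peptide (same-genome orthogonality is
never violated). Coding sequences are reverse-translated with GC-steered
synonymous codons plus a greedy repair pass that pins gene GC within 0.01
of target (mobile genes are additionally capped at background − delta), and
every gene is flanked by a 12-mer carrying stop codons in all three frames
so planted ORF boundaries are unambiguous. Background is i.i.d. sequence at
background GC plus 25 random protein genes per strain — enough for a
≥ 20-gene strain GC distribution; there is no codon-usage or intergenic
realism beyond GC and reading frames, so passing tests demonstrate
correctness of the analyses under these statistical assumptions, not
performance on real assemblies (no annotation noise, no repeats/mobile
element families, no assembly gaps).

All randomness derives from one seed through named substreams, so a fixed
configuration reproduces genomes byte for byte, and the per-branch event
log replays exactly from the root states to the tip presence patterns.

## Problem sizes and numerical choices

Default analyses run on the 20-strain scale: full-pipeline recovery,
mobility AUC and repeat accuracy are measured against the generator's
truth; the end-to-end run (mining, progressive MSA of ~240 receptors, NJ,
clustering, population statistics) completes in a few minutes on one CPU,
and bootstrap replicates default to 25 in the pipeline (100 in the
standalone tree builder). Distance ties in NJ fall to scikit-bio's
deterministic resolution; cluster ids are assigned in sorted member order;
summary JSON is key-sorted so reruns are byte-identical.

## Known limitations

* No real genome corpus is bundled: every quantitative result is computed
  on the generator's study conditions rather than on downloaded *Bacillus*
  assemblies; the database loader accepts existing survey spreadsheets when
  they are available locally.
* Penta/hexa disambiguation for singleton clusters is conventionally hexa.
* The signal-peptide scorer is a compact PWM, not a full predictor; its
  scores are calibrated for the synthetic margin, and real-genome use
  should recalibrate the threshold against annotated phr genes.
* Non-C-terminal autoinducers (phrH/phrE-like) are covered by the window
  scan, but confidence semantics for them are unvalidated.
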