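# Methods

## The analysis in one paragraph

`polyhap` models a multi-copy gene in a highly polyploid crop as a set of
near-identical haplotypes (distinct full-length alleles of one amplicon)
distributed across accessions, each accession carrying up to ploidy-many of
them.  Clone sequences sampled from an accession are grouped by exact
string identity, pooled across accessions, and a group becomes a confirmed
haplotype when its pooled support reaches `min_support` (default 2
identical assemblies).  Confirmed haplotypes are multiply aligned; the MSA
yields a variant catalogue (SNP sites on gap-free columns, InDel events as
maximal gap runs against a designated reference haplotype), diversity
statistics, Nei–Gojobori Ka/Ks against ancestral reference haplotypes, a
minimum-spanning haplotype network, and a numeric mutation encoding that is
correlated site-by-site with accession sugar traits.

## Haplotype confirmation and clone coverage

Identity grouping pools clones across accessions because a haplotype is a
property of the locus, not of one accession; per-accession support is
retained for reporting.  Haplotype ids (HAP1, HAP2, …) are assigned by
decreasing pooled support, ties broken lexicographically on the sequence —
a pure reproducibility convention.  Clones containing an ambiguous base (N)
are dropped, with a logged count, before grouping.  If nothing survives
filtering and the support rule, a typed empty-result error is raised rather
than returning an empty set silently.

Read-pair merging joins two same-orientation reads over their longest exact
suffix/prefix overlap of at least `min_overlap` (default 6) bases.  A read
wholly contained in the other is treated as a 100 %-identity full overlap
and merges regardless of the threshold; this is the only consistent reading
when one read subsumes the other (e.g. two identical reads).

The clone-coverage planner answers: how many successful assemblies per
accession guarantee, with confidence `confidence`, that even a
single-copy haplotype of a `ploidy`-plex locus — sampled with probability
1/ploidy per clone — is seen at least `min_copies` times?  It returns the
smallest c with P[Binomial(c, 1/ploidy) ≥ min_copies] ≥ confidence, using
the exact binomial tail (scipy).  At the default see-it-twice / 95 % level
a 12-ploid needs 56 assemblies.  The (min_copies=2, confidence=0.95)
defaults are the unique simple criterion consistent with that figure and
with the support rule; both are exposed configuration.

## Alignment

Pairwise alignment is global Needleman–Wunsch/Gotoh with affine gaps: a
k-base gap costs `gap_open + (k−1)·gap_extend`, defaults
match/mismatch/open/extend = +2/−3/−5/−2.  The scheme is chosen for
nucleotide sequences at ~99 % identity, where gaps are rare, short and
should not fragment; all four numbers are exposed.  Traceback ties resolve
diagonal > up > left, and within each DP state predecessor ties resolve
match-state first, so alignments are bit-reproducible.

The MSA is classic progressive alignment: a UPGMA guide tree on a
shared-8-mer distance (1 − Sørensen fraction of shared 8-mers; with
sequences this similar any reasonable k-mer distance produces the same
tree), profile–profile merges scored as the count-weighted average
substitution score between columns (gap characters score 0), and "once a
gap, always a gap" propagation.  UPGMA ties break on the smallest cluster
index pair.  The DP inner loops are numba-compiled; a 2.8 kb × ~40-row
problem aligns in seconds.

Coding sequence is spliced from an alignment row using exon coordinates
given on the ungapped reference row (0-based half-open internally; all
human-readable reports are 1-based).  Columns inserted relative to the
reference belong to no exon and are excluded.  A spliced CDS whose length
is not a multiple of three is flagged as frameshifted and excluded from
translation-based analyses with a logged warning, never an error.

## Variant catalogue

Site statistics use complete deletion: any column containing a gap is
excluded from S, η and π and routed to InDel event calling.  S counts
columns with ≥ 2 states; η adds (distinct states − 1) per column.
Transition/transversion class is recorded for biallelic sites only — at a
tri-allelic site the per-site class is ambiguous, and such sites carry an
NA.  InDel events are maximal gap runs polarized against the designated
reference row (deletion: row gaps over reference bases; insertion: row
bases over reference gaps); events identical in position, length, polarity
and inserted sequence merge across carriers, so a 277 bp insertion shared
by three haplotypes is one event with three carriers.  SNP density is
amplicon length / SNP count, reported rounded to the integer as is
conventional ("42 bp per SNP").

The splice-motif scanner matches degenerate IUPAC patterns (default
YNYYRAY, the plant branch-point consensus) inside given intervals,
reporting every — possibly overlapping — offset.  Note that two YNYYRAY
matches cannot overlap by more than one base (the R at position 5 of one
match would have to be the Y of the other), so the closest possible pair
shares exactly the terminal/initial pyrimidine.

Protein types group haplotypes by exact amino-acid identity of the spliced
CDS under the standard genetic code; a trailing stop is stripped, an
internal stop excludes the haplotype with a warning.  Types are labelled
P1, P2, … by decreasing member count.

## Diversity

Hd = n(1 − Σp²)/(n − 1) and its sampling variance
Hv = (2/(n(n−1)))·{2(n−2)(Σp³ − (Σp²)²) + Σp² − (Σp²)²}.  Hd is evaluated
as (n² − Σc²)/(n(n−1)) on integer counts so the closed-form cases (all
singletons → 1, one class → 0) are exact in floating point.  When every
haplotype is counted once Hd is exactly 1 by construction; diversity below
1 only arises under a weighting (e.g. by carrying-accession count), which
is what the pipeline's group reports use.

π is the average number of pairwise differences per analyzed (gap-free)
site, with no multiple-hit correction: at ~99 % identity a Jukes–Cantor
correction changes nothing at reported precision.  Sliding-window π uses
window/step defaults of 100/25 alignment columns, excluding gap columns
within each window; windows are indexed by their 1-based midpoint column.
Global π equals the analyzed-site-weighted mean of window π when the
windows tile the alignment.

## Selection (NG86)

Synonymous site counts per codon are the per-position fraction of the
three single-base changes that are synonymous, with changes to stop codons
excluded from the denominator; syn + nonsyn = 3 always.  Between codons
differing at 2–3 positions, observed synonymous/nonsynonymous differences
are averaged with equal weights over all mutational pathways that avoid
stop-codon intermediates; when every pathway is blocked the unweighted
average over all pathways is used and the pair is flagged.  Codons
containing gaps or N in either sequence are dropped pairwise.  Proportions
pN, pS are corrected with d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 leaves the
rate undefined (flagged), never infinite.  Selection classes: identical
(no differences), positive (Ka > Ks + tol, including Ks = 0 with Ka > 0),
purifying (Ka < Ks − tol), neutral otherwise, with tol = 1e−9 — a pure
floating-point guard, exposed in configuration.

## Haplotype network

The distance between two haplotypes is mutational steps on the MSA:
differing columns where both rows have bases, plus one step per InDel event
carried by exactly one of the pair (length-independent — a long insertion
is one mutation).  The network is the ε=0 minimum-spanning network:
distances ascend Kruskal-style, and when components first meet at distance
d every inter-component pair at distance d becomes an edge (tie
retention).  This keeps the reticulations a statistical-parsimony layout
would show for closely related haplotypes while avoiding any
connection-limit machinery; for the near-identical haplotypes this tool
targets the two constructions coincide on the backbone, whose total weight
always equals the minimum-spanning-tree weight.  Edges of k > 1 steps can
be expanded through k − 1 unlabeled inferred intermediates so every drawn
edge is one mutation.  The most-central haplotype (minimum eccentricity in
steps, ties to higher carrying-accession frequency then id) is reported as
the candidate primitive haplotype.  Group assignment beyond connectivity is
deliberately not claimed: a single-linkage cut at a user distance
threshold (`single_linkage_groups`) is available as plumbing but is
labelled non-canonical.

## Trait association

Variant sites are encoded numerically per (reference state, observed
state) category: C↔T 0.5, A↔G 0.555, C↔A 7, C↔G 7.777, T↔A 70, T↔G 70.777,
insertion 900, deletion 900.999, identity 0.  The codes are arbitrary but
category-distinguishing, and are used exactly as published in the
procedure this package reproduces; they impose an artificial metric on
categories (a T↔G transversion is "140×" a C↔T transition), which is why a
binary mutation-presence mode (`one_hot`) exists for methodological
comparison.  The reference haplotype's rows are zero by construction.

The observation unit is the (accession, haplotype) carriage pair with the
accession's traits attached; a `per_accession` mode instead averages codes
over the accession's haplotypes so each accession is one observation.
Pearson correlations use the exact t-transform with n − 2 df, two-sided;
missing trait values drop pairwise; zero-variance columns are flagged
undefined, not errors.  No multiple-testing correction is applied by
default (flags are raw P < alpha with alpha = 0.01); Benjamini–Hochberg is
available behind a flag.  One-way ANOVA uses the classical decomposition
(Sq_between = Σ n_g(mean_g − grand)², df = (g−1, n−g)) with the p-value
from the F distribution.

## The synthetic study generator

The generator emulates the full data-generating process at the scale of
the motivating study, and its defaults *are* those study conditions:

| parameter | default | meaning |
|---|---|---|
| amplicon | 2,824 bp, 8 exons / 7 introns | gene template; spliced frame kept stop-free |
| n_hap | 39 | planted haplotypes; H1 is the template itself |
| n_snp / n_indel | 67 / 6 | planted variants; InDels intronic only |
| ts:tv | 44:23 | transition count fixed to round(n_snp·tstv/(1+tstv)), placement random |
| large insertion | 277 bp, 3rd intron, 3 carriers | the one large structural allele |
| n_acc / ploidy | 18 / 12 | accessions and per-accession haplotype cap |
| clones_per_acc | 60 | clones picked per accession |
| error_rate | 0.0009 /base | high-fidelity polymerase substitution error |
| dropout | 0.2 | clone sequencing/assembly failure fraction |
| traits | baseline 14 %, additive effects, Gaussian noise | accession trait = baseline + Σ effect×dosage + N(0, sd) |

Design choices worth knowing:

* **Errors are substitutions only.**  High-fidelity polymerase errors are
  overwhelmingly substitutions, and the support rule discards singleton
  sequences anyway, so simulated sequencing indels would add nothing the
  pipeline could distinguish.
* **Clone sources are stratified.**  Each accession's clones are drawn by
  shuffled round-robin over its assigned haplotypes rather than i.i.d., so
  `clones_per_acc ≥ 2×ploidy` with no dropout guarantees every assigned
  haplotype is seen at least twice.  This makes "error-free simulation is
  recovered exactly" a theorem about the pipeline, not a coin flip about
  the sampler.
* **Every planted haplotype is assigned somewhere** (default): the
  simulated population is exactly the planted set, so catalogue recovery
  can be checked as set equality.
* **The transition count is fixed, not drawn**, so the default composition
  is exactly 44:23; the degenerate limit (tstv → ∞ → all transitions)
  still holds.
* **Planted variants keep their distance.**  SNPs stay ≥ 4 bp from InDel
  edges and InDel events keep a length-scaled separation (capped at
  40 bp), because a progressive aligner can legitimately absorb a
  substitution adjacent to an insertion into the gap columns, or
  interleave two nearly touching insertions.  Those are alignment
  ambiguities, not pipeline defects, and the generator avoids planting
  unresolvable configurations.  Exonic SNPs avoid creating stop codons so
  every haplotype translates.

What the generator does **not** emulate: chimeric PCR artifacts,
chromatogram-level noise, paralog contamination, transposon biology (a
large insertion is plain inserted sequence), or linkage between the trait
noise and genotype.  Passing the recovery suites therefore shows the
pipeline is correct on clean, well-separated variation; it does not show
robustness to artifacts the generator never produces.

## Replicate experiments (power and calibration)

Two seeded experiments validate the association stage end to end on a
small study shape (370 bp gene, 8 haplotypes, 16 SNPs + 2 InDels, 18
accessions of ploidy ≤ 4 with substantial sharing):

* **Causal recovery** plants one causal SNP (the one with maximal carrier
  dosage variance across accessions — a site without dosage variation is
  unidentifiable by design) with effect 2.0 against noise sd 0.2, runs the
  real path (MSA → catalogue → encoding → correlation on per-accession
  observations, the unit matching the additive dosage model), and asks
  whether exactly that site is flagged significant with the right sign.
  Measured: 99/100 seeds.
* **Null calibration** runs the same path with no causal site and counts
  significant flags among defined tests.  Per-accession observations make
  each accession one independent data point, so the nominal t-test level
  applies.  The false-positive count is slightly over-dispersed relative
  to binomial because the ~18 sites of one replicate share the same trait
  noise; the rate itself stays at the nominal level.

## Determinism

A single seed drives every stochastic stage through numpy `SeedSequence`
substreams; reports and all written outputs are byte-identical for a fixed
seed and configuration.  For that reason the machine-readable run report
contains no wall-clock timings — they go to the stderr log.

## Known limitations

* The progressive aligner is built for ~99 % identity; at high divergence
  its guide distances and profile scores degrade and a dedicated MSA tool
  is the right choice.
* InDel placement within the MSA is convention-dependent; statistics on
  substitution columns are stable, but event boundaries for adjacent or
  repeat-flanked indels can differ between aligners.
* Hd/Hv depend on the chosen weighting of haplotype counts (once vs by
  carriage); the pipeline reports the weighting it used.
* The mutation encoding is reproduced as published; its numeric magnitudes
  are arbitrary, and correlation results should be read as
  category-association signals, not effect sizes on a meaningful scale.
* The network's ε=0 construction approximates a statistical-parsimony
  layout; it never disconnects distant haplotypes and adds no
  parsimony-probability reticulations beyond distance ties.
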