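# Methods

`subtelomap` models the analysis side of single-molecule nanochannel
mapping applied to human subtelomeres: long genomic DNA fragments are
nick-labeled at a sequence motif, imaged, and their ordered label patterns
compared with electronically digested reference sequences to delineate
structural variation, long-range haplotypes and single-telomere lengths.
Everything below is implemented and exercised by the test suite; no claim
here goes beyond what the tests and `scripts/acceptance.py` compute.

## The physical model

A subtelomere is modeled as, from the chromosome end inward: a terminal
(TTAGGG)n tract, optionally some unsequenced telomere-adjacent DNA (the
"gap" of incomplete assemblies), segmentally duplicated subtelomeric
repeat element (SRE) blocks shared between subtelomeres, and
chromosome-specific 1-copy DNA.  Reference assemblies start at the
subtelomeric sequence and carry essentially no telomere repeat, and the
nicking motif (Nt.BspQI's GCTCTTC, on either strand) does not occur inside
(TTAGGG)n.  A molecule that aligns to the reference and runs past its
telomeric edge therefore ends in an unlabeled overhang whose length is the
telomere tract.

Coordinates are 0-based, half-open.  Reference maps are strand-collapsed
(the imaging system cannot distinguish strands); strand is retained only
for inverted-nick-pair (INP) detection, where two close opposite-strand
sites amount to a double-strand break.

## Simulator

The generator (`simulate`) produces diploid subtelomeres from a backbone
(SRE blocks seeded deterministically by block id, so re-using an id across
subtelomeres reproduces paralogy sharing; then a 1-copy region) plus
per-haplotype edits: insertions, deletions, single nick-site loss (a point
mutation in one motif), and tandem arrays (a motif-free unit repeated a
set number of times, with motif sites planted at both array flanks so the
array length is readable as one inter-label interval).  Generated content
is guaranteed at least ~70% of the genome-average motif density (one site
per 9.3 kb); an individual random draw can otherwise come out
unrealistically sparse.

Molecules are drawn until the total genomic footprint reaches the target
fold-coverage (default 30x for the bundled scenarios; deep-coverage runs
use more).  Each draw: haplotype uniform; length log-normal (median 250
kb, shape 0.35) clipped at the chromosome ends and truncated at the
minimum molecule length (150 kb, matching the long-molecule regime the
method needs); each spanned true site labeled with probability 0.9 (10%
false negatives); spurious labels Poisson at 10% of the true-site count
(interpreted per true label; a per-kb mode exists); every inter-label
interval perturbed by Gaussian noise with SD = max(0.03 x interval,
250 bp); orientation reversed with probability 1/2; fragmentation at each
spanned INP locus with probability 0.5.  Hidden truth (haplotype, origin,
orientation, spanned/labeled site counts) is recorded before noise.

What the simulator does **not** model: chimeric molecules, imaging
resolution limits (labels closer than ~1 kb would not be resolved in real
data), backbone-intensity information, base-composition biases, somatic
mosaicism.  Passing tests therefore demonstrate correctness of the
algorithms under the stated error model, not performance on real imaging
data.

## Alignment

Alignment of a molecule's label pattern to a reference map is a
maximum-score monotone chain over (label, site) pairs, in both
orientations.  Scoring is a log-likelihood ratio:

- each matched pair earns a fixed credit (5 nats);
- each matched interval earns ln(spacing_genome / (sd * sqrt(2 pi))) -
  z^2/2, with z the interval discrepancy standardized by the sizing SD --
  i.e. Gaussian sizing likelihood against a flat null at genomic label
  density;
- the sizing term is capped at 12 nats, so a large indel crosses the
  alignment as one bounded-cost outlier interval; labels/sites inside a
  capped (outlier) interval are not additionally charged, because the
  indel itself explains them;
- otherwise skipped sites and labels cost ~ -ln(0.1) = 2.3 nats each,
  matching the stated 10% miss/spurious rates; at most 8 consecutive
  skips (so one transition can bridge roughly 75 kb of labeled indel
  content at genomic density).

Alignment is semi-global in the molecule: unmatched labels beyond the
chain ends are charged when they would project inside the reference and
are free when they project beyond it (telomere overhangs, gap extensions,
molecules running off the map end).  This is exact in the DP because the
start-side charge depends only on the chain's first pair and the end-side
charge only on its last.  The optimum is verified against exhaustive
chain enumeration on hundreds of random instances.

**Confidence** is the log10 margin between the best alignment and its
strongest genuine competitor: the best placement at a distinctly different
offset (sub-chains of the winner and chains explaining less than half as
many labels are not competitors) or the best alignment to
interval-shuffled decoy maps (identity and mirror shuffles excluded; a
mirrored map is the true map read backwards).  The scale is this
package's own.  The default threshold of 12 was calibrated so that none
of 1,200 random molecules (uniform labels at genomic density against four
preset references) passes, while typical well-anchored molecules with
15+ labels score 25-40.  The conventional cutoff of 20 quoted for
commercial mapping pipelines refers to an unpublished proprietary score
and is not comparable; a three-label schematic molecule carries only a
few log10 units of placement evidence on any honest scale and is
evaluated on the alignment itself rather than an ensemble threshold.

Chromosome-specific assignment additionally requires anchoring: at least
one matched site inside the subtelomere's 1-copy interval.

## Consensus, haplotypes, SV calls

Aligned molecules' labels are clustered into consensus sites:
reference-matched labels cluster by their site; unmatched labels cluster
*per segment* (between their molecule's flanking matched anchors, keyed
by measured offset from the anchor label), which keeps inserted, gap-fill
and extension content geometrically consistent across molecules.  Runs of
unmatched labels whose offset spread exceeds twice the sizing SD are
split recursively (random false-positive labels chain into broad runs at
this density; genuine sites are tight).  Consensus positions walk the
reference-matched clusters using the median molecule-measured spacing,
snapping onto the reference position when within 5 kb (absorbing sizing
drift) and keeping measured geometry across indels; segment clusters sit
at their median offset from the anchoring site.  Sites are retained with
support >= max(3, 30% of spanning molecules) (35% for non-reference
sites, where false-positive coincidences concentrate).  The walk is
re-run after the support filter so that a handful of mis-matched labels
cannot anchor it onto reference sites the sample lacks.  End extension is
the consensus content beyond the outermost reference-matched site, less
the reference DNA remaining past it.

Haplotype discriminants are proposed from bimodality:

- *site presence*: an interior reference site carried by 30-65% of the
  molecules whose alignments match sites on both its flanks.  A true
  heterozygous site sits near 45% (half the molecules, less 10% FN);
  homozygous sites sit at 70-90% once aligner slop is added, which is why
  the window is asymmetric around one half (a symmetric 20-80% window
  admits too many single-allele artifacts).  Sites with a reference
  neighbour closer than 1.5 kb are not candidates (labels there are not
  attributable to one site), and both sides of the split must have at
  least 5 molecules.  In the end-extension region the same logic applies
  to segment clusters with a slightly higher floor.
- *interval length*: an inter-site interval (between well-supported
  reference-matched clusters) whose molecule-measured lengths split at
  the largest gap into two modes at least 10 kb apart, each with >= 5
  molecules, with the gap at least 60% of the separation.

Molecules join the haplotype signature (a distinct complete feature
vector carried by >= 5 molecules; at most two signatures) agreeing with
the majority of their observed features; ties and conflicts stay
unassigned, so false-negative labels push molecules out of the
partition rather than across it.  Per-group consensus maps are then
rebuilt from members only.

Large insertions/deletions are called from clustered per-molecule outlier
residuals (matched intervals whose sizing discrepancy exceeds 20 kb),
sized by the median residual over supporting molecules.  This is robust
to a known aligner failure mode: for indels whose labeled content offers
chance matches to reference sites, the DP sometimes "absorbs" part of the
content, smearing that molecule's residual below threshold -- such
molecules drop out of the supporting set instead of biasing the size.
When no molecule-level data is available the consensus map itself is
aligned to the reference (the same DP) and interval discrepancies are
reported.  Consensus sites inside reference gap intervals become
`gap_fill` calls; positive end extension becomes `distal_extension`.
Calls are coded `g` (gap fill/extension), `sv` (indel), plus `h` when the
call is absent from, or differently sized in, another haplotype group.

**Trio consistency**: each child haplotype group is matched to the
closest parental group by consensus-map distance = 1 - (co-matched site
fraction under nick-pattern DP alignment of the two maps, sizing slack
1.5 kb/3).  Pattern alignment rather than positional matching absorbs
the slow positional drift consensus chains acquire away from
reference-snapped anchors.  Same-allele maps from different individuals
measure 0.03-0.06; different alleles sharing a backbone ~0.13; unrelated
maps of the same density ~0.35; the Mendelian-consistency bound is 0.10.
Both child-to-parent pairings are scored and the better one reported;
equal pairings (e.g. both parents homozygous for one allele) are flagged
ambiguous.

## Telomere length estimation

For a p-arm, with the molecule in reference orientation, the estimate is
`label(first matched pair) - site(first matched pair)`: the unlabeled
overhang beyond the telomere-proximal *matched* label, less that site's
distance from the reference origin (q-arms are mirror-symmetric using the
reference end).  Matched pairs, not raw first labels, anchor the
measurement because the overhang may contain spurious labels.  A known
`distal_offset` (e.g. an assembly's 10 kb unsequenced-telomere
placeholder) is subtracted; when the offset is unknown (gap haplotypes)
the estimate is flagged as an overestimate -- and simulations reproduce
the expected law: with 10 kb of unmodeled telomere-adjacent DNA the mean
estimate exceeds the true tract by 10.0 +/- 0.15 kb.  Negative raw values
(possible under sizing noise) clamp to zero with a flag; more than one
unmatched overhang label per 10 kb flags likely non-telomeric content.
Estimates are refused (not errored) below the confidence threshold or
without 1-copy anchoring.  Aggregation reports arithmetic mean, sample SD
(n-1), and molecule count per telomere and haplotype, in kb at one
decimal, with a gap asterisk inherited from any flagged member.

## Numerical and design choices

- Problem sizes: bundled scenarios use 230-320 kb references (25-40
  sites) at 30x coverage (~100 molecules); the overestimation law uses
  deep coverage to collect ~200 telomere-terminal fragments; the SV size
  calibration plants 12 indels of 20-60 kb.  These sizes keep every
  property statistically decisive at desk scale.
- Ties in alignment resolve by (score, more pairs, smaller total
  |residual|, forward orientation) for determinism.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give bit-identical
  molecule sets, and results are independent of thread count (the
  implementation is sequential).
- Degenerate inputs: molecules with fewer than two labels are
  "unalignable" (None, not an error); empty estimate groups are omitted;
  zero coverage simulates zero molecules; empty FASTA digests to an empty
  map set.

## Known limitations

- Contiguous indels whose labeled content exceeds the 8-skip window
  (~75 kb at genomic density) cannot be bridged in one transition;
  detection sensitivity degrades near that limit (size accuracy of called
  indels is unaffected).  `max_skips` is configurable at quadratic cost.
- Reference-anchored consensus only: regions with no alignable flank in
  the reference (entirely novel subtelomeres) are delineated only as end
  extension, not assembled de novo.
- At most two haplotype groups per subtelomere (diploid model); somatic
  mosaicism and chimeric molecules are out of scope.
- Gap-region delineation is bounded by the most distal *labeled* content;
  unlabeled distal DNA is indistinguishable from telomere repeat.
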