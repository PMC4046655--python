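# Methods

## Motif model and scanning rule

A motif model assigns each position a non-negative weight per base
(columns A, C, G, T). Built from a consensus string, each specified
position carries weight 1 for its base and 0 otherwise; `N` positions are
all-zero, so they contribute nothing to either a window's score or the
model maximum. The canonical CtrA box `TTAA-N7-TTAAC` therefore has
`S_max = 9`. Numeric matrices are accepted as well; because the
fraction-of-maximum rule is ill-posed for negative (log-odds-style)
entries, matrix models are by default rescaled per position by subtracting
the position minimum, which preserves within-position ranking.

A window is reported when `S ≥ f·S_max` (default `f = 0.85`; on the
9-point consensus model this means at least 8 of 9 specified positions
match, since scores are integral). Both strands are scanned by default —
transcription-factor boxes act in either orientation — with a
`forward`-only switch. Reverse-strand hits are reported at the offset of
the match's leftmost base on the scanned sequence. Overlapping hits are
all kept; collapsing hits per promoter is done at the summary level, which
is why the headline regulon statistic is "promoters with ≥ 1 site" rather
than a site count. A float comparison epsilon of `1e-9·max(1, S_max)`
guards the threshold and the perfect-site test for rescaled matrices.

One structural property of the box is worth knowing: its reverse
complement, `GTTAA-N7-TTAA`, contains an 8-of-9 match to the consensus
shifted by one base. Every perfect site therefore casts a deterministic
opposite-strand "shadow" hit at ±1 with score 8 (9 when the flanking base
happens to complete the second half-site). Site-level counts from
double-strand scans include these shadows; promoter-level counts do not
change, and perfect-site counts are unaffected when the flank does not
extend the match.

## Promoter windows

Windows run from 400 bp upstream to 50 bp downstream of the translation
start, taken from the annotation (CDS start for + genes, CDS end for −
genes; no start-codon verification). Input coordinates are 1-based
inclusive (GFF3 convention); oriented promoter offsets are 0-based.
For a + gene the genomic window is `[start−400, start+49]`; for a − gene
`[end−49, end+400]`, reverse complemented, so the extracted sequence always
reads 5′→3′ with respect to the gene and a planted site at oriented offset
*k* is found at offset *k* regardless of strand. On linear contigs the
window is clamped at the edges and flagged `truncated`; contigs declared
circular wrap instead (an explicit per-contig flag — wrap vs. truncation
changes edge-gene windows and should never be guessed). Promoters are not
trimmed when they overlap neighbouring genes.

## Regulon scan and quorum-sensing screen

`genome_scan` extracts and scans every gene's promoter; genes whose
promoter cannot be extracted are logged and excluded from denominators.
Summaries report promoters-with-site, total sites, perfect sites and
promoters-with-perfect-site. The cross-species screen first selects
quorum-sensing genes by precomputed domain labels (pfam00765 autoinducer
synthase, pfam03475 autoinducer binding — domain detection itself is
upstream annotation, not recomputed here), then scans only those promoters
per strain. Because comparative figures of this kind are ambiguous about
whether a strain's class counts QS promoters carrying a site or total
sites, both numbers are reported and neither is treated as canonical.
Output ordering is by strain id, so results are invariant to input order,
and a strain with unreadable inputs is recorded as failed without aborting
the screen.

## Phylogeny

The pipeline is complete deletion → p-distance → Poisson correction →
neighbor joining:

* **Complete deletion** removes every column containing `-`, `?` or `X`
  (`?` is missing data, `X` an ambiguous residue, following MEGA's
  behaviour).
* **p-distance** is the fraction of differing positions; the **Poisson
  correction** `d = −ln(1−p)` converts it to expected substitutions per
  site. `p = 1` is saturated and aborts with the offending pair named.
* **Neighbor joining** uses the Studier–Keppler criterion
  `Q(i,j) = (n−2)d(i,j) − r_i − r_j` with ties broken toward the lowest
  (i, j) pair in the current node ordering, making the tree deterministic.
  Branch lengths come from the standard two-point formulas; negative
  lengths are kept by default (`clamp_negative` zeroes them, which changes
  the total branch length and is therefore opt-in). The returned tree is
  unrooted, represented with a trifurcating seed node. Two taxa yield a
  single leaf pair carrying d/2 each, so the leaf-to-leaf path equals
  d(1,2). The implementation is cross-checked in the test suite against
  scikit-bio's NJ and recovers additive matrices to 1e−9.

Note that NJ joins the pair minimising Q, not the closest pair: when
corrected distances violate the triangle inequality, two identical
sequences need not form a zero-length cherry.

## Differential-expression calling

A gene is called per contrast when |log₂FC| ≥ 1 and BH-adjusted p < 0.05.
The inclusive fold-change boundary is the default (a `strict_gt` option
gives the strictly-greater variant, since both phrasings circulate for
this rule). Adjustment is per contrast over that contrast's gene list,
via the standard step-up procedure (statsmodels' `fdr_bh`); precomputed
adjusted p-values can be used instead. Genes with missing statistics are
excluded from calling, with a logged count. With permissive thresholds
(`lfc_min = 0`, `alpha = 1`) genes split by fold-change sign and an exact
zero belongs to neither set. Venn partitions assign every called gene in
the union to exactly one membership signature (all 2^k−1 cells are
reported, zeros included); the direction used per contrast (up, down, or
either) is a parameter, with `either` the default. Category tallies count
up/down calls per user-supplied gene→category label, with unmapped genes
under `unassigned`; microarray preprocessing and model fitting are
consumed as input, never recomputed.

## Synthetic data

The generators exist so that every pipeline stage can be tested against
exact known truth; all are deterministic under a fixed seed (byte-identical
outputs).

* **Genomes.** Genes are laid out in private 1150-bp blocks (600-bp CDS,
  room for a full 450-bp promoter on either strand, 100-bp gap), strands
  drawn with a configurable minus fraction. Motif instances with a
  requested mismatch count (applied to specified consensus positions) are
  planted at requested oriented promoter offsets. The background is
  rejection-sampled against the live scanner at a guard threshold of 0.75
  of the maximum — below the 0.85 operating point so a two-mismatch plant
  (7/9 = 0.78) is still the only thing near threshold in its window — and
  every non-planted, non-shadow hit has its background positions redrawn
  until none remain. Shadow hits (see the motif section) are whitelisted
  and their flanking base is pinned so they can never be perfect. As a
  result, promoters-with-site and perfect-site counts are exact truths.
* **Strain collections** plant one perfect site per selected QS promoter,
  so promoter-level and site-level classes coincide by construction, and
  label QS genes alternately with the synthase and receptor domains.
  Decoy sites upstream of unlabelled genes can be added to test the
  selection rule.
* **Protein families** evolve along a given tree from a uniform random
  root: along a branch of length d each site substitutes with probability
  1 − e^(−d), to a uniformly chosen *different* residue, at most once per
  branch. This is deliberately the idealised process whose pairwise
  expectation the Poisson correction inverts — making distance recovery a
  clean inverse problem — not an empirical substitution matrix; back and
  convergent substitutions across branches still occur, so pairwise
  p-distances fall slightly below 1 − e^(−path). Optional gap columns
  (one gapped row in each of g distinct columns) exercise complete
  deletion.
* **DE tables** place a shared core of up/down genes in every contrast and
  draw the remaining calls from contrast-private pools, so the
  all-contrast intersection is exactly the core. True calls get
  |log₂FC| drawn from [1, 3] and raw p-values below 1e−8; null genes get
  |log₂FC| < 0.9, so recomputing the BH adjustment cannot flip any call.
  The generator verifies its own truth by running the caller before
  returning.

Passing tests on these fixtures demonstrate the correctness of the
scanning, extraction, tree-building and calling machinery under the stated
models. They do not probe properties the generators deliberately omit:
realistic intergenic architecture and base composition, overlapping genes,
empirical amino-acid exchangeabilities or rate heterogeneity, microarray
noise, or correlated p-value structure.

## Problem sizes and numerical choices

The acceptance script mirrors the study's printed analysis shapes on
synthetic inputs: 4000-gene expression tables with the published
per-mutant up/down counts (28/168, 6/98, 17/135 exponential; 526/417/517
totals with a 349-gene core stationary), a 305-gene genome carrying boxes
in 101 promoters (five designated flagellar), a four-strain screen with
site classes 0/1/2/4, and a 93-taxon protein phylogeny. Topology-recovery
performance of the Poisson/NJ stage is measured over 50 replicates of an
8-taxon tree at 2000 aligned positions, settings at which the correction's
assumptions hold well and recovery is expected to be near-certain. All
randomness in tests and the acceptance script flows from explicit seeds.

## Known limitations

* The consensus-derived model weights all specified positions equally; a
  laboratory-calibrated PWM with graded weights can be supplied as a
  matrix file but none is bundled.
* Whether published scans covered one or both strands is not always
  stated; both-strand scanning is the default here and affects site-level
  (not promoter-level) counts via the shadow property.
* Joined/spliced CDS features, operon structure and TSS-based promoter
  definitions are out of scope; the promoter window is a fixed
  annotation-anchored rectangle.
* Reproducing a published tree's exact branch-length sum requires the
  original alignment; with alignment construction out of scope, only
  pipeline behaviour (taxon counts, retained columns, recovery on known
  truth) is asserted.
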