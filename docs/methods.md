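# Methods

## Coordinate conventions

All intervals are 0-based half-open on named sequences. BED input is
native; any 1-based dialect must be converted before the readers.
Reverse-orientation anchors and SFs keep `start < end` on both genomes
with orientation as a separate flag, so interval arithmetic never branches
on strand. Output tables are TSV with a commented header carrying the
column names and tool version.

## Syntenic fragment chaining

Anchors of one species are sorted by reference position and chained
greedily. An anchor extends the open chain iff it (i) hits the same
target sequence, (ii) has the same orientation, (iii) advances the target
in the direction the orientation implies, and (iv) leaves a gap smaller
than the resolution on *both* genomes. Chains whose reference span falls
short of the resolution are discarded, which is what makes `resolution`
the smallest detectable rearrangement: an insertion of foreign material
shorter than the resolution cannot terminate a block, and an inverted
segment shorter than the resolution cannot survive as its own block.

Parameters: `resolution` (typical 100/300/500 kb; the simulator's
validation runs use one segment, see below), `min_anchor` (default 1 kb)
suppressing spurious micro-matches before chaining.

Candidate SFs reached through different target sequences can still overlap
on the reference. Overlaps are resolved deterministically: the SF with
more aligned bases wins (ties: the SF starting first); a loser contained
in the winner is dropped, a partial overlap is trimmed off the loser back
to the winner's boundary, and a trimmed loser falling below the resolution
is dropped. Only the loser is touched so the better-supported block's
coordinates are never degraded; trimming at the winner's boundary (rather
than inside the overlap) is what guarantees the non-overlap invariant that
breakpoint derivation relies on.

### Ortholog-order filter

One-to-one ortholog lists are screened by applying the same chaining idea
to gene *ranks* in the two genomes: a gene extends a block if it is on the
same chromosome pair, continues the block's direction, and skips at most
`resolution_genes` (default 1) intervening ranks on both sides. Blocks of
size 1 are removed — labelled *out-of-place* when they fall inside the
reference span of a kept block (wrong neighbourhood), *singleton*
otherwise (no colinear support at all). Open blocks tolerate one
interloper, so two interleaved colinear runs survive intact.

## Breakpoint regions and cross-species groups

One BR per adjacent SF pair per reference chromosome; chromosome ends are
not BRs. SFs abutting exactly still witness a junction and are kept as
1 bp point BRs. A BR whose flanking SFs map to different target sequences
is unobservable in a scaffold-level assembly (the junction may simply be
an assembly break), so it can only support an EBR call when the species is
assembled to chromosomes.

BRs from all species are grouped by single-linkage overlap (≥ 1 bp — the
minimum overlap is a parameter, as the appropriate value is a property of
the input alignments). Within a group:

* the representative interval is the intersection of member BRs when
  non-empty (the conservative shared locus), else the union (flagged);
* several BRs of one species collapse to the smallest (determinism);
* per species: **present** when it contributes an eligible BR; **unknown**
  when its BR crosses a scaffold join, or when its SFs cover less than
  `min_coverage` (default 50%) of the `flank` (default 100 kb) on either
  side of the group — missing data must not masquerade as conserved
  synteny; **absent** otherwise. Flank probes are clipped at chromosome
  ends when reference chromosome sizes are supplied, since absent sequence
  is no evidence of missing data.

EBR intervals are translated into target coordinates through the
target-side boundaries of the flanking SFs (`tgt.end` of a `+` left
flank, `tgt.start` of a `−` left flank, mirrored on the right), normalised
to `start < end`.

## Branch assignment

The likelihood model is in the README. Two design points deserve
elaboration:

* **Pattern-equivalence classes.** With a single reference, an edge on
  the reference path predicts the same observation pattern as the edge
  whose clade is its complement (most visibly the two edges at a
  bifurcating root). Enumerating raw edges would make every such pattern
  an exact tie and nothing on those edges could ever be classified.
  Classification therefore ranks pattern classes; the reported branch is
  the one whose clade equals the predicted observer set, and the all-ones
  pattern is reported on the terminal reference branch, because deeper
  placement along the reference lineage is unidentifiable from overlap
  data.
* **Single-origin model.** Each group is explained by one branch;
  recurrent breakage at the same locus on two branches is absorbed by α
  or, when the two lineages are disjoint, surfaces as a likelihood tie
  and an honest *uncertain* call.

Defaults α = 0.02, β = 0.10, LR threshold 10. Note the deliberate
consequence: a pattern supporting a terminal branch with every other
species absent has LR = (1−α)/β ≈ 9.8 against the parent edge, so a
single-species signal is *not* confident at the defaults — one species'
private breakpoint is exactly one missed observation away from its parent
edge. Datasets with better-characterised error processes should tighten
α, β accordingly; the simulation benchmark, whose anchors are noiseless by
construction, uses α = β = 0.01, under which the same pattern yields
LR = 99. Branch lengths are ignored throughout (pattern congruence, not
rates). Ties (LR = 1) are always *uncertain* regardless of threshold.

## Chimeric-scaffold QC

Candidate EBRs inside scaffolds are screened on the minimum paired-read
spanning coverage over the EBR interval, thresholded per
sequencing-coverage class. Thresholds are calibrated on examples labelled
by independent verification, minimising false positives + false negatives
over all integer cutoffs (ties: smallest). The *direction* of the
criterion — whether low or high spanning support marks an artifact — is a
configuration switch (`reject_low_span` / `reject_high_span`), defaulting
to `reject_low_span`: in a correctly assembled scaffold read pairs do span
a genuine evolutionary junction, whereas a chimeric joint tends to lack
physical coverage. Both directions are first-class and tested, since the
appropriate convention depends on how the spanning statistic was computed
upstream. Spanning input is a precomputed per-interval TSV, not a BAM.

## msHSBs and length statistics

For a clade set, msHSBs are the within-chromosome complement of (a)
representative intervals of groups classified EBR on a branch whose
predicted observer set intersects the clade and (b) uncertain groups
observed present by any clade species. Uncertain breakpoints are excised
deliberately: a region is only called conserved when nothing *suggests*
breakage. The default working resolution for msHSBs is the finest
available (100 kb in a standard three-resolution run), since missed EBRs
inflate multispecies synteny.

Lengths are tested against Exp(1/mean) with a one-sample KS test
(asymptotic p). Because the rate is estimated from the same data the
plain p-value is conservative (Lilliefors effect); a seeded
parametric-bootstrap p (999 resamples, off by default) is provided for
calibrated inference — under simulation the plain test rejects below
nominal α while the bootstrap rejects at ~α. Blocks longer than expected
by chance are flagged by the closed form
P(max of n iid Exp(λ̂) ≥ x) = 1 − (1 − e^{−λ̂x})^n < α (default 0.05);
no simulation is needed and the maximum construction gives family-level
control.

## Windowed enrichment

Chromosomes are tiled with non-overlapping windows (default 10 kb,
trailing partials dropped). Feature load is bp of overlap (TEs, CNE and
coding bases) or a midpoint-rule count (genes). TE enrichment compares
loads in EBR-containing windows (≥ 1 bp overlap) against the rest with a
two-sided Mann–Whitney U — exact for samples of ≤ 8 without ties, else
the tie-corrected normal approximation — restricted to abundant families
(mean ≥ 100 bp in EBR or non-EBR windows), with Benjamini–Hochberg FDR
across the lineage × family tests. The rank test is the deliberate choice
for zero-inflated bp loads; Welch's t is a swappable alternative.

Density ratios (CNEs, genes in msHSBs) use windows *fully contained* in a
region, with an optional region-length floor (the "> 1.5 Mb" variant);
genes are counted per window while CNEs default to count mode for
ratio tables and bp mode for the coding-control, matching the magnitudes
those statistics are conventionally reported in. The coding-as-CNE
control relabels coding bases as CNE bases and reports the mean per-window
ratio of inflated to real CNE bases over windows with any CNE base,
genome-wide and per stratum — a value near 1 shows CNE enrichment is not
an artifact of gene sparsity. Gene lists are exported per EBR (± 300 kb
flank, a gene may hit several EBRs) and per msHSB (full containment,
≥ 1.5 Mb floor) for external GO tooling; GO testing itself is out of
scope.

## The simulator

Genomes are signed permutations of atomic segments (default 10 kb) over
chromosomes; nucleotides are never simulated because breakpoint placement
and branch assignment are the quantities under test. Events are drawn per
branch in preorder: inversions (chromosome chosen ∝ length, two internal
boundaries, span ≥ `min_inv_segments`), translocations of internal runs,
head-to-tail fusions, fissions. The default mix is 80/10/5/5
(inversion/translocation/fusion/fission), reflecting the predominantly
intrachromosomal mode of avian genome evolution; the validation benchmark
uses inversions only, as the criteria it checks concern junction placement
and branch assignment. A boundary already used on a branch is not reused
on that branch (rejection sampling); reuse *across* branches is allowed
and stresses the classifier. Leaf assemblies can be fragmented to a
target N50 with optional chimeric joins (logged as QC ground truth), and
anchors are emitted per maximal shared-segment run with optional dropout
and boundary jitter. Everything is reproducible from the seed.

**Ground truth.** An event contributes one true EBR per junction whose
broken-or-created segment adjacency survives in the *final* reference
genome; junctions subsequently reworked on the reference lineage are not
reference-observable, and fusion/fission junctions landing on reference
chromosome ends drop out of the same rule (chromosome ends are not BRs).

**Recovery scoring** is hit-based: a truth junction is recovered if a
detected EBR lies within the tolerance (overlap or gap); a detection is a
true positive if it matches any truth junction; branch accuracy is scored
per recovered junction against its nearest detection. Hit-based matching
is used instead of one-to-one assignment because two branches can break
the same boundary, putting two truth entries at one reference coordinate.

**Benchmark conditions.** Six-leaf tree `(((A,B),(C,D)),(E,R))` with
reference R, 500 segments (5 Mb) over 5 chromosomes, 8 inversions of
≥ 12 segments per branch, noiseless anchors, chromosome-level leaves.
Detection runs at a resolution of one segment — the simulator's own
breakpoint-placement precision — with matching 10 kb tolerance. At this
event density ~3–6 boundaries per genome are hit on two branches;
disjoint-lineage collisions are structurally ambiguous (likelihood ties →
*uncertain*), nested ones resolve to the ancestral branch, so single-run
recall and branch accuracy fluctuate by a few percent with the random
incidence of collisions. The benchmark therefore reports means over 30
independent replicates of the same conditions (~150 runs: recall ≈ 0.96,
precision 1.0, branch accuracy ≈ 0.92), which measures expected pipeline
performance rather than one draw of collision luck.

## What the simulator does and does not show

Passing the benchmark demonstrates correct junction placement, grouping
and branch assignment under the observation model's own assumptions. Real
alignments add features the generator does not emulate: duplicated and
repetitive anchors, alignment boundary error far beyond uniform jitter,
assembly base error, unequal genome sizes and missing chromosomes, and
rate heterogeneity across lineages. The QC stage is exercised against
simulated chimeras only; its thresholds on real data must be calibrated
from wet-lab-verified examples.

## Numerical choices and degenerate inputs

* Likelihood ties are resolved to the smallest branch id before ranking so
  float jitter in log-sums cannot flip the reported branch; a tie always
  means *uncertain*.
* Zero-length SF gaps become 1 bp point BRs; abutting target boundaries
  translate to 1 bp target intervals.
* `calibrate_threshold` requires both label classes; all-absent patterns
  classify as *uncertain* (no signal); KS fitting requires n ≥ 3 positive
  lengths; density ratios are undefined (error) when the outside mean is
  zero.
* Seeds: every stochastic routine takes an explicit seed; derived
  sub-seeds are reduced mod 2³¹.

## Known limitations

* The error model is iid across species and branches; no rate or
  branch-length information is used.
* Breakpoint reuse across branches is simulated but not modelled by the
  classifier (single-origin); reused boundaries are reported *uncertain*
  by design rather than split into multiple events.
* SF overlap trimming adjusts reference coordinates only; the target
  interval of a trimmed SF retains its pre-trim extent, which slightly
  widens translated EBRs adjacent to trimmed blocks.
* The spanning-coverage statistic is consumed precomputed; mapping
  artifacts upstream of that TSV are invisible to the QC stage.
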