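# Methods

## Model and procedure

The pipeline detects gene pairs retained from whole-genome duplication (WGD)
in a paleo-polyploid genome by macro-synteny: conservation of gene *content*
between large windows of gene order, deliberately ignoring exact order and
strand. All coordinates are 0-based order ranks along chromosomes; windows
are half-open rank intervals. Genes not anchored on a named chromosome
(scaffold/contig/unplaced labels) are excluded at load time, since rank-based
windows are meaningless on fragmented sequence.

### Windows

Each chromosome is tiled at every configured window size (default 100, 200,
300, 400, 500 genes) with step `size/2` (50% overlap). The step is a design
choice: overlapping windows prevent a duplicated segment from being split
across a window boundary at every size simultaneously. A chromosome shorter
than the window size forms a single window; a trailing window shorter than
half the size is merged into its predecessor rather than standing alone, so
no window except a lone short chromosome carries fewer than `size/2` genes.

### Doubly conserved synteny anchors

For an outgroup window, `n` counts its genes with at least one ortholog
anywhere in the target; each such gene contributes at most one hit `k` per
target window however many orthologs it has there (one-to-many ortholog
links are kept — they are the raw material of the duplication signature).
An anchor requires at least two pairwise non-overlapping target windows
with `k ≥ min_hits`, where `min_hits` defaults to 6 per 100 window genes and
scales proportionally with window size (floor 2). Target windows on the
same chromosome are allowed by default (post-WGD fusions can carry both
copies); `allow_same_chromosome=False` restricts anchors to distinct
chromosomes.

Self-comparison anchors run the same machinery on one genome against itself
with WGD-epoch paralog links in place of orthologs. Window pairs overlapping
in rank space are excluded (this removes tandem-cluster artifacts), each
unordered window pair is reported once, and a single qualifying partner
window suffices — in self comparison the query window and its partner *are*
the two copies of the duplicated segment, so the "two windows" requirement
of the outgroup comparison is already embodied by the pair itself.

### q-scores

Null model: the `n` placed orthologs of an outgroup window are a uniform
draw of `n` positions among the `G` anchored genes of the target genome, so
the number falling inside a `K`-gene target window is
`X ~ Hypergeometric(G, K, n)`. The raw score of a window pair is the upper
tail `P(X ≥ k)`, computed through scipy's log-space survival function; all
downstream aggregation stays in log space, so no q underflows for any
realistic genome size.

For a candidate pair supported by an anchor, the raw pair score is the
product of the two supporting windows' tails, multiplied by a Bonferroni
factor `m` = the number of target windows with at least one hit for that
outgroup window (the set of windows actually examined as potential
paralogons), capped at 1. Aggregation order is fixed: minimum over
supporting anchors within a window size, geometric mean over window sizes,
then a weighted geometric mean over outgroup species. Self-comparison
scores use the single linked window pair's tail times `m`, with the same
min/geometric-mean aggregation; there is no cross-species combination for
the self score. Candidates never landing in any anchor are reported as
"unsupported" diagnostics rather than assigned q = 1.

Per-outgroup-window Bonferroni is the only multiplicity correction;
genome-wide FDR is deliberately not applied — the tier thresholds play that
role and remain interpretable as per-pair chance probabilities.

### Species weights

Sampled vertebrate genomes are phylogenetically redundant. Let `s_ij` be the
Jaccard similarity of the sets of target genes for which outgroups `i` and
`j` supply orthologs, computed from the actual input tables so the weighting
adapts to any panel. Weights solve the linear system `Σ_j s_ij w_j = 1`
(minimum-norm least squares): each species should contribute one unit of
*independent* evidence, discounted by the share already carried by similar
genomes. The defining property, enforced by test, is clone invariance —
duplicating a genome splits that genome's weight between the copies and
leaves every other weight and the combined q unchanged (< 1e-12 drift), so
oversampling a lineage can never increase its effective vote. For
independent panels all weights are 1 and the combination reduces to the
plain geometric mean. Should a pathological similarity structure (not
achievable by Jaccard indices, which satisfy the triangle inequality on
1−J) yield a non-positive weight, the implementation falls back to
reciprocal row sums `w_i = 1/Σ_j s_ij`.

### Candidate filtering and tiers

Candidates are paralog pairs whose duplication-epoch label is explicitly in
the configured target set (e.g. `{Vertebrata}` for 2R, `{Clupeocephala}`
for 3R in annotation-derived tables; `{WGD_1, WGD_2}` in simulated ones);
unknown labels are never remapped. When multiple annotation snapshots
disagree, `consensus_epoch` takes the strict majority and excludes ties as
UNRESOLVED. Genes with more than 30 paralogs (any epoch) are removed first:
massive small-scale expansion inflates window hit counts and the synteny
statistics.

Tier thresholds on (combined outgroup q, self q) default to strict
(0.01, 0.01), intermediate (0.05, 0.30), relaxed (0.30, 0.30); both bounds
must pass (AND), thresholds are config keys and validated to be nested, so
strict ⊆ intermediate ⊆ relaxed holds by construction. A missing self or
outgroup score fails every tier and is logged. Families are connected
components of the pair graph per tier, with ids assigned by the smallest
member id, so output is independent of input order.

## The simulator

`simulate` lays `n_genes` ancestors on `n_chromosomes`, branches
`n_outgroups` non-duplicated lineages (independent per-gene loss at
`outgroup_loss_prob`, then inversions and tail translocations), and applies
`wgd_rounds` duplications to the target lineage. Every duplicated pair
keeps both copies with `retention_prob`, else one uniformly chosen copy
dies — genes are never lost outright, so the expected extant count is
`n_genes·(1+p)^rounds`. Rearrangements are applied after the rounds;
small-scale duplications then insert copies in tandem (probability 0.5) or
at a uniform position, at `ssd_rate` expected events per gene. Every gene
records its ancestor and copy path, so paralog epochs (first path
divergence = that WGD round; identical paths = SSD) and true ohnolog pairs
are exact, and ortholog links follow ancestor identity (one-to-many after
WGD). `retention_odds_multiplier` multiplies later-round retention *odds*
for genes already in a retained earlier pair, which reproduces the observed
coupling where earlier-WGD ohnologs preferentially retain later-WGD
duplicates; by construction the gene-level odds ratio equals the multiplier.

Outgroups always branch before the simulated rounds. A 3R-like analysis —
where real outgroups are non-teleost vertebrates that branched after 2R but
before 3R — is represented by simulating only the 3R round
(`wgd_rounds=1`), which is equivalent from the method's point of view.

What the simulator does *not* model: sequence evolution, epoch-label noise
(annotation-derived duplication dates in real data are imperfect, simulated
ones are exact — so precision measured against simulated truth exercises
the scoring path, not label error), chromosome fission/fusion beyond tail
translocation, and gene family birth/death in outgroups. Passing recovery
tests therefore demonstrate the synteny/scoring machinery, not robustness
to mis-dated paralogs.

## Numerical and degenerate-input choices

- Tails are exact (`scipy.stats.hypergeom`), `k = 0` returns exactly 1, and
  parameters are validated (`0 ≤ k ≤ n ≤ G`, `K ≤ G`, `k ≤ K`).
- Being exact and discrete, the tails are conservative as p-values: under a
  shuffled-genome null the fraction below α sits slightly *under* α
  (≈0.007 at α = 0.01 for the default window sizes on a 1000-gene genome),
  matching the analytically computed attained level of the discrete test.
  The calibration tests assert agreement with that exact expectation and
  that the statistic is never anti-conservative.
- Ties when ordering genes with equal start coordinates break by
  lexicographic gene id; greedy anchor-window selection orders by
  descending k, then chromosome, then start rank — all deterministic.
- Reruns with identical inputs, configuration and seed produce
  byte-identical outputs (sorted rows, full-precision float formatting,
  sorted-key JSON manifest).
- Empty genomes, empty epoch sets, self paralog pairs, links to unknown
  genes and zero-margin contingency tables are rejected or flagged
  explicitly, never silently repaired.

## Problem sizes used in tests and the acceptance script

Recovery runs use 2000 ancestral genes, 8 chromosomes, retention 0.25 per
round, 50 inversions + 10 translocations per lineage, 3 outgroups and
`ssd_rate` 0.02 (the family-structure runs set it to 0); null calibration
uses 200 shuffled replicates of a 1000-gene genome against one outgroup;
the retention-coupling recovery uses 10 replicate simulations. These sizes
give stable statistics (≈1500 true pairs, ≈70k null tails) while a full
acceptance run completes in about a minute.

## Known limitations

- Micro-synteny (adjacency conservation) is out of scope; the method cannot
  place ohnologs that moved to entirely non-syntenic locations in *all*
  outgroups and in the self comparison.
- Duplication epochs are taken as input labels; no Ks/Ka or tree-based
  dating is performed.
- The intermediate/relaxed tiers combine outgroup and self thresholds with
  AND; an OR-style combination is expressible only by re-running with
  different thresholds.
- The Bonferroni multiplicity counts hit windows, not all windows — a
  deliberate middle ground between per-comparison and genome-wide
  correction, documented here because the choice is not unique.
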