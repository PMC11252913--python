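# Methods

## The analysis model

The assay sequences two kinds of libraries: *treated* libraries enriched for
fragments containing a polymerase-specific nucleotide analog, and untreated
*control* libraries representing input DNA.  The analysis assumes that after
alignment both reduce to sets of fragment intervals, and that relative
polymerase activity in a genomic region is captured by the ratio of
normalized treated to control coverage in that region.

The map is built per bin *i* of a fixed-width grid (default 50 kb):

1. each fragment is assigned to the single bin containing its midpoint
   `floor((start+end)/2)`, with half-open bins so a boundary midpoint belongs
   to the right-hand bin;
2. each library's counts are scaled to sum to 10⁶ (counts-per-million);
3. enrichment is `log2((T_r + c)/(C + c))` per treated replicate *r*, with
   pseudocount *c* and the control shared across replicates (several controls
   are pooled by summed raw counts before normalization).

Comparisons with genomic features use Spearman's rank correlation computed
per replicate on the bins that survive masking, summarized as mean ± sample
SD (n−1) over the replicates.  Rank correlation is deliberate: enrichment is
a log-ratio with heavy tails and the feature aggregations live on different
scales, so only monotone association is claimed.  No p-values are attached;
a permutation band (99% quantile of |ρ| between random rank permutations at
the observed bin count) is used in the test suite as a null reference.

Replication timing enters as `log2(E/L)`: early and late S-phase count
tracks are each total-count normalized, then log-ratioed with the same
pseudocount logic, making the score invariant to the two libraries' depths.

Anchor profiles work below bin resolution: fragment coverage is counted in
small step windows (a fragment increments every window it overlaps), scaled
to coverage-per-million, and `log2((t+c)/(c+c))` is averaged over anchors per
signed offset.  Minus-strand anchors have their offset axis reversed, so
negative offsets always mean "upstream in element orientation".  Windows
truncated by chromosome ends contribute only where defined; the per-offset
anchor count is reported alongside the mean and its standard error.

## The synthetic-data generator

The simulator emulates the statistical structure the analysis assumes, not
any particular genome.  A toy genome carries per-tile (default 1 kb) latent
tracks:

| feature            | construction                                   | range   |
|--------------------|------------------------------------------------|---------|
| gc                 | smoothed Gaussian field, affinely mapped       | [0.05, 0.95] |
| open_chromatin     | peak intervals, clustered placement; tile coverage fraction | [0, 1] |
| active/repressive mark | softplus of smoothed standardized fields   | ≥ 0     |
| replication_timing | smoothed standardized field × sd, read as log2(E/L) | ℝ  |
| sine/line_density  | repeat-interval coverage fraction per tile     | [0, 1]  |
| promoter           | indicator of tiles within ±1 kb of a TSS       | {0, 1}  |

Smoothing lengths default to 20 kb (GC), 10 kb (marks), 100 kb (timing) and
200 kb (repeat/peak cluster intensity); an infinite smoothing length
degenerates to a constant per chromosome.  SINE (150–450 bp), LINE (2–6 kb)
and simple-repeat elements are placed with smoothly varying intensity —
repeat families cluster regionally in real genomes, and without clustering
the 50 kb-bin density of short frequent elements would be nearly constant
and carry no recoverable signal.  Default coverages are coarse human-like
values: SINE 13%, LINE 20%, simple repeats 2%.  Gene models are
non-overlapping, stranded, 20–100 kb long with 2–4 exons obeying BED12
block rules; the default count is 100 per 50 Mb.  When a sequence is
emitted, each tile gets exactly `round(gc·len)` G/C bases at random
positions, so sequence-derived GC matches the latent track to rounding.

Treated libraries draw each fragment's midpoint tile with probability
∝ `exp(Σ_f β_f z_f(t))`, where `z_f` are the latent values as stored (no
hidden standardization), then jitter the midpoint uniformly within the tile;
controls draw tiles uniformly, modeling input DNA with no capture bias (the
real composition of untreated controls is not characterized; uniform is the
neutral stand-in, and this is the main idealization).  Fragment lengths are
truncated normal, mean 330 sd 60, clipped to the assay's 200–500 bp shear
range; fragments are shifted, never truncated, at chromosome ends so length
invariants hold exactly.  Default design: six treated replicates plus one
control, 200,000 fragments per library — the study scale the tests target.
Default planted effects are β = {gc +0.8, open_chromatin +0.6, active_mark
+0.5, repressive_mark +0.1, sine_density +0.5, line_density −0.2}, with
replication timing and promoter at 0 unless an experiment plants them.

Randomness uses one master seed expanded by a fixed counter scheme
(`SeedSequence((seed, 0))` for the genome, `(seed, 1, condition_code,
replicate)` per library, `(seed, 3)` for early/late timing counts), so
libraries are independent but bit-reproducible.

What passing recovery tests shows — and does not.  Recovery of planted signs
and orderings demonstrates that the pipeline's statistics are faithful to a
known generative model at realistic depth and bin counts.  It does not show
that real capture data follow a log-linear tile model, that real features
are independent (here they are, by construction, except repeat clustering),
or anything about mappability, PCR duplicates, copy-number variation or
sequencing error, none of which are modeled.

## Numerical and design choices

* Midpoint bin assignment (not fractional overlap): keeps counts integral
  and conservation exact; with 200–500 bp fragments in 50 kb bins the
  difference is negligible.
* Pseudocount 0.5 on the normalized (CPM) scale for both bins and profile
  windows; required strictly positive whenever a control value is zero.
* Masking flags bins rather than dropping them, so tracks on one grid stay
  positionally aligned; correlations intersect masks pairwise and report the
  bin count used.
* Cross-replicate aggregation defaults to the bin-wise mean of per-replicate
  log2 tracks; pooled-count aggregation is provided as an alternative.
* Profile statistic is mean-of-log-ratio per offset (robust to a few
  high-coverage anchors; a normalized-coverage mode exists).  Note that
  mean-of-log of noisy ratios carries a small depth-dependent positive
  offset (Jensen bias, larger when the control is shallower than the treated
  pool); it is constant across offsets, so interior-vs-flank contrasts — the
  quantities the package interprets — are unaffected.
* Exact aggregation: union coverage and bp-weighted signal means are
  computed through cumulative-coverage functions evaluated at bin
  boundaries, so results equal per-base brute force to float precision.
* Ties in Spearman's ρ get average ranks (coverage-fraction features tie
  often); constant vectors are rejected as undefined rather than returned as
  NaN.
* bedGraph values are written with shortest-round-trip float formatting, so
  write→read is lossless and pipeline reruns are byte-identical.
* Chromosome order follows the chrom.sizes file everywhere; coordinates are
  0-based half-open in every file and structure.

## Problem sizes

Simulation-based checks run on a 50 Mb single-chromosome genome (1,000 bins
of 50 kb, ≈ 1,000 bins as in genome-scale panels), six treated replicates of
200,000 fragments; profile checks use 20–30 Mb genomes with 200 genes or
the default repeat complement and two treated replicates.  These sizes give
the correlation and profile estimators enough bins/anchors for stable signs
while keeping any single check to a few seconds.

## Known limitations

* The control model is uniform over tiles; real input libraries have GC and
  mappability structure that would attenuate or inflate particular
  correlations.
* Latent features are mutually independent by construction (up to shared
  clustering fields); real chromatin features are strongly collinear, so
  real-data correlations cannot be read as per-feature effects.
* No duplicate collapsing, mappability or GC correction; fragments are taken
  as given.
* Alignment ingestion accepts only proper pairs and reconstructs inserts as
  leftmost-to-rightmost span; chimeric or discordant evidence is ignored.
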