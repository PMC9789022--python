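# Methods

This note documents the models, parameter choices and numerical conventions
behind `clonescribe`, and what the synthetic-data generator does and does
not emulate.

## The measurement model

A cell population is lentivirally tagged so that each cell carries one
30-base barcode drawn from a (W S N)×10 degenerate design (W = A/T,
S = G/C, N = any base; 8^10 ≈ 1.07×10⁹ possible on-pattern sequences).
Barcode read counts per sample estimate clone proportions. In
expression-recording lines the amplicon additionally carries a 20-nt stgRNA
whose locus is cut by Cas9 at a rate proportional to the tagged gene's
expression; non-homologous end joining leaves indels, so the edited
fraction and the indel sizes of a clone's stgRNA reads proxy its cumulative
expression.

## Read processing

Stages mirror the standard amplicon tool chain as native operations:

* **Adapter trimming** — mismatch-only sliding comparison of the 3' adapter;
  an occurrence with mismatch fraction ≤ 0.2 (default) and everything after
  it is removed; fewest mismatches wins, leftmost on ties. Indels inside the
  adapter and partial 3' occurrences are not modeled; on simulator output
  the adapter is always complete.
* **Quality gates** — 3' bases with Phred < 20 are trimmed; reads shorter
  than 25 after trimming, or with fewer than 80% of bases ≥ Q20, are
  rejected. Encoding is fixed at Phred+33.
* **Extraction** — flanks anchor the windows, each flank tolerating one
  mismatch and no indels. The barcode window must be exactly 30 unambiguous
  bases (no WSN-pattern restriction: synthesis error puts many real barcodes
  off pattern, and rejecting them would discard real clones). The stg window
  is length-free up to a cap (default 40) because indels are the signal.
  Rejection reasons are exhaustive and mutually exclusive; passes plus
  rejects always equal input reads.

The amplicon architecture (flank sequences, barcode length, stg template) is
one configuration object shared by the simulator and the extractor, so
round-trip tests cannot drift.

## Barcode collapsing

Within a sample, barcodes are visited in descending read count (ties
lexicographic). A barcode within Hamming distance ≤ 2 of an existing
representative is absorbed into the closest one — ties broken by the
representative's own (pre-absorption) read count, then lexicographically —
otherwise it founds a new representative. Absorbed barcodes never absorb
others, so representatives form an independent set at the threshold and the
procedure is order-deterministic and platform-independent. Reads are
conserved exactly; the absorbed→representative map is returned.

The reference barcode set is the intersection of the collapsed plasmid
library and all independently barcoded cell pools; other samples are then
restricted to it, with discarded reads tallied. For (barcode, stg, reads)
triplets, barcodes are canonicalized to the closest reference
representative within distance 2; reads merge only within identical
(representative, stg) pairs, so distinct stg variants persist under one
clone. Triplets with no representative within distance are dropped and
tallied — the alternative (keeping them as novel clones) would reintroduce
exactly the error variants the reference intersection removes.

## Mutation-score alignment

Global alignment (end gaps charged) with mismatch 1.0, gap open 2.5 and gap
extension 0.5: a k-base gap costs 2.5 + 0.5(k−1). The alternative reading
"2.5 plus 0.5 per base" (a k-base gap costing 2.5 + 0.5k) is obtained by
setting `gap_open_cost=3.0`. End gaps are charged because the stg window is
flank-anchored: a missing terminal base is a real deletion the recorder
must count.

The implementation is a three-state (diagonal / insertion / deletion)
affine-gap dynamic program computed over suffixes, which makes the
tie-break exact: walking forward from the start, the first operation in the
preference order mismatch > insertion > deletion that is consistent with an
optimal completion is taken at every column. Costs are multiples of 0.5 and
exactly representable; comparisons still use a 1e-9 tolerance. The aligner
is verified against exhaustive edit-path enumeration (branch-and-bound over
the raw path tree, no DP) on random short pairs.

Insertions are query-only bases, deletions template-only; the total
decomposes additively and only insertion + deletion feeds the expression
indicator. In positional profiles an insertion is assigned to the template
position it precedes (clamped to the final position at the 3' end).

## Wrong-template filtering

Plasmid stg variants with total score ≥ 4.0 from the template form the
blacklist. A read whose score to some blacklist member is *strictly*
smaller than its score to the template is classed wrong and ignored; ties
retain the read. The threshold participates with the full total (mismatch
included), since the blacklist criterion is overall divergence from the
template, not indel load.

## Diversity and association statistics

Natural logarithms throughout. Corrected barcode number = exp(Shannon
entropy), the Hill number of order 1; it equals richness exactly on uniform
profiles and is ≤ richness otherwise. Jensen–Shannon divergence is computed
on the union support; in top-10 mode, profiles are first restricted to the
union of per-sample top-10 lists and renormalized (a `renormalize=False`
switch keeps raw restricted masses, leaving an implicit "other" category
outside the comparison). Welch's t-test uses Welch–Satterthwaite degrees of
freedom; Bonferroni multiplies by the number of pairwise comparisons and
caps at 1. Two zero-variance groups with equal means give p = 1.

Weighted ranks follow the cumulative-weight mid-rank convention,
rank_i = W(x < x_i) + W(x = x_i)/2, which reduces to ordinary mid-ranks
(shifted by the constant ½, irrelevant to correlations) under unit weights.
Weighted Spearman is the weighted Pearson correlation of these ranks; it is
invariant to strictly increasing transforms of either variable and to
weight rescaling, and reported as NaN when a rank vector has zero weighted
variance. Whether inputs are log-transformed is immaterial for this
statistic. Top-mutated-clone tables select, per sample, the top 10 clones
by mutated-read count (reads with indel score > 0; ties by total reads,
then barcode), take the deduplicated union as rows, and fill entries with
read-weighted mean indel scores (0 where absent).

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions of the package's built-in experiments.

* **Library** — unique WSN×10 draws; a configurable fraction (default 10%
  in the scenario presets) carries off-pattern bases, produced by
  substituting random bases at Binomial(30, 0.05) positions of a WSN draw,
  redrawn until the pattern is actually violated. This emulates per-base
  oligo-synthesis error.
* **Growth** — at dispersion 0 counts scale deterministically; otherwise
  clone probabilities are drawn from Dirichlet(frequencies/dispersion) and
  counts multinomially (Dirichlet-multinomial), leaving frequencies
  unchanged in expectation while adding clone-level growth variability.
  Scenario presets use ~200-fold growth with dispersion 2.5e-4 for tumors,
  matching the regime where a few thousand clones lose modest diversity
  during outgrowth.
* **Bottleneck** — founder cells sampled without replacement (multivariate
  hypergeometric); support ≤ founders. Metastasis presets default to 2
  founders.
* **Selection** — binomial thinning; scalar survival = stochastic,
  clone-independent killing; vector survival = heritable resistance.
* **Recording** — each editable molecule is edited with probability
  1 − exp(−rate · expression · days) (exponential waiting time to first
  cut). Indel lengths are geometric with mean 2, truncated at 10 (tail mass
  lumped at 10); deletions:insertions 3:1; deletions centered at the cut
  (default position 16 of 20). Insertions are templated duplications of the
  bases immediately 5' of the cut — the dominant NHEJ +1-type outcome —
  which also keeps the outcome space small and cacheable. A molecule is
  editable only while its cut-site ±3 window is intact at its template
  position (equal length and matching window); every cut-site indel
  destroys this permanently, so molecules are edited at most once and
  percent mutation is monotone in time. Whether multi-edit molecules occur
  in the real system is unknown; this single-edit convention is the
  conservative default.
* **FASTQ emission** — amplicon = flank + barcode (+ stg flank + stg) +
  flank + adapter; per-base substitution errors (default 1e-3) and rare
  indels (1e-5); flat Q37 qualities with optional linear 3' decay; read
  order shuffled so clone identity does not imprint on file order; a
  read-id → clone truth table is written beside the FASTQ. Identical seeds
  give byte-identical output.

What the generator does **not** emulate: paired-end reads and overlap
merging (reads are emitted pre-merged), PCR chimeras and jackpotting,
quality-dependent error rates, immune editing, and any spatial structure.
Passing round-trip tests therefore demonstrate correctness of the analysis
chain under the stated error model, not robustness to every artifact of
real libraries.

## Scenario presets and problem sizes

The built-in experiments are scaled-down analogues chosen to run in seconds
per seed: treatment uses 2000 clones × 50 cells grown 200-fold
(control vs uniform 50% survival); metastasis uses 1000 clones with
2-founder bottlenecks regrown 1000-fold; expression–proliferation coupling
uses 300 clones × 200 cells with Gamma(2, ½) expression, relative fitness
exp(coupling·z + ε), ε ~ N(0, 1) clone-level growth noise independent of
expression, 20-fold multinomial growth, then recording at rate 0.05/day for
14 days. The fitness noise is what makes the coupling detectable as a
graded signal: at coupling 0 abundance carries no expression information,
and the weighted Spearman rises monotonically through couplings
0.25 / 0.5 / 1.0 (≈ 0.2 / 0.5 / 0.85 averaged over 50 seeds).

## Known limitations

* The greedy collapse is a heuristic; a directional-network or Bayesian
  deduplicator could differ on pathological count configurations. The exact
  absorption rule (including both tie-breaks) is fixed and oracle-tested
  instead.
* The aligner is quadratic per (variant, template) pair in pure Python;
  results are cached per distinct variant, which is effective because the
  templated-duplication edit model and real recording data both reuse a
  limited variant vocabulary. Long stg windows (cap 40) keep the DP small.
* `merge_triplets` assumes reference representatives are pairwise > 2×
  threshold apart (guaranteed when built by `merge_barcodes`); overlapping
  reference sets from other sources would make assignment order-dependent.
* Percent mutation defaults to read-weighting; per-clone weighting is a
  switch (`per_barcode=True`), and the two differ whenever clone abundance
  correlates with editing.
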