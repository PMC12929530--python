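# Methods

## The allocation model

One simulation replicate consumes three ordered person streams: an initial
waitlist of `W` candidates with arrival indices `0..W-1` (lower index =
longer waiting), a sequence of `floor(W / ratio)` deceased donors, and a
replenishment stream of exactly two candidates per donor.  For each donor
in turn the engine allocates kidney 1, then kidney 2, each to the chosen
candidate among those on the current waitlist with the donor's exact ABO
group (ABO identity, the rule that protects group-O candidates).  After
both offers, two replenishment candidates join the bottom of the list, so
the waitlist size is constant across donor cycles.  All offers are
accepted; there is no calendar time — the donor sequence is the clock.

Two strategies are implemented.  *Base-case* (an approximation of current
queue-based practice) picks the longest-waiting eligible candidate.
*Deliberate* matching picks the eligible candidate with the lowest
mismatch score summed over the strategy's objective loci (any subset of
A, B, C, DRB1, DQB1), with waiting time breaking score ties and candidate
id as a final, normally unreachable, tie-break so that every replicate is
a pure function of its streams.  A kidney with no ABO-identical candidate
is recorded as unallocated and the run proceeds; the waitlist invariant
then becomes `len(waitlist) == W + #unallocated`, which the engine asserts
after every cycle.  `run_base_and_deliberate_paired` runs two strategies
over byte-identical streams so that downstream patient-flow accounting
compares allocation logic only.

Priority rules for sensitized, pediatric or urgent patients, offer
declines, cold-ischemia logistics and interprovincial sharing are out of
scope by design.

## Mismatch scoring

The score of donor `d` against recipient `r` at locus `L` is the number of
unique peptides (contiguous k-mers, default k = 9) of the donor's two
allele sequences at `L` that are

1. absent from the recipient's self-peptidome — the union of k-mers of all
   ten recipient allele sequences across the five loci, not only the
   scored locus ("non-self" is defined against the whole HLA complement);
2. accepted by the presenter model for the recipient's DRB1 allele pair.

Scores are counts of unique peptides, deduplicated across the donor's two
alleles; the 5-locus sum is the sum of the per-locus scores and is the
quantity stratified into the clinical risk categories <9, 9–34, 35–89,
≥90.  Match records carry both the stratum of the sum and the strategy's
objective score; cumulative-probability curves are computed on the
objective score.

The presenter is a deterministic keyed hash: `accepts(peptide, drb1_pair)`
is true when `crc32(seed | sorted pair | peptide) < acceptance_rate * 2^32`.
It is a pure function (the same query always returns the same answer), is
symmetric in the DRB1 pair, and marginally accepts a fraction
`acceptance_rate` of random queries.  It deliberately has no biochemical
content: it stands in for a trained presentation predictor so that the
*allocation* dynamics — which depend on score magnitudes, zero-score
structure and between-patient heterogeneity, not on which specific peptide
binds — can be studied reproducibly with no external database.  Users with
real predictor output can bypass it entirely via the score-matrix loader
(`load_score_matrix`), which serves precomputed per-locus scores by
(donor id, recipient id) and always recomputes the sum.

### Performance

Deliberate matching scores every donor against every eligible candidate on
the waitlist, which at a national waitlist of ~2,300 means ~10⁶ pair
scores per replicate.  `SurrogateScorer` therefore indexes every k-mer in
the pool once and represents peptide sets as integer bitmasks: a locus
score is `popcount(donor_mask & ~self_mask & accept_mask)`, with
per-allele, per-genotype, per-DRB1-pair and per-genotype-pair caches.  A
full national-scale deliberate replicate runs in a few seconds on one
core; `clear_pair_cache()` bounds memory between unrelated replicates (the
grid runner calls it automatically).

## Synthetic cohorts

The generator emulates the statistical structure of a heterogeneous
national transplant population rather than any real genotype set:

- **Haplotype pool** — `n_haplotypes` 5-locus haplotypes with frequencies
  drawn from a symmetric Dirichlet (concentration `c`, sorted descending).
  Defaults `n_haplotypes=120`, `c=0.3`: a cohort of ~1,000 patients is
  dominated by a few common haplotypes with a long rare tail, which is
  what produces a realistic hard-to-match minority.
- **Alleles and sequences** — each locus has `round(0.3·n_haplotypes)`
  distinct alleles (default 36); each allele sequence is the locus
  backbone (length 60, random over the 20 amino acids) with substitutions
  at a random half of 24 designated polymorphic sites.  Different loci
  have unrelated backbones, so cross-locus peptide collisions are
  negligible; alleles shared between donor and recipient contribute no
  non-self peptides, giving the correct zero-score structure.
- **Genotypes** — two haplotypes drawn independently (Hardy–Weinberg at
  the haplotype level; no linkage-disequilibrium estimation), ABO drawn
  independently with default frequencies O 0.46, A 0.42, B 0.09, AB 0.03
  (approximately Canadian; configurable).

Identical seeds reproduce identical pools, cohorts and streams
byte-for-byte, and scenario-grid cells derive their seeds by hashing the
cell key, so extending a grid never perturbs existing cells.

### Calibration

`acceptance_rate` is the single knob coupling sequence diversity to score
magnitude.  Its default (0.17) was calibrated once so that base-case
allocation over the default pool lands where five-locus molecular-mismatch
cohorts typically sit: per-locus medians ≈ 15, 5-locus sum median ≈ 77,
per-locus zero-score fractions ≈ 2–4%.  The calibration test asserts the
window (per-locus medians in [8, 30], sum median in [50, 110], zero
fraction < 0.15) rather than point values.

What the generator does **not** emulate: real IMGT allele sequences and
their phylogenetic similarity structure, linkage disequilibrium between
loci, ethnicity strata, and any correlation between ABO and HLA.  Passing
tests therefore demonstrate properties of the allocation *method* (greedy
dominance, waitlist-size scaling, conservation), not quantitative
predictions for a specific real population.

## Scenario grids and analytics

- Default grid: waitlist sizes {100, 200, 290, 400, 800, 1600, 2000, 2286,
  2500} × ratios {2, 2.6, 3, 4}; 10 replicates per cell (heavy tests use
  2 replicates at ratio 3 — the problem sizes used are stated in each
  test).  Replicate-level proportions are aggregated as mean ± SD
  (`ddof=1`; a single replicate reports SD 0).
- *Saturation point* of a probability-vs-W curve is operationalised as
  plateau onset: the smallest size from which every subsequent step of the
  mean curve changes by less than `tolerance` (default 0.01) × curve
  range; a never-flattening curve returns the largest size with a flag.
- Medians use the lower-middle convention (lower of the two central values
  for even counts) so integer scores give integer summaries.
- Patient-flow accounting takes a paired base-case/deliberate run (stream
  fingerprints are checked), derives quartile category edges from the
  baseline matched scores at the empirical 25/50/75 percentiles
  (next-observation convention, so integer scores give integer edges, and
  e.g. a DRB1 multiset with edges 8/14/21 reproduces categories 0–7,
  8–13, 14–20, ≥21), and tabulates every tracked patient's baseline →
  deliberate category, with "Waiting" for patients still listed at the
  end.  Row/column totals conserve the tracked-patient count.
- Hard-to-match detection orders patients by their median static score
  against all ABO-identical donors, smooths the median curve with a
  centred ±5 moving average (truncated at the edges — there is no data to
  reflect), takes first differences of the smoothed curve as a discrete
  slope, and flags patients whose difference exceeds 0.2% of the maximum
  median.  The threshold is relative, so rescaling all scores leaves the
  flagged set unchanged.  All-equal degenerate inputs and
  fewer-than-window cohorts warn instead of failing.

## Numerical and design notes

- Scores, strata and quartile edges are exact integer computations; the
  only stochastic elements are cohort sampling and the presenter hash,
  both seeded.
- The per-locus score cap implied by sequence length (52 k-mers per
  allele) bounds locus scores near 100, comfortably above the highest
  clinical stratum boundary.
- Curve aggregation returns a long-form `pandas.DataFrame`
  (`strategy, ratio, W, threshold_or_stratum, mean, sd, n_replicates`),
  which is also the on-disk TSV schema.
- The CLI (`allosim generate|simulate|analyze|all`) is a thin layer over
  the library: YAML config with strict key validation, TSV-only outputs,
  and a JSON manifest (config echo, version, master seed, per-cell seeds)
  sufficient to reproduce every output.

## Known limitations

- The surrogate presenter has no peptide-binding biochemistry; absolute
  score values are calibrated, not predicted, and only distributional and
  comparative conclusions transfer.
- Unweighted peptide counts; no binding-promiscuity weighting.
- One-year horizon with a constant-size waitlist; no arrival/death
  processes, so long-run equity effects (who accumulates on the list) are
  visible only through the patient-flow snapshot.
- Greedy per-kidney assignment is myopic by construction; it does not
  optimise any global objective across donors.
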