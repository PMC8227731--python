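# Methods notes

This note records the modelling assumptions, parameter choices, and numerical
conventions behind `tfcoop`, and what the synthetic benchmarks do and do not
demonstrate.

## Model and assumptions

The unit of inference is the unordered TF pair. The underlying model is that
two factors which physically cooperate tend to bind at short, roughly
constant spacing in the promoters of co-regulated genes, so their predicted
binding sites co-occur within a 5–20 bp gap far more often than sequence
composition alone would produce. The statistic is association, not mechanism:
a significant pair is *potentially* cooperative, and the method cannot
distinguish direct protein–protein contact from joint recruitment or
correlated motif content beyond what the shuffled background removes.

Assumptions worth stating explicitly:

- **Promoter windows represent regulatory input.** Analysis is restricted to
  −500/+100 bp around the TSS; distal enhancers are invisible.
- **PWMs are independent-position models.** Site prediction uses per-position
  frequencies only; no dinucleotide or shape terms.
- **TF identity is the matrix name.** Matrices are pooled by normalized
  factor name (`V$GATA4_Q3` → `GATA4`), so "cooperation" is scored between
  factor labels, not individual matrices. The normalization rule (strip
  site-type prefix, strip trailing version/quality suffixes, uppercase) is a
  package convention; matrix collections differ in naming discipline and the
  pooling should be reviewed when a library mixes family and member names.
- **Co-occurrence counts are promoter-weighted events.** Every qualifying
  site pair counts once; a promoter with many sites contributes many events.

## Pipeline parameters

| parameter | default | units | rationale |
|---|---|---|---|
| upstream / downstream | 500 / 100 | bp | standard proximal-promoter window |
| pseudocount | 1e-3 | counts | strictly positive frequencies, finite logs |
| core width | 5 | positions | most conserved consecutive window |
| core / matrix cutoff | 0.75 / 0.80 | score | conventional conservative profile; cutoff-sensitive, overridable per matrix |
| d_min / d_max | 5 / 20 | bp edge-to-edge gap | spacing compatible with direct TF–TF contact; gap metric excludes overlapping calls |
| α | 0.2 | — | recommended background scaling in the corrected-PMI scheme |
| n_shuffles | 10 | replicates | background precision vs runtime; AVG(PMI) Monte-Carlo error shrinks as 1/√n |
| log base | 2 | — | PMI in bits |
| z threshold | 3.0 | population z | conservative tail of the scored-pair distribution |

Distance is measured edge-to-edge, `max(start) − min(end)`, negative for
overlapping sites, so `d_min = 5` excludes overlapping and abutting calls; a
center-to-center mode exists for sensitivity analysis. Homotypic pairs (same
factor name, any matrices) are excluded by default and can be enabled.

### PMI normalization

The corrected statistic needs fixed definitions of `p_ab` and `p_a`. The
package normalizes a pair's co-occurrence count by the total number of
co-occurrence events, and a factor's site count by the total site count over
the kept promoters, with log base 2. Pairs never observed to co-occur are
excluded from scoring rather than assigned −∞. A pair absent from every
shuffle replicate contributes AVG(PMI) = 0 — no background co-occurrence is
treated as zero background cooperation, leaving PMIcor = PMI.

One property of this normalization to keep in mind: pairs observed only once
or twice still enter the z-transform, and when a factor has very few sites
overall its pairs can reach large PMI from tiny marginals. Benchmarks
therefore keep factor site counts comparable (see below); real analyses
should treat significant pairs built on single-digit `f_ab` with caution.

### z-transform

z-scores use the population (not sample) standard deviation over all scored
pairs, since the transform describes the full population of scored pairs
rather than a sample from it. If all values are identical the z-scores are
defined as 0. A structural consequence: with K strong pairs among N scored
pairs, no z can exceed ≈ √((N−K)/K); detecting several planted pairs at
z ≥ 3 requires enough chance pairs to populate the null (the shared/private
study scenario uses a 24-motif library for exactly this reason).

## Scanning

The scanner is vectorized over window offsets but algebraically identical to
the per-window definition; the test suite checks exact equality against an
independent brute-force scorer on random instances. `N` bases contribute the
position's minimum frequency — penalizing, never site-creating. An
all-uniform matrix (Max = Min) scores 0 by convention. Minus-strand hits are
reported in forward coordinates; output ordering is fixed (start, end,
tf_name, strand) and scores are rounded to 6 decimals in all outputs. In
`core_positions` the maximal 5-window is chosen leftmost among windows within
1e−9 of the maximum, making the tie-break robust to float summation order.

## Dinucleotide-preserving shuffle

The background correction shuffles each promoter while preserving its exact
dinucleotide counts (hence mononucleotide content, GC content, GC skew and
CpG density). The implementation is the Eulerian-path construction: the
sequence is an Eulerian path in the 4-vertex multigraph of its dinucleotides;
a uniformly random last-exit arborescence into the final character is drawn
by rejection sampling, remaining out-edges are permuted, and the path is
walked. First and last characters are invariants of the construction. The
tests verify exact count preservation on random sequences and, for a small
word, that the sampler reaches exactly the brute-force-enumerated set of
valid arrangements.

## Synthetic corpora: what they emulate, and what they do not

`generate_corpus` emulates the statistical structure the method assumes:
600 bp promoters (the −500/+100 geometry) with i.i.d. or first-order-Markov
background (default mononucleotide A/T 0.315, C/G 0.185 — an AT-rich
vertebrate promoter neighbourhood), a planted pair whose two sites are drawn
from the PWM frequencies (not consensus, so scan scores vary realistically)
at a gap uniform on the scoring window, on random strands, and Poisson-placed
independent decoy sites. Placements never overwrite earlier sites.

It does **not** emulate: positional preference relative to the TSS, CpG
islands or isochore structure, homotypic site clustering, overlapping or
nested true sites, motif-similarity between library entries, or correlated
decoys. Passing benchmarks therefore demonstrate the statistic's correctness
and its power/specificity under idealized promoter-like sequence, not
performance on real genomes, where motif redundancy in the library and
compositional heterogeneity are the dominant nuisances.

Benchmark geometry (200 promoters × 600 bp, one planted pair at penetrance
0.4, 8 decoy motifs at 0.5 sites/promoter, 10 shuffles) mirrors a
study-scale candidate panel between roughly 70 and 190 genes. The
shared/private study scenario uses 250 promoters per phenotype, penetrance
0.7, sharper planted motifs (dominance 0.92) and 18 random decoys, and makes
every unplanted motif a decoy in each corpus so all factors have comparable
marginals; 3 shuffle replicates suffice there because the corpora are large
and the comparison is structural. These sizes were chosen as the smallest
that give the statistic a stable null.

## Determinism

All randomness flows through `numpy.random.Generator` seeded from explicit
seeds; each pipeline stage derives its own 31-bit stream from the master seed
and stage name (SHA-256), so adding shuffle replicates does not perturb
corpus generation. Two runs with the same seed write byte-identical outputs,
and TSV exports print floats at full precision (`repr`) so edge weights
round-trip bit-exactly.

## Known limitations

- MATCH-style cutoffs are global defaults; per-matrix optimized profiles
  (minFN/minFP-style) require curated site collections and are out of scope.
- Redundancy filtering removes exact duplicate promoter sequences only;
  near-duplicates from recent paralogs are kept (no similarity threshold is
  defined here) and can inflate pair counts.
- No multiple-testing layer beyond the z ≥ 3 rule, which controls the tail of
  the scored-pair population, not a per-pair error rate.
- Alternative TSSs are not modelled; the first TSS record per gene wins.
- The z-score ceiling for multi-pair corpora (above) means studies expecting
  many true pairs need a large scored-pair population for all of them to be
  detectable.
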