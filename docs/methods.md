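# Methods

## Model

Input is one or two sets of equal-length sequences (length *L*) and a
compendium of motifs given as position probability matrices. For each
motif of width *w*, every sequence contributes at most one site: the
placement maximising the log-odds score in bits against a 0-order
background, over all *N* = *L* − *w* + 1 forward-coordinate start
positions and, for DNA, both strands. A minus-strand site is indexed by
its leftmost forward-strand base, so the trial space is the same *N*
in both strand modes. Sequences whose best placement scores below the
threshold contribute nothing.

Under the null model that a best site is equally likely to start at any
of the *N* positions, the number *s* of the *S* observed sites starting
inside a sub-region covering *M* positions is Bin(*S*, *r*) with
*r* = *M*/*N*; the enrichment p-value is the upper tail P(X ≥ *s*).
With *n* sub-regions tested, the adjusted p-value is
*p* = 1 − (1 − *p*′)ⁿ (exact under independence; conservative under the
strong positive dependence of overlapping regions — the null-calibration
test measures an empirical false-positive fraction of ~0.002 at the
0.05 level). The E-value multiplies *p* by the compendium size and is
therefore capped at it.

Differential analysis applies a two-sided Fisher exact test (sum of
hypergeometric probabilities of all same-margin tables at most as
likely as the observed one, with 1e-7 relative slack for floating-point
ties) to the table (inside/outside region) × (primary/control), for
each sub-region significantly enriched in the primary set. The Fisher
p-value is adjusted with the same *n* as the enrichment test, and the
Fisher E-value again multiplies by the compendium size. A motif with no
significantly enriched sub-region makes no differential claim: its
Fisher adjusted p-value is reported at the ceiling 1, which is also how
ceiling E-values in paired ChIP-seq comparisons should be read. The
control-suitability verdict judges each direction of a paired run by
the known motif's Fisher E-value: < 0.05 means the other set missed
true sites and is unsafe as a control, ≥ 1 means it is safe, and the
band between is reported as inconclusive.

## Parameters

- **Score threshold** (bits, default 5): conventional cutoff for
  "a match"; the value is user-set rather than derived. Optional
  per-motif optimisation picks the candidate threshold (distinct
  observed best-match scores, quantile-thinned to ≤ 100) minimising the
  motif's adjusted p-value, and conservatively multiplies *n* by the
  number of candidates evaluated. Ties between candidates resolve to
  the lower threshold (more sites retained).
- **Pseudocount** (default 0.1, distributed proportionally to the
  background): keeps log-odds scores finite; with pseudocount 0,
  zero-probability letters score a −1e30 sentinel so window sums stay
  finite, and any placement at or below half the sentinel is treated as
  impossible rather than merely poor.
- **Width grid, local mode** (min 10 bp, max *N*, step 5): local mode
  enumerates every start for every width on the grid, so cost and *n*
  grow quadratically in *L*; the default grid bounds both while
  covering the space, and full enumeration is available through the
  width parameters. Central mode enumerates every width of matching
  parity (defaults 1..*N* step 1), one centered region each, and
  reports only the single best region.
- **E-value gate** (default 10): report-many/filter-later. With a
  realistic compendium (hundreds of motifs) the gate corresponds to an
  adjusted p of roughly 0.01; with very few motifs it excludes almost
  nothing, and downstream protocols that need "significantly enriched"
  regions (the differential fixture analyses and the suitability
  protocol) gate at adjusted p ≤ 0.01 explicitly, the same stringency
  as E-value ≤ 10 against an 884-motif compendium.
- **Background** (default estimated from the input, DNA symmetrised
  over strands, floored at 1e-3 and renormalised): the floor prevents
  degenerate log-odds on skewed inputs.

## Numerical choices

- Binomial tails come from the regularised incomplete beta function
  (`scipy.stats.binom.sf`); log-space tails (`logsf`) back the reported
  log-adjusted p-value, with ln *p* ≈ ln *n* + ln *p*′ once
  *p*′ < 1e-9, so column 6 of the report stays finite and ordered even
  when the adjusted p-value underflows.
- The adjustment 1 − (1 − *p*′)ⁿ is evaluated as −expm1(n·log1p(−p′)).
- Exact score ties in scanning are broken uniformly at random from a
  stream seeded by (run seed, CRC32 of the sequence id), making results
  deterministic per seed and equivariant under permutation of the input
  records; a leftmost rule would bias positional ties.
- Ties in raw p-value during region selection break toward smaller
  width, then smaller start, for deterministic output.
- Odds ratios add 0.5 to every cell only when some cell is zero
  (Haldane–Anscombe).
- An all-zero Fisher table has p = 1 by convention.

## Synthetic data

The generator emulates aligned-window designs: i.i.d. background
letters from a 0-order composition, one sampled site (drawn from the
probability matrix, not the consensus, so score distributions are
realistic) planted per sequence with a set occupancy, placed uniformly,
at a fixed offset, or Gaussian around a center offset. Gaussian draws
falling outside the valid start range are resampled rather than
clipped, avoiding edge pile-ups that would mimic enrichment. The
paired fixtures use 500 sequences of 500 bp, occupancy 0.6 and
positional sd 30 bp — window counts, sizes and central concentration
typical of ChIP-seq peak-region sets — with an AP-1-like 10 bp planted
motif at 0.85 per-column consensus probability.

What the fixtures do not emulate: higher-order sequence composition,
repeats, copy-number and mappability artifacts, correlated occurrences
of multiple motifs, and peak-calling noise. Passing tests therefore
demonstrate the statistics and the machinery, not robustness to every
property of real genomic data.

## Design decisions

- Region coordinates are reported as (center, width) in bp relative to
  the sequence center, matching how positional plots are read.
- *n* counts every enumerated region (no region's test is degenerate)
  and, when threshold optimisation is on, is multiplied by the number
  of candidates tried; whether a separate count should apply to the
  Fisher adjustment was resolved by reusing the enrichment *n*.
- A motif whose best region misses the E-value gate still yields one
  report row (its best region, Fisher columns at the ceiling) so that
  compendium-wide rank queries are total functions.
- The report serialises floats with 6 significant digits; re-parsing a
  written table is exact (a fixed point) after one pass.
- Problem sizes in the test and acceptance runs (20 replicates of the
  500×500 bp fixture; 10,000 simulated motifs at S=100, N=400 for
  calibration) were chosen to give stable pass/fail margins at desk
  scale.

## Known limitations

- Local mode's quadratic enumeration makes whole-compendium runs on
  long windows expensive; the width grid is the intended control.
- The binomial null assumes one exchangeable best site per sequence;
  sequence weighting and multiple sites per sequence are out of scope.
- The multiple-test adjustment is deliberately conservative under
  region overlap; adjusted p-values are upper bounds, not calibrated
  tail probabilities.
- Only the letter-probability subset of the MEME motif format is
  parsed; other blocks are ignored with a warning.
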