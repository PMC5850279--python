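# Methods

## The matching model

The census treats complementarity as exact, contiguous, strict Watson-Crick
antisense identity: a segment window `s` of length *k* matches a sector
position `j` when the sector's k-mer equals `revcomp(s)` under A↔U and G↔C
only. G:U wobble pairs, bulges and mismatches are outside the model; the
lower bound *k* = 7 reflects the instability of shorter (and of AU-rich
6-nt) duplexes at mammalian body temperature, which is why the headline
totals pool 7-15 nt while the scan extends to 20 nt.

Counting is exhaustive: both sequences are slid one nucleotide at a time, so
a segment of length *L* contributes `L − k + 1` windows and every (window,
position) pair is one match. Overlapping, repeated and nested occurrences
all count, and different *k* are tallied independently — a 10-nt match
necessarily contains two 9-nt matches, which is exactly why per-cell counts
must be non-increasing in *k* (asserted at run time by
`MatchTally.validate`). Two optional modes depart from this convention and
are off by default: `unique_windows` deduplicates identical windows within a
segment, and `maximal_only` keeps only duplexes extendable in neither
direction.

The production engine builds, per *k* and orientation, a hash index from
sector-side k-mer to segment window offsets, then streams each sector once;
a naive double-loop scan with the identical contract is kept as an
independent oracle and compared cell-by-cell in the tests. Windows or
positions containing N never match. Sense matches (plain string identity)
use the same machinery.

## Segment handling

Boundary tables use 1-based inclusive coordinates (the rRNA-literature
convention); conversion to half-open indexing happens once, at extraction.
Expansion segments shorter than 6 nt are absorbed into an adjacent core
segment, which keeps its own identifier. The absorbing neighbour is the
*preceding* CS by default — the convention only states that such fragments
join the surrounding core, without a direction — and `merge_direction`
flips this; a leading sub-threshold ES falls forward to the following CS.
Nucleotide totals are invariant under the merge.

GC content counts G+C over the full length, with N in the denominator only:
an uncertain position dilutes rather than inflates the estimate. Pooled
group GC is the size-weighted mean, so `pooled_gc` applied to the five large
human 28S expansion segments (801/104/182/712/208 nt at
83.8/79.8/84.1/86.5/82.7% GC) returns 84.5%.

## Summary statistics

* **Density** is matches divided by segment nucleotides, with no hidden
  factor: 19.312×10⁶ matches over 2,387 nt is a density of ~8,090 per nt.
  Published tables label this quantity "per 100 nt"; the output column here
  is named for what it is, and the per-1,000-mRNA normalization used for
  per-segment profiles is an explicit scale option.
* **Decay regressions** fit log₁₀(count) on *k* by OLS over 7-15 (configur-
  able). Zero counts cannot enter the log and are excluded with a warning;
  fewer than three usable points is an error. The regression x-variable is
  the match length, so the ESL 5′UTR slope of ≈ −0.34 corresponds to a
  ≈ 2.2-fold drop in matches per added nucleotide. The reported `slope_sd`
  is the OLS standard error — appropriate for the 2-SD separation rule
  between groups, but *not* for comparing a slope against the analytic
  expectation on simulated data, where counts across *k* share sampling
  noise; the acceptance suite uses a transcript-level jackknife SE for that.
* **GC of matches** is occurrence-weighted by default (a tract matched five
  times contributes five times); unique-tract weighting is a flag, since
  either convention is defensible. **GC of matched sectors** averages one
  value per qualifying sector (≥ 1 match), unweighted by default with an
  nt-weighted option.

## Null model and tests

The scramble null permutes a segment's residues uniformly (Fisher-Yates via
numpy), preserving the base multiset and hence GC exactly; replicate *i*
uses seed `seed + i`. The compared statistic is the number of transcripts
with at least one antisense 7-nt match in any sector (total match counts are
carried alongside). Because the published aggregate does not state its
pooling weights, both aggregations are emitted: per-segment (each segment's
mean |%diff| and CV averaged) and per-replicate (all replicate values
pooled). A dinucleotide-preserving shuffle is deliberately not the default —
the reference control was a plain permutation.

Wilcoxon signed-rank and rank-sum tests delegate to scipy behind the module
surface: exact null distributions when sample sizes permit and ties are
absent (n ≤ 25 for signed-rank; C(n1+n2, n1) ≤ 10⁶ for rank-sum), otherwise
the normal approximation with continuity/tie correction. Zeros are dropped
before ranking (Wilcoxon's original treatment); p-values are two-sided by
default since sidedness was not specified upstream. The Monte Carlo test
permutes group labels and uses the Welch (unequal-variance) t statistic with
the add-one p-value convention, which is exactly valid under
exchangeability; 199 permutations make the achievable p-values multiples of
1/200, so the nominal 0.05 level is attained exactly in calibration runs.
No multiple-testing correction is applied by default, matching the upstream
reporting convention; a Benjamini-Hochberg adjustment helper is provided for
callers who want one. Slope separation declares two regression slopes
distinct when their closed ±2 SD intervals are disjoint (a touching
boundary is not separation).

## Protein-interaction potential

The per-group profile reweights the pooled base composition by per-base
interaction parameters and renormalizes to 100%:
`freq[b] = 100 · n_b w(b) / Σ n_b' w(b')`, separately for hydrogen-bonding
and van der Waals modes. The parameter table is an external input (the
published source is not reproduced here); the repository ships a synthetic
weight table, labelled as such, whose only commitments are qualitative —
guanine most contacted, pyrimidines intermediate. Consequences that depend
only on composition (the G+C share of an ~80%-GC group exceeds that of a
~57%-GC group for any positive G and C weights) are tested; exact published
frequencies are not, as they require the external parameter source.
Backbone (ribose/phosphate) contributions are excluded; the run manifest
records this.

## Synthetic data

The generator draws iid bases with an even G/C and A/U split inside the
configured GC fraction (a first-order Markov alternative was considered and
rejected as default: the analytic expected-count law that anchors the tests
is an iid statement). Sector lengths are lognormal with mean-corrected mu
(`mu = ln(mean) − σ²/2`, σ = 0.35 by default, 0 giving fixed lengths) around
means 250/1,678/1,474 nt — the human 5′UTR/CDS/3′UTR averages. Default
sector GC is 63/53.5/44%, reproducing the 5′UTR > CDS > 3′UTR gradient of
human mRNA in the neighbourhood of the matched-sector GC values reported
for the low-GC segment groups. The default segment panel covers all four
groups at their reported sizes and GC (an 801-nt, 83.8%-GC ESL7-like and a
182-nt, 84.1%-GC ESL15-like segment versus ~56-58%-GC cores and ESS);
homoiteron runs (e.g. G×6) can be stamped in for repeat studies. The default
scale of 200 transcripts keeps every downstream stage under a minute;
`full_scale()` switches to the full 18,810 for benchmarking.

What the generator does *not* emulate: codon structure, splice isoforms,
UTR motifs, real length-GC covariation, or shared evolutionary history
between rRNA and mRNA. Tests passing on generator output therefore
demonstrate correctness of the counting and statistics under the iid model,
not biological conclusions about real transcriptomes.

Planted-truth fixtures overwrite exact reverse complements of segment
windows at recorded sector positions (redrawn on overlap), giving a known
answer; on a pure-A/U background with a pure-G/C segment, chance collisions
are impossible and recall must be exactly 100%.

## Numerical and scale choices

Acceptance-style checks compare stochastic quantities at 3 standard errors:
binomial SEs for GC and matched-fraction checks, per-transcript sampling
SEs for count totals, and jackknife-over-transcripts SEs for decay slopes.
Problem sizes in the test and acceptance runs (200 transcripts, segments of
a few hundred nt, 500 oracle instances of ≤ 200 nt, 1,000 calibration
datasets at 199 permutations) were chosen so the full suite completes in a
few minutes on one core while keeping every 3-SE band narrow enough to be
informative. Ratios with zero denominators and GC statistics with no
qualifying matches return NaN and are flagged in logs rather than raised,
so sparse large-*k* cells do not abort a run; genuinely invalid inputs
(empty sequences, overlapping boundaries, groups with no members, all-zero
weights) raise immediately.

## Known limitations

* Thermodynamics are not modelled: a 7-nt AU-rich and a 7-nt GC-rich match
  count equally, although their duplex stabilities differ greatly.
* The exhaustive convention double-counts nested matches by design;
  `maximal_only` exists but group summaries assume the exhaustive counts.
* Boundary tables are trusted input; deriving segment boundaries by
  multiple alignment is out of scope, as is any secondary-structure or
  accessibility weighting of the match counts.
* The scramble null preserves composition only; conclusions about motif-
  level (rather than composition-level) selectivity would need the
  dinucleotide or Markov nulls it deliberately does not default to.
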