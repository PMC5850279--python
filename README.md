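# esmatch

Exhaustive antisense complementarity between ribosomal-RNA segments and
messenger RNAs.

Eukaryotic rRNAs carry *expansion segments* (ES) — lineage-specific
insertions between the conserved, prokaryote-related *core segments* (CS).
The large expansion segments of human 28S rRNA are extremely GC-rich
(~80% GC versus ~56-58% elsewhere) and substantially exposed on the ribosome
surface, which makes them candidates for direct base-pairing contact with
mRNAs. `esmatch` quantifies that potential: it counts every contiguous exact
antisense match (strict Watson-Crick pairing, G:C and A:U only, no G:U
wobble) of length *k* = 7-20 nt between every rRNA segment and the three
sectors of every mRNA (5′UTR, CDS, 3′UTR), and derives the summary
statistics used to compare segment groups — ESL/CSL (large subunit) and
ESS/CSS (small subunit).

The package is aimed at RNA biologists who want to reproduce or extend this
style of complementarity census on their own rRNA boundary tables and
transcript collections, with synthetic data generators making every stage
testable without any download.

## The quantities computed

For a segment of length *L*, each *k* yields `L − k + 1` sliding windows
(an 801-nt segment is scanned by 795 successive 7-nt windows); a *match* is
one (segment window, sector position) pair whose sequences are exact reverse
complements. From the per-(segment, sector, *k*) tally the package derives:

* **group totals** over *k* = 7-15 and **densities** — matches per segment
  nucleotide, optionally per 1,000 mRNAs;
* **percentages relative to a reference group** (ESL by default);
* per-*k* **sector ratios** (e.g. 3′UTR/5′UTR);
* **GC content of matched tracts** (occurrence-weighted) and of the full
  sector sequences that carry at least one match;
* **decay regressions**: OLS of log₁₀(count) on *k*; the slope *b* gives a
  fold decrease of 10^(−*b*) in match count per added nucleotide;
* a **scramble null**: matched-transcript counts for the native segment
  versus composition-preserving random permutations;
* nonparametric tests (exact Wilcoxon signed-rank and rank-sum, Monte Carlo
  Welch *t*) and a 2-SD slope-separation rule;
* a composition-weighted **nucleobase protein-interaction profile**
  (hydrogen-bonding and van der Waals modes) per segment group, from a
  user-supplied per-base weight table.

## Worked example

Run the full pipeline on synthetic inputs drawn at the default study
conditions (200 transcripts with sector length means 250/1,678/1,474 nt and
a 5′UTR→3′UTR GC gradient; six segments including an 801-nt, 83.8%-GC
ESL7-like segment):

```sh
esmatch run --out-dir demo --seed 7
```

which reports

```
run complete; outputs in demo (seed 7, 200 transcripts)
```

and writes `segments.tsv`, `tally.tsv`, `summary.tsv`, `gc.tsv`,
`regressions.tsv`, `null_report.tsv`, `potential.tsv` and `manifest.json`.
The same computation from Python:

```python
from esmatch import (GeneratorConfig, generate_inputs, count_matches,
                     summarize_groups)

transcripts, synth, _ = generate_inputs(GeneratorConfig(seed=7))
tally = count_matches(synth.segment_set, transcripts, k_range=(7, 15))
summaries = summarize_groups(tally, list(synth.segment_set))
s = summaries["ESL"]
print(s.total_nt, s.matches["all"], round(s.density["all"], 1))
# 983 64022 65.1
```

meaning: the two ESL-like segments pool 983 nt and accumulate 64,022
antisense matches of 7-15 nt against the 200 synthetic mRNAs — a density of
65.1 matches per segment nucleotide, above the ~56%-GC core-like groups in
the same run (`round(summaries["CSS"].density["all"], 1)` prints 53.9), the
GC-driven contrast the census is designed to expose.

Individual stages are available as `esmatch simulate / segments / match /
metrics / null / stats / potential`, all reading and writing plain
FASTA/TSV so they compose with standard tools.

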