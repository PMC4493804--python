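# Methods

## Problem and model

An integrating retroviral or lentiviral vector joins the host genome at a
single base; LTR-primed amplification (LAM-PCR and relatives) of the
vector–genome junction yields reads of the form

```
[LTR] [genomic flank, junction base first] [linker cassette (optional)] ...
```

The analysis recovers, for each read, the genomic coordinate of the junction
base, collapses reads into unique integration sites, and characterises the
integration profile relative to gene annotations. Two per-site counts carry
the clonality signal: **frequency**, the number of supporting reads, and
**span count**, the number of distinct distal fragment endpoints. Fragment
ends are set by DNA shearing (or restriction digestion), so identical spans
across many reads indicate PCR re-amplification of one molecule, while many
distinct spans indicate independent source molecules, i.e. clonal expansion
of a transduced cell.

## Pipeline stages and parameters

All thresholds live in `PipelineConfig`; defaults below are the recommended
settings and every one is overridable per run (CLI flag, YAML config, or
constructor argument).

| parameter | default | role |
|---|---|---|
| `min_query_len` | 30 bp | minimum trimmed query; shorter queries cannot reach the score cutoff |
| `n_run_limit` | 3 | N-run length that truncates a query |
| `min_score` | 60 | initial alignment-score floor (blast8 column 12) |
| `min_identity_initial` | 92 % | initial identity floor |
| `max_qstart_offset` | 3 bp | max unaligned query prefix; q_start − 1 > 3 rejects |
| `top_k` | 5 | alignments retained per query |
| `ratio_hi` / `ratio_lo` | 95 % / 90 % | second-best/best rejection tiers |
| `ratio_score_boundary` | 100 | best score below this uses the 90 % tier |
| `min_best_identity` | 95 % | identity floor for the accepted best hit |
| `cluster_halfwidth` | 5 bp | ±window merging candidates into one site |
| `gene_max_dist` | 5000 bp | nearest-gene reporting cap |
| `random_n_default` | 100 000 | default random-control size |
| `random_len_bounds` / `random_n_bounds` | 30–1000 bp / 1–100 000 | request validation |

Trimming order is fixed: LTR → LC → N-run → length, with the length check
applied to the final truncated query. LTR and LC matching is exact,
case-insensitive, first-occurrence; a mismatch-tolerant mode is deliberately
not provided — reads whose primer region sequenced poorly are reported under
`no_ltr` rather than rescued. N-run truncation keeps the prefix before the
run, preserving the LTR-proximal junction base that defines the site. If the
LC happens to precede the LTR in a malformed read, the LC search (which runs
inside the query, i.e. after the LTR) will not fire; such reads fail later at
alignment rather than being silently mis-trimmed.

## Alignment

"Alignment score" means blast8 column 12 throughout; the threshold semantics
are configurable because external aligners differ in how they populate it.

The built-in aligner is an exhaustive, ungapped, both-strands seed-and-extend:
every full-length placement of the query that shares an exact 10-mer with the
target is scored as `2·matches − 6·mismatches` (so a perfect 30 bp placement
scores exactly 60, matching the coupling between the minimum query length and
the score cutoff) and reported when identity ≥ 90 %. By the pigeonhole
principle any placement at ≥ 92 % identity of a ≥ 30 bp query contains a clean
10-mer, so at the pipeline's operating thresholds the seed heuristic is
exhaustive — the tests assert exact hit-set equality with an all-offsets
Hamming scan. It is a test oracle and toy-genome workhorse, not a BLAT
replacement: it produces no gapped or partial alignments. Production-scale
data should come in as pre-computed blast8 (`--backend blast8`) or through
the external-command adapter, whose indexing/tuning is the caller's concern.

Query bases `N` count as mismatches; e-values are reported as 0.0 (the
built-in aligner is exhaustive, not statistical, and nothing downstream
consumes the column).

## Site calling

Clustering is greedy and global per (chromosome, strand): repeatedly promote
the greatest-scoring unassigned candidate — ties broken by lowest position,
then read id, for order-independence — and absorb all unassigned candidates
within ±5 bp. This resolves the inherent ambiguity of fixed 10 bp windows
(a candidate 4 bp from each of two stronger sites joins the stronger one).
Opposite-strand candidates at one coordinate are distinct sites: proviruses in
opposite orientations are biologically different integrations. Frequency
counts all grouped members, in-range ones included; span count is the number
of distinct `far_end` (shear-side) coordinates among them.

## Annotation

Gene bodies are transcription bounds (tx_start–tx_end), not CDS. The 5 kb
nearest-gene search is purely positional (nearer of the two gene ends), but
the side is reported strand-aware (`upstream`/`downstream`) because the
dysregulation mechanism differs by side — enhancer activation upstream,
premature polyadenylation within. TSS distances are signed in gene
orientation: negative upstream, positive downstream. All ties (equidistant
genes or features, nested containing genes) break lexicographically after the
primary criterion (distance, or smallest span for containment), making
annotation deterministic. Internally every coordinate is 1-based inclusive
(blast8-native); BED and genePred/refFlat inputs are converted at the parsing
boundary. Gene and feature scans are linear per site — adequate for the
toy-genome scales this package targets in tests; an interval index would be
the first change for genome-scale annotation sets.

## Random controls and the chi-squared test

Random sites are drawn with chromosome probability proportional to
`length − site_length + 1` (uniform positional density genome-wide — the
meaning of a random-integration null), uniform strand, and are
reverse-complemented on the minus strand. N-containing draws are redrawn,
bounded at 100× the requested count, so site lengths stay exact. The sites
skip trimming (they carry no LTR) and enter at alignment, passing through the
same filter and annotation functions as real reads, so mapping bias affects
both sides of the comparison equally.

The gene test uses three categories — in a gene, within 5 kb but not in a
gene, beyond — with expected proportions taken from the random set and scaled
to the observed total; each custom feature list gets a 2-category
within/not-within test. Categories empty in both sets are dropped before
testing; a category observed but with zero random proportion raises an error
advising a merge rather than producing an infinite statistic. The statistic
is computed directly as Σ(O−E)²/E and the p-value from the χ² upper tail with
k−1 degrees of freedom; an independent reference implementation is used in the
test suite as a cross-check, never as the implementation.

## Synthetic data

`simulate_dataset` emulates an error-bearing LAM-PCR junction library on a
toy genome. Defaults: 2 chromosomes × 20 kb of uniform random sequence; 1 kb
genes on a regular grid at 0.1 genes/kb (alternating strands), so in-gene and
near-gene fractions have closed form; 20 integrations × 3 reads; fragment
lengths 40–60 bp (uniform over a 20 bp shear spread), giving realistic
per-site span diversity; substitution and N rates default to 0 so the
planted truth is exact — error rates are opt-in per experiment (the recovery
tests use 1 %). Planted junction flanks are screened to be genome-unique at
40 bp on both strands, so with zero error the pipeline must recover every
site exactly (recall = precision = 1); ambiguity-filter behaviour is instead
exercised by deliberately duplicated segments. The generator is fully
deterministic under its seed.

What a green end-to-end test does *not* establish: behaviour on repetitive
real genomes, gapped/spliced alignments, indel or quality-correlated errors,
restriction-site fragment bias, or multi-sample designs — none of which the
generator models.

## Known limitations

- The built-in aligner is ungapped; indel-bearing reads must be aligned
  externally and imported as blast8.
- Linear-scan annotation; no interval index.
- Single-test usage: no multiple-testing correction across feature lists.
- No common-integration-site (CIS) statistics or breakpoint-corrected
  abundance estimators; span count is reported raw.
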