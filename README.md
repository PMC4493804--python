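# riscall

Retroviral vector integration-site (RIS) analysis for gene-therapy and
insertional-mutagenesis studies. Given LTR-primed junction reads (e.g. from a
LAM-PCR library), `riscall` trims the non-genomic LTR/linker sequence, aligns
the genomic queries to a reference genome plus the vector, filters out reads
that cannot be placed unequivocally, clusters the surviving placements into
unique integration sites with read-frequency and shear-span counts, annotates
each site's proximity to genes, transcription start sites and custom genomic
features, and tests integration-profile enrichment against random genomic
control sites with a Pearson chi-squared goodness-of-fit test.

## The method

Each read is trimmed in a fixed order: the vector **LTR** is located by exact
substring search and everything through it removed (reads without an
LTR-chromosome junction are discarded); the optional **linker cassette** (LC)
is removed from the 3′ side; the query is truncated before any run of ≥ 3
ambiguous bases; queries shorter than 30 bp are eliminated (they cannot reach
the alignment score cutoff). Queries are aligned to genome + vector (built-in
exhaustive ungapped aligner, a pre-computed blast8 file, or an external
aligner command), and alignments with score < 60, identity < 92 %, or starting
more than 3 bp into the query are dropped. Per query the top 5 alignments are
kept and the read is rejected if its best hit is the vector, if the second-best
score exceeds 95 % of the best (90 % when the best score is < 100), or if the
best identity is < 95 %. The best alignment's target coordinate at the first
query base — the junction base — is the candidate site.

Candidates within ±5 bp on the same chromosome and strand are taken to be the
same site: the greatest-scoring candidate becomes the **unique RIS**,
same-coordinate members are *repeat* and in-window members *in-range*. Each
unique site reports its **frequency** (total supporting reads) and **span
count** (distinct distal fragment endpoints = distinct shear points), which
together separate PCR duplication from genuine clonal expansion. Annotation
runs in two phases — gene-body containment or distance to the nearest gene up
to 5 kb, then nearest-TSS distance (signed, negative upstream) over all genes —
plus containment/distance for user-supplied BED features. Observed category
proportions are compared to those of random control sites drawn
length-proportionally from the genome and pushed through the identical
alignment/filter/annotation code with `X² = Σ (O−E)²/E`, df = k−1.

## Worked example

Simulate a toy dataset (2 × 20 kb genome, 20 planted proviruses, 3 reads
each) and run the full pipeline with a 500-site random control:

```bash
riscall simulate --seed 7 --out demo
riscall run --reads demo/reads.fa \
    --ltr TGTGGAAAATCTCTAGCAGT --lc GATCCTGCAGGTCGAC \
    --genome demo/genome.fa --vector demo/vector.fa \
    --genes demo/genes.refFlat \
    --random-n 500 --random-length 100 --seed 7 --out demo/out
```

which prints the stage funnel

```
reads 60 -> queries 60 -> candidates 60 -> unique sites 20
```

— all 60 reads contained a junction, every query aligned unambiguously, and
the 60 candidates collapsed to the 20 planted sites. `demo/out/concise.csv`
begins

```
chrom,position,strand,frequency,span_count,score,in_gene,nearest_gene,gene_distance,gene_side,nearest_tss_gene,tss_distance
chr1,3324,+,3,3,114.00,false,gene1,1676,upstream,gene1,-1676
chr1,5017,+,3,3,118.00,true,gene1,0,within,gene1,17
```

each row one unique site: the site at chr1:3324 is supported by 3 reads with
3 distinct shear endpoints (clonal-expansion-like, not pure PCR duplication),
lies 1676 bp upstream of `gene1`, and 1676 bp upstream of the nearest TSS.
`summary.csv` reports 20 unique sites, 5 % inside genes and 19 within 5 kb of
one; `chisq.csv` holds the goodness-of-fit against the random control
(here X² = 0.56, p = 0.46 — the planted sites are not enriched, as expected
for uniformly placed integrations). The complete output adds `members.csv`
(every read's unique/repeat/in-range label) and one `filtered_<reason>.csv`
per elimination reason, plus `manifest.json` with the config snapshot and
stage counts.

Every step is also available as a library (`riscall.trim_batch`,
`riscall.align`, `riscall.call_unique_ris`, `riscall.annotate_site`,
`riscall.chisq_gof`, …) and as individual subcommands (`trim`, `align`,
`filter`, `call`, `annotate`, `random`, `simulate`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole computation from scratch: it simulates the default toy
dataset under the given seed, executes trimming, alignment, filtering,
unique-site calling, annotation and the random-control chi-squared
comparison, prints the stage funnel, and writes the results JSON.

See `docs/methods.md` for the model, parameter defaults, numerical choices
and known limitations.
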