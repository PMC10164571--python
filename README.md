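# irscan

Discovery and classification of inverted transposable-element (TE) pairs
inside designated single-stranded-DNA (ssDNA) regions, plus a
fluctuation-test mutation/GCR rate estimator and a strand-coordination
scorer for clustered mutations.

## The problem

Two homologous sequences on one chromosome in opposite orientations — an
inverted repeat (IR) — can anneal intramolecularly when the region becomes
single-stranded, fold back into a hairpin, and seed gross chromosomal
rearrangements (GCRs) such as dicentric chromosomes and terminal deletions.
In double-stranded DNA only close, near-identical IRs are dangerous; in long
ssDNA tracts (telomere-uncapping resection in yeast, or the regions marked
by APOBEC hypermutation clusters in tumor genomes) the constraints relax
dramatically: IR pairs remain efficient rearrangement triggers up to ~30 kb
of separation and down to ~75% arm identity.

`irscan` operationalizes those structural parameters as a scanner. For each
region of interest it enumerates every same-family, opposite-strand,
non-overlapping element pair (convergent `+ −` and divergent `− +` alike),
aligns the upstream element against the reverse complement of the downstream
one with a local Smith–Waterman alignment (affine gaps, BLASTN-like scoring
+2/−3, gap open 5, extend 2), and retains pairs with

- identity > 75% (identities over alignment columns, gaps included),
- matched length > 100 bp,
- inner separation (spacer) < 30 kb.

It is written for genomicists who have a genome FASTA, a RepeatMasker `.out`
(or BED6) annotation, and a BED file of regions — e.g. APOBEC
mutation-cluster intervals — and want the per-region inventory of
potentially interacting IRs, with distance and identity distributions.

## Rate estimation

The companion `fluctuation` module estimates mutation/GCR rates from
parallel-culture fluctuation tests by Drake's median method: the rate μ per
cell per generation is the root of

    μ · ln(N·μ) = f

with f the mutant frequency and N the population size of a culture. The
experiment-level estimate is the median of per-culture rates with a 95%
percentile-bootstrap confidence interval (seeded, order-invariant).
`strand_coordination` scores whether clustered mutations all carry their
pyrimidine on one designated strand — the signature of lesions fixed in a
persistent single strand.

Because real inputs (hg19 RepeatMasker tracks, tumor cluster tables, wet-lab
cultures) are large or unavailable offline, the `synthetic_data` module
generates every input from scratch: genomes with planted 320 bp Alu-like
inverted pairs at controlled identity (100/94/86/75/65%) and spacer (12 bp –
30 kb) with ground-truth records, and Luria–Delbrück culture outcomes
simulated by discrete doublings with binomial mutation per division.

## Worked example

Generate a synthetic dataset (20 regions, 12 of them carrying one planted
Alu-like inverted pair), scan it, and estimate a rate from simulated
cultures:

```sh
$ irscan simulate-genome --outdir fixtures --seed 7 --n-regions 20 --plant-fraction 0.6
{"outdir": "fixtures", "n_regions": 20, "n_planted_pairs": 12, "genome_bp": 109652}

$ irscan scan --genome fixtures/genome.fa --repeats fixtures/repeats.out \
    --regions fixtures/regions.bed --out pairs.tsv --summary summary.json
```

`pairs.tsv` holds one row per evaluated pair:

```
region_id    family    chrom_a start_a end_a strand_a ... separation_bp orientation_class identity_fraction matched_length pass_filter
region_0000  SINE/Alu  chr1    3500    3820  +        ... 1500          convergent        0.9434            318            True
region_0001  SINE/Alu  chr1    9840    10160 -        ... 5000          divergent         0.8644            317            True
```

and `summary.json` reports that all 12 planted pairs — and nothing else —
were recovered, with their distance and identity histograms:

```json
{"n_regions": 20, "n_passing_pairs": 12,
 "per_family_region_counts": {"SINE/Alu": 12},
 "distance_histogram": {"0-10kb": 12, "10-20kb": 0, "20-30kb": 0},
 "identity_histogram": {"75-80": 0, "80-85": 0, "85-90": 4, "90-95": 5, "95-100": 3}}
```

The identity fractions (e.g. 0.9434 for a pair planted at 94% target
identity) are the best-local-alignment identities, which can differ from the
planted divergence by a column or two of end trimming.

```sh
$ irscan simulate-cultures --mu 5e-7 --n-final 2e8 --cultures 24 --seed 7 --out cultures.tsv
$ irscan estimate-rate --cultures cultures.tsv --seed 1
{"mu": 4.723e-07, "ci_low": 4.091e-07, "ci_high": 5.584e-07, "n_cultures": 24,
 "method_note": "median_of_rates; 95% CI by bootstrap"}
```

The true simulated rate was 5 × 10⁻⁷; the median-method estimate 4.72 × 10⁻⁷
recovers it well within its confidence interval.

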