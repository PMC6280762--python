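# clonesift

Discovery of low-frequency clonal ("selfish") mutations in multi-biopsy deep
amplicon sequencing data. The package reimplements, as a tested reusable
pipeline, a screening strategy for mosaic variants at VAFs of ~0.05%–3% in
spatially registered tissue biopsies:

- **`synthetic`** — generates amplicon panels (with overlapping amplicons and
  pathway labels), testis/slice/biopsy layouts with batch covariates, clonal
  variants spiked along connected biopsy walks (including tandem dinucleotide
  and broadly distributed post-zygotic events), and overdispersed
  background-structured pileups with known ground truth — so the whole
  pipeline runs with no external data.
- **`pileup`** — builds the per-(sample, amplicon, position) count matrix from
  pre-aligned read records: primer trimming, a >10-mismatch read filter
  (counted post-trim), and mate-overlap resolution keeping the higher-quality
  base so a read pair never counts twice.
- **`background`** — normalizes logit-transformed allele fractions for batch
  covariates (lane, nested in flow cell, plus per-position mean base quality),
  removes the per-lane median, and calls per-sample outliers one-sided —
  either by a leave-one-out robust z or by the exact upper tail of a
  beta-binomial null fitted (with contamination trimming) to the other
  samples' counts. Coverage-based amplicon QC (median per-sample mean depth
  ≥ 5000×).
- **`prioritize`** — the post-call filter cascade (read floor, excess-call
  samples/amplicons, primer-proximal positions, ≥3% VAF cap, low-coverage
  positions), the ≥2-independent-calls rule, per-sample VAF aggregation,
  tandem-candidate merging, and confidence tiers 1–4.
- **`geography`** — groups candidate variants into clonal events over the
  biopsy adjacency graph, counts independent mutational events (one per
  variant per testis), and flags scattered multi-slice patterns consistent
  with an early post-zygotic origin.
- **`enrichment`** — two-tailed Fisher's exact test (hypergeometric
  enumeration), per-base logistic regression (closed-form log odds ratio with
  Wald P), and tandem-substitution fold enrichment.
- **`io` / `cli` / `pipeline`** — TSV/BED/VCF-like/YAML/JSON readers and
  writers that all round-trip, plus seeded end-to-end orchestration.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked-example
numbers, dual-route oracle equivalence for the Fisher and beta-binomial
tails, parameter recovery and null specificity on default synthetic runs,
and the structural invariants).

## CLI

```sh
# full synthetic run (simulate -> call -> prioritize -> clones -> enrich)
clonesift run-all --seed 1 --outdir run1

# or the same thing stage by stage (byte-identical outputs)
clonesift simulate  --seed 1 --outdir run1
clonesift call      --seed 1 --outdir run1
clonesift prioritize --seed 1 --outdir run1
clonesift clones    --seed 1 --outdir run1
clonesift enrich    --seed 1 --outdir run1

# build a pileup from pre-aligned read records
clonesift pileup --reads reads.tsv --panel-bed panel.bed \
    --panel-meta panel_meta.tsv --out pileup.tsv
```

All parameters live in a YAML config (`--config cfg.yaml`); unknown keys are
rejected. `--mode {robust_z,betabinom}`, `--p-cutoff` and `--min-alt-reads`
override the calling thresholds. The run directory receives the panel
(BED + metadata TSV), sample sheet, biopsy adjacency tables, ground truth,
pileup, raw calls, candidates (TSV + VCF-like), clonal events, enrichment
report, and a manifest with per-stage counts.

## Conventions

Coordinates are 0-based half-open internally and in BED output; VCF-like
output is 1-based. All randomness derives from one root seed through named
substreams, so every artifact is byte-reproducible under a fixed
(config, seed) pair.
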