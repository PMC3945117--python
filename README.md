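# rhythmochip

Analysis toolkit for around-the-clock (circadian) ChIP-seq time courses:

- **Tag processing** — multi-hit weighted read loading (SAM/BAM or 4-column
  tag text), redundant-tag removal, and strand shifting by
  `round(fragment_size/2 − read_length/2)`.
- **Peak calling** — 500-nt block tiling (twice, with a half-block offset),
  a 40-tag raw-count floor, log2(count+1) transform, quantile normalization
  over libraries, selection of blocks with normalized ChIP − input > 2 at
  ≥ 1 time point, merging of the two tilings, and iterative border
  refinement (trim the emptier 50-nt border while ≥ 75% of reads are
  retained; halve the border width until < 10 nt).
- **Rhythm estimation** — cosinor fits `x(t) = b0 + b1·cos(b3 + 2πt/24)` by
  Gauss–Newton from the closed-form harmonic regression; amplitude p-values
  (2-df F-test), delta-method phase confidence intervals; a joint
  two-genotype model with per-genotype mean/amplitude/phase and additive
  batch offsets; hierarchical clustering with 1 − Pearson distances;
  shortest circular phase intervals and wrapped-Gaussian phase densities.
- **Motif enrichment** — IUPAC/PWM scanning on both strands and empirical
  p-values against 1000 random region groups matched on peak length, signed
  TSS distance, and gene expression; Fisher's exact test for per-cluster
  motif frequencies.
- **Annotation** — nearest-TSS assignment with signed distances (negative =
  upstream), peak feature tables, and overlap counting against other
  region sets.
- **Synthetic data** — ground-truthed fixtures: rhythmic site occupancy
  `baseline·fold·(1 + amp·cos(2π(t − phase)/24))` with strand-separated
  Poisson-sampled reads, uniform input, motif-embedded genomes, and
  clustered expression matrices with batch and genotype effects.

## CLI

```sh
# ground-truthed synthetic fixture (text files + truth.json)
rhythmochip simulate --seed 1 --out fixtures/

# per-library tag processing
rhythmochip tags --in chip_ZT2.tags --fragment-size 190 --read-length 80 --out ZT2.bed

# peak calling across the time course
rhythmochip callpeaks \
  --chip fixtures/chip_ZT2.tags --chip fixtures/chip_ZT6.tags ... \
  --input fixtures/input_ZT2.tags --input fixtures/input_ZT6.tags ... \
  --times 2,6,10,14,18,22,26 --fragment-sizes 190,190,... --out run

# cosine fits, clustering, phase statistics
rhythmochip rhythm --matrix run.signal.tsv --k 4 --pcut 0.1 --out run

# motif enrichment vs matched random regions
rhythmochip motifs --genome fixtures/genome.fa --peaks run.peaks.bed \
  --tss fixtures/tss.bed --expr fixtures/expression.tsv \
  --motifs motifs.tsv --groups 1000 --seed 7 --out run

# nearest-TSS annotation (+ optional cistrome overlap)
rhythmochip annotate --peaks run.peaks.bed --tss fixtures/tss.bed --out run

# everything from one JSON/YAML config, with provenance records
rhythmochip run --config run.json --seed 1
```

Motif files are tab text: `name<TAB>IUPAC` per line, or a
`name<TAB>PWM<TAB>L` header followed by L rows of 4 probabilities (A C G T).

## Conventions

Coordinates are 0-based half-open everywhere; SAM input is converted from
pysam's 0-based `reference_start`. Tag positions are leftmost coordinates;
`+` tags shift right and `−` tags shift left. All simulation randomness is
driven by a single seed and reruns are byte-identical.
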