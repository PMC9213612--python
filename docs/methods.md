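# Methods

## PSI quantification

For a cassette exon *i* (an internal exon of at least one transcript) three
splice junctions are diagnostic: the two flanking inclusion junctions
(upstream exon → cassette, cassette → downstream exon) and the skip junction
joining the flanking exons directly. A split read — one whose CIGAR contains an
N (skipped reference) operation — supports a junction when its gap coordinates
match the junction *exactly* and the aligned blocks on both sides of the gap
are at least `anchor_min` bases (default 8 bp). Raw counts:

- `ir_raw` — reads matching the upstream or downstream inclusion junction
  (a read spanning both counts once);
- `er_raw` — reads matching the skip junction.

Normalization divides each raw count by (number of junctions able to support
the outcome) × (number of distinct read placements across one junction,
`read_length − 2·anchor_min + 1`):

```
IR_n = ir_raw / (2 · P),   ER_n = er_raw / (1 · P),   P = L − 2a + 1
PSI  = IR_n / (IR_n + ER_n)
```

The placement factor `P` cancels inside PSI when read length is uniform; the
junction-count factor does not, and is what makes PSI unbiased: a transcript
that includes the exon contributes coverage to *two* junctions while a
skipping transcript contributes to one, so dividing inclusion evidence by two
converts read-level counts back to transcript-level proportions.

PSI is undefined (missing value) for a sample/exon when
`ir_raw + er_raw < min_junction_reads` (default 10) or when both rates are
zero. An optional exon-body mode (counting unsplit reads inside the exon as
inclusion evidence with an exon-length-dependent placement divisor) was
considered and deliberately not enabled by default: junction-only counting
keeps the evidence unit uniform and exactly recoverable in simulation.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `read_length` | 124 bp | uniform read length used in normalization |
| `anchor_min` | 8 bp | minimum aligned bases flanking a gap |
| `min_junction_reads` | 10 reads | coverage below which PSI is undefined |
| `n_inclusion_junctions` | 2 | junctions supporting inclusion |

Anchor and coverage defaults are conventional split-read-quantification
values; both are config-exposed because their optimum depends on depth and
read length.

## Coordinates

GTF and SAM are 1-based inclusive on disk; in memory everything is 0-based
half-open, converted only in the readers/writers. A junction is stored as
`(donor_end, acceptor_start)` where `donor_end` is the *half-open end* of the
block left of the gap and `acceptor_start` the start of the right block — the
same convention on the annotation side (flanking-exon end, cassette start), so
annotation and alignment junctions compare by tuple equality with no ±1
adjustment. Junctions are stored in genomic (forward) orientation; strand is
metadata. Only primary alignments are counted (secondary/supplementary flags
skipped) so a split read contributes evidence once; mates are independent
reads; no MAPQ filter by default.

## Cohort ΔPSI comparison

Per-exon cohort means are arithmetic means over samples with defined PSI; an
exon is dropped when either cohort has fewer than `min_defined_samples`
(default 3) defined values. Δψ = mean(old) − mean(young), so positive values
mean more inclusion in the old cohort. Flagging uses a *strict* inequality
|Δψ| > 0.20 (the threshold is config-exposed; at the exact boundary an exon is
not flagged). Concordance between cohorts is Spearman's ρ on paired cohort
means. No significance test is attached to Δψ — the procedure is a threshold
rule, and the simulation suite characterizes its error rates instead: at
junction depth 200 with 6+7 samples the per-sample PSI standard error is
≈ √(ψ(1−ψ)/200) ≤ 0.035, the Δ standard error ≈ 0.02, so a 0.20 threshold
yields a null flagging rate ≪ 1% and essentially certain detection of
|Δψ| = 0.4.

## Expression summaries

- **CPM**: `counts / library_size × 1e6`, library size = column sum unless
  overridden. 0.3 CPM ≈ 20 reads at ~70 M depth, which motivates the default
  detection threshold.
- **Detection**: a gene is detected in a cohort when CPM ≥ 0.3 in ≥ 1 sample of
  that cohort; exclusive genes are detected in exactly one cohort, and for each
  the fraction of other-cohort samples below threshold is reported.
- **Fold-change bins** (FC = old/young, linear): up (FC > 1), down (FC < 1),
  strong up (FC > 1.5, strict), strong down (FC ≤ 0.5 — "a 50% or larger
  decrease", inclusive), small vs large change split at the same bounds.
  FC = 1 exactly is counted neither up nor down and warned about. Percentages
  are rounded half-up to one decimal.
- **Metadata**: per-cohort mean and sample (n−1) SD of body mass rounded
  half-up to one decimal, age range, sex counts.
- **MDS**: distance between samples s,t in `logfc` mode is the root mean
  square of the `top_n` (default 500) largest
  `|log2((cpm_s + c)/(cpm_t + c))|` over genes, with prior count c = 2 to
  avoid log 0 — the leading log-fold-change distance; `top_n=None` uses all
  genes. `bcv` mode replaces the per-gene quantity with a
  coefficient-of-variation proxy `|cpm_s − cpm_t| / (½(cpm_s + cpm_t) + c)` on
  the `top_n` genes of highest log-CPM variance; it is an explicit
  simplification of dispersion-based (biological coefficient of variation)
  distances and does not fit a count model. Embedding is classical (Torgerson)
  MDS: double-center the squared distances, eigendecompose, keep the top two
  components; negative eigenvalues of non-Euclidean inputs are truncated to
  zero. The embedding is unique up to rotation/reflection, so tests compare
  distances, not raw coordinates.

## Overrepresentation test

Per term: observed = |target ∩ term|, expected = |term ∩ reference| ·
|target| / |reference|, fold enrichment = observed/expected, two-sided Fisher
exact p (equivalently the sum of hypergeometric outcomes no more probable than
the observed table — both over- and underrepresentation are reported, so the
two-sided test is the right default), Benjamini–Hochberg FDR across tested
terms. Annotation sets are intersected with the reference before testing and
terms with < 2 reference genes are skipped. Expected counts from external
annotation services depend on their internal gene mapping and are not
reproduced here; fold enrichment is always observed/expected on this
package's own expecteds.

## ΔΔCt

Duplicate wells are averaged per sample and gene before any contrast. ΔCt =
Ct(target) − Ct(reference gene, default GAPDH) per sample; ΔΔCt = mean
ΔCt(test) − mean ΔCt(calibrator); FC = 2^(−ΔΔCt), assuming perfect per-cycle
doubling (no primer-efficiency correction). Concordance with sequencing is
Pearson r on log2 fold changes — the log scale makes up- and downregulation
symmetric and is the conventional scale for such validation plots.

## Synthetic data

The simulator emulates the *statistical structure* of the emulated study, not
its sequences: 6 + 7 samples, library sizes ~Normal(74 M × depth_factor,
15% CV), 124 bp reads, log-normal expression weights, a configurable DEG
fraction with log2 FC ~ Normal(0, σ), negative-binomial counts
(variance μ + φμ², Poisson at φ = 0, default φ = 0.05 — a typical bulk
biological-replicate dispersion).

For splicing, each sample × cassette exon draws a number of transcript events
~ Poisson(`junction_depth_mean`, default 200). Each event includes the exon
with the cohort's true ψ and emits **two** split reads (one per inclusion
junction); an exclusion event emits one skip-junction read. This mirrors the
physical coverage asymmetry that the 2-junction normalization corrects, so
the quantifier recovers ψ exactly in expectation; the event-level
inclusion fraction is Binomial(n, ψ). Junction placement within a read is
uniform subject to ≥ `anchor_min` bases on each side, so anchor filtering is
exercised but never rejects a simulated read at matched settings. By default
no intra-exon background reads are emitted, keeping raw-count truth exact; a
`background_reads_per_exon` option adds unsplit exon-body reads to stress the
junction-only counting rules.

What the simulator does **not** model: sequencing error, quality scores,
paired-end fragment geometry, multi-mapping, novel junctions, overlapping
genes, and expression-coupled junction depth. Passing recovery tests therefore
demonstrates correctness of the counting and normalization logic under the
stated model, not robustness to alignment artifacts in real data.

Problem sizes in the test and acceptance suites (50 exons × 13 samples at
depth 200; 300–500-gene count matrices) were chosen as the smallest scales at
which the binomial/NB sampling bounds in the assertions are comfortably
non-trivial.

## Numerical and degenerate-input choices

- PSI undefined (NaN in tables, empty TSV field) rather than 0 when coverage
  is absent — 0 is a legitimate biological value and must not be conflated
  with missingness.
- Exact junction matching, no fuzz window: deterministic, and the simulator
  emits exact coordinates. Real aligner wobble would need a tolerance layer
  upstream of counting.
- Strict ">" at every "greater than" threshold (ΔPSI 0.20, FC 1.5); inclusive
  "≤ 0.5" for the 50%-decrease bin (it is inclusive by arithmetic: a 50%
  decrease *is* FC 0.5).
- Spearman ρ undefined (None, with a warning) below 3 pairs; concordance
  raises below 3 shared genes.
- Ties in MDS eigenvalues or gene selection are resolved by numpy's stable
  ordering; embeddings are compared up to isometry.
- All randomness flows from one integer seed through named, hashed
  SeedSequence substreams, so adding a new stream never perturbs existing
  ones.

## Known limitations

- Cassette events are enumerated from annotation only (no novel junctions);
  the flanking junctions of an exon shared by several transcripts are taken
  from the first transcript in sorted id order.
- Only cassette exons: intron retention, alternative 5'/3' sites and mutually
  exclusive exons are out of scope.
- The `bcv` MDS mode is a documented proxy, not a dispersion-model fit.
- The differential-expression test itself is external; this package consumes
  DEG tables (gene, fold change, q-value) and summarizes them.
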