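# psicohort

Splice-junction **percent-spliced-in (PSI)** quantification and cohort-level
transcriptome comparison, built for two-cohort bulk RNA-seq designs such as a
young-vs-old brain aging study (6 vs 7 dogs, ~74 M reads/sample, 124 bp reads).

Alternative splicing shifts with age, and a direct way to measure it is to ask,
for each internal ("cassette") exon, what fraction of a gene's transcripts
include it. For exon *i*, split reads whose gapped alignment crosses one of the
two flanking junctions are **inclusion** evidence (IR), and reads whose gap
skips the exon entirely are **exclusion** evidence (ER). After normalizing each
count by the number of junctions that can support it and by the number of valid
read placements per junction,

```
PSI_i = IR_i,n / (IR_i,n + ER_i,n)
```

PSI = 1 means the exon is in every transcript; PSI = 0.1 means it is in 10% of
them. Cohort means are compared per exon and exons with |ΔPSI| > 0.20 are
flagged as divergent. Around this core the package provides the rest of the
cohort-comparison bookkeeping: CPM normalization with a 0.3-CPM detection rule
and cohort-exclusive gene sets, fold-change binning of differential-expression
tables, classical (Torgerson) MDS of samples from leading log-fold-change
distances, a Fisher-exact overrepresentation test with BH FDR and fold
enrichment, ΔΔCt qPCR fold changes with RNA-seq concordance, and a seeded
simulator that generates SAM alignments and count tables with known ground
truth so the whole pipeline is testable end to end.

## Worked example

Simulate a 6+7-sample cohort with one exon planted at Δψ = 0.4 and run the full
pipeline:

```sh
psicohort all --outdir demo --seed 11
```

```
fixture bundle written to demo
PSI matrix (10 exons x 13 samples) -> demo
1 divergent exons in 1 genes (rho = 0.673)
{
  "detected_old": 500,
  "detected_young": 500,
  ...
}
```

`demo/delta_psi.tsv` shows the planted exon recovered at the top, with the null
exons unflagged:

```
exon_key          gene_id    mean_psi_young  mean_psi_old  delta_psi  flagged
chrSim:1700-1900  sgene_000  0.197942        0.611743      0.413801   True
chrSim:37200-37400 sgene_005 0.795184        0.823670      0.028486   False
```

The planted truth was psi_young = 0.2, psi_old = 0.6: at junction depth ~200
the cohort means land within a few hundredths of truth and the Δ = 0.41
estimate clears the 0.20 flagging threshold, while the strongest null exon
shows Δ = 0.03. Spearman ρ between cohort mean PSI vectors is reported
alongside (0.67 here — only 10 exons, three of them planted; on null-only
simulations it approaches 1).

The same stages are importable as functions
(`psicohort.psi.psi_matrix`, `psicohort.diffsplice.compare_cohorts`,
`psicohort.expression.mds_embedding`, ...) for use without the CLI.

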