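# crypticseq

Exon-level detection of **cryptic intragenic transcription** from bulk
RNA-seq count matrices, with a synthetic ground-truth generator and the
gene-list overlap statistics used to integrate parallel analyses.

## The problem

H3K36me3 is deposited co-transcriptionally over gene bodies and suppresses
transcription initiation from within coding regions.  When it is lost
(e.g. after *Setd2* knockdown, or environmental insults such as adolescent
binge ethanol in mouse prefrontal cortex), RNA polymerase II can initiate
inside a gene body and produce truncated transcripts.  In exon-level
RNA-seq data this leaves a characteristic footprint: read counts over a
contiguous 3' run of exon bins are elevated in the treatment group while
the annotated 5' end is not.

`crypticseq` detects that footprint.  Given a flattened exon-bin
annotation (DEXSeq-style collapsed counting bins, gene aggregation
disabled), an exon-by-sample integer count matrix and two-group sample
metadata, it:

1. normalizes counts with **median-of-ratios** size factors and tests each
   exon bin between groups with a negative-binomial Wald test
   (Var = μ + αμ², per-feature moment dispersion with empirical-Bayes
   moderation), or imports a per-exon statistics table from an external
   exon-usage tool;
2. classifies each gene with a five-rule cascade over exon bins in
   transcriptional (5'→3') order, with SIG(e) := p_e < 0.05 and elevated:
   * at least one elevated exon (else `NO_UP`);
   * the first annotated *and expressed* exon must not itself be elevated
     — that is an up-regulated full-length mRNA (`FULL_LENGTH_UP`);
   * the cryptic TSS c is the first elevated exon;
   * at least 60% of the exons from c onward must be elevated
     (`DOWNSTREAM_FRAC`);
   * c must lie in the first half of the gene's exons, c ≤ ⌈E/2⌉
     (`LATE_TSS`);
3. scores gene-list overlaps with an exact one-sided hypergeometric test
   computed in log space, inverts it to calibrate an unreported universe
   size N from a printed p-value, and builds multi-analysis membership
   tables.

A synthetic experiment generator produces NB exon counts over realistic
gene models with known per-gene labels — null, full-length up/down,
cryptic, and two decoy classes built to trip exactly one cascade rule —
so every stage is testable end to end without any external data.

## Worked example

```python
import crypticseq as cs

cfg = cs.SimConfig(n_genes=500, seed=42)        # 5 control vs 6 treatment
models, samples, counts, truth = cs.simulate_experiment(cfg)
test = cs.ExonDifferentialTest().fit(counts, samples)
caller = cs.CrypticCaller().fit(test.results_, models=models)
print("cryptic PASS calls:", len(caller.passing_genes_))
print("rejection summary:", dict(caller.summary_))
metrics = cs.evaluate_vs_truth(caller.calls_, truth.genes)
print("sensitivity: %.3f  null pass rate: %.4f  cTSS exact: %.3f"
      % (metrics["sensitivity"], metrics["null_pass_rate"], metrics["ctss_exact_rate"]))
```

prints

```
cryptic PASS calls: 28
rejection summary: {'PASS': 28, 'NO_UP': 358, 'FULL_LENGTH_UP': 36, 'DOWNSTREAM_FRAC': 68, 'LATE_TSS': 8, 'NOT_EXPRESSED': 2}
sensitivity: 0.963  null pass rate: 0.0000  cTSS exact: 0.885
```

28 of 500 genes pass the cascade; 26 of the 27 simulated cryptic genes are
recovered (sensitivity 0.963), no null gene passes, and 88.5% of the true
positives have the cryptic TSS localized to exactly the right exon bin.
The overlap statistic is exact:

```python
res = cs.fisher_overlap(cs.OverlapQuery({"g1","g2","g3","g4"},
                                        {"g1","g2","g3","g9","g10"}, 10))
# k=3, p_upper = 66/252 = 0.26190, odds ratio 6.0
```

The same steps are available from a shell:

```bash
crypticseq simulate --n-genes 500 --seed 42 --out-dir fix/
crypticseq test-exons --annotation fix/annotation.gff --counts fix/counts.tsv \
    --samples fix/samples.tsv --out exon_stats.tsv
crypticseq call-cryptic --exon-stats exon_stats.tsv --annotation fix/annotation.gff \
    --out calls.tsv --bed cryptic_tss.bed
crypticseq run-all --simulate --n-genes 2000 --seed 0 --out-dir run/   # everything + manifest
```

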