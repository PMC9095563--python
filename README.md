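# mirmaster

Candidate master-miRNA regulator discovery from multi-omics count data.

## The problem

Steady-state RNA-seq conflates two regulatory layers: how much a gene is
transcribed, and how stable its mRNA is once made. Nascent-transcription
assays (run-on sequencing such as PRO-seq/ChRO-seq, which map actively
engaged RNA polymerase at single-base resolution) measure the first layer
directly. A gene whose mRNA falls while its transcription stays flat has
*gained* post-transcriptional suppression (GPS); the mirror case has *lost*
it (LPS). When one up-regulated miRNA's predicted target sites are
over-represented among the GPS genes, that miRNA is a candidate master
post-transcriptional regulator of the response.

`mirmaster` implements this reasoning as a tested, reusable pipeline for
anyone with (a) a gene annotation, (b) per-base stranded polymerase-position
signal, (c) RNA-seq and small-RNA-seq count matrices, and (d) 3′UTR
sequences for the study species plus comparison species. A first-class
synthetic-data module generates complete studies with planted effects, so
every stage is verifiable by recovery before it ever touches real data.

## The method

1. **Gene-body counting** — polymerase-position signal is summed per gene
   over the *truncated* gene body: the first 500 bp downstream of the TSS
   are excluded (promoter-proximal pause peak), and genes shorter than
   1 kb are dropped because the truncation biases against them. Counting
   is strand-matched and half-open: a base at `body_start` counts, a base
   at `body_end` does not.
2. **Differential expression** — per-assay NB GLM with log link,
   median-of-ratios size factors `s_j = median_g (y_gj / (∏_j y_gj)^{1/m})`,
   moment-based dispersion with a `α ~ a₀ + a₁/μ` trend and log-space
   shrinkage, Wald tests under `~ batch + condition` (the batch term drops
   out automatically for single-batch comparisons), and Benjamini–Hochberg
   adjustment. Significance filters: padj < 0.05, |log2FC| > 0.5,
   baseMean > 500 (all strict).
3. **Post-transcriptional classification** — a joint NB fit of both assays
   with design `~ assay + condition + assay:condition`; the interaction
   coefficient estimates (steady-state effect − transcriptional effect)
   and its Wald padj < 0.2 flags post-transcriptional regulation. GPS
   additionally requires flat transcription (ChRO padj > 0.2,
   baseMean > 100) and decreased mRNA (RNA padj < 0.2, log2FC < −0.5,
   baseMean > 100); LPS mirrors with log2FC > 0.5.
4. **Target enrichment** — canonical seed sites (8mer, 7mer-m8, 7mer-A1;
   seed = miRNA nucleotides 2–8) are detected in 3′UTRs of all four
   species; a site in the study species counts as conserved when at least
   two comparison species carry any site for the same gene/miRNA. Each
   up-regulated miRNA's conserved-site density over the GPS list is
   compared with 1000 Monte-Carlo random same-size lists from the
   expressed background: `p_emp = (#{null ≥ observed} + 1) / 1001`.

## Worked example

Generate a synthetic study (2000 genes, 20 miRNAs, 3 replicates per group,
100 planted GPS genes, one planted master miRNA) and run the pipeline:

```bash
mirmaster simulate --outdir study --seed 1
cat > config.yaml <<EOF
gtf: study/annotation.gtf
metadata: study/metadata.tsv
counts_rna: study/counts_rna.tsv
counts_mirna: study/counts_mirna.tsv
mirna_fasta: study/mirnas.fa
utr_fastas: {rat: study/utr_rat.fa, human: study/utr_human.fa,
             mouse: study/utr_mouse.fa, dog: study/utr_dog.fa}
outdir: results_run
rng_seed: 1
contrasts: [[treated, control]]
EOF
mirmaster run-all --config config.yaml
mirmaster evaluate --study-dir study --results-dir results_run
```

`run-all` prints a summary whose contrast block looks like:

```
"treated_vs_control": {
  "concordance_r": 0.5736,      # transcription vs mRNA fold-change agreement
  "n_gps": 80, "n_lps": 100,    # post-transcriptional calls
  "n_mirnas_up": 3,
  "top_mirna": {"mirna_id": "syn-miR-01", "p_emp": 0.000999, "frac_targeted": 0.775}
}
```

and `evaluate` compares the calls with the planted truth:

```
"GPS": {"n_planted": 100, "n_called": 80, "sensitivity": 0.76, "fdr": 0.05},
"master_mirna": {"mirna_id": "syn-miR-01", "rank": 1, "p_emp": 0.000999}
```

Read: the planted master miRNA ranks first among all 20 tested miRNAs at
the permutation floor 1/1001; 77.5% of the called GPS genes carry its
conserved sites against a 5% background rate; 76 of the 100 planted GPS
genes are recovered at the published thresholds with 4 false calls.

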