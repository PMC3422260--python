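# trilevel

Tri-level (methylation / microRNA / mRNA) gene-set dysfunction ranking for
two-class omics studies.

## The problem

Tumors differ from normal tissue at several molecular levels at once:
promoter methylation, microRNA expression and mRNA expression. Given three
feature-by-sample matrices (one per level, each with tumor/normal labels)
and a functional annotation (e.g. Gene Ontology terms), `trilevel` asks,
*for each functional term, at which molecular level is it most altered,
and which terms are most altered overall?*

Each term is represented by three parallel member sets:

* **methylation set** — the annotated genes with methylation measurements;
* **microRNA set** — the measured microRNAs with at least one predicted
  target gene annotated to the term, where a microRNA–gene pair counts as
  a target only when predicted by ≥ 3 of the supplied prediction tools
  (6 tools by default);
* **mRNA set** — the annotated genes measured on the mRNA platform.

The discriminating ability of each set is the Matthews correlation
coefficient (MCC) of a 1-nearest-neighbor classifier under cosine
distance, evaluated by leave-one-out cross-validation (LOOCV) with tumor
as the positive class:

```
d(x, y)  =  1 − (x · y) / (‖x‖ ‖y‖)
MCC      =  (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
```

MCCs are then ranked **within each level** (rank 1 = highest MCC, ties get
mean ranks). Comparing a term's three ranks assigns it to one of the six
possible orderings of {methylation, microRNA, mRNA} — the level listed
first is the one most altered for that term. Summing the three ranks gives
the overall dysfunction ranking (smallest sum = most dysfunctional).
Downstream, members recurring in more than a threshold number of the
top-k dysfunctional sets ("high-frequency" genes/microRNAs) are extracted,
tested for overlap with a reference pathway (upper-tail hypergeometric
test), and re-validated by LOOCV on an independent cohort.

A synthetic-study generator (`trilevel.simulate`) produces all inputs —
three matrices with planted per-(term, level) effect sizes, annotation,
multi-tool target predictions, and an independent cohort — so the whole
pipeline runs and is testable without any external download.

## Worked example

Simulate a 40-term study (300 genes, 60 microRNAs, 30 tumor + 30 normal
samples per platform) in which terms 0–2 are strongly altered at all three
levels (3 SD), and terms 3–5 at exactly one level each (2.5 SD), then run
every stage:

```sh
cat > demo.yaml <<'YAML'
simulate:
  planted_effects:
    - [0, methylation, 3.0]
    - [0, microRNA, 3.0]
    - [0, mRNA, 3.0]
    - [1, methylation, 3.0]
    - [1, microRNA, 3.0]
    - [1, mRNA, 3.0]
    - [2, methylation, 3.0]
    - [2, microRNA, 3.0]
    - [2, mRNA, 3.0]
    - [3, methylation, 2.5]
    - [4, microRNA, 2.5]
    - [5, mRNA, 2.5]
YAML
trilevel run-all --config demo.yaml --out demo --seed 7 --top-k 8 --freq-threshold 1
```

The run logs each stage and ends with a manifest:

```
INFO:trilevel.pipeline:build-sets: 40/40 terms have members at all three levels
INFO:trilevel.pipeline:score: 40 terms scored on {'methylation': 60, 'microRNA': 60, 'mRNA': 60}
INFO:trilevel.pipeline:rank: six-group counts [6, 7, 11, 4, 7, 5] sum to 40 of 40 terms
INFO:trilevel.pipeline:frequency: 16 high-frequency genes, 17 high-frequency microRNAs
INFO:trilevel.pipeline:validate: independent-cohort MCC 1.0000 on 16 genes
```

`demo/dysfunction.tsv` holds, per term, the three MCCs, the three
within-level ranks, the six-group assignment and the summed rank; the
fully planted terms head the ranking with MCC 1.0 at every level:

```
term    mcc_methylation  mcc_microRNA  mcc_mRNA  ...  group                      summed_rank  position
T0000   1.0              1.0           1.0       ...  methylation<mRNA<microRNA  16.5         1
T0002   1.0              1.0           1.0       ...  methylation<mRNA<microRNA  16.5         2
```

The six group counts (`demo/group_counts.tsv`) always sum to the number of
terms — every term is forced into exactly one ordering. The genes
recurring in ≥ 2 of the top-8 sets are exactly the strongly planted ones,
and they classify the independent 20+20-sample cohort perfectly
(`demo/validation.tsv`: MCC = 1.0), the behavior expected when the top
dysfunctional sets carry genuine signal. Re-running the same command
reproduces every table byte for byte.

Each stage is also available as its own subcommand (`simulate`,
`build-sets`, `score`, `rank`, `groups`, `top`, `frequency`, `enrich`,
`validate`) operating on plain TSV/GMT files, and as library functions
(`trilevel.score_all`, `trilevel.classify_groups`, …).

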