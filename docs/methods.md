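# Methods

## The procedure

`trilevel` scores functional terms for tumor-vs-normal dysfunction at
three molecular levels and ranks them. The stages, in order:

1. **Consensus targets.** A microRNA–gene pair is accepted when predicted
   by at least `min_tools` (default 3) *distinct* tools out of the
   supplied tool universe (default 6). Duplicate records from one tool
   count once.
2. **Tri-level sets.** Per term: methylation set = annotated genes ∩
   methylation-measured universe; microRNA set = measured microRNAs whose
   consensus targets intersect the annotated genes; mRNA set = annotated
   genes ∩ mRNA-measured universe. Terms lacking members at any level are
   dropped (`min_size`, default 1). The mRNA set is intersected with the
   measured universe up front: unmeasured genes cannot contribute feature
   values, so keeping them would only misstate set sizes.
3. **Scoring.** For each (term, level), the platform matrix restricted to
   the member set is evaluated by leave-one-out cross-validation of a
   1-nearest-neighbor classifier under cosine distance; the confusion
   counts (tumor = positive class) are summarized by the Matthews
   correlation coefficient.
4. **Ranking and classification.** MCCs are ranked across terms within
   each level, descending, with tied values receiving mean ranks. Each
   term is assigned the ordering of its three ranks — one of the 3! = 6
   possible orderings — and terms are ordered overall by the sum of their
   three ranks, ascending.
5. **Downstream.** Member frequencies over the top-k sets (k default 300),
   high-frequency members (count strictly greater than the threshold,
   default 50), upper-tail hypergeometric overlap with a reference gene
   list, and LOOCV re-validation of the high-frequency genes on an
   independent cohort.

## Numerical conventions

The nearest-neighbor/LOOCV machinery is under-determined in three corner
cases; the package fixes them as follows and documents rather than infers
them:

* **Distance ties** go to the smallest training-sample position. This
  makes every run deterministic and permutation tests well defined.
* **Zero-norm vectors** get cosine distance 1 (maximal indifference)
  instead of raising, so a constant-zero sample slice cannot abort a scan;
  a warning is logged. Norm underflow to zero is treated the same way.
* **MCC denominator** — whenever a marginal factor is zero the MCC is
  defined as 0, the standard convention.

Rank direction: rank 1 = highest MCC, i.e. "dysfunctional" means "most
discriminating between tumor and normal". Within-term rank ties are
resolved by the fixed level priority methylation → microRNA → mRNA and
flagged (`tie_flag`) rather than forming a seventh "tied" category, so the
six group counts always partition the terms. Overall-ranking ties are
broken lexicographically by term id and flagged. Level-wise MCC
distributions are compared with Welch (unequal-variance) one-sided-greater
t-tests; when both distributions are degenerate the p-value is reported as
0, 1 or 0.5 by the sign of the mean difference and flagged.

All identifiers are case-sensitive exact strings; no aliasing or
normalization is attempted (identifier mapping is an input
responsibility). Missing matrix values are rejected, not imputed.

## The synthetic-study generator

The generator emulates the structure the analysis assumes: three platforms
measuring overlapping but non-identical universes on two-class cohorts, a
term → gene annotation, per-tool target predictions, and an independent
validation cohort. Its generative model, chosen as the simplest one under
which cosine-distance 1-NN separability is tunable:

* Every feature f has a fixed baseline level b_f ~ Normal(8, 2) shared by
  all samples (a log-intensity scale); sample values add
  Normal(0, `noise_sd`) noise (default SD 1). The shared baseline is
  essential for cosine distance to behave as it does on real array data:
  samples of a class cluster around a common profile direction. With a
  zero baseline, normals would be mutually near-orthogonal and no effect
  size could produce error-free classification.
* A planted effect (term, level, Δ) shifts the tumor-class mean of every
  member feature of that term at that level by Δ · `noise_sd`, with a
  random sign per feature. Random signs reflect that dysregulated sets
  contain both up- and down-regulated members; they are also what makes
  the effect visible to cosine distance — a uniform one-directional shift
  is nearly parallel to the baseline profile and mostly absorbed into the
  vector norm. A feature planted by several terms at one level keeps the
  largest-magnitude shift; its sign is drawn once.
* MicroRNA signal is planted on the microRNA matrix rows themselves (the
  pipeline scores microRNA sets on the microRNA matrix, not on target
  mRNA). The member features at the microRNA level are the microRNAs whose
  *true* (generative) target sets intersect the term.
* Tool predictions are conditionally independent given true-target status:
  each tool reports a true pair with probability 0.8 and a background pair
  with probability 0.05 — the simplest mechanism under which the ≥ 3-of-6
  consensus is a meaningful filter (at these rates it passes ~90% of true
  pairs and ~0.2% of background pairs).
* The independent cohort is a fresh mRNA draw from the same law: same
  per-gene baselines and planted shifts, new samples.

Defaults are sized for desk-scale runs: 300 genes, 60 microRNAs, 40 terms,
30 tumor + 30 normal samples per platform, 20 + 20 in the independent
cohort, methylation covering 70% of genes. Term sizes (5–12 genes) and
per-microRNA target counts (3–6 genes) are kept to a few percent of the
gene universe, mirroring the sparsity of real annotations and targetomes
relative to a genome; denser settings make every term's member sets share
the same planted features, so no level assignment could be recovered even
in principle. Effects are in units of within-class SD; Δ = 2.5–3 gives
near-perfect single-set separation at n = 30 + 30, Δ ≈ 0.5 barely
detectable — the range used across the tests.

What the generator does **not** emulate: realistic beta-value
distributions (methylation values are on the same Gaussian scale as the
other platforms), batch effects, correlated features, copy-number
confounding, or correlated tool errors. Tests passing on this model show
the pipeline's logic is correct and that planted multi-level structure is
recovered; they do not certify performance on real cohort data, where
cross-study heterogeneity (the three platforms come from different
patient series) is the dominant unmodeled difficulty.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` reports quantities from three studies, re-derived
from the given seed: (a) a 100-term study planting
Δ_mRNA = 1.5 > Δ_microRNA = 1.0 > Δ_methylation = 0.5 on every term
(terms of 8–15 genes, so that every term has members at every level with
near certainty) — level-wise mean MCCs, Welch one-sided p-values, and the
six-group partition total; (b) a 40-term study with 10 terms planted at a
single level (Δ = 2.5) — the percentage of planted terms whose assigned
group leads with the planted level and whose planted level attains the
best within-term rank; (c) a 40-term study with 8 terms planted at all
three levels (Δ = 3) — top-8 summed-rank selection, high-frequency genes
(frequency > 1), their hypergeometric enrichment against the planted gene
set, consensus-target precision/recall against the generative truth, and
the LOOCV MCC of the high-frequency genes on the independent cohort. In
the rare draw where a planted term has no measured member at its planted
level, the study is redrawn with a deterministically shifted seed.

## Known limitations

* LOOCV with 1-NN yields a discrete MCC grid at small n; at 60 samples
  many terms tie exactly, which is why mean ranks and explicit tie flags
  matter.
* Group assignment compares *ranks*, not effect sizes: a term can lead
  with a level whose absolute MCC is modest if the other levels rank even
  lower. This matches the method's intent (ranks absorb cross-platform
  incomparability) but means group labels are relative statements.
* The enrichment universe defaults to the mRNA-measured genes; with a
  differently chosen universe the p-value changes — it must be fixed by
  the analyst, not compared across choices.
* Cross-cohort validation is LOOCV *within* the independent cohort, not
  training on one cohort and testing on the other.
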