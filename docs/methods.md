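# Methods

## Model

`targetexpress` treats context-specific miRNA target prediction as a
binary classification problem per perturbation experiment.  The unit of
analysis is a (transcript, miRNA) pair carrying at least one of six
sequence-based scores — TargetScan Total Context+ (more negative =
stronger) and P<sub>CT</sub> ∈ [0,1], microT-CDS miTG, and three
per-transcript MIRZA aggregates (canonical, target-frequency,
non-canonical), each formed as Σ ln(site score) over the transcript's
sites — plus one expression value for the cellular context.

Training labels come from the experiment's differential-expression
table.  In the default `fdr` mode, TT = predicted ∧ measured ∧
log2FC < 0 ∧ FDR < 0.1 and FT = predicted ∧ measured ∧ FDR > 0.2
(both inequalities strict; direction is ignored for FT).  Predicted
targets that were not measured are excluded.  The alternative `topk`
mode takes the k = 250 most down-regulated transcripts (t < 0,
ascending t) as TT and the 250 with |t| < 1 closest to zero as FT,
which puts two platforms on an equal footing; "top" among the
non-changing genes is read as smallest |t|, and ties at the k-th value
break lexicographically on transcript id so labelling is deterministic.

### Feature scaling

Each of the 7 feature columns is independently converted to average-tie
ranks and affinely mapped so min → −1, max → +1; missing scores take
the centre 0, and a constant column maps wholly to 0 rather than
erroring (a flat profile is legal on small inputs).  Scaling is
per-matrix: a training matrix and an evaluation matrix are each ranked
internally and no min/max carries over, which is what makes arbitrary
monotone expression measures interchangeable.  Before ranking every
feature is oriented so larger = stronger predicted targeting; only
Total Context+ needs negating.  The orientation is configurable since
the convention cannot be recovered from first principles for every
upstream score table.

### Ensemble

One soft-margin RBF SVM is trained per eligible experiment (γ = 1/7 —
one over the number of features, kept fixed even for single-method
variants where other columns are neutralised to 0; cost = 1; no
internal rescaling).  Class imbalance (FT ≫ TT) is offset by per-class
penalties cost·c₁ and cost·c₂ with c₁ = (1/n₁)/(1/n₁+1/n₂),
c₂ = (1/n₂)/(1/n₁+1/n₂); these satisfy c₁+c₂ = 1 and c₁n₁ = c₂n₂, the
standard inverse-class-size weighting (equivalent to e1071's
`class.weights` up to a global constant absorbed by cost).  Eligibility
requires a passing seed-enrichment gate and ≥ 20 TT.

The consensus score of a transcript is the **sum of the signed
continuous decision values** of all members; positive = predicted true
target in the supplied context.  Summing hard ±1 votes is available as
`mode="vote"`, but the decision-value sum is the default: the score
distribution is continuous and the extra resolution matters for
ranking-based evaluation.  Consensus is additive and invariant to
member order, and training is deterministic for fixed data.

### Single-method variants and baselines

`restrict_features` zeroes the score columns outside a chosen method
(flagging them imputed), leaving the matrix shape unchanged — this
yields the TS-only / MT-only / sum variants.  The median-intersect
baseline retains a target's score only when its expression strictly
exceeds the median of the *entire* profile (even-length profiles use
the midpoint of the central order statistics); for ROC purposes removed
targets are ranked below every retained one.  The sum baseline adds the
selected rank-scaled columns, imputed zeros contributing nothing.

## Evaluation

AUC is the tie-aware Mann-Whitney probability
(concordant + ½·tied)/(n₊·n₋), computed via rank sums; curve points are
taken at every distinct threshold and the operating point minimises the
Euclidean distance to (sensitivity = 1, specificity = 1), ties going to
the higher sensitivity.  An optional 95% CI uses DeLong's variance
estimator.  Cross-validation is experiment-level leave-one-out: train
the ensemble on n−1 experiments, score the held-out experiment's
labeled transcripts, repeat per method.  Method AUC vectors, paired by
left-out experiment, are compared with a one-sided Wilcoxon
**signed-rank** test (the paired design dictates signed-rank): the tail
probability is exact — a dynamic program over the 2ⁿ sign assignments
of the observed |difference| ranks, which also handles tied ranks — for
n ≤ 25, and a normal approximation with tie and continuity correction
above.  All-zero difference vectors return p = 1 with a warning.

## Seed-enrichment QC and gene-set tests

The QC gate is a minimal reimplementation of the core seed-landscape
statistic: at each of 20 evenly spaced leading-bin cutoffs along the
t-ranked gene list, a hypergeometric tail test of UTRs containing the
seed word (7mer-m8 = reverse complement of miRNA positions 2–8;
7mer-A1 = reverse complement of 2–7 plus A) in the leading bin versus
the remainder.  Word presence is binary per UTR, which keeps the null
exactly hypergeometric; per-occurrence counting and composition-bias
correction are deliberately out of scope, since the gate's role is a
sound pass/fail filter, not a full enrichment landscape.  The gate
passes when the minimum over-representation p across cutoffs,
Bonferroni-corrected for the number of cutoffs, falls below α (default
0.001).  The published inclusion threshold was a visual judgement; the
α-based gate is an explicit stand-in and is not claimed to reproduce
any particular inclusion list.  Bonferroni over strongly dependent
cutoffs makes the gate conservative: its null pass rate is bounded by α
rather than centred on it.

The gene-set test asks whether a GO term's members rank higher among
prediction scores than the rest of the predicted-target universe
(one-sided Wilcoxon rank-sum on within-universe ranks).  It is exact by
exhaustive subset enumeration when C(|universe|, |set|) ≤ 10⁵ (correct
under ties), exact via the Mann-Whitney distribution for tie-free data
with a side ≤ 10, and a tie-corrected normal approximation otherwise.
Term size is filtered strictly: 5 < |members ∩ universe| < 100.

## Synthetic data

The generator produces what training consumes: per-experiment
prediction tables, an expression profile, a DE table and 3'UTRs.
Structure and defaults (chosen once as the package's study conditions):

- **Expression**: 10^N(1.5, 1) — positive, heavy-tailed, spanning ~4
  orders of magnitude, as real transcriptomes do.
- **Scores**: a latent per-transcript affinity a ~ N(0,1) with loading
  0.75 plus independent method noise, pushed through method-specific
  monotone transforms (Context+ negative and bounded above by 0, PCT
  and miTG squashed to (0,1), MIRZA-style log-sums unbounded); default
  per-method missingness 25–35%, with at least one score forced present
  per transcript.
- **Repression**: P(repressed) = σ(α + 1.5·z_score + 1.5·z_expr) with
  α set from the target prevalence 0.15; expression and sequence signal
  carry comparable weight, reflecting the observation that abundance is
  a strong determinant of measured targeting.
- **DE**: repressed transcripts receive a negative t-shift whose
  magnitude grows with abundance — this abundance–response coupling is
  part of the expression effect and therefore scales with
  `effect_expr`, vanishing in the `effect_expr = 0` control so that
  control is a true null for the expression feature.  p-values are
  two-sided normal tails, FDR is Benjamini–Hochberg, log2FC is a
  scaled copy of t.
- **UTRs**: uniform random sequence, 200–600 nt, with the expected
  miRNA's 7mer-m8 seed word planted in each truly repressed
  transcript's UTR, tying the QC gate to ground truth.
- Sizes: 5 experiments × 2000 transcripts per replicate; a full
  leave-one-out replicate runs in a few seconds, and the bundled
  analyses use 20 replicates for the signal regime.

What the generator does **not** emulate: probe effects, batch and
platform noise, correlated UTR composition, secondary (indirect) DE
effects, or real inter-method score distributions.  Passing tests
therefore demonstrate that the machinery recovers the assumed
score-and-abundance structure when it is present, not that any
particular real dataset will reach the same AUCs.

## Numerical choices and edge cases

- Natural log for MIRZA aggregation (rank scaling erases the base; a
  base argument exists for matching external output); empty site lists
  mean "no MIRZA score", non-positive site scores are errors.
- UTR windows: full 50-nt windows every 25 nt; when sequence remains
  past the last full window, one final window starts one step after the
  last full one, so trailing fragments shorter than the step are merged
  rather than emitted (a <25 nt window is not scoreable); sequences
  ≤ 50 nt give one full-length window.
- Duplicate expression ids collapse by max (microarray probe
  convention) by default; mean and error policies are exposed because
  the original probeset-to-transcript rule is not recoverable.
- Missing scores are encoded on disk as empty or "NA" and internally as
  None/NaN, never a sentinel number (0 is a legal score).
- Model persistence (joblib) stores a format version and the feature
  order; loading verifies both.

## Known limitations

- The consensus is an uncalibrated margin sum; it orders targets within
  a context but is not a probability, and magnitudes are not comparable
  across ensembles of different size.
- The seed gate tests only the two canonical 7-mers of the expected
  miRNA, not the full k-mer landscape.
- No transcript-id translation is performed; all tables must share one
  id namespace.
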