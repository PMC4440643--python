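# Methods

## The procedure and its assumptions

The pipeline treats per-CpG methylation (β ∈ [0,1], the methylated
fraction of signal at one CpG) as a read-out of phenotype-linked
regulatory activity and asks which TF binding motifs concentrate in the
sequence neighborhoods of phenotype-associated CpGs.

**Screens.** Differential methylation uses a pooled-variance two-tailed
Student t-test per CpG (Wilcoxon rank-sum available), BH-adjusted with the
family restricted to testable CpGs; CpGs significant at adjusted p < 0.05
are split by the sign of the statistic into hyper-/hypomethylated sets.
The survival screen fits one univariate Cox model per CpG, β untransformed
as the covariate, so the coefficient is log hazard per unit β. The screen
is deliberately unadjusted: CpGs at Wald p < 0.02 with HR<1 / HR>1 are
protective / hazardous, and the enrichment stage is designed to tolerate
the resulting false positives (they dilute relative enrichment toward 1
rather than invalidating it). The Cox assumptions are proportional hazards
and independent censoring; ties are handled by Efron's approximation
(Breslow available), Newton–Raphson to |Δβ| < 1e-8, max 50 iterations,
standard errors from the observed information. Monotone-likelihood data
are flagged non-converged rather than raised.

**Regions.** Each selected CpG contributes a 102-bp window: 50 bp flank +
CG + 50 bp flank, i.e. [p−51, p+51) in 0-based half-open coordinates for a
C at 1-based p. "Centered" is ambiguous for an even window on a 2-bp
site; the 50/2/50 decomposition is the unique symmetric reading and is
fixed here. Windows are never clipped — CpGs too close to a chromosome
end are dropped — so all scanned regions are equal-length and motif
presence probabilities are comparable. Overlap filtering is greedy per
(chromosome, strand): within each connected component of the
interval-overlap graph, keep the smallest-p region, discard everything
overlapping it, repeat. Ties in p break by smaller start coordinate, then
lexicographic CpG id, making the output deterministic. The filter is
idempotent and always retains each component's minimum-p region.

**Scanning.** Motif models are probability matrices (counts get a +0.1
pseudocount per cell; probability matrices are floored at 1e-4 and
renormalized) scored as log₂ odds against a zero-order background
(uniform 0.25 by default; a background estimated from the scanned regions
is available — the uniform default is parameter-free and reproducible).
Scores are discretized at granularity 1e-4 bits and the exact null
distribution of the window score is obtained by dynamic programming over
the integer grid; the presence threshold is the smallest *achievable*
score s with P(score ≥ s) < 1e-4 under the background. If no score is
that rare (low-information motifs: e.g. any width-6 consensus under a
uniform background, best tail 0.25⁶ ≈ 2.4e-4), the motif is marked
unattainable and never called present. Both strands are always scanned —
the reverse strand by scanning the forward sequence with the
reverse-complemented matrix — so presence is invariant under reverse
complement. Windows containing N are skipped. All matches within one
region collapse to a single Boolean. Discretization error is bounded by
width × granularity ≈ 1e-3 bits, far below one grid step of the
per-position scores.

**Enrichment.** For each motif, the 2×2 table (foreground / background ×
present / absent) gets a two-sided Fisher exact p — the sum of
hypergeometric point probabilities (fixed margins) of all tables at most
as probable as the observed one, with the conventional (1 + 1e-7)
relative gate; point probabilities are computed in log space so tables
with N ~ 1e5 are stable. Any zero margin yields p = 1. Relative
enrichment is the ratio of presence proportions — the only definition
that lets a motif be reported "depleted 0.93-fold" while still carrying a
significant p on large sets. The **background definition** is a genuine
gap in the procedure's description: this implementation defaults to *all
overlap-filtered tested regions not in the foreground* (choice
`background_choice="rest"`), with the non-significant complement as an
alternative. BH is applied per analysis across its motif family. When two
foregrounds of different size are compared, `match_set_sizes` truncates
both to the top n = min(|A|, |B|) smallest p-values (boundary ties by
coordinate, then id).

**Clusters and networks.** K-means (k-means++ seeding, best of 10
restarts by WCSS) clusters CpG rows; cluster indices are relabeled in
descending centroid mean β so cluster 1 is always the most methylated.
The WCSS curve over k = 1..10 is reported for elbow-style selection, with
k = 5 as the analysis default; the curve is made monotone by construction
(each k also tries an initialization derived from the k−1 solution plus
its worst-fit point). TF aggregation keeps motifs with adjusted p below
the network threshold (default 0.01) and RE > 1 (depletion excluded),
averages their p-values per TF (raw p averaged, adjusted p used for the
threshold; both emitted, since the convention is underdetermined), and
extracts the induced subgraph on significant TFs plus their first-order
partners — induced, so neighbor–neighbor edges are kept, which is what a
displayed first-order network shows. Node attributes (mean_p, degree,
category) are emitted in GraphML and TSV rather than as rendering.

## The synthetic cohort

The generator's defaults define the study conditions used by the test
suite and the acceptance script: a 2 × 1 Mb random genome, 10,000 CpGs at
true CG dinucleotides, 300 samples split 77/23 into ER+/ER−, 2 planted +
40 decoy motifs of width 8–12, plant rates 0.6 in the windows of 300
survival-linked CpGs vs 0.05 elsewhere, 500 differential CpGs with
Δβ = 0.15, target censoring 0.3.

Per-sample survival follows an exponential with hazard
h₀·exp(γ·mean β over causal CpGs), h₀ = 1/1500 per day, γ = 3 — the
simplest model satisfying proportional hazards, matching the screen's
assumptions. γ is per *unit* β (the covariate spans [0,1]); with the
latent spread below this gives Wald z ≈ 10 for causal CpGs at n = 300,
i.e. a clearly detectable but not degenerate signal. Censoring is an
independent exponential whose rate is solved by bisection on the exact
censoring probability E[λc/(λc+λ)], so the censored fraction lands within
a few percent of target.

Causal CpGs draw β around a shared per-sample latent propensity
u ~ Beta(2,2) (concentration 30); this is deliberate: the hazard depends
on the *mean* β over causal CpGs, and if every CpG were independent no
univariate screen could see a signal diluted by 1/n_causal. The shared
factor encodes the method's own premise — survival-associated CpGs are
individually informative. Non-causal CpGs get independent per-CpG means
(uniform 0.15–0.85, Beta noise at concentration 30); differential CpGs
shift ±Δβ/2 between groups with random sign; optional planted cluster
structure replaces the per-CpG means with k evenly spaced levels.

Plants overwrite the genome (rather than mutate probabilistically) so
ground truth is unambiguous; minus-strand plants are reverse-complemented
before insertion and scanning is strand-symmetric. Planted motifs are
high-information (dominant base 0.9), so a PWM-sampled occurrence passes
the exact 1e-4 threshold in roughly three quarters of cases — enough for
the enrichment signal to dominate while keeping a realistic miss rate.

What the generator does **not** emulate: probe chemistry and batch
effects, copy-number confounding, spatial autocorrelation of methylation,
realistic genome composition (CpG islands, repeats), or motif–motif
co-occurrence. Passing tests therefore demonstrate the statistical
machinery is correct and calibrated under the model's own assumptions,
not that the biological conclusions transfer to any particular cohort.

## Problem sizes and numerical choices in the checks

The whole-method checks run at: all 2×2 tables with N ≤ 48 plus 1,000
random tables with totals ~1e4 (Fisher vs enumeration; at much larger
totals both routes hit the double-precision floor near 1e-10); 20 random
PWMs of width ≤ 8 against exhaustive 4^w enumeration; 5,000 null CpGs ×
300 samples and 200 replicates at γ = 0.8, n = 500 (Cox calibration and
recovery); 1,000 random interval instances of ≤ 200 regions (overlap
filter vs brute force); five full pipeline seeds at the default cohort
scale (planted-motif recovery); and one 500-CpG five-cluster cohort
(k-means recovery). These sizes keep a full run in minutes on one CPU
while leaving the binomial tolerance bands meaningful.

## Known limitations

- The 102-bp window is local by construction; long-range chromatin
  effects are out of scope.
- The Fisher background choice materially affects enrichment on real
  data; both provided options are documented, neither is canonical.
- The scanner's background is zero-order; higher-order genomic
  composition (CpG islands) would shift exact thresholds.
- Fold change in the expression screen uses arithmetic means on the
  provided scale; log-scaling beforehand is a caller choice
  (default off).
- The survival endpoint is whatever the clinical table encodes; the
  package does not distinguish overall from progression-free survival.
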