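# Methods

## Overview

`fluxaging` estimates condition-specific metabolic flux differences from
bulk RNA-seq. Given a constraint-based metabolic model (stoichiometry `S`,
flux bounds in mmol/gDW/h, gene-protein-reaction rules, subsystem labels)
and a gene x sample count matrix over k groups, the pipeline:

1. normalizes counts (median-of-ratios size factors, then log2 with a
   pseudocount);
2. maps each sample's expression onto reactions through GPR rules
   (AND = min, OR = max) to obtain per-reaction evidence;
3. converts evidence to confidence scores 3/2/1 by percentile rank —
   top 35% -> 3, 35-90% -> 2, 90-100% -> 1 — optionally forcing a list of
   vital subsystems to score 3;
4. extracts a context-specific submodel per sample that keeps every
   score-3 reaction functional at minimal penalized use of score-2
   (penalty 1) and score-1 (penalty 100) reactions;
5. profiles fluxes by FBA, optimizing each retained reaction in turn and
   recording its optimal flux (plus the maximal ATPM flux as the ATP
   synthesis capacity readout);
6. compares each reaction's flux levels across groups with the Van der
   Waerden (VdW) normal-scores test, bands p-values (sig: p < 0.05;
   marginal: 0.05 <= p < 0.1), computes row-wise Z-scores, and summarizes
   per subsystem with a decreased/increased direction call.

A preranked GSEA (ES/NES with gene-label permutations) and the
|log2FC| >= 2 & p < 0.05 DEG filter accompany the flux pipeline on the
expression side.

## Statistical model and assumptions

**Normalization.** Size factor for sample j is the median over genes g
(restricted to genes positive in every sample) of `count_gj / ref_g`,
with `ref_g` the geometric mean across samples; normalized values are
`log2(count/sf + pseudocount)` (pseudocount default 1). This is a
documented, monotone substitute for a dispersion-fitted variance
stabilizing transform: every downstream consumer (z-scores, percentile
ranks, GSEA ranking) uses only the ordering and scale-stabilization of
the values, not their variance model. Note that the overall scale of
median-of-ratios size factors is arbitrary: multiplying one sample's
library by c rescales *all* normalized columns by the single global
factor c^(1/n); per-column values are meaningful only relative to each
other (a property test pins this down exactly).

**GPR aggregation.** AND = min, OR = max — the dominant convention for
mapping expression to reactions; it is monotone (raising any gene's
expression never lowers a reaction's evidence), which percentile scoring
inherits. Genes in rules but missing from the matrix are imputed with the
matrix-wide minimum (absence of evidence must not promote a reaction) and
reported in the run manifest. Reactions without a GPR receive the median
evidence of GPR-backed reactions (neutral prior); a fixed "always score
2" policy is available (`no_gpr_policy="score2"`).

**Confidence scoring.** Percentile rank = average rank from the top
(ties share their average rank) divided by the number of reactions; a
reaction exactly at the 35.000% boundary scores 3 (inclusive "top 35%").
Forced subsystems score 3 regardless of evidence. The default forced
list contains the twelve vital pathways needed for stability on
genome-scale models (oxidative phosphorylation, citric acid cycle,
glycolysis/gluconeogenesis, CoA biosynthesis and catabolism, NAD
metabolism, fatty acid metabolism/activation/elongation/oxidation, ROS
detoxification, biomass and maintenance functions).

**Context extraction.** A deterministic cost-optimization reaction
dependency assessment. For each score-3 target r (each direction
separately if reversible): (i) maximize v_r; if the capacity is below the
flux threshold (1e-6) in both directions, r is reported as blocked;
(ii) otherwise re-solve at demand `min(capacity, 1.0)` minimizing
`sum(penalty_i * |v_i|)` over score-1/2 reactions (|v| via the standard
split variables), and accumulate as support every score-1/2 reaction with
flux >= threshold. Score-2 reactions not used as support are retained if
they can independently carry flux when added to the candidate submodel
(evaluated one at a time against the candidate, in model order).
Score-1 reactions enter only as support. The extracted submodel re-verifies
that every retained score-3 reaction is functional. The demand level of
1.0 mmol/gDW/h keeps support fluxes well above solver tolerance; with
threshold-level demand the support pattern would sit at the numerical
noise floor. This variant preserves the published method's contract
(high-confidence reactions functional, minimal low-confidence inclusion)
while being deterministic and provable against exhaustive subset
enumeration; it does not reproduce the original algorithm's stochastic
noise injection or iterative inclusion order.

The mentioned "minimization of the flux standard deviation across
samples" is exposed purely as a diagnostic table
(`flux_sd_within_group.tsv`): no search procedure over score thresholds
is defined, so none is guessed.

**Flux profiling.** Each reaction of a context model is optimized as the
LP objective (`max c'v s.t. Sv = 0, lb <= v <= ub`, HiGHS backend,
deterministic). For reversible reactions both directions are solved and
the signed optimum of larger magnitude is reported (tie -> the
maximization value); `maximize_only=True` restores one-sided profiling.
Only objective values are contract-guaranteed: non-objective flux
components of an optimal basis are not unique under alternate optima, and
the group comparison consumes objective values exclusively.

**Group comparison.** VdW test: pooled average ranks R_ij, normal scores
A_ij = Phi^-1(R_ij/(N+1)), s^2 = sum(A^2)/(N-1), statistic
T = (1/s^2) sum_j n_j Abar_j^2, asymptotically chi-square with k-1 df.
Rows with zero spread are degenerate (p = 1, flagged, excluded from
heatmaps). Banding uses raw p-values (no multiplicity correction, as in
the flux-heatmap convention this reproduces); a Benjamini-Hochberg
q-value column is emitted as a safety rail but never used for banding.

*Small-sample caveat.* With k = 4 groups of n = 2 the statistic has a
hard ceiling: the most extreme configuration (adjacent order-statistic
pairs per group) gives T = 6.55, i.e. chi-square p = 0.088 — **no** data
can reach p < 0.05 at that design (a test asserts this). The package
therefore provides `method="permutation"`: exact enumeration when the
number of group assignments is <= 20000 (e.g. 2520 at 4x2), Monte-Carlo
label shuffles otherwise. Even exact permutation cannot beat p = 1/7 at
4x2 for two-valued rows. Consequently power analyses and the end-to-end
recovery checks run at 4 replicates per group (N = 16), where a clean
suppressed row reaches chi-square p ~ 0.002; with 2 replicates the test
is structurally unable to produce "sig" bands. The 40k-draw calibration
of the chi-square reference at 4x4 shows it is conservative (type-I
~0.031 at nominal 0.05); the permutation method is well calibrated
(~0.046).

**Preranked GSEA.** Genes ordered by decreasing score (ties broken by
gene id). ES is the signed maximal deviation of the weighted KS running
sum: hit increments proportional to |score|^p (p = 1 default) normalized
over the set, miss decrement 1/(N - set size). NES = ES / mean|ES*| over
same-sign gene-label permutations; p = (1 + #{|ES*| >= |ES|, same sign})
/ (1 + #same-sign). Sets below `min_size` (default 3) are excluded and
reported. Null simulations show near-nominal behavior (~0.05 rejection
at alpha = 0.05 over 500 draws).

## Synthetic data

`make_toy_model(n_linear_pathways, ...)` builds independent linear
pathways: uptake (bounds [0, 10] mmol/gDW/h) -> chain conversions ->
demand sink, each with a GPR over fresh genes; pathway 1's terminal
metabolite also feeds the ATPM pseudoreaction (subsystem "Biomass and
maintenance functions"). By construction every pathway reaction's maximal
flux equals the uptake bound — an analytic FBA oracle.

`simulate_counts` draws negative-binomial counts (dispersion 0.1, i.e.
CV^2 ~ 0.1 at high means) for 4 groups (WT_young, KO_young, WT_old,
KO_old) x `replicates` libraries. Gene means are `baseline_mean` (500)
times a fixed log2 offset by reaction role — uptake +2, sink +1.5, chain
+1/0/-1. The offsets give every pathway a stable high-expression anchor
reaction at baseline; this stands in for the expressed transcriptome
background a genome-scale model provides, without which percentile
scoring (a purely relative rule) has no stable reference in a
20-60-reaction network. Genes of the suppressed subsystems (default:
fatty acid oxidation, citric acid cycle, carnitine shuttle, NAD
metabolism) have their means multiplied by `2^suppression_lfc`
(default -2) in KO_old only.

Replicates default to 2, mirroring the emulated study's two libraries
per condition; because of the VdW ceiling above, the demo used in the
worked example, the end-to-end recovery tests, and any power study
should use >= 4 (the study's animal-level n was larger than its
library-level n, so this is not an inflation of the design).

What the generator does **not** emulate: transcriptome-wide gene counts,
batch effects, GC/length bias, gene-gene correlation, metabolite
sharing between pathways, or realistic genome-scale network redundancy.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of a planted signal under idealized conditions — not
performance on real kidney RNA-seq.

**Forcing on toy networks.** The demo config leaves `forced_pathways`
empty. On a self-contained toy pathway, forcing it to score 3 guarantees
its whole chain is pulled in as support, so its flux becomes
expression-independent and the planted suppression is masked by
construction. On genome-scale models the forced vital pathways still
depend on unforced transporters and exchanges, so forcing and
expression-driven variation coexist there.

## Numerical choices

- LP backend: `scipy.optimize.linprog(method="highs")`; flux threshold
  1e-6; steady-state residuals verified to 1e-6, bounds to 1e-9.
- Unbounded-flux sentinel +/-1000 (community convention) for bounds
  missing from model files.
- Degenerate inputs: all-equal VdW rows -> p = 1 with flag; zero-SD
  z-score rows -> 0 with flag; empty GPR -> NaN evidence sentinel
  resolved by the no-GPR policy.
- Determinism: a single `seed` drives count simulation, GSEA and
  Monte-Carlo permutations (`numpy.random.default_rng`); result TSVs are
  byte-identical across reruns (floats printed at %.10g).

## Problem sizes

Default demo and test scale: 12 pathways (61 reactions, 60 genes), 4
groups x 4 samples -> 16 context models and roughly 2000 small LPs per
pipeline run (a few seconds on one core). Oracle comparisons
(exhaustive support enumeration, COBRA-toolkit FBA, independent VdW
reimplementation) run on instances of <= 12 reactions or <= 20 variables.

## Known limitations

- The extraction variant is deterministic and penalty-driven; it will not
  reproduce the inclusion order of stochastic implementations of the
  original dependency-assessment algorithm.
- Flux "levels" are per-reaction optima (capacities), not a single
  consistent flux distribution; they should not be summed across
  reactions.
- The chi-square VdW reference is unusable at 2 replicates per group (see
  ceiling above) and conservative at 4; use the permutation method for
  small designs.
- SBML support covers Level 3 + fbc bounds/GPRs and groups-based
  subsystems; kinetic laws and events are ignored.
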