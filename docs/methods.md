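# Methods

This note documents the models and procedures `pignet` implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real observations.

## Event model and fight bouts

Events are half-open intervals `[t_start, t_start + duration)` in seconds
from mixing, over a 5-h (18 000 s) observation window. Point behaviours
(head-knock, lunge, shove, flick, single bite, retreat, mount) carry
duration 0; state behaviours (displays, pushing, bullying, fighting,
within-fight rest) carry positive durations. Ties in event order break by
(time, actor ID, behaviour code). The shipped ethogram is a YAML config;
users can extend it, and all scoring-window constants (the 3-s
reciprocation window, the 60-s fight-end rule, the 2-h subtle-behaviour
cutoff) live there.

Fight bouts chain a dyad's aggressive acts: a bout continues while no gap
of ≥ 60 s separates consecutive aggressive acts (rest states neither break
nor extend the chain; an interleaved bite keeps a bout alive). The bout
span runs from the first to the last fight state; `duration_s` is that
span (rest included), while `fighting_seconds` sums only active fighting.
Outcome assignment: a retreat point event by exactly one participant in
the window `[t_end, t_end + 3 s]` decides the bout for the other pig;
both-retreat and no-retreat are undecided. The 2-h cutoff for shove/flick
is inclusive at exactly 7 200 s. These boundary choices (inclusive cutoff,
the 3-s outcome window reusing the ethogram's reciprocation window, the
earliest-window pass trial below) were made once for determinism where the
protocol leaves them open.

## Networks

ALL/UNI/WIN are directed, FIGHT undirected. Weights: summed durations with
points worth 1 s (ALL, UNI), active fighting seconds per bout (FIGHT), and
the count of decided fights won (WIN). FIGHT edges use active fighting
time rather than the bout span so that, per dyad, the FIGHT weight can
never exceed the ALL weight (within-bout rest carries no aggression and
enters neither). "Non-reciprocated" for UNI is evaluated against the 3-s
window: a damaging act by A enters UNI unless B delivers a damaging act
back with any overlap of `[start − 3 s, end + 3 s]`; a reciprocated
exchange is a fight, not unilateral aggression. Damaging aggression means
the biting behaviours (single bite, bullying).

Littermate dyads are excluded from all four networks. Rationale:
centralities are normalised by the number of non-littermates, and in
practice nearly every pig exchanges some agonistic behaviour with every
non-littermate (unweighted ALL degree pins at 1), which is only consistent
if littermate edges do not count against that denominator. Isolated pigs
remain as nodes with centrality 0. Parallel edges collapse by summing
weights (idempotent, weight-conserving).

## Centrality and size correction

Degree (in/out/all, unweighted and weighted) comes from neighbour counts
and incident edge weights; betweenness uses Brandes' algorithm with the
fractional split across tied shortest paths, and the weighted variant
travels on edge distance 1/weight (strong ties are cheap to traverse; the
−log w alternative was considered and not used). Unreachable pairs
contribute nothing; no harmonic variant. Eigenvector centrality is
computed on the undirected weighted projection (reciprocal directed
weights summed) by exact symmetric eigendecomposition, entries
non-negative and max-scaled; it is reported for the FIGHT and WIN
networks.

Size corrections, per focal pig with *n* non-littermates: degree family
divided by *n*; betweenness divided by the number of ordered pairs of
other animals in a group of n+1, i.e. n(n−1), halved for undirected
networks; eigenvector needs none beyond max-scaling. The exact correction used in the field is not fully
standardised; this reconstruction applies the non-littermate denominator
to degree and extends the same logic to pair counts for betweenness, and
the tests show it does not fully remove group-size effects (network size
remains a fixed effect in every model for exactly that reason).

An exhaustive oracle (`betweenness_oracle`, ≤ 8 nodes) enumerates every
simple path per pair and applies the same fractional split; the test suite
checks the shortest-path implementation against it on hundreds of random
directed/undirected, weighted/unweighted graphs. Near-tie tolerance is
1e−12 on path length; test graphs draw continuous weights so exact ties
occur only for genuinely identical paths.

The redundancy screen computes Pearson r (the conventional default; the
choice over Spearman is a judgement call) between each weighted metric and
its unweighted counterpart within a network type, flagging r > 0.8. The
comparison carries a 1e−12 epsilon so a correlation of exactly 0.8 lands
on the non-redundant side regardless of rounding.

## Cognitive scoring

The pass criterion scans for the earliest 12-trial window holding ≥ 10
correct decisions; the pass trial is the last trial of that window. The
chance probability of such a window is the exact binomial tail
(79/4096 ≈ 0.0193 for 10/12 at p = 0.5), and the suite cross-checks it by
enumerating all 2^12 sequences. Learning speed counts trials from the
first opening of the negative-location box (first experience of both cue
types) to the pass trial, inclusive on both ends and clamped to the
12–36 bound; completers that never pass score 36. Pigs that
never opened the negative box with ≥ 12 trials remaining are *not
completed* — distinct from failing, and carried as missing into the
models (inclusion is a separate binary effect). Fast/slow splits at 17
trials. Reversal passes on a 6-run or a 10-of-12 window among ≤ 20 trials;
an empty record is missing, not a failure.

Group allocation sums points for SDT pass, above-average learning speed
and reversal pass. "Above average" means strictly fewer trials than the
mean of completers in the training cohort (the cohort mean is a parameter;
it defaults to the supplied profiles because synthetic studies are a
single cohort). Within each litter of up to four test pigs, the top two by
points go to the high-performance group, ties broken by faster speed and
then pig ID; single-pig litters fall back to a points-at-median threshold.

## Mixed models

Gaussian outcomes use a linear mixed model with fixed effects sex, body
weight and network size, a pen random intercept and a litter variance
component nested within pen, fitted by REML for reporting and by ML for
likelihood comparisons (statsmodels MixedLM, its default optimisation
schedule; explicit single-optimiser settings converged noticeably worse in
null simulations and are only fallbacks). Skewed outcomes are
log(x+1)-transformed and LS-means back-transformed with e^(m±se) − 1;
LS-means average fixed-effect predictions over the observed covariate
distribution. A litter component estimated at numerically zero triggers a
refit without it, flagged on the result. Wald tests use t statistics with
df = n − k; without Satterthwaite/Kenward–Roger denominators this is
mildly anticonservative (measured ≈ 5.7–6 % at α = 0.05 in 300-replicate
null simulations), which the type-I acceptance band accommodates.
Variance inflation factors and an RMSE accompany every Gaussian fit.

The full-model comparison adds terms in the order the protocol implies:
test inclusion (tested vs not) is evaluated on all pigs in its own model,
because a cognitive outcome is undefined for untested pigs; the cognitive
term itself is then tested on the tested subset against a null refit *on
the same rows and with the same random structure*, by a 1-df Wald test, an
ML likelihood ratio and ΔAIC. Terms with fewer than two observed levels
are refused.

Count and binary outcomes (lesion counts; sparse-region presence) use
Poisson and binomial mixed GLMs fitted by variational Bayes
(statsmodels BayesMixedGLM) with pen and litter variance components;
contrasts are Wald z tests on the posterior means and logit-scale results
are reported as odds ratios e^(m±se). Likelihood-ratio tests and AIC are
not defined for these fits, so the comparison reports Wald only — the
main limitation of delegating the GLMM solve.

Crossed random effects are not supported by the delegated solver: litter
enters nested within pen. For the synthetic data this is exact (sibling
groups are co-housed); for real data where a litter spans two pens it
approximates the crossed design by treating the pen-litter cell as the
litter level.

Significance is read at p < 0.05 with a tendency below 0.1. No
multiple-testing correction is applied, deliberately matching the
analysis convention the pipeline reproduces.

## Synthetic data generator

The generator is a first-class, tested module, not a fixture. It emulates
the statistical structure the pipeline assumes, with every effect
user-settable (including all-zero for a null world) and full determinism
from one seed (numpy Generator; per-pen substreams spawned from the master
seed).

* **Pens.** 12–14 pigs (mean ≈ 12.8), balanced sexes, sibling groups of
  1–4 (mostly pairs) constrained so every pig has 6–14 non-littermates
  (achieved mean ≈ 10.6–10.8). Weights are Normal with a between-pen
  component (overall ≈ 62.4 ± 7 kg) and a reduced within-pen SD (≈ 5.5 kg),
  reflecting weight-matched pen assembly.
* **Trials.** Each pig carries a latent ability; correct-decision
  probability is 0.5 before a geometric learning-onset trial and
  sigmoid(1.8 + 0.9·ability) after it, with negative locations never
  presented more than twice consecutively. These values were calibrated
  once against the study conditions the generator emulates (median
  trials-to-pass near the 17-trial fast/slow split, roughly a third of
  passers at the 12-trial minimum, a high pass rate among completers) and
  then frozen. Reversal
  uses a later onset and sigmoid(1.2 + 0.9·ability), giving ≈ 50 % passes.
  About 29 % of pigs never enter the SDT and a further share never enter
  reversal, reproducing test attrition.
* **Events.** Per non-littermate dyad, three Poisson streams
  (non-damaging/display, damaging, fights) with exponentially decaying
  onset times (τ = 5 400 s — aggression peaks immediately after mixing).
  Actors are chosen in proportion to exp-linear propensity in sex and
  weight; fights get lognormal durations, occasional rest-split segments,
  and decide with probability 0.55, the heavier pig winning with logistic
  probability and the loser retreating within the outcome window.
  Littermate dyads receive only a small residual rate of mild behaviour.
  Default rates put median per-pig agonistic involvement near 600 s of
  5 h. The injected cognition effect multiplies damaging-aggression rates
  for dyads involving a reversal passer; its default (1.5) was sized by
  power analysis so a 14-pen study detects it with ≥ 80 % power (measured
  ≈ 90 %), and the sex multiplier (1.6) reproduces the male excess in
  aggression given.
* **Lesions.** Poisson counts per region and timepoint with means linear
  in damaging seconds received and anterior ≫ central > posterior shares,
  plus small weekly baselines; the pre/24-h pair exercises the floored
  delta.

What passing tests on these data establish: that the pipeline's scoring,
network construction, normalisation and model comparison recover known
structure at realistic sizes, and that its tests are calibrated under the
null. What they do not establish: behavioural realism beyond that
structure — no diurnal pattern, no dominance memory across bouts, no
spatial constraints, no observer error — so quantitative agreement with
any real study's coefficients is out of scope.

## Problem sizes in the checks

The repeated-study checks run at sizes chosen to finish quickly while
keeping their statistical bands meaningful: 100 independent 14-pen studies
for the sign-recovery check, 500 independent 6-pen studies for the type-I
calibration (the band is 5 % ± 2 binomial SE at the replicate count used),
200 random graphs of ≤ 8 nodes for the betweenness oracle, 50 random
12-node graphs for eigenvector residuals.

## Known limitations

* Wald denominators are asymptotic (no Satterthwaite df); small-study
  p-values are mildly anticonservative, quantified above.
* Non-Gaussian families report Wald-only comparisons (variational fits).
* The size correction is a reconstruction; group-size effects persist and
  must stay in the fixed structure.
* The pipeline scores what the ethogram encodes: unlogged within-bout
  pauses (no rest state) inflate bout spans but never FIGHT edge weights.
* Real litters spanning pens are approximated by nested pen-litter cells.
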