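# Methods

`preysel` implements the quantitative analysis chain of multiple-choice
predation experiments: several prey types are offered simultaneously to one
predator individual for a fixed period (24 h in the design the package
mirrors), surviving prey are counted, and the replicate individuals of each
predator stage together yield estimates of selectivity, diet overlap,
food-web module structure and prey vulnerability.

## Selectivity

For one individual offered `m` prey types with initial counts `n_i0` and
consuming `r_i` of type `i`, Manly's selectivity index is

    alpha_i = (r_i / n_i0) / sum_j (r_j / n_j0),

the probability that the next capture would be prey `i` if all prey were
equally available. Two corrections reflect the no-replacement design:

* **Background mortality.** The mean number of each prey dying in
  predator-free control trials is subtracted from the prey missing at the end
  of a trial, and the result clamped to `[0, n_i0]`. Consumption is therefore
  real-valued; no rounding is applied before computing alpha, because the
  subtracted quantity is a mean.
* **Depletion.** When an individual consumed *every* item of a prey (zero
  survivors), that prey's initial count is inflated by one — in its own ratio
  and in the normalising sum — assuming the extra item would have survived.
  The resulting alpha is slightly conservative: strictly below the
  uncorrected value whenever any other prey was eaten (a tested invariant).
  The trigger is "zero survivors" rather than "corrected consumption equals
  the offer" because the two differ for prey with non-zero control mortality,
  and only the former is directly observable.

Individuals that consumed nothing carry no selectivity information; they are
excluded from averaging with a warning. Species-level alpha is the arithmetic
mean of the per-individual vectors (each individual is one replicate).

Alpha is presented as Chesson's electivity
`eps_i = (m*alpha_i - 1) / ((m - 2)*alpha_i + 1)`, which maps `[0, 1]` onto
`[-1, +1]` with 0 at unselective feeding (`alpha = 1/m`). The formula
requires `m >= 3` and is rejected otherwise. Diet breadth is the number of
prey consumed at all (equivalently, mean electivity above -1).

Per-prey selectivity tests are one-sample t-tests of the individual alphas
against `1/m`, with Holm's step-down correction across the `m` prey of each
predator. Zero-variance prey are degenerate: p = 1 when the common value
equals `1/m`, otherwise p -> 0 with a flag that the test statistic is not
trustworthy. Ontogenetic stage contrasts are two-sample t-tests per prey,
oriented so positive t means the later stage prefers the prey more; Welch's
unequal-variance form is the default (the pooled form is a switch, since
either is defensible for 5-9 replicates per stage), and prey consumed by
neither stage yield a missing marker rather than a number.

## Overlap, clustering and ordination

Pianka's index — the cosine similarity of two non-negative resource-use
vectors — is applied in two directions: species-mean alpha vectors give the
diet overlap of two predators, and mortality-by-predator vectors (mean
proportion of offered prey consumed, original offers in the denominator) give
the predation-pressure overlap of two prey. Overlaps are scale-invariant,
symmetric, bounded in [0, 1], and equal 1 exactly when the vectors are
proportional (all property-tested).

Dissimilarities `D = 1 - overlap` feed Ward's minimum-variance hierarchical
clustering. The default variant is the classic Lance-Williams Ward update on
the raw dissimilarities (the behaviour of R's original `hclust(method =
"ward")`, now called `ward.D`), implemented as scipy Ward linkage on the
element-wise square root with squared merge heights; this equivalence was
verified against R's `hclust` to 1e-6 on the bundled published matrices, and
those merge heights are frozen in the test suite as oracle values. A
`ward.D2` variant (scipy Ward applied directly) is available. Tie-breaking
follows scipy's deterministic scan order; with continuous dissimilarities
ties are not expected.

Non-metric MDS minimises Kruskal stress-1 via SMACOF with monotone
regression, best-of-N random restarts under a single seed; the reported
stress is multiplied by 100, the conventional presentation scale. Different
NMDS engines reach slightly different local minima, so stress values are
reproducible within this package but not across implementations.

## Bipartite modularity

The experimental food web is a weighted two-mode network: predator stages x
prey types, with weights given by either interaction-strength measure
(species-mean alpha or mean mortality), multiplied by 100 and rounded to the
nearest integer. For a joint partition g of rows and columns, Barber's
modularity is

    Q = (1/F) * sum_ij (A_ij - k_i d_j / F) * [g(i) == g(j)],

with `F` the total weight, `k_i` row sums and `d_j` column sums. Q is
maximised by simulated annealing over joint label assignments
(move/merge/split proposals, geometric cooling, greedy single-node polish),
best of a configurable number of restarts (default 50) under a fixed seed.
On every web small enough to enumerate (<= 12 nodes) the optimiser attains
the exhaustive-enumeration optimum, which is a tested property. Module
*composition* is the robust output; the numerical Q value depends on the
weight measure and scaling.

## Prey vulnerability

Mortality of prey p under predator k is the replicate-level proportion of
offered individuals consumed (control-corrected), averaged per predator
stage; the grand mean per prey weights every predator stage equally. Whether
vulnerability differs across predators is tested per prey with a
quasi-binomial GLM: binomial-logit IRLS on replicate-level proportions
weighted by their denominators, Pearson-based dispersion, and an
analysis-of-deviance F test. Replicate-level (not stage-pooled) fitting was
chosen because the individual predator is the experiment's unit of
replication. Complete separation is flagged; the F-based p is still
reported. Degenerate fits with identical proportions everywhere return F = 0
rather than floating-point noise ratios.

## Literature synthesis

Published multiple-choice experiments are scored on a binary scale: every
taxon tied for "most preferred" in an experiment scores 1, all other offered
taxa 0, and unselective experiments score 0 everywhere. Experiments offering
prey from a single taxon are excluded (they cannot rank taxa). Ties all
score 1, which inflates per-experiment score sums but matches how published
summaries highlight multiple preferred prey; this choice changes denominators
and is therefore stated here.

Differences between taxa are tested with the same quasi-binomial GLM
machinery on the binary scores. Because a one-factor binomial GLM depends on
the data only through per-taxon totals, a score table can equivalently be
reconstructed from aggregate counts (`score_table_from_counts`), which is how
the bundled published per-taxon counts are analysed. Post-hoc pairwise
contrasts compare taxon logits using the dispersion-scaled covariance; the
default family-wise adjustment is a single-step max-modulus correction whose
reference distribution is estimated from seeded Monte-Carlo draws of the
joint contrast distribution (50 000 draws by default), with Holm's step-down
as an exact fallback. Taxa never (or always) preferred lie on the boundary
of the parameter space: their logits diverge and their contrasts, while
still computed from the fitted covariance, are flagged. A compact letter
display summarises the grouping.

An incomplete-ranking analysis is deliberately not implemented: with typical
published designs offering 2-6 prey from a large taxon pool, the
experiments-x-taxa rank matrix is overwhelmingly empty. The occupancy
diagnostic (`rank_matrix_occupancy`) reproduces that screening step — such
methods need roughly half the cells filled.

The microhabitat association is a 2x2 table (predator microhabitat x
preferred-prey microhabitat) counting experiments whose preferred prey all
share one microhabitat with at least one non-preferred prey from the other;
it is tested with a one-tailed Fisher exact test for a positive
same-microhabitat association. On the bundled published table `[[10, 4], [1,
3]]` the exact hypergeometric tail is 420/3060 = 0.137.

## Synthetic data generator

The generator emulates the structure of the mirrored laboratory study: 7
prey with fixed offers per trial (6 Rana tadpoles, 6 Lymnaea, 10 Chironomus,
10 Cloeon, 10 Culex, 10 Asellus, 30 Daphnia), 13 predator stages with 5-9
replicates, and 4 predator-free control trials. Each trial draws a feeding
budget K — negative binomial by default (dispersion parameter 5, an
over-dispersed appetite; Poisson and fixed are options) with stage-specific
means from 8 to 25 prey per 24 h, chosen to scale with predator body size and
to land total consumption in the range such experiments report — then
consumes K prey sequentially, each capture picking type i with probability
proportional to `w_i * n_i(t)` among the items still alive. Background
mortality is applied afterwards as independent binomial thinning of the
survivors at the per-prey control rates (0-11.7 % per day, the measured
predator-free values), because control trials show what non-predation
mortality looks like on its own. All randomness flows through one seeded
generator; identical seeds give byte-identical fixtures.

The planted attack weights `w`, normalised, are the ground truth that
Manly's alpha estimates. Two default parameterisations exist:
`default_config`, whose weights echo the qualitative structure the mirrored
study reported (a nektonic block, medium benthic predators on Chironomus,
large benthic predators on Asellus/Chironomus/Rana, benthic odonates), and
`planted_module_config`, whose weights are exactly block-diagonal in three
modules for module-recovery tests.

**What passing tests do and do not show.** The generator targets the
statistical structure of such experiments only — no handling times,
encounter geometry, predator satiation dynamics or prey anti-predator
behaviour. Two consequences matter for interpreting results. First, Manly's
estimator assumes constant prey availability; under realistic 24 h
consumption the sequential process depletes preferred prey within a trial
and the estimated alpha is pulled toward uniformity. Recovery of the planted
weights within 3 SE is therefore asserted in a low-depletion regime (offers
inflated 2000-fold, fixed budget of 200 captures, the 13 x 5-9 design
otherwise unchanged), while at study-scale consumption the tests assert
qualitative recovery (correlation above 0.9 with the planted weights;
never-attacked prey near zero). Second, background mortality is corrected
only in expectation, so corrected consumption is noisy for prey with high
control mortality.

## Problem sizes and numerical choices

The bundled published matrices are analysed exactly as printed (2-decimal
overlaps). Synthetic analyses in the test suite and the acceptance script
use the 13-stage x 7-prey design with its configured 5-9 replicates (100
trials); module detection uses 10 restarts x 10 optimiser seeds per web in
stochastic-recovery checks and 50 restarts as the pipeline default; NMDS
uses 20-30 restarts; the max-modulus adjustment uses 50 000 Monte-Carlo
draws. Tolerances: alpha normalisation to 1e-9; the Ward/R equivalence to
1e-5; GLM coefficients against an independent Newton-scoring oracle to 1e-6;
exact hypergeometric Fisher probabilities to 1e-12. Degenerate inputs
(all-zero consumption, single-level factors, webs with a single row or
column, fewer than 3 ordination labels, m < 3 for electivity) raise explicit
errors or produce flagged trivial results rather than silent numbers.

## Known limitations

* The package ships the published summary tables, not the underlying
  per-replicate counts (released only as supplementary spreadsheets), so
  index-engine reproductions of the published overlap matrices require the
  user to supply a transcribed `trials.csv`.
* The annealing optimiser guarantees the global Q optimum only on
  enumerable webs; on larger webs it is best-of-restarts.
* Quasi-binomial inference on binary scores with boundary taxa relies on a
  finite-iteration fit; those contrasts are flagged rather than suppressed.
* NMDS stress values are implementation-specific local minima.
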