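# Methods

This note documents the statistical models, the numerical choices, and the
design decisions behind `intdelim`, and what the synthetic-data tests do and do
not establish about real data.

## Tolerance intervals

A tolerance interval differs from a confidence interval for the mean: it is an
interval expected to contain at least a proportion *P* of the *population*
(the content) with confidence 1 − α. Both families here use P = 0.95 and
confidence 0.95, the convention of the packaged study data; both are
configurable through `ToleranceConfig`.

**Normal (continuous characters).** The two-sided interval is x̄ ± k·s with the
plain Howe k₂ factor

k = z₍(1+P)/2₎ · √( (n−1)(1 + 1/n) / χ²₍α,n−1₎ ),

where χ²₍α,n−1₎ is the lower α-quantile. We use the plain k₂ form without a
small-n correction term: on the packaged meristic tables it reproduces the
published limits to one decimal in every verified cell, and a correction factor
would perturb exactly that surface. Quantiles are exact numerical inversions
(`scipy.stats`); the Wilson–Hilferty approximation is used only as a test
oracle. Meristic characters are treated as continuous at the TI stage (their
published summaries are means/SDs), consistent with the source tables.
`sd = 0` degenerates cleanly to the point interval (mean, mean).

**Gap rule.** Two taxa show a gap in a character iff their closed intervals are
disjoint; *touching endpoints count as overlap*. This is the conservative
tie-break — a shared boundary value is not evidence of discontinuity.

**Binomial (discrete characters).** For a character fixed in the observed
samples, the one-sided bound proceeds in two steps: (1) a Wilson score
confidence bound on the true proportion of the unobserved state, with z at the
confidence quantile directly (one-sided α, not α/2); (2) an exact binomial
quantile at content P under that bound, giving the count of a future sample of
size *m* that may carry the alternative state. The future-sample size *m*
defaults to the observed n of the same taxon and is configurable; published
accounts of this procedure rarely state *m*, and bounds are sensitive to it
(for x = 0, n = m = 12 the bound is 5/12 ≈ 42%). The bound is *reported* next
to each fixed difference but never vetoes a verdict: fixation is judged on the
observed samples, the bound quantifies how provisional that judgement is.

**Diagnosability.** A fixed difference requires disjoint, non-empty observed
state sets. Characters carry applicability flags (`all`, `adults-only`,
`adult-males-only`); masking happens at load time so the statistics never
re-implement stratification. With zero scored individuals in either taxon the
character is *not assessed* — deliberately distinct from "no difference".

## Climate envelope and niche statistics

**Envelope model.** The niche engine is a percentile-clamped rectilinear
envelope: per layer, score 1 inside the [q₀.₀₅, q₀.₉₅] training percentiles,
linear decay to 0 at the training min/max, 0 beyond; cell suitability is the
mean of per-layer scores. It is deterministic given the training matrix, which
makes every downstream randomization exactly reproducible. The engine sits
behind a fit/predict interface (scikit-learn protocol), so a maximum-entropy
engine could be substituted without touching the comparison statistics.
Constant training layers are widened by a machine tolerance so they score 1 at
their single value without division by zero. Because suitability is a *mean*
over layers, uninformative layers dilute contrast between taxa; niche
separation between two taxa is only strongly expressed when the separating
layers dominate the stack (the simulation studies therefore use single-layer
worlds for separation scenarios).

**Schoener's D** is computed on surfaces normalized to sum to 1 over the
intersection of the two valid-cell masks (normalization-first is required by
the formula; D on raw suitabilities is not scale-invariant).

**Identity test.** Records are deduplicated to one per raster cell per taxon
before anything else. The pooled set is the union of the two taxa's cells
(deduplicated across taxa, so a pseudo-taxon can never contain one cell twice);
each of `reps` pseudoreplicates partitions the pool at random without
replacement into sizes (|a|, pool − |a|), refits both envelopes, and records D.
The default is 100 pseudoreplicates. p = (1 + #{D_null ≤ D_obs}) / (reps + 1),
one-tailed: identity is rejected when the observed overlap is unusually *low*.
The add-one convention keeps p ≥ 1/(reps+1) and the test valid. The rejection
threshold α = 0.05 is configurable (`DecisionConfig.alpha_identity`).

**Range maps.** The binarization threshold is the mean over k = 10
deterministic contiguous folds of the minimum model suitability among that
fold's presences (folds with < 2 presences merge into the previous fold). A
single fitted model scores all folds; there is no per-fold refitting. Two taxa
are range-disjoint iff no cell is suitable in both maps.

**AUC and importance.** AUC is the rank statistic
P(score(presence) > score(background)) + ½·P(tie) over all pairs, against a
seeded background sample of 10,000 valid cells (all cells if fewer).
Variable importance permutes one layer's values across the presence +
background rows, measures the AUC drop, clips negatives at zero and normalizes
to percentages; an entirely uninformative model spreads importance evenly.

## Candidate discovery

Monophyly is evaluated on the rooted tree as supplied (no unrooted bipartition
fallback): a taxon is exclusive iff the smallest clade containing all its tips
contains no others. Single-tip taxa are trivially monophyletic and flagged.
Node labels are read as clade support, auto-detected as proportions or
percentages by whether any value exceeds 1; `min_support` (optional) filters
candidates.

## Decision rule

The verbal logic of "congruent lines of evidence in different combinations" is
formalized as: a pair is **delimited** iff (a) neither taxon is demonstrably
non-monophyletic (when `require_monophyly`, the default; a missing tree never
vetoes) and (b) at least `min_corroborating_lines` (default 1) of the three
lines hold — ≥ 1 fixed discrete difference, ≥ 1 continuous gap, identity test
rejected at α. **insufficient** means no line could be assessed at all.
The default minimum of one corroborating line reflects the "count the fixed
differences" reading of the source study; note that under this default a
niche-identity rejection *alone* can delimit a pair — a deliberate, flagged
choice, tightened by raising `min_corroborating_lines`. Corroboration counting
is monotone: additional corroborating evidence can never revoke a delimited
verdict (only a non-monophyly finding can).

## Synthetic data

The generator emulates exactly the structure the analysis assumes:
per-taxon Bernoulli state frequencies; Normal(μ, σ) continuous characters with
meristic rounding; climate layers built from a linear gradient (amplitude 10),
a sinusoidal term (amplitude 2) and N(0, 0.5) cell noise on a 25×25 grid of
0.05° cells; occurrences sampled without replacement across cells with
probability proportional to a per-taxon Gaussian suitability
∏ₗ exp(−(vₗ−optₗ)²/(2·breadthₗ²)); and balanced per-taxon clades with a
per-tip regrafting probability (`discordance`). Default taxon sizes (15
individuals per sex, 25 occurrence records, 4 tips) match the scale of the
packaged study samples. Occurrence coordinates are cell centers, making
deduplication a no-op by construction.

What the generator does **not** emulate: spatial autocorrelation beyond the
smooth gradient terms, sampling bias, measurement error, character
correlations, ontogenetic variation, or realistic coalescent genealogies.
Passing simulation tests therefore demonstrates the statistical machinery is
correct and calibrated under its own assumptions — not that those assumptions
hold for any particular empirical dataset.

## Simulation study sizes

The test suite's simulation studies use: 2,000 replicates (samples of size 20)
for TI coverage; 200 null datasets (shared niche, 3-layer world, 25 records
per taxon, 100 pseudoreplicates each) for identity-test calibration; 100
datasets with optima 6 breadths apart on a single-layer world for power; 50
random ≤ 12-tip trees against a clade-enumeration oracle; and 100 seeds of a
3-taxon world (one fixed character per pair, 8σ-separated continuous
character, separated niches, concordant tree) for end-to-end known-truth
recovery. These sizes give Monte-Carlo standard errors comfortably inside the
asserted margins while keeping the full suite fast on a single CPU.

## Known limitations and data notes

- The packaged summary tables carry the source's printed (rounded) means and
  SDs; recomputed tolerance limits can differ from the printed limits by more
  than rounding alone explains in a few cells (worst ≈ 0.4 on one upper
  limit), indicating the source computed from unrounded raw data that differ
  slightly from its printed summaries. The seven independently verified cells
  reproduce exactly.
- The source tables disagree on n for two taxa (41 vs 42; 78 vs 79 at
  different stages); the fixtures carry the tolerance-stage n in an explicit
  column, and n is never re-derived from other columns.
- Published binomial-caveat percentages for this complex (36/31/44/33%) are
  not reproducible from the documented Wilson procedure with m = n; the
  package reports its own bounds and exposes (m, one-sided α) as
  configuration.
- The individual-level discrete matrix is reconstructed from per-taxon/per-sex
  state summaries: mixed ("yes/no") cells pin state *counts* (50/50 unless a
  frequency was published, e.g. 90% for lateral-field marks in *L. walkeri*),
  not which individual carries which state. Fixed-difference and
  tolerance-bound results depend only on the counts, so this reconstruction is
  exact for every statistic the pipeline computes from it.
- The envelope model is not a maximum-entropy model; published per-study AUCs,
  variable contributions and D values obtained with a different engine are not
  comparable numbers.
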