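# Methods

## The screening model

A trial's integrity assessment is a walk over six ordered domains
(retraction, registration, ethics, authorship, plausibility of methods,
plausibility of results). Each domain yields one of three active verdicts
— *no concern*, *awaiting classification*, *exclude* — plus, in the
registration and methods-plausibility domains only, the terminal finding
that the study is not a randomized trial at all (*non_rct*). The fold over
a verdict vector is:

- first terminal verdict (exclude / non_rct) wins and truncates the walk;
  later domains are *not assessed* and can never alter the overall class;
- otherwise the study is *awaiting* if any domain is awaiting, and
  *no concern* only if all six domains raised no concern.

Non-RCT is modeled as a fourth terminal state parallel to exclusion
because the two are accounted for separately in screening reports; it
truncates identically. First-round assessors have no non-RCT category —
for agreement statistics their exclusions and the senior assessor's
non-RCT calls collapse onto the same ordinal category (see below).

### Adjudication

Two independent assessors rate every trial. A senior third assessor
re-rates domains 1–3 for every study, and domains 4–6 when the pair is
discrepant, agrees on a non-"no concern" verdict, or left fewer than two
ratings (each trigger is a policy flag; all default on). The final vector
takes the third assessor's verdict wherever they were involved and the
consistent pair verdict elsewhere, then re-applies the truncation fold.
The third assessor's ratings are represented as an *untruncated* rating
sheet (`RatingSheet`): they rate domains on demand, so their own terminal
calls do not cut their sheet short — consensus truncation is applied by
`adjudicate`, not by the sheet. If a policy disables the on-demand
triggers, domains left without any rating are reported as `unresolved` and
held as awaiting rather than guessed; the worklist (deterministically
ordered by study id then domain) exposes exactly what the senior assessor
was asked to rate.

### Author correspondence

An awaiting domain flips to no concern only when a matching query is
marked resolved and, when dates are recorded, the response arrived within
the 14-day window plus the 7-day reminder extension. Absent dates,
`resolved` alone decides — screening reports record outcomes, not always
timestamps. Unresolved or late queries leave the study awaiting. An empty
query list is the identity.

## Interrater reliability

Agreement per domain is Cohen's kappa over the ordered categories
no concern (0) < awaiting (1) < exclude (2), with linear agreement weights
w_ij = 1 − |i−j|/2 — "awaiting" is genuinely intermediate in the workflow,
so near-miss disagreements earn partial credit. A pair exists only when
both assessors actively rated the domain; single- and no-rating studies
(products of upstream truncation) are tallied separately, which is why the
number of pairs declines from domain 1 to domain 6 and later-domain kappas
are less stable.

p_o = Σ w_ij f_ij / n, p_e from the marginal products, κ_w =
(p_o − p_e)/(1 − p_e). The standard error is the large-sample
Fleiss–Cohen–Everitt variance for a single two-way table (it matches
statsmodels' `cohens_kappa(wt="linear")` exactly and a 10,000-rep
multinomial bootstrap within ~1%); a bootstrap is used only as a test
oracle. When all mass sits in one cell, chance agreement is 1 and kappa is
reported as undefined rather than silently NaN.

Interpretation bands (no agreement < 0, slight 0.00–0.20, fair 0.21–0.40,
moderate 0.41–0.60, substantial 0.61–0.80, almost perfect 0.81–1.00) are
applied after rounding κ half-away-from-zero to two decimals, because the
bands are closed two-decimal ranges with gaps; 0.205 is therefore "fair".

A monotonicity caveat: resolving one disagreement (moving a pair from an
off-diagonal cell to the diagonal) never lowers κ_w when agreement starts
at or above chance, but *can* lower it on tables with κ_w < 0 (the move
also shifts a marginal, and below chance the expected-agreement term can
grow faster than the observed one). The property test asserts the κ ≥ 0
regime only.

## Meta-analysis

Per-trial effects from 2×2 tables: RR = (a/n₁)/(c/n₂) with
SE(log RR) = √(1/a − 1/n₁ + 1/c − 1/n₂); OR = ad/bc with
SE(log OR) = √(1/a + 1/b + 1/c + 1/d). Any zero cell adds 0.5 to all four
cells (the default of the standard meta-analysis software this mirrors);
trials with zero events in both arms carry no information about a ratio
and are dropped from pooling, flagged non-contributing.

Pooling is inverse-variance: common-effect, or DerSimonian–Laird
random-effects with the moment estimator
τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)) and weights 1/(vᵢ + τ²). CIs are
Wald with z = 1.96 (no Hartung–Knapp — the headline CIs of the reviews
this models use the normal quantile), exponentiated to the ratio scale.
A single-trial "pool" returns that trial's effect with τ² = 0, because
impact tables do print one-trial rows; an empty set is *not estimable*.
The implementation matches R `metafor` (method="DL") to 1e-12 on a frozen
three-study fixture and a step-by-step oracle to 1e-10 on random sets.

The sensitivity re-analysis keeps only trials whose final classification
is no concern — awaiting trials are excluded alongside excluded/non-RCT
ones, reflecting that an unresolved integrity concern already disqualifies
a trial from the trustworthy evidence base. Network-meta-analysis rows in
the bundled summary data are carried but never re-pooled. When a review
offers several comparisons, selection is by most trials, then most
randomized participants, then lexicographic id (deterministic).

## Equivalence-range classification

Direction: a point inside the closed range [0.9, 1.11] is *no or minimal
effect*; below/above maps to benefit or harm through the outcome's
polarity (mortality: lower is benefit; clinical improvement: higher is
benefit). Precision: the 95% CI is *imprecise* iff a range boundary lies
strictly inside the open interval (ci_low, ci_high) — an endpoint exactly
on a boundary does not cross, which is what makes a CI of (0.90, 1.06)
precise. Interpretation is the (direction, precision) pair, or *not
estimable*. CIs are classified at full parsed precision; no rounding. The
change report between original and sensitivity classifications flags
direction, precision, interpretation and became-not-estimable; the
interpretation flag is exactly the disjunction of the others.

The configured range must satisfy low < high; a truly degenerate range is
rejected, and the "everything off the boundary is directional" limit is
exercised with an epsilon-width range in tests.

## Corpus summaries

Medians use the midpoint convention; quartiles default to linear
interpolation (numpy type 7) and are configurable, because printed IQRs in
this literature rarely pin the convention down — medians, which are
convention-robust, are the compared quantities. Percentages print to one
decimal, rounded half away from zero. The per-review unit of analysis is
one row per (review, intervention) — 26 rows for the bundled corpus —
since that is the granularity of the published impact table; reviews
covering two interventions contribute two rows. Times are seconds
internally, h:mm:ss only at presentation; a tier total is the sum of its
six domain means and is flagged partial when a domain is missing. The
record-filter ledger conserves counts exactly and refuses negative pools.

Two documented artifacts of the published summaries: the expert
assessment-time column sums to 20:52 while the printed total is 20:51
(rounding of the printed per-domain means), and the fail-stratum high-RoB
percentage computes to 21.3 from the reconstructed counts (19/89) against
a printed 21.4. Both are flagged in `datasets`, not asserted equal.

## Synthetic corpus generator

The generator emulates the structure of a 206-trial, 23-review COVID-19
drug-trial screening corpus; all defaults live in the versioned
`data/calibration.yaml`.

- **Reviews and trials.** 23 reviews (56.5% Cochrane-type), trial counts
  negative-binomial (mean 10.3, dispersion 3, min 3), arm sizes lognormal
  with median ~80/arm so trial sizes center near 160 randomized
  participants with an IQR spanning roughly 78–506.
- **Outcomes.** Binomial 2×2 mortality-like outcomes, control risk 0.25,
  per-review true log risk ratio (default log 0.9).
- **Integrity ground truth.** Per-domain issue rates conditional on
  reaching the domain (e.g. registration: 25.8% exclude-level, 5.05%
  non-RCT, 14.1% awaiting-level; ethics: 45.3% awaiting-level). Terminal
  issues are independent across domains. Awaiting-level issues are *not*
  independent: a latent two-class documentation-quality mixture makes 37%
  of trials "well-documented" (no awaiting-level issues anywhere) and
  concentrates each domain's rate on the rest, inflated by 1/(1 − 0.37).
  This preserves every per-domain marginal rate while reproducing the
  observed overall mix (~28% no concern / 38% awaiting / 29% exclude / 5%
  non-RCT analytically); fully independent awaiting issues would drive
  no-concern down to ~17%, which real corpora do not show — documentation
  problems cluster within trials.
- **Assessors.** Each tier has a 3×3 row-stochastic confusion matrix
  P(rated | true collapsed category). Beginners shift mass from no-concern
  toward awaiting (over-flagging), the senior profile is near-exact. First
  and second assessors walk hierarchically and stop at their own terminal
  verdict; the senior assessor's sheet is untruncated (see Adjudication).
  The magnitudes are free parameters of the generator, not estimates.
- **RoB labels** are drawn independently of integrity truth (0.33 / 0.45 /
  0.22 low / some concerns / high) — the screen and risk-of-bias measure
  different things, and the generator encodes no association.
- **Time logs** are lognormal per (tier, domain) with means set to the
  published per-domain means and shape σ = 0.4.
- **Determinism.** Every review/trial/assessor stream is seeded via
  `SeedSequence(seed, spawn_key=(review, trial, stream))`: one seed gives a
  bit-identical corpus, and appending reviews never perturbs earlier ones.

What the generator does **not** emulate: correlation between trial size
and integrity status, non-mortality outcome structures, per-assessor
drift/learning over time, free-text correspondence, or any
fraud-generating data mechanism. Tests passing on synthetic corpora
therefore validate the pipeline's logic and statistical calibration, not
the real-world prevalence of integrity problems.

## Problem sizes used in tests and the acceptance script

Statistical checks run at sizes chosen to make Monte-Carlo tolerances
meaningful while keeping the suite quick: ~5,000 trials for calibration
and kappa-recovery checks (3 SE tolerances), 500 replicate 30-trial
meta-analyses for DL coverage (≥ 93% against nominal 95%), 1,000 random
3×3 tables and 300 random ≤ 10-study sets for the exact-oracle
comparisons. The acceptance script re-derives the published-corpus
quantities from the bundled 26-row summary and the simulation quantities
from a freshly generated default corpus at the given seed.

## Known limitations

- The workflow models decisions at domain level; the signaling questions
  inside each domain are out of scope.
- Only RR/OR with common-effect or DL pooling are implemented; no network
  meta-analysis, Peto OR, Hartung–Knapp, prediction intervals, or
  continuous outcomes.
- The asymptotic kappa SE is a large-sample approximation; for the small
  late-domain pair counts typical of truncating workflows it is noisy
  (the generator's corpora show this too).
- Per-domain agreement between assessors arises in the generator only
  through shared truth; real assessors also share heuristics, which can
  push observed agreement above the conditional-independence prediction.
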