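# Methods

## Models

All models predict, per design cell (set size `N_i` × base-rate condition
`j`), a hit probability and a false-alarm probability for a single-probe
change-detection judgment.

**All-or-none family.** The probe is in memory with probability
`m = min(K/N_i, 1)` (capacity `K` is a continuous free parameter; the `min`
clamps over-capacity, since `K/N` enters the equations as a probability);
an unstored probe elicits a guess "change" with rate `g_j`. The *principled*
variant multiplies in an attention-lapse probability `a`: with probability
`1 − a` nothing is encoded and responses are pure guesses. Setting `a = 1`
recovers the standard model; letting `K_i` vary per load gives the
free-capacity variant. All variants predict linear, slope-1 ROCs:
`p(hit) − p(fa) = a·m` independently of `g`.

**Equal-variance SDT family.** Memory strength is `N(d′_i, 1)` on change
trials, `N(0, 1)` on no-change trials. Two decision rules are implemented:

* *likelihood ratio* — respond "change" when the density ratio exceeds
  `β_j`, giving `p(hit) = Φ(d′/2 − ln β/d′)`, `p(fa) = Φ(−d′/2 − ln β/d′)`.
  The rule is undefined at `d′ = 0` (the likelihood ratio is flat); this is
  raised as an error rather than silently patched, and the fitting bounds
  keep `d′ ≥ 10⁻³`.
* *strength* — respond "change" when the observed strength exceeds a
  criterion `c`: `p(hit) = Φ(d′ − c)`, `p(fa) = Φ(−c)`. The two rules trace
  the same ROC: `c = d′/2 + ln β / d′` maps one onto the other exactly,
  but they differ in what "criteria shared across load" means, which is why
  both are exposed. The conventional criterion-on-strength form is used for
  the strength rule; the enumerated default space uses the likelihood-ratio
  rule, with strength selectable.

The *principled* SDT variant constrains resources across load by a power
law, `d′(N) = d′·N^(−α)`.

**Factorial space and matched pairs.** Crossing memory constraint
(fixed / free / principled) with criterion constraint (shared per base-rate
condition / free per cell) gives six variants per family, twelve in all.
"Shared across load" means one criterion per base-rate condition reused at
every set size. Variants are paired across families with identical
constraints (lapse pairs with power law), which makes parameter counts equal
— memory: 1 fixed, S free, 2 principled; criteria: J shared, S·J free — so
matched pairs can be compared on raw likelihood. For a single-set-size
design the three memory constraints are mutually unidentifiable and collapse
to "fixed", leaving four labelled variants (the criterion distinction is
kept as a label even though shared and free coincide at S = 1).

## Fitting

Each cell contributes two independent binomials (hits of change trials,
false alarms of no-change trials). The NLL omits binomial coefficients —
constant across models on the same data — and predicted rates are clamped to
`[10⁻⁶, 1 − 10⁻⁶]` before logs (the all-or-none family predicts `p(fa) = 0`
at `K ≥ N`, which would otherwise make the likelihood degenerate).

Estimation is L-BFGS-B with analytic gradients (chain rule through each
family's rate equations; clamped rates get zero gradient), multiple
restarts, bounds: `K ∈ [0, max N]`, `a ∈ [0, 1]`, `g ∈ [10⁻⁴, 1 − 10⁻⁴]`,
`d′ ∈ [10⁻³, 10]` (optimized on the log scale), `α ∈ [0, 3]`,
`ln β ∈ [−10, 10]`, `c ∈ [−10, 10]`. The first start is a moment estimate
from smoothed observed rates (inverse-normal transforms for SDT, rate
differences for all-or-none); the remaining starts are uniform draws from a
central start box (`ln β ∈ [−3, 3]`, `d′ ∈ [0.2, 5]`, `g ∈ [0.05, 0.95]`,
…) rather than the full bounded box, because extreme parameter regions push
every rate onto the clamp where the likelihood is flat and a local optimizer
cannot move. With this policy the 18-parameter free-criterion models reach
the same optimum as 60-restart runs in the cases we checked. Default: 20
restarts for data fits, 10 for refits inside recovery (both configurable);
fits are deterministic given `(spec, data, n_restarts, seed)`.

## Comparison and inference

`AIC = 2k + 2·NLL`; `BIC = k·ln(n) + 2·NLL` with `n` the participant's total
Bernoulli trial count (the standard reading; no other convention is
implied by the likelihood). Raw-NLL comparison is allowed only for
equal-`k` pairs, where AIC/BIC/NLL rankings coincide. Ties are declared at
`|Δ| ≤ 10⁻⁹`. Cohort-level inference is a two-sided one-sample t test of
per-participant metric differences against zero at α = 0.05; zero-variance
samples are decided by sign (p reported as 0, or 1 when all differences are
zero). Summed evidence, per-participant winners, and the t test are all
reported, since each supports a different reading of "which model won".

## Model recovery and the audit gate

For each participant, `n_sims` datasets are simulated from a generative
model at that participant's fitted parameters and original trial counts;
every candidate is refit to each simulated dataset and the winner per metric
is the lowest value, ties split equally (the per-simulation winner is
decided per participant, not pooled). Refit seeds derive from a content hash
of the model spec, so an identical competitor reproduces the generative fit
exactly and self-recovery is 0.5 by construction. The bias test is a paired
t test of `p_rec(A as generative) − p_rec(B as generative)` across
participants: a significantly positive mean means the metric is biased
toward A.

The pipeline enforces audit-then-infer structurally: any comparison whose
metric fails its bias audit is flagged non-diagnostic and its winner is
withheld in every table and narrative. A metric that cannot recover the
generating model in simulation cannot be used to pick winners in data.

## Synthetic cohorts

Presets reproduce the structure of the classic designs — `rouder08`
(3 base rates × set sizes {2, 5, 8}, 60 trials/cell, 23 participants),
`donkin_e1` (same grid, 91 participants), `donkin_e2` (5 base rates
{0.1, …, 0.9} × 3 set sizes, 140 trials/cell = 2,100 trials per participant,
10 participants), `donkin_e3` (5 base rates at a single set size,
300 trials/cell, 20 participants). The published sources do not print exact
base-rate levels, set sizes, or per-cell trial counts, so these numeric
values are documented, configurable defaults chosen to be representative,
not reconstructions. Change trials per cell are `round(rate × trials)`.

Participant heterogeneity is modelled as independent truncated-normal draws
per parameter (truncated at the fitting bounds; SD 0 yields the mean
exactly) — the simplest structure supporting per-participant fitting and
paired t tests. Default population means: `K = 3` (SD 0.5), `a = 0.9`
(SD 0.05), guessing rates equal to the base rates (probability matching,
SD 0.05), `d′` falling from 2.5 to 1.0 across set sizes {2, 5, 8}
(SD 0.2; other grids follow a power-law profile `3.95·N^(−0.66)` through
those values), `ln β` at the base-rate-optimal `ln((1 − r)/r)` (SD 0.3),
`α = 0.6` (SD 0.1). Counts are binomial draws from the generative model, so
generated datasets always satisfy the data-model invariants.

What the generator does *not* emulate: sequential and block effects,
learning or fatigue, lapses correlated across cells, non-Gaussian
individual differences, and any departure of real observers from the fitted
model class. Passing recovery and bias checks on these cohorts therefore
demonstrates properties of the *method* under the stated designs, not that
real data are this well behaved.

## Problem sizes for the reproduction checks

The stochastic checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` use cohorts of 10 participants: parameter recovery
at 5,000 trials/cell; BIC-bias reproduction at the `rouder08` scale with
25 recovery simulations per participant; matched-pair fairness at the
`donkin_e2` scale with 16 simulations per pair and generative role;
audit-gated inference at the same scale with 12 simulations, with 5 refit
restarts inside recovery. These sizes were fixed once as representative of
the scaled-down designs and give runtimes of a few minutes on one CPU.

## Numerical and design notes

* Guessing rates `g_j` are always free parameters; they are not pinned to
  the nominal base rates when fitting.
* Criteria are keyed by base-rate condition index, not the numeric rate;
  the numeric rate is metadata.
* Empirical ROC points are exact count ratios — no 1/(2n) correction; rate
  extremes are handled inside the likelihood clamp instead, keeping the
  descriptive ROC faithful to the raw data.
* The `min(K/N, 1)` kink leaves a one-sided derivative at `K = N`; L-BFGS-B
  treats the over-capacity region as zero-gradient in `K`, which is the
  correct subgradient on that face.
* At very high trial counts a genuine small asymmetry can appear in the
  free-criterion matched pair: with generating all-or-none parameters
  obtained by fitting near-curvilinear data, the SDT form occasionally beats
  the all-or-none model on its own simulated data (verified not to be an
  optimizer failure). This is the functional-form flexibility that
  parameter-count penalties cannot see, and it is the kind of effect the
  recovery audit exists to catch.

## Known limitations

* Only equal-variance Gaussian SDT; no unequal-variance, mixture, or
  dual-process variants, and no confidence-rating ROCs.
* No hierarchical/Bayesian estimation and no standard errors on parameters;
  inference is cohort-level via paired t tests, mirroring the analytic
  tradition the package re-examines.
* Recovery defaults examine one model pair at a time; full confusion
  matrices across all twelve variants are possible via `RecoverySpec` but
  are not the standard report.
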