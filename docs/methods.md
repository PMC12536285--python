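# Methods

This note documents the scientific and numerical choices behind `decadd`:
the taxonomy's decision rules, the stimulus-generation constraints, the
generative behaviour model, the measurement conventions, and the
statistical machinery — with the reasoning for each choice that was
genuinely open.

## Taxonomy

Single-addend steps `Au + a` (`a ∈ 1…9`) are classified by the unit digit
`u = Au mod 10` and the unit sum `u + a` (post-complement `u = 0`;
sub/complement/supercomplement by `u + a` below / at / above 10).  The
classification depends only on `u`, so augends of any size are handled by
reduction mod 10.  The base is an internal constant (`taxonomy.BASE = 10`);
only base 10 is exercised.

Dual-addend steps `Au + a1 + a2` are classified by a cascade over the
decade relations of `u+a1`, `u+a2`, `a1+a2` and the total:

1. round augend (`u = 0`) → types 1/2/3 by `a1+a2` (<, =, > 10);
2. any pairwise sum equal to 10 → type 6, subtypes by *which* sums hit 10
   with precedence 6d (`u+a1` and the pair) > 6e (`u+a2` and the pair) >
   6a (`u+a1`) > 6b (`u+a2`) > 6c (the pair only);
3. otherwise types 4/5/7/8/9 by the total (<10, =10, 11–19, =20, >20).

The cascade is proven equivalent, by exhaustive enumeration over all 900
single and 720 dual cases, to an independent evaluation of the defining
feature columns (tests).  Degenerate inputs with `a1 = a2` (never generated
— adjacent repetition is forbidden — but classifiable) follow the same
cascade; the only doubly-complementing equal-addend case (`u = 5`,
`a1 = a2 = 5`) collapses onto the direct subtype 6a, so 6d/6e always imply
distinct addends.

`optimal_sequences` enumerates the three evaluation plans (linear,
commuted, associative).  The associative plan's first step combines the
two addends (typed as a single addition `a1 + a2`, so an exact pair is a
complement-class step) and its second step adds the combined addend to
the augend, where adding an exact multiple of 10 is treated as a pure
decade increment (post-complement class).  Plans are ranked by (i) the
number of facilitative steps (post-complements + complements) they
induce, then (ii) the summed difficulty weight of their steps using the
empirical single-addend latency ordering `[-] 638 < [=] 823 < [<] 935 <
[>] 1298` ms, with the deterministic tie-break linear → commuted →
associative.  The tie-break keeps the linear order whenever reordering
buys nothing, which is the behaviourally conservative assumption.

## Stimulus generation

Lists are uniform random digit sequences (1–9, no adjacent repetitions)
accepted by rejection against the list-type constraints, which keeps the
conditional distribution uniform over the valid lists of each type.
Acceptance rates for the tightest specs are ~2–8%, so no constructive
search is needed; a `max_attempts` bound (200,000) turns an unsatisfiable
spec into an explicit `GenerationError`.

Constraints per type:

- single-addend task: lengths 4–6; exactly 0 / 1 / 2 complement steps
  along the running total.  Forbidding complements automatically forbids
  post-complements on non-initial steps: a supercomplement leaves a
  non-round total, so a round running total can only arise from a
  complement.
- dual-addend task: lengths 8/10/12 (even — consumed pairwise from an
  initial total of zero); "no" lists have every pairwise sum off 10
  (no overt complements, no pairs), "some" have exactly one overt
  complement and one pair, "many" have at least three overt opportunities
  in total.  *Covert* complements (totals reaching a decade only after
  combining both addends, types 2/5/8) are counted but never forbidden —
  one of the published example lists for the "many" condition itself
  contains one, so the conditions cannot be defined by their absence.

The exact per-type length and sum windows used in the original materials
are not published.  The defaults here were chosen by calibrating the
generator against the published per-type summary tables (mean elements
4.92/5.06/5.23 and sums 24.5/25.1/25.7 in the single-addend task;
9.79/10.03/10.26 and 49.5/50.2/51.3 in the dual task): nominal length
weights and sum windows were tuned, on generator output alone, so the
*realized* means (after rejection tilts the conditional length
distribution) approximate those values and increase slightly with the
number of facilitators.  This bias direction is deliberate — it matches
the original design logic that complement-rich lists must not be shorter
or smaller, so a facilitation effect cannot be a problem-size artifact.
All windows are plain `ListSpec` fields and can be reconfigured.

## Generative behaviour model

One participant adds a 30-list set in a random order; lists with a
miscalculation or a late entry return to the back of the queue with an
incremented presentation index until added correctly (as in the original
procedure, where the repetition was invisible to participants).

Step latency is `base[type] + slope·size + u_p`, multiplied by lognormal
noise with unit mean and coefficient of variation `residual_cv`; the
lognormal gives the right-skewed, strictly positive shape typical of
response times, and the multiplicative form preserves the mean so the
noise-free identity `E[latency] = base + slope·size + u_p` holds exactly.
`u_p ~ N(0, participant_sd²)` is drawn once per participant.

Defaults (per-type values ordered POST/COMP/SUB/SUPER):

| parameter | default | rationale |
|---|---|---|
| `base_latency` (ms) | 638 / 823 / 935 / 1298 | the empirical single-addend type means |
| `addend_slope` (ms per unit) | 40 | a problem-size slope of the order of the within-type spread; the size covariate is centred (addend − 5, or (addend-sum − 10)/2 per executed sub-step) so type means stay at their bases |
| `participant_sd` (ms) | 150 | typical adult between-participant RT spread |
| `residual_cv` | 0.25 | typical trial-level RT noise; yields ~0.5–2% upper-3SD exclusions, the order observed empirically |
| `error_hazard` | .005 / .01 / .04 / .08 | per-addition miscalculation; compounds to first-presentation list error rates of roughly 20%/14%/4% across the three single-addend list types, near the observed gradient |
| `late_prob` | 0.02 | entry exceeding the 2-s limit; its own hazard, independent of miscalculation |
| `strategy_prob` | 0.9 | probability of executing the top-ranked evaluation plan in the dual task; high, because indirect complements were observed to be only marginally slower than direct ones |
| `search_cost` (ms) | 100 | surcharge for executing a non-linear plan |

Miscalculation is modelled per addition but observed only per list (the
paradigm never reveals which step failed).  The result-entry interval is
drawn separately (`entry_latency` = 900 ms default) and recorded in its
own column, so list latency can be computed with or without it; lateness
is a Bernoulli flag rather than a tail event of the entry distribution,
which keeps the two measurement conventions cleanly separable.

In the dual task the executed plan's two single steps are simulated
individually (each with its own noise and hazard), so the strategy
diagnostic *emerges* rather than being scripted: with `strategy_prob = 1`
an indirect complement is executed as complement-then-post-complement and
its mean latency sits `search_cost` above the direct complement's; with
`strategy_prob = 0` it is executed linearly (sub- then supercomplement)
and becomes indistinguishable from a plain type-7 supercomplement.

What the generator does *not* emulate: learning or fatigue across trials,
memory-decay errors (hazards are latency-independent), keystroke-level
motor variance, and any within-participant variation in strategy use.  In
particular, the two sub-steps of a dual addition are priced independently,
so simulated round-augend pairs (types 1–3) are not the fastest category
at the pair level as they are empirically.  Passing tests therefore
certify the pipeline's statistical machinery under a known generative
process, not the psychological completeness of that process.

## Measurement

Accuracy: proportion of genuine errors among first presentations, with
late entries removed from numerator and denominator (they are neither
correct nor miscalculations).  Latency: correctly added, on-time lists
only.  Outlier screening excludes values exceeding the overall mean by
more than 3 SD (ddof = 1), computed once, not iteratively; it is
one-sided by default because the rule targets slow lapses and the
paradigm produces no implausibly fast responses — a two-sided variant is
a config flag.  Empty cells are reported as missing, never as zero.

## Inference

- **Accuracy**: logistic random-intercept model fitted by maximum
  likelihood with 21-node Gauss–Hermite quadrature (written in-house;
  validated to 3–4 decimals against `lme4::glmer` with `nAGQ = 25` in the
  test suite).  Zero-variance outcomes raise a structured
  `DegenerateDataError`; optimizer failures raise `ConvergenceError` with
  diagnostics (a gradient-flatness tolerance of 1.0 on the negative
  log-likelihood absorbs the numerical-gradient precision-loss reports
  that BFGS emits at genuine optima).
- **Latency**: `statsmodels` `MixedLM`, REML by default — with ~21
  participants the ML random-variance estimate is biased low and its
  Wald intervals undercover, which REML corrects; likelihood-ratio
  comparisons refit by ML.  Marginal means are evaluated at the sample
  mean of any covariate; their 95% intervals use a t distribution with
  `n_groups − 1` df (the between-participant level at which a mean is
  estimated).  A single-participant fit warns and reports a ~0 random
  variance.
- **Contrasts**: all pairwise level differences, Tukey studentized-range
  adjustment (`k` = number of levels; residual df `n − k_fixed −
  n_groups` for linear models, the normal limit for logistic Wald
  contrasts).  Logistic contrasts report odds ratios; latency contrasts
  report partial eta-squared as `t²/(t² + df)` — the standard conversion,
  used because no formula is canonical for mixed-model contrasts.
- **Model comparison**: likelihood-ratio χ² between ML fits of nested
  fixed-effect structures on identical rows, df = difference in fixed
  parameters; refuses non-nested requests.  Incremental pseudo-R² is by
  default the increase in *marginal* R² — `var(Xβ) / (var(Xβ) + σ²_u +
  σ²_e)`, with `π²/3` as the latent residual for the logistic family — a
  variant chosen because it isolates the fixed factor's share of variance;
  a likelihood-based (Cox–Snell) alternative is reported alongside since
  the choice is not identifiable from summary statistics alone.

## Test design notes

- The null-calibration check equalizes base latencies and hazards *and*
  fixes a single list length with a common sum window across list types:
  the default specs deliberately confound list type with length, so they
  are not a null for list-level outcomes.  Family-wise rejection rates
  between 0.01 and 0.12 are accepted at nominal α = 0.05: Wald-based
  contrast families with 21 participants and a boundary random variance
  run mildly liberal.
- The parameter-recovery check fits the latency model on correct
  additions *without* outlier screening: the one-sided 3-SD screen trims
  the genuine lognormal tail (~0.5–3% of the slowest type) and would
  bias its recovered mean by ~2% — a property of the screen, not of the
  estimator under test.
- Problem sizes: simulations use the experiment's own scale (21
  participants × 30 lists); replication counts are 100 (recovery
  coverage) and 200 (null calibration).

## Limitations

- The exact appendix-level stimulus constraints of the original materials
  are re-derived, not transcribed; the generator matches the published
  set-level summaries, not necessarily the original sampler.
- Exact replication of the deposited raw data requires downloading it
  (see the `replicate` command and the schema-map adapter); printed model
  coefficients (ORs, χ², pseudo-R²) are expected to match in direction
  and significance only, as estimator variants differ across software.
- No subtraction, no bases other than 10, no process-level model of
  retrieval vs counting.
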