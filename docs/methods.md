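# Methods

## Problem setting

Spontaneous-report databases such as the FDA Adverse Event Reporting
System (FAERS) collect voluntarily submitted case reports of suspected
drug–event associations. There is no denominator of exposed patients, so
risk cannot be estimated; instead, *disproportionality analysis* asks
whether a (drug, event) pair is reported more often than expected given
the drug's and event's overall reporting frequencies. faersig implements
that analysis for a single target drug against the background of all
other reports, at MedDRA preferred-term (PT) and system-organ-class (SOC)
level, together with the ingestion and case-processing steps that the
statistics depend on.

## Counting model

The unit of counting is the deduplicated report (case). For an event `e`
the 2×2 table is: `a` = cases whose primary-suspect (PS) drug matches the
target synonym set and that mention `e`; `b` = PS-target cases without
`e`; `c` = other cases with `e`; `d` = the remainder. A case contributes
at most once per cell: duplicate PT rows within a case are collapsed, and
at SOC level a case counts once per SOC even if several of its PTs map
there. Consequently `a+b` (PS-target cases) and `n` (all cases) are
constant across events at a given level, while a single case can appear
in `a` for several SOCs. The comparator is all other reports in the
corpus, not a restricted drug class.

## Disproportionality estimators

*ROR and PRR* are the frequentist estimators defined in the README, with
log-scale Wald intervals. Zero cells leave them undefined; the package
returns NaN rather than silently adding a Haldane ½ correction (available
behind an explicit `haldane=True` flag), because the `a ≥ 3` signal gate
makes zero-cell pairs irrelevant and silent corrections distort CIs. The
χ² statistic uses the Yates continuity correction with the correction
term floored at zero.

*BCPNN.* The information component is computed in closed form from the
table and the prior hyperparameters `α₁ = β₁ = 1`, `α = β = 2`,
`γ₁₁ = 1`, with the coupling prior
`γ = γ₁₁(C+α)(C+β)/((Cx+α₁)(Cy+β₁))` evaluated first (`C = n`,
`Cx = a+b`, `Cy = a+c`, `Cxy = a`). These defaults center `E(IC)` at
exactly 0 for an empty table. The reported lower bound `IC025` is
`E(IC) − 2√V(IC)` — a mean-minus-two-standard-deviations bound, not a
posterior 2.5% quantile; the two differ slightly for small counts.

*MGPS/EBGM.* The expected count is `E = (a+b)(a+c)/n`. The relative
reporting ratio λ gets a two-component gamma mixture prior
`P·Gamma(α₁,β₁) + (1−P)·Gamma(α₂,β₂)` (shape/rate), shared across all
tables of a corpus. Given `a ~ Poisson(λE)` the posterior is again a
two-component gamma mixture; `EBGM = 2^{E[log₂ λ]}` uses the digamma
closed form per component, and `EBGM05` is found by root-finding on the
mixture CDF (Brent, tolerance 1e−10). By default the five
hyperparameters are fitted by maximizing the product of
negative-binomial-mixture marginals with a deterministic quasi-Newton
(L-BFGS-B) on log/logit-transformed parameters from the conventional
start `(0.2, 0.1, 2, 4, 1/3)`; there is no randomness in the fit. A
corpus in which every `a` is zero cannot identify the prior and raises
an error advising a fixed prior. Stratified expected counts and
multiple-testing adjustment are out of scope.

*Signal criteria.* `ror_signal`: `a ≥ 3 ∧ ROR ≥ 2 ∧ CI_low > 1`;
`prr_signal`: `a ≥ 3 ∧ PRR ≥ 2 ∧ χ² ≥ 4`; `bcpnn_signal`:
`a ≥ 3 ∧ IC−2SD > 0`; `ebgm_signal`: `a ≥ 3 ∧ EBGM05 > 2`. The ROR/PRR
cuts are inclusive and the bound cuts strict, matching how the
conventions are written. The EBGM05 > 2 cut is the customary one and is
overridable, since published analyses often print EBGM05 without a
criterion. No single combined rule is canonical, so both the conjunction
(`all_of`) and disjunction (`any_of`) of the four flags are exported.
Ranking is by descending EBGM with ties broken by larger `a`, then label.

## Ingestion and case processing

Quarterly files are `$`-delimited ASCII with one header line
(`DEMOyyQq.txt`, `DRUGyyQq.txt`, `REACyyQq.txt`, `OUTCyyQq.txt`,
`RPSRyyQq.txt`, `THERyyQq.txt`); the missing token is the empty field.
Rows with the wrong field count are logged and skipped; parsing fails if
they exceed 1% (configurable). Ages are normalized to years via the unit
codes YR/DEC/MON/WK/DY/HR, weights to kilograms; unparseable values
become missing.

*Deduplication* keeps, per `caseid`, the row maximizing
`(caseversion, fda_dt, primaryid)` lexicographically — the latest
version, ties broken by receipt date then identifier. Public corpora
rarely document their exact collapse rule; this one is the common
practice and is exactly testable. Output order is sorted by caseid, and
the operation is idempotent.

*Primary-suspect filtering* matches normalized drug names (uppercased,
trimmed, inner whitespace collapsed) exactly against a synonym set —
reproducibility is preferred over recall, so no fuzzy matching.

*Time to onset* is event date minus earliest therapy start date in whole
days; negative intervals are implausible and become missing (counted and
logged) rather than clamped to zero, so they cannot inflate the
first-week onset bucket.

*PT→SOC mapping* uses a two-column CSV surrogate `(pt, soc, is_primary)`
because MedDRA itself is licensed. Each PT must have exactly one primary
SOC; the default aggregation policy uses only the primary SOC so that
SOC-level counts partition PT-level counts per case. Unmapped terms go
to an `UNMAPPED` sentinel with a warning.

## Descriptive summaries

Categorical blocks report `count (percent)` with the denominator equal
to the sum of the displayed categories; an explicit Unknown row is shown
where convention displays one (age, weight, reporter, onset bands).
Percentages are computed in exact decimal arithmetic and rounded
*half-up* to two decimals, which reproduces published tables of this
kind cell-for-cell. Band boundaries are lower-inclusive/upper-exclusive
(age 45.0 → "45–65", onset day 7 → "7–28") since printed band labels
overlap at their edges. Outcome blocks count outcome entries rather than
cases (a case may carry several outcomes). Quartiles use linear
interpolation between order statistics (type-7), missing values
excluded.

## Synthetic report generator

The generator emulates the structure of FAERS quarterly data with a
fully known generative model so that every downstream stage has an exact
oracle.

Per report: drug mentions are independent Bernoulli draws (default 25
drugs at prevalence 0.05; empty reports get one forced mention), one
mentioned drug is uniformly designated PS and the rest get SS/C/I roles;
events are independent Bernoulli draws per PT (default 40 events at base
rate 0.04, i.e. 1.6 reactions per case in expectation), with an injected
association multiplying the paired event's rate by a configurable
relative risk when — and only when — the paired drug is PS, mirroring the
primary-suspect inclusion rule. Reports with no event are redrawn, so
the emitted corpus is the model conditioned on ≥ 1 reaction per case;
`analytic_odds_ratio` accounts for this conditioning exactly, giving a
closed-form target for calibration tests. The per-event Bernoulli design
was chosen over drawing a per-case reaction count precisely because it
keeps that odds ratio in closed form; the expected reaction multiplicity
is matched through the base rates instead.

Duplicate case versions re-emit a case with version 2, a later receipt
date and a new primaryid, perturbing nothing else, so deduplication
correctness is exactly testable. Missingness is applied per field at
observation time; the ground-truth ledger keeps unmasked values.
Demographic marginals default to the profile of a published ketorolac
case series (68% female, median age ≈ 51, consumer-heavy reporting,
US-dominant geography, ~73% of onsets within 7 days with day 0 the
modal onset day); all are configurable and validated to sum to 1.
A single top-level seed drives six derived substreams, making output
byte-identical across runs.

What the generator does **not** emulate: free-text drug names and
indications, masking/competition bias between drugs, correlated event
co-occurrence, reporting trends over time, or legacy pre-2012 file
layouts. Passing the pipeline tests therefore demonstrates correctness
of the machinery under a clean independence model, not performance on
real FAERS idiosyncrasies.

## Problem sizes and numerical choices

The replicate-based recovery check uses 20 seeded simulations of 100,000
reports each — large enough that an injected relative risk of 10 on a
1-in-25 drug is unambiguous, small enough to run in about a minute.
Statistical oracles use exact rational arithmetic (BCPNN) and direct
numerical integration of the unnormalized posterior (EBGM), never the
implementation's own closed forms. Root-finding tolerances are 1e−10
(EBGM05); the BCPNN agreement tolerance is 1e−12 absolute; EBGM vs
quadrature 1e−6 relative.

## Known limitations

- Crude (unstratified) disproportionality only; confounding by age, sex
  or calendar time is not adjusted for.
- The EBGM prior fit is a local optimum from a fixed start; with few
  tables or extreme outliers the mixture can be weakly identified
  (likelihood dominance over the generating parameters is what is
  guaranteed and tested).
- Percentages and flags are computed per corpus; cross-quarter
  accumulation must be done by concatenating quarters before ingestion.
- Signals are statistical associations over a biased reporting stream;
  they generate hypotheses and establish no causality or incidence.
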