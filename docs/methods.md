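# Methods

## Model structure

The model is a non-recursive decision tree over an in-hospital time horizon
(two to three days after cesarean delivery; no discounting). For each
strategy — no prophylaxis, intermittent pneumatic compression (IPC),
low-molecular-weight heparin (LMWH) — a patient passes:

1. **Intraoperative chance node**: spinal-anesthesia hypotension with
   probability `p_hypo`, adding management cost `c_hypo`. Hypotension is an
   intermediate event: it contributes cost but is never counted against
   effectiveness.
2. **Postoperative chance node** (mutually exclusive): DVT with `p_dvt`,
   minor bleed with `p_minor`, major bleed with `p_major`, and "no adverse
   event" as the additive complement `1 − p_dvt − p_minor − p_major`. The
   DVT branch splits by the conditional PE probability `p_pe_given_dvt`; the
   DVT-with-PE pathway accrues `c_dvt + c_pe` because PE care is incremental
   to the DVT it evolved from.

That yields 10 terminal pathways per strategy (2 intraoperative × 5
postoperative outcomes). Expected cost and effectiveness are
probability-weighted sums over pathways; effectiveness pays 1 exactly on the
no-adverse-event pathways, so expected effectiveness is the probability of
avoiding every VTE-related adverse event. Intraoperative and postoperative
events are modelled as independent (no joint distribution is available).

Mortality (`p_mortality` = 0.0026) is attached as PE case fatality and
reported only as a secondary expected-deaths output
(`p_dvt × p_pe|dvt × p_mortality`); death pathways accrue no extra cost and
do not alter effectiveness, consistent with defining effectiveness purely as
adverse-event avoidance and assuming zero non-adverse-event mortality over
the short horizon.

## Strategy effects

Relative risks map the no-prophylaxis baselines onto the active strategies:

| strategy | DVT | minor bleed | major bleed | hypotension | prophylaxis cost |
|---|---|---|---|---|---|
| no prophylaxis | 0.007 | 0.068 | 0.014 | 0.6629 | 0 |
| LMWH | ×0.33 | ×2.12 | ×1.48 | baseline | R$50 |
| IPC | ×0.33×0.87 | baseline | baseline | ×0.36 | R$102 |

No direct IPC-versus-no-treatment relative risk exists in the inputs, so the
IPC DVT effect is the transitive composition through LMWH (baseline × RR of
LMWH vs none × RR of IPC vs LMWH). The RR labelled "IPC versus LMWH on DVT
or PE" is applied to the DVT probability only; since PE arises solely via
DVT, the PE pathway scales proportionally. Every probability × RR product is
clamped at 1. The conditional PE probability is strategy-invariant.

The IPC phase variants alter effects, not the device cost: `intra_only`
keeps the hypotension reduction but leaves DVT at baseline (no postoperative
protection); `post_only` keeps the DVT reduction but leaves hypotension at
baseline.

## Parameters

Probabilities are fractions in [0, 1] (published percentages converted
once); costs are 2021 Brazilian Real; relative risks unitless. Published
ranges are read as 95% uncertainty intervals — the standard convention of
the source meta-analyses. Where the sources give no variance (mortality,
hypotension incidence, minor/major bleed costs, LMWH and IPC unit costs) a
±10% interval around the point value is assumed. Analysis settings:
willingness-to-pay R$15,000 per adverse event avoided, 1,000 Monte Carlo
iterations.

The configuration dialect is a flat `key = value` text file with one
canonical key per parameter plus optional `.low`/`.high` sub-keys; floats
are serialized at full `repr` precision so write→load round trips are
bit-exact. A bare value override widens the stored range when necessary so
single-key overrides remain valid.

## Incremental analysis

Strategies are sorted by expected cost; exact cost-and-effect duplicates are
flagged as ties; strongly dominated strategies (another strategy no costlier
and no less effective, one strictly) are removed; extended dominance is
removed iteratively (a strategy whose frontier ICER exceeds that of the next
more effective strategy); ICERs are then computed between adjacent frontier
members. ICERs are kept unrounded internally. Both dominance kinds are
implemented even though the base case only exhibits strong dominance, so the
machinery remains correct for arbitrary inputs during sensitivity analysis.
The quadrant convention for a raw ICER: numeric when both deltas are
positive (or both negative, read from the cheaper comparator's perspective),
otherwise a dominance status.

## Sensitivity analyses

* **One-way (tornado)**: each parameter in turn at its low and high bound,
  all others at base; outcomes offered are the IPC-vs-no-prophylaxis ICER
  and the IPC-vs-LMWH / IPC-vs-no-prophylaxis cost differences (the tornado
  is published for two different outcomes). For the ICER outcome the signed
  ratio ΔC/ΔE is used so the swing stays defined when a bound flips the
  dominance quadrant; it is NaN only when ΔE = 0.
* **Threshold**: the baseline DVT probability is the x-axis of the
  "incidence of VTE" analysis (DVT is the tree's entry VTE event; PE scales
  through the conditional probability). The crossing where IPC's and
  no-prophylaxis's expected costs are equal is found with Brent's method on
  the cost difference (|Δcost| < 10⁻⁶ R$ at the root), bracket default
  [0.001, 0.05], with a 50-point evaluation grid attached for plotting.
* **Scenario**: IPC under `intra_and_post`, `post_only`, `intra_only`.

## Probabilistic sensitivity analysis

Distributions per family, each fitted from the point value and its 95%
interval with sd = (high − low)/3.92:

* **beta** (probabilities): method of moments on (value, sd); infeasible
  moments (sd² ≥ m(1−m)) are an error, not silently adjusted.
* **gamma** (costs): method of moments, shape = m²/sd², scale = sd²/m.
* **lognormal** (relative risks): the point estimate is the *median*
  (log-mean = ln value), log-sd = (ln high − ln low)/3.92 — RR confidence
  intervals are symmetric on the log scale in the source meta-analyses.
  Consequently the sampled RR *means* exceed the point estimates for the
  wide intervals (e.g. the LMWH DVT RR 0.33 [0.01–7.93] samples with mean
  ≈1.4); the PSA is deliberately not mean-matched for RRs, and the PSA mean
  therefore sits above the deterministic base case wherever a skewed RR
  enters.

Each of 1,000 draws samples the 17 uncertain quantities once (all parameters
except mortality, which feeds only the secondary deaths output and is held
at its point value), resolves all three strategies from the *same* sampled
vector, and rolls back the tree with the sampled unit costs. Probability ×
RR products above 1 are clamped and counted; draws whose postoperative
probabilities sum above 1 after clamping are rescaled to sum exactly 1
(no-adverse-event complement zero) and counted — both counts are reported on
the run object, never silent. Sampling order is the fixed canonical key
order from a single seeded NumPy generator, so runs are bitwise reproducible
per (parameters, n, seed).

Summaries: per-pair incremental cost-effectiveness plane with the dominant-
quadrant proportion and the below-the-WTP-line proportion (both are
reported; "superior" here means the dominant quadrant), a 95% confidence
ellipse from the mean and covariance of the incremental pairs (chi-square
0.95 quantile, 2 df; a rank-deficient covariance is flagged degenerate), and
the acceptability curve as the fraction of draws in which each strategy
attains the maximum net monetary benefit (ties split equally) over a WTP
grid of R$0–30,000 in R$500 steps (brackets the R$15,000 threshold).

## Microsimulation oracle

`simulate_cohort` realizes individual patients through the same tree:
Bernoulli hypotension, one uniform draw against the ordered categories
(DVT, minor, major, none) for the postoperative node, Bernoulli PE within
DVT and Bernoulli death within PE. The fixed category ordering and the
always-consumed PE/death draws keep random-stream consumption independent of
outcomes, so cohorts are reproducible across platforms by seed. Per-record
cost is exactly one of the 10 pathway costs; cohort means converge on the
rollback expectations (checked at 200,000 patients per strategy, within 3
standard errors), giving an independent route to the same quantities. It
emulates the homogeneous modelled cohort only: no covariates, risk
stratification, or correlation between events beyond the tree structure, so
agreement validates the arithmetic of the model, not its clinical realism.
Deaths never truncate cost accrual, matching the tree's payoff rules.

`generate_fixture` jitters every point value by up to a relative
±perturbation (probabilities clamped to [0, 1], ranges widened as needed) to
property-test downstream modules away from the published inputs.

## Problem sizes and determinism

Default analysis sizes are the study conditions: 1,000 PSA draws, a 10-seed
sweep for PSA summary statistics, 200,000 patients per strategy for the
microsimulation cross-check, a 50-point threshold grid. All randomness flows
through explicit integer seeds into `numpy.random.default_rng`; identical
(inputs, n, seed) give byte-identical CSV outputs.

## Known divergences from the published figures

With the published input table and the structure above, the no-prophylaxis
and IPC results match the published table within rounding (cost R$920 vs
914, R$951 vs 950; effectiveness 0.911 vs 0.912, 0.916 vs 0.916), the
break-even VTE incidence is 1.08% (published 1.20%), the scenario deltas are
R$12.7 and R$58.1 (published 13 and 54), and IPC is dominant over LMWH in
86.5% of PSA draws (published 86.3%) and over no prophylaxis in 17.5%
(published 17.6%). Three published figures are not recoverable from the
published inputs:

* **LMWH cost R$1,301 / effectiveness 0.861.** Applying the published
  bleeding relative risks (2.12 minor, 1.48 major) to the published
  baselines gives an adverse-event probability of 0.167 and a cost of
  R$1,504 under the declared structure — and no alternative structure tried
  (sequential-conditional nodes, PE cost replacing DVT cost, odds-ratio
  conversion of the RRs) reproduces both printed values either. The
  implementation keeps the declared structure and documents the gap rather
  than reverse-fitting hidden inputs.
* **ICER R$7,843.** The published unrounded increments (36/0.00459) imply an
  effectiveness delta consistent with a *product-form* (sequential
  independent risks) effectiveness, which contradicts the stated mutual
  exclusivity of the adverse events; under the declared additive structure
  the ICER is R$6,242. Both readings leave IPC clearly cost-effective at
  the R$15,000 threshold, so the decision conclusion is unaffected.
* **CEAC probability for LMWH ≈0.07 at R$15,000.** This inherits the LMWH
  gap above: with the published bleeding RRs the LMWH arm is too far from
  the frontier to win max-NMB in more than ≈1.5% of draws.

## Limitations

Short-horizon, homogeneous-cohort model: no long-term sequelae (chronic
thromboembolic pulmonary hypertension, post-thrombotic syndrome), no
neonatal outcomes, no risk stratification, no combined IPC+LMWH or
graduated-compression-stockings arms, and effectiveness is adverse-event
avoidance, not QALYs. Cost inputs are taken as already expressed in 2021
R$; no currency or inflation handling is included.
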