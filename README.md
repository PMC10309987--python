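# vtecea

Decision-tree cost-effectiveness analysis of thromboprophylaxis for cesarean
delivery, from a Brazilian hospital perspective.

Cesarean delivery raises the risk of venous thromboembolism (VTE: deep vein
thrombosis, possibly progressing to pulmonary embolism). Pharmacological
prophylaxis with low-molecular-weight heparin (LMWH) lowers the DVT risk but
raises bleeding risk; intermittent pneumatic compression (IPC) is a
mechanical alternative with no bleeding risk that, worn intraoperatively,
also reduces spinal-anesthesia hypotension. This package implements a
decision-analytic model that compares **no prophylaxis**, **IPC**, and
**LMWH** on the cost of care (2021 Brazilian Real, hospital payer
perspective, in-hospital time horizon) and on effectiveness defined as the
probability of avoiding any VTE-related adverse event (DVT, PE, minor or
major bleed). It is aimed at health-economics analysts who want the model's
every stage — parameters, tree, incremental analysis, uncertainty analyses —
as testable, scriptable Python.

## The model

Each strategy passes the same tree: an intraoperative chance node for
hypotension (probability `p_hypo`, management cost `c_hypo`; an intermediate
event, not an adverse event), then a mutually exclusive postoperative chance
node over {DVT, minor bleed, major bleed, no adverse event}, with DVT
splitting by the conditional PE probability. Expected values are
probability-weighted sums over the 10 terminal pathways. Strategy effects
enter as relative risks applied to the no-prophylaxis baselines, e.g.
`p_dvt(IPC) = p_dvt × RR_LMWH-vs-none × RR_IPC-vs-LMWH`.

Strategies are compared by the incremental cost-effectiveness ratio

    ICER = ΔCost / ΔEffectiveness   [R$ per adverse event avoided]

with strong and extended dominance handled, a willingness-to-pay threshold of
R$15,000 per adverse event avoided, and net monetary benefit
`NMB = λ·E − C` as the decision rule for the acceptability curve.
Uncertainty is explored by one-way (tornado) analysis, a threshold analysis
on the baseline VTE incidence, phase-of-use scenarios for IPC, and a
probabilistic sensitivity analysis (beta distributions for probabilities,
gamma for costs, lognormal for relative risks; 1,000 Monte Carlo draws).

## Worked example

```sh
python examples/base_case.py
```

```
      strategy      cost  incremental_cost  effectiveness  incremental_effectiveness     icer    status
no_prophylaxis  920.2122               NaN         0.9110                        NaN      NaN reference
           IPC  951.3595           31.1473         0.9160                      0.005 6241.569          
          LMWH 1503.5312               NaN         0.8328                        NaN      NaN dominated
```

Reading the table: without prophylaxis the expected cost of
VTE-prophylaxis-related care is R$920 per patient and 91.1% of patients avoid
every adverse event. IPC adds R$31 per patient and lifts the adverse-event-
free probability to 91.6%, an ICER of about R$6,242 per adverse event avoided
— well below the R$15,000 willingness-to-pay threshold, so IPC is
cost-effective against no prophylaxis. LMWH is *dominated*: it is both more
expensive (the bleeding it causes is costly) and less effective than either
alternative.

The other examples follow the same pattern: `sensitivity_analyses.py`
(tornado ranking — the baseline DVT probability is by far the strongest ICER
driver; the break-even VTE incidence of ≈1.08% above which IPC is outright
cost-saving; the IPC phase-of-use scenarios), `probabilistic_analysis.py`
(IPC cheaper *and* more effective than LMWH in ≈87% of 1,000 draws; CEAC
probabilities at R$15,000), and `microsimulation_check.py` (200,000 simulated
patients per strategy reproducing the analytic expectations).

A thin CLI wraps the same functions for batch use:

```sh
vtecea all --out results/full --seed 1 --n 1000   # every analysis + manifest
vtecea base-case --out results/base               # deterministic table only
vtecea write-defaults params.cfg                  # editable parameter file
```

Parameters live in a flat `key = value` text file (see `vtecea
write-defaults`); any subset of keys may be overridden, the rest fall back to
the built-in published values.

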