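# cardiocea

A Markov cohort cost-effectiveness model of a workplace cardiovascular
disease prevention program that adds a coronary-artery-disease polygenic
risk score (CAD-PRS) to standard risk screening.

Employers that self-insure bear the medical claims and the lost
productivity (absenteeism and presenteeism) of their workforce. Standard
workplace health programs stratify employees' 10-year atherosclerotic risk
with the pooled cohort equations (PCE); a polygenic score identifies the
additional high-genetic-risk employees invisible to traditional risk
factors. This package simulates a closed cohort of 50-year-old employees
over a 5-year horizon under three strategies:

* **CardioriskSCORE** — PCE plus CAD-PRS; every enrolled employee in the
  risk-bearing set (top-20% PRS with moderate/high PCE risk, or high PCE
  risk alone) is recommended statin prevention therapy;
* **StandardWHP** — PCE only; enrolled high-PCE employees initiate statins;
* **NoWHP** — no program, no screening costs, no treatment.

## Model

The cohort moves annually between 22 health states: 6 event-free risk
strata ({low, moderate, high} PCE × {bottom-80%, top-20%} PRS), 5
single-condition states (CAD, ischemic stroke, and the statin side effects
hemorrhagic stroke, diabetes, myopathy), all C(5,2)=10 comorbid pairs, and
death. Adherent statin users face hazard-ratio risk reductions for CAD
(HR 0.56) and ischemic stroke (HR 0.77) plus small side-effect risks;
acute events carry case fatality, acute costs and disutility in the entry
cycle, chronic states carry follow-up costs and utility weights, and every
state accrues background healthcare cost and age-related disutility.
Costs (US$2019, employer perspective, including lost productivity) and
QALYs are discounted at 3%/year. Outputs:

* base-case totals, incremental costs/QALYs, dominance/ICER and net
  monetary benefit `NMB = WTP x QALYs - cost` at WTP $50,000/QALY;
* one-way sensitivity (tornado of incremental NMB over every parameter's
  published range);
* probabilistic sensitivity (beta/log-normal/gamma distributions, 10,000
  Monte-Carlo draws, CE plane and cost-effectiveness acceptability curves);
* a scenario with annual migration of the event-free cohort across PCE
  risk categories, blending natural and in-program risk change by program
  enrollment.

See `docs/methods.md` for assumptions, conventions and limitations, and
`src/cardiocea/data/data_dictionary.md` for every parameter.

## Worked example

```python
from cardiocea import (
    compare, default_parameters, default_strategies,
    run_strategies, synth_life_table, total_outcomes,
)

ps = default_parameters()            # packaged annual parameter table
lt = synth_life_table()              # synthetic period life table, q(50)=0.004
traces = run_strategies(default_strategies(), ps, lt)   # 5 y, 3% discount
result = compare({k: total_outcomes(t) for k, t in traces.items()})
print(result.to_frame().to_string(index=False))
```

prints

```
       strategy         cost    qalys  incremental_cost  qalys_gained     icer           nmb
CardioriskSCORE 28305.661358 4.513137               NaN           NaN Dominant 197351.204994
    StandardWHP 28327.679230 4.512163         22.017872     -0.000974     None 197280.462613
          NoWHP 28580.400879 4.508986        274.739521     -0.004151     None 196868.900968
```

Per employee over five years, the PRS-guided program accrues 4.513
discounted QALYs and costs $28,306; it is *dominant* — cheaper and more
effective — against both comparators, saving $22 vs the standard program
and $275 vs no program while gaining 0.001 and 0.004 QALYs. The savings
come from averted acute events and their follow-up and productivity
costs, net of screening, PRS testing and statin costs.

The same analyses are available from the shell:

```bash
cardiocea run-base-case --out results/
cardiocea owsa --comparator NoWHP --out results/
cardiocea psa --n 10000 --seed 20190711 --out results/
cardiocea scenario --out results/
```

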