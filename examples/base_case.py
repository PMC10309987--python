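"""Deterministic base case: roll back the decision tree for each strategy
and build the incremental comparison table.

Run:  python examples/base_case.py
"""

from vtecea import (
    StrategySpec,
    default_parameters,
    evaluate_strategy,
    incremental_frame,
    incremental_table,
)

params = default_parameters()
results = [
    evaluate_strategy(params, StrategySpec(name))
    for name in ("no_prophylaxis", "IPC", "LMWH")
]

print(incremental_frame(incremental_table(results)).round(4).to_string(index=False))
print()
print(
    "Each row is one prophylaxis strategy: expected cost per patient (2021 R$)\n"
    "and the probability of avoiding every VTE-related adverse event.\n"
    "'dominated' means another strategy is cheaper AND more effective; a\n"
    "numeric ICER is the extra cost per additional adverse event avoided\n"
    "relative to the previous strategy on the efficiency frontier."
)
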