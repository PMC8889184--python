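"""Threshold effects: binary splitting at maximal maturity size wins.

Under a neutral size schedule, a volunteer's dilemma with contribution
threshold k selects symmetric binary splitting (N/2)+(N/2) for small k
and the asymmetric split (N-k)+k for k > N/2; at k = 1 nearly all
strategies perform alike, and for k >= N the benefit is unreachable.
"""

from lifecycles import GameParams, SizeSchedule, scan_threshold

records = scan_threshold(k_values=range(1, 9), N_values=[8], params=GameParams())
print(" k | optimal strategy | category           | max lambda")
print("---+------------------+--------------------+-----------")
for k in range(1, 9):
    rec = records[(k, 8)]
    label = str(rec.unique_optimum) if rec.unique_optimum else "many"
    print(f" {k} | {label:16s} | {rec.category:18s} | {rec.max_lambda:.4f}")
rec1 = records[(1, 8)]
near = sum(
    1 for lam in rec1.lambda_by_strategy.values()
    if lam >= rec1.max_lambda * (1 - 2e-3)
)
print(f"\nAt k = 1 the label above hides near-ties: {near} of 58 strategies")
print("lie within 0.2% of the maximum — effectively multiple optima.")
print("Growth rates fall as k rises (fewer beneficial newborns) and drop")
print("below 1 once k >= 8: B cells then pay their cost for no benefit.")
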