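"""Score candidate memory models on two games of free throws.

Walks the built-in two-game example ('+' make, '-' miss): order-1
transition counts, maximum-likelihood transition probabilities, and the
full criteria table for h = 0 vs h = 1, ending with each criterion's
choice.  Lower criterion values are better (deviance scale).
"""

from markovselect import (
    MemorySpec,
    count_transitions,
    evaluate_all,
    free_throw_example,
    mle,
    select_model,
)

trajs = free_throw_example()
print("games:", ["".join(t) for t in trajs.trajectories])

counts = count_transitions(trajs, h=1)
print("\norder-1 pooled counts [miss, make] by context (.= start of game):")
for ctx, vec in sorted(counts.pooled.items()):
    print(f"  after {''.join(ctx)!r}: {vec.tolist()}")

print("\nmaximum-likelihood make probabilities:")
for ctx, p in sorted(mle(counts).items()):
    print(f"  after {''.join(ctx)!r}: {p[1]:.3f}")

specs = [MemorySpec(order=0), MemorySpec(order=1)]
report = evaluate_all(trajs, specs)
cols = ["AIC", "BIC", "nLML", "WAIC1", "WAIC2", "DIC1", "LOO", "LHO", "k_param"]
print("\ncriteria (deviance scale, lower is better):")
print(report.table[cols].round(4).to_string())

for crit in ("AIC", "LOO", "WAIC1"):
    print(f"{crit} selects {select_model(report, crit).label()}")
print(
    "\nWith only 18 shots the criteria split: the fit improves at h=1 "
    "(AIC) but the predictive criteria prefer the simpler h=0 model."
)
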