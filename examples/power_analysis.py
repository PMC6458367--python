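"""How often is a memory-free shooter correctly identified?

Simulates seasons with independent shots (no memory), lets each
criterion choose h among {0, 1, 2, 3}, and reports how often each order
is selected.  The h=0 column is the probability of correctly concluding
"no memory"; everything else is a false detection.  200 replicates keep
this quick; the published-scale figure uses 1000+.
"""

from markovselect import FreeThrowConfig, IIDProcess, power_analysis_freethrow

cfg = FreeThrowConfig(games=91, mean_attempts=7.6, process=IIDProcess(0.68))
res = power_analysis_freethrow(cfg, h_candidates=[0, 1, 2, 3], replicates=200, seed=0)

print("selection frequency by criterion (rows) and order h (columns):")
print(res.freq.round(3).to_string())
loo0 = res.freq.loc["LOO", 0]
print(
    f"\nLOO selects h=0 in {100 * loo0:.0f}% of simulated seasons: even a "
    "season of ~690 independent shots yields spurious memory detections "
    "at a nontrivial rate, and the pointwise-predictive-density criteria "
    "(nLPD/nLPPD) overfit badly without their complexity penalties."
)
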