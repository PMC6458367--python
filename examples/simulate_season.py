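"""Simulate a season of free-throw games and check its calibration.

A season is 91 games; each game's attempt count is zero-truncated
Poisson with mean 7.6 and every shot is an independent make with
probability 0.68 — the scale of a high-volume NBA shooter's season.
"""

import numpy as np

from markovselect import FreeThrowConfig, IIDProcess, simulate_season

cfg = FreeThrowConfig(games=91, mean_attempts=7.6, process=IIDProcess(0.68), seed=1)
season = simulate_season(cfg)

lengths = np.array(season.lengths)
makes = sum(t.count("+") for t in season.trajectories)
print("first three games:", ["".join(t) for t in season.trajectories[:3]])
print(f"games: {season.n_trajectories}, attempts: {lengths.sum()}")
print(f"mean attempts per game: {lengths.mean():.2f} (target 7.6)")
print(f"season make fraction:   {makes / lengths.sum():.3f} (target 0.68)")
print(
    "\nOne season is a single draw, so both statistics scatter around "
    "their targets; across many seeds they match to Monte-Carlo error."
)
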