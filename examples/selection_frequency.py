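"""Selection frequencies on a random 4-state network with one step of memory.

Draws one fixed 4-state order-1 network (Dirichlet(1) transition rows,
designated start and absorbing states), repeatedly samples J trajectory
sets, and tabulates which order each criterion selects.  Doubling J from
4 to 16 shows every predictive criterion homing in on the true order.
"""

from markovselect import selection_experiment

for J in (4, 16):
    res = selection_experiment(
        M=4, h_true=1, J=J, h_candidates=[0, 1, 2, 3], replicates=400, seed=7
    )
    print(f"\nJ = {J} trajectories per replicate (true order 1):")
    print(res.freq.round(3).to_string())

print(
    "\nThe h=1 column grows with J for LOO/WAIC/DIC; the raw predictive "
    "densities (nLPD, nLPPD) keep overfitting, and BIC is the slowest to "
    "abandon h=0."
)
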