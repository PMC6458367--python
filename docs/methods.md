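# Methods

## Model

A trajectory ξ = (ξ₁, …, ξ_L) over an alphabet of M states is modelled
as an order-h Markov chain: Pr(ξ) = Π_l p_{x(l), ξ_l}, where
x(l) is the history of the h symbols preceding position l. Histories
that would reach past the start of a trajectory are left-padded with a
reserved boundary sentinel ("." by default), so the first symbol is
conditioned on an all-boundary context, the second on one real symbol,
and so on. This makes the likelihood a complete factorisation over
observed symbols — every symbol is explained by exactly one context —
and reproduces the familiar two-extra-states bookkeeping of the
free-throw case at h = 1. For h ≥ 2 the padding is our generalisation
of that convention; boundary markers only ever appear as a leading
prefix of a context.

With J independent trajectories the sufficient statistics are the
per-context transition counts N_{x,m} and their per-trajectory
decomposition N⁽ʲ⁾_{x,m}. Each context's row p_x gets an independent
conjugate prior p_x ~ Dirichlet(α) with a single α shared across
contexts (default α = 1, the uniform prior; α = 1/2 gives Jeffreys').
The posterior is Dirichlet(α + N_x), which assigns unobserved
transitions a posterior-mean probability α_m / (Σα + N_x) instead of
the maximum-likelihood zero.

Variable-length models are expressed as a partition of the order-h
context set into blocks sharing one parameter vector; merging the
counts within a block keeps the likelihood a product of
Dirichlet-multinomial terms, so every criterion below applies verbatim
to the merged table. Blocks are defined over a single base order (no
arbitrary-depth context trees), which covers models such as
"independent except immediately after a miss" while leaving model
*search* out of scope.

## Criteria

All eleven criteria are closed-form functionals of the counts and are
reported on the deviance scale (−2 × log predictive quantity):

- AIC/BIC use the MLE deviance −2 Σ N log(N/N·) with 0·log 0 ≡ 0.
  Two parameter-counting conventions are provided because both are in
  circulation: `literal` k = Mʰ(M − 1) (the full fixed-order parameter
  space; boundary contexts excluded), and `contexts` k = (#observed
  contexts or blocks) × (M − 1), which is the natural count for
  boundary-padded data and the only coherent one for merged tables.
- nLML, nLPD, nLPPD are ratios of multivariate beta functions
  B(x) = Π Γ(x_m) / Γ(Σ x_m), evaluated entirely in log space via
  `gammaln`.
- WAIC₁/WAIC₂ penalise −2·LPPD by twice an effective parameter count:
  variant 1 from the gap between LPPD and the posterior expectation of
  the log-likelihood (digamma form), variant 2 from the pointwise
  posterior variance (trigamma form).
- DIC₁/DIC₂ use the plug-in deviance at the posterior mean with the
  analogous digamma/trigamma penalties.
- LOO scores each trajectory against the posterior built from the other
  J − 1; LHO splits the trajectory list into its first ⌈J/2⌉ members
  versus the rest and scores each trajectory against the opposite
  half's posterior. (The published LHO summation bounds overlap at
  j = J/2; we treat that as a typo and use the disjoint split.)
  Trajectory order in the input file is therefore significant for LHO.
- Selection is argmin; exact ties break toward fewer parameters, then
  lower order. LHO is undefined at J = 1 and is dropped with a warning.

Unobserved contexts contribute nothing to any criterion (their
beta-function ratios cancel), so count tables are stored sparsely and
the Mʰ blow-up never materialises in memory.

A Stirling expansion of log B through the 1/(12x) terms is provided for
asymptotic analysis; it is accurate to relative error below 1e−6 once
all components exceed ~100 and is deliberately unguarded below that.

## Verification strategy

Because every marginal-likelihood-type criterion equals a sequential
predictive probability under conjugacy, the test suite re-derives LML,
LPPD, LOO and LHO with an independent Pólya-urn implementation (one
symbol at a time, no beta functions) on hundreds of random small
fixtures, requiring agreement to 1e−9. The expectation/variance-based
quantities (nLPD, the WAIC₁ expectation term, k_DIC2) are checked
against Monte-Carlo posterior sampling within 3 standard errors.

## Synthetic data

`generate_network` draws an M-state, order-h_true chain whose
transition rows are independent Dirichlet(1) vectors, with the first
state designated as start and the last as absorbing. Trajectories begin
with a history of start-state padding and run to absorption, so their
lengths are first-passage times (mean ≈ M under Dirichlet(1) rows).
Absorption and start-revisit probabilities are random like any other
entry. When fitting candidates to network trajectories, histories are
padded with the start state — it is genuinely known to precede every
trajectory — so all contexts live in the ordinary order-h context set
and the literal Mʰ(M − 1) count applies exactly. Free-throw analyses
keep the boundary-sentinel convention instead, since a game has no
meaningful "previous shot".

`simulate_season` emulates a season of free-throw games: attempt counts
per game are zero-truncated Poisson (λ solved so the truncated mean
equals `mean_attempts`; every counted game has ≥ 1 attempt), with
defaults of 91 games and mean 7.6 attempts at a 68% make rate — the
scale of a high-volume NBA shooter's season. Outcome processes:
independent Bernoulli; order-1 Markov (separate first-shot,
after-make, after-miss probabilities); and the two-parameter error
correction process (different probability only after a miss). What the
generator does **not** emulate: shot-level covariates (fatigue, score
pressure, venue), non-stationarity within or across seasons, and any
hidden-state dynamics — so passing tests demonstrate correct behaviour
of the selection machinery under the stated generating processes, not
that real shooters are Markovian.

## Experiments and problem sizes

`selection_experiment` fixes one network per run (`fixed_network`,
matching the published design; `fresh_network` redraws per replicate
and widens the dispersion), resamples J-trajectory sets, and tabulates
each criterion's chosen order. `delta_experiment` collects
Criterion(h) − Criterion(h_true) samples. `power_analysis_freethrow`
does the same over simulated seasons.

Desk-scale defaults keep every study reproducible on one CPU in
minutes: 2000 replicates for selection tables (the original studies
used 10⁴; binomial standard error at 2000 is ≤ 1.1 points), 1000 for
the power analysis, 800 per cell for sample-size trend ladders, and
candidate orders 0–5 (networks) or 0–3 (seasons). All randomness flows
from a single seed through `numpy` SeedSequence spawning;
results are bit-reproducible given the seed.

Two behaviours discovered at these scales are worth recording. First,
selection frequencies on random networks vary widely from network to
network (a WAIC₁ true-order rate anywhere from ~0.45 to ~0.95 at
M = 8, h_true = 1, J = 4), so single-network figures should be read as
draws from that spread — the acceptance test prints the across-network
distribution alongside its fixed-network value. Second, the marginal
likelihood (nLML) is the *most conservative* criterion at desk scale —
at M = 4, J = 64 its mean selected order sits slightly below LOO's —
even though it is known to favour complexity in large-sample regimes;
the package simply reports both, and the complexity-bias comparison is
made at the 8-state system where both criteria are at ceiling.

## Degenerate inputs and numerical notes

- Empty count tables give 0 for every criterion (AIC/BIC reduce to
  their penalties; the BIC penalty is 0 when there are no observations,
  as log N is undefined).
- A zero MLE probability facing a positive count returns −inf with a
  warning from `log_likelihood`; the Bayesian criteria never hit this
  because α > 0.
- All beta/gamma evaluations are in log space; criteria sums are
  vectorised over a stacked dense view of the sparse table.
- The zero-truncated Poisson sampler redraws zeros rather than
  inverting the truncated CDF; at the default mean the zero class has
  probability e^(−7.6) ≈ 5 × 10⁻⁴, so the redraw loop is negligible.

## Limitations

- No automated search over variable-length partitions; the user supplies
  candidate partitions explicitly.
- No AICc (its small-sample correction is problem-specific), no
  model-averaging weights, no hidden Markov models.
- A single α vector is shared across contexts; per-context priors are
  not supported.
- FASTA input treats each record as one trajectory verbatim: no
  alignment, reverse-complement or quality handling.
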