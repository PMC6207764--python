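# Methods

## Model

A well-mixed population of `N` players, each a cooperator (C) or defector
(D), plays the one-shot Prisoner's Dilemma with payoff entries
`R` (mutual cooperation), `T` (temptation), `S` (sucker), `P` (mutual
defection), validated against the dilemma ordering `T > R > P > S` unless
explicitly constructed unchecked. With `k` cooperators present, average
payoffs exclude self-interaction:

    Pi_C(k) = ((k-1) R + (N-k) S) / (N-1)
    Pi_D(k) = (k T + (N-k-1) P) / (N-1)

An external interference scheme Θ = (θ₁, …, θ_{N−1}) pays a total θ_k,
split evenly, to the cooperators whenever the state holds `k` of them, so
each cooperator's payoff gains θ_k/k. Interference is modelled exclusively
as this additive bonus — it is the only way investment enters the
dynamics. θ is defined only on the mixed states; the homogeneous states 0
and N receive nothing (the cost sum runs over transient states only).

Strategy revision follows the pairwise-comparison rule: a focal player
imitates a model player with the Fermi probability
`1/(1 + exp(-beta * (f_model - f_focal)))`, where the selection intensity
`beta >= 0` interpolates between neutral drift (beta = 0) and
deterministic imitation of the fitter. One time step is one revision
event with focal and model drawn uniformly and independently from the
whole population (a coincident pair is a no-op). This convention makes
the one-step kernel of the cooperator count exactly

    T^{+/-}(k) = ((N-k)/N) * (k/N) * sigmoid(+/- beta * Delta_k),
    Delta_k    = Pi_C(k) + theta_k/k - Pi_D(k),

with no rescaling between the agent-level process and the analytic chain.

## Cooperation frequency

In the small-mutation limit the population is monomorphic almost always
and the long-run behaviour reduces to a two-state chain over all-D and
all-C whose transition rates are the single-mutant fixation probabilities
ρ_{D,C} (a C invading all-D) and ρ_{C,D}. The cooperation frequency is
the stationary weight of all-C, ρ_{D,C}/(ρ_{D,C}+ρ_{C,D}). We deliberately
use this (standard) definition rather than time-averaged interior
occupancy; the two differ at finite mutation rates.

Fixation probabilities follow from the classic ratio sum. Because
T^-(k)/T^+(k) = exp(-beta Delta_k) exactly, the products collapse to
cumulative sums of Delta and

    rho_DC = 1 / sum_{i=0}^{N-1} exp(-beta * sum_{k<=i} Delta_k).

Numerics: beta * N * payoff can reach hundreds, so the sums are evaluated
with log-sum-exp; products of Fermi factors are never formed. beta = 0 is
special-cased to the exact neutral values (rho = 1/N, frequency = 1/2)
rather than evaluated as a limit. The log of the cooperation ratio also
has a closed form, beta*(N(R+S-T-P)/2 + (P-R) + G) with G = Σ_k θ_k/k,
which the test suite verifies against the sum-based route to 1e-8
relative over randomized games, schemes, beta <= 2 and N <= 200; the two
agree near machine precision because both reduce to the same cumulative
sums.

## Expected interference cost

The cooperator count is an absorbing birth-death chain (absorbing at 0 and
N); with the convention that a mutant arises at S_1 or S_{N-1} with
probability 1/2 each, the expected visits to the transient state S_i are
v_i = (n_{1,i} + n_{N-1,i})/2, where n is the fundamental matrix
(I - U)^{-1}, and the expected cost is EC = Σ_i v_i θ_i. A "visit" is a
time step spent in the state, self-loop steps included: θ_i is charged for
every revision event that begins in S_i, whether or not the state changes.
The reported count of interference events uses the same semantics (visits
to states with θ_i > 0). The start convention is fixed; other start
distributions would only reweight the two fundamental-matrix rows.

Numerics: generic tridiagonal solves for the fundamental-matrix rows are
*not* numerically adequate here. For strong selection and an interior
investment threshold the chain is quasi-stationary near the threshold —
drift pushes up below `t` and down above it — and the visit counts span
hundreds of orders of magnitude; LU-based solvers then return large
negative entries in the small components. We instead evaluate the exact
birth-death Green's function. With gamma_0 = 1,
gamma_k = prod_{i<=k} T^-(i)/T^+(i) and scale sums S_j = sum_{k<j}
gamma_k:

    n_{a,j} = hit(a,j) * S_j (S_N - S_j) / (T^+(j) gamma_j S_N),

where hit(a,j) is the probability of ever reaching j from a (a ratio of
scale sums). Every ingredient is a sum of positive terms, so computing the
gammas and scale sums in log space (cumulative log-add-exp) is accurate to
rounding regardless of dynamic range, and costs O(N). The dense inverse is
retained as a cross-check for N <= 50 in well-conditioned regimes, and a
first-step-analysis banded solve independently reproduces the fixation
probabilities from the same chain. If a Fermi factor underflows to exactly
zero (|beta*Delta| beyond ~745) the visit counts are not representable in
float64 and the code raises rather than returning garbage.

## Sufficient conditions and threshold optimisation

A target cooperation fraction omega in (0, 1) is achieved iff

    G >= (1/beta) log(omega/(1-omega)) + N(T+P-R-S)/2 + (R-P);

the condition is tight, not merely sufficient, because frequency is a
strictly increasing logistic function of G. Endpoints omega in {0, 1} are
rejected (the log diverges); omega = 0.5 cancels the log term exactly and
is handled without limits. The bound decreases with beta for omega > 0.5
and increases with beta for omega < 0.5, as the formula forces.

For the individual-based family (θ per cooperator while the count is at
most t, G = t·θ) the bound inverts to minimal θ at fixed t and minimal
integer t at fixed θ. Integer thresholds use ceil(x - 1e-9) so an
analytically exact integer boundary (e.g. a bound of exactly 101) is
itself admissible. `min_t` always reports the required integer, with an
explicit feasibility flag comparing it to N-1, so an out-of-reach target
is informative rather than an error.

`optimal_threshold` scans every t in 1..N-1 (each evaluation is O(N), so
the scan is O(N^2) and takes ~50 ms at N = 100), computes frequency and
EC, and minimises EC over the feasible set with ties broken toward the
smallest t (fewer states trigger payment; deterministic output). An empty
feasible set returns an explicit infeasible result. At beta = 0 every
scheme yields exactly 50% cooperation, so the result is flagged
`neutral_selection`: feasible iff omega <= 0.5, with the optimal action
being no investment at all (zero cost, no threshold).

Feasibility in the scan uses the computed frequency with a 1e-9 boundary
slack, which the bound-equivalence property test ties back to the
closed-form condition.

## The Monte-Carlo simulator

The simulator is an independent check, not a faster analytic path. It
implements the same microscopic process:

- **Episode mode** starts a single mutant at S_1 or S_{N-1} (probability
  1/2 each) and runs to absorption, accumulating per-state dwell steps and
  payouts θ_i per step; estimates of rho_DC, rho_CD, visits and episode
  cost carry binomial/sample standard errors. Intended for small
  populations (soft cap N <= 50).
- **Stationary mode** runs one long trajectory in which each revision
  event mutates with probability mu (the focal player adopts a uniformly
  random strategy instead of imitating; default mu = 1e-3, and mu <= 1/N^2
  is recommended to approximate the small-mutation limit). The reported
  cooperation frequency is the time in all-C divided by the time in the
  two homogeneous states — the estimator that converges to
  rho_DC/(rho_DC+rho_CD) as mu -> 0; the unconditional occupancies of
  all-C, all-D and the interior are reported alongside. Standard errors
  come from batch means over 32 contiguous blocks, which is honest only
  when the run contains many regime switches; runs of >= 1e7 events are
  advisable for rare-transition regimes.

Both modes simulate the embedded jump chain with geometrically distributed
dwell times — distributionally identical to stepping single revision
events (self-loops are recovered exactly by the geometric dwell) but
orders of magnitude faster, which is what makes 3e7-event validation runs
take a fraction of a second. The agent-level event itself (focal/model
draw plus Fermi adoption) is exposed as `empirical_kernel` and validated
directly against T^{+/-}(k), so the jump-chain shortcut is itself under
test. All randomness flows from one seeded numpy Generator; a seed is
mandatory and identical seeds reproduce summaries bit-for-bit.

The simulator emulates exactly the model's idealisations: well-mixed
interactions, average (not sampled) payoffs, and state-conditioned
deterministic payouts. Agreement between simulator and analytic chain
therefore validates the mathematics and the code, not the model's fit to
any empirical population.

## Experiments

`coopctl.experiments` drives three deterministic studies at N = 100 with
the standard payoffs (R, T, S, P) = (1, 2, -1, 0): the threshold sweep
(frequency, paying steps, EC versus t for θ in {1, 5, 40} at beta = 0.1),
the t* grid (beta in {0.001, 0.01, 0.1, 1} x omega in {0.1, 0.5, 0.7,
0.9}), and the cost-efficiency range (thresholds beating FULL-INVEST, beta
in {0.01, 0.1} x omega in {0.1, 0.5, 0.9}). The θ grid for the latter two
is 0.5, 1.0, …, 50 by default and is recorded in each run's manifest;
tests assert trends and anchor values only, never grid-dependent
specifics. Outputs are CSV plus a JSON manifest; any log scaling is
applied at plot time only and stored values are never transformed.

## Known limitations

- Two strategies, one-shot pairwise game, well-mixed population:
  structured populations, multi-player games and adaptive (state-history
  dependent) interference policies are out of scope.
- The cooperation frequency is the small-mutation-limit quantity; finite
  mutation rates shift it (the stationary simulator quantifies the bias at
  a given mu but the analytic path does not).
- The expected-cost accounting charges per revision event spent in a
  state. Counting only state-changing events, or charging per generation
  of N events, would rescale EC (the optimal threshold comparison is
  unaffected by a uniform rescaling).
- Under extremely strong selection (|beta * Delta_k| beyond ~745) Fermi
  factors underflow and cost computations raise; cooperation frequencies
  remain available since they saturate stably in log space.
- General schemes beyond the individual-based family are fully supported
  for frequency and cost evaluation, but the threshold optimiser searches
  only the individual-based family: for a fixed guarantee the frequency
  depends on Θ only through G, making per-state allocation degenerate for
  the constraint, and cost-optimal general allocation is left open.
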