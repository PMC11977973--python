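# Methods

## The process being sampled

A well-mixed reaction system with species counts `n = (n_1, …, n_N)` and
reaction channels `r = 1, …, R` is a continuous-time jump process: channel
`r` fires in `[t, t+dt)` with probability `f_r(n) dt`. For mass-action
channels the propensity uses the combinatorial (counting) convention

    f_r(n) = c_r · Π_i C(n_i, ν_ri),

so a second-order channel `2X → …` has propensity `c · n(n−1)/2`, which is
the convention under which the chemical master equation (CME) is exact.
Channels may instead carry an arbitrary custom propensity `n ↦ f(n) ≥ 0`;
this is required for Hill-type gene-regulation terms, which are not
mass-action.

Each reaction holds three per-species integer vectors: reactant counts
(the ν used for propensity order), an immediate change column applied at
firing, and a delayed change column applied at completion, a lag τ after
firing. Stacked over reactions these are the reactant matrix and the two
stoichiometric matrices. τ is either a constant or a function of the RNG,
drawn fresh at every firing.

Delayed reactions come in two classes:

* **consuming** — reactants are removed at initiation, products appear at
  completion; the state is adjusted twice.
* **completion-only** — nothing changes at initiation; the full net change
  lands at `t + τ`. Reactant availability is deliberately *not* checked at
  initiation for this class (the reactants are untouched during the lag,
  so the propensity still sees them); infeasibilities are handled at
  completion by conflict resolution. A corollary users should know: a
  completion-only channel can re-initiate on the same molecules during the
  lag, which is the intended semantics of this class, not a bug.

## Engines

Markovian (no delays): Gillespie Direct, First Reaction, and Anderson's
Modified Next Reaction (MNR) with per-channel unit-rate internal clocks
`T_k` and thresholds `P_k`. All three are exact samplers of the same law.

Delay-capable, sharing a pending-event queue (a min-heap keyed by
completion time with FIFO tie-break):

* **DelayRejection** — tentative step `Δ ~ Exp(a0)`; if a scheduled
  completion occurs first, the step is discarded, time advances to the
  completion, its delta is applied, and sampling restarts. Exact because
  the exponential is memoryless only within a segment of constant `a0`.
* **DelayDirect** — the waiting time `w` solves
  `∫_t^{t+w} a0(s) ds = Exp(1)` with `a0` piecewise constant across
  completions; the integral is accumulated segment by segment with exact
  re-evaluation of propensities after each applied completion, no
  interpolation. The firing channel is chosen proportional to the
  propensities at the firing time.
* **DelayMNR** — Anderson's MNR where the next event is the earlier of
  the earliest channel firing `(P_k − T_k)/a_k` and the earliest queued
  completion; clocks advance by `a_k · Δt` in either case.

When a completion and a sampled firing coincide exactly, the completion is
applied first: completions were committed in the past, and the fixed order
makes runs reproducible. With all delays zero, every delay engine reduces
distributionally to its Markovian counterpart (verified by KS suites).

Output is sampled onto a user grid, piecewise-constant: the state reported
at grid time `t` includes every event with event time ≤ `t`. When all
propensities vanish and no completions are pending, the state freezes to
the horizon — absorbing states are legitimate model behaviour, not errors.
Ensembles run independent trajectories with replicate `i` seeded
`seed + i`.

## Conflict resolution

A completion may try to remove molecules that a faster channel already
consumed. When applying a delta drives a species negative, one live
pending event that decrements that species is cancelled, chosen uniformly
at random; its scheduled decrement is credited against the deficit
(capped, so cancelling a −k event never mints molecules) and the check
repeats. The physical reading: the current removal takes over the target
of the cancelled future removal.

If no cancellable event exists and the infeasible proposal is itself a
completion, the proposal's residual deficit is dropped — an *orphaned*
completion whose targets are already gone. This fallback is required for
correctness: in a model where a non-delayed degradation races a
completion-only degradation, a perfectly legitimate trajectory can orphan
the last pending removal, and aborting there would make the engine unable
to simulate the model at all. An immediate (non-delayed) proposal that
cannot be repaired raises a model-consistency error instead.

Uniform choice among candidates is one reading of "remove one conflicting
event at random"; alternatives (oldest/newest first) would bias which
future completions survive. In conflict-heavy regimes the rule is a
modelling convention, not exact physics — the stationary law of a heavily
conflicted species depends mildly on it. The candidate sampling uses a
per-species index with swap-delete rejection sampling, keeping resolution
O(1) amortized even with tens of thousands of queued events (the SOX2
degrader scenario below).

## Model library

**Bursty transcription** (defaults α = 0.0282, b = 3.46, τ = 120, the
published parameter set). Burst sizes are geometric with mean `b`
(support k ≥ 0; only k ≥ 1 is observable), encoded as a truncated family
of channels `∅ → k·M` with constant propensity `α·b^k/(1+b)^(k+1)`,
truncated where the relative tail `(b/(1+b))^(k+1)` drops below 1e−6
(configurable). Each burst adds `k` molecules immediately and schedules
their joint removal at `t + τ`; with a fixed τ this is law-equivalent to
k unit removals. Stationary mean `α·b·τ` by Little's law; the stationary
distribution is compound-Poisson, so the Fano factor exceeds 1.

**Refractory promoter** (defaults k1 = 0.15, k2 = 0.1, k3 = 0.05,
k4 = 10, τ = 1). A unidirectional cycle G0 → G1 → G2 → G0 — the three
printed rate constants admit exactly three transitions, and the cycle is
the standard refractory construction — with transcription only in G2 and
each mRNA removed τ after synthesis. Renewal occupancy gives
`P(G2) = (1/k3)/(1/k1 + 1/k2 + 1/k3)` and stationary mean
`k4·τ·P(G2) ≈ 5.455`; the long silent periods give the bimodal marginal
with its heaviest mode at zero.

**RNA velocity** — `∅ → U` at α, `U → S` at β, `S → ∅` at γ (optionally
completion-only delayed). Transcription shuts off at `t_switch`; the
simulation continues with the same state *and* pending queue, so removals
scheduled before the switch still complete after it. Defaults α = 20,
β = 1, γ = 0.5, t_switch = 50 are implementation choices (the source
figure's parameters are unreadable); they give clean phase-1 plateaus
`E[U] = α/β = 20`, `E[S] = α/γ = 40` and the two-arc U–S loop.

**AST network.** The published concentration-based ODEs for FOXA2 (F),
NKX2-1 (N), P63 (P) and SOX2 (S) are rescaled to molecule counts by
`X = x·V·N_A = x·B`; rewriting term by term gives, e.g.,

    dF/dt = B³·αF / (B² + a1·P² + a2·S²) − dF·F,

and analogously for the other three species (SOX2 combines its
self-activation `B·βS·S²/(B²a7² + S²)` and basal
`B³·αS/(B² + a8·F² + a9·N²)` terms in one production channel). `B = 1`
is the identity, and molecule trajectories divided by B reproduce the
concentration trajectories exactly — both are tested. The stochastic
model uses one production channel (custom propensity = the positive term)
and one linear degradation per species; B = 6023 (V = 1e−20 L) throughout.
The SOX2 degrader is an extra channel with propensity `k_deg·S` whose
single-molecule removal completes a fixed `τ_S = 1` after initiation
(completion-only). k_deg has no published value; 2.0 (five times the
basal `d_S = 0.4`) is used as a representative strong degrader in tests.

## Landscapes and attractors

Quasi-potential: pool ensemble states, bin two chosen species on an
`n_bins × n_bins` grid, normalise to frequencies `P`, and set
`U = −ln(P + ε)` with `ε = 1/(2·n_samples)` by default — finite on empty
bins, bias vanishing with sample size, and order-preserving (the U
ranking is exactly the reversed P ranking). Local minima use the
8-neighbour definition with boundary bins excluded, since sparse
histograms accumulate edge artifacts.

`count_attractors` integrates an ODE right-hand side (solve_ivp,
rtol 1e−8) from uniform random starts in a box to `t_long = 200`,
clusters endpoints within a merge radius (default 0.05·B in molecule
units), and reports distinct attractors with basin counts. Failed
integrations are excluded with a warning.

## What the tests establish — and what they do not

The synthetic checks are closed-form oracles: the M/D/∞ queue
(Poisson(α·τ) stationary law) for all delay engines, Little's law for the
bursty mean, renewal occupancy for the refractory mean, the truncated-CME
matrix exponential for the Markovian engines, and pairwise KS agreement
plus zero-delay reduction across all six engines. Stationary-mean checks
pool late-time snapshots spaced at least one delay apart across
independent trajectories; this is statistically equivalent for stationary
marginals and far cheaper than one trajectory per sample. Green tests
establish exactness of the samplers on these laws; they do not certify
behaviour under heavy conflict loads (where the resolution rule is a
convention) nor performance claims of any kind.

Scaled-down choices made purely for CI budget, with the stated worlds
unchanged: the SSA-vs-ODE agreement check runs 8 trajectories to t = 2
(not 300 long ones), and the degrader check runs 6 trajectories to
t = 10 pooling late snapshots. The AST SSA costs ~5×10⁴ events per model
time unit at B = 6023, which rules out multi-thousand-sample landscape
reproductions in pure Python; AST bistability is pinned at the ODE level
and the SSA landscape machinery by constructed bimodal inputs.

## Numerical notes

* Counts are integers, time is continuous; concentration models must be
  converted before stochastic simulation.
* Custom propensities must be finite and nonnegative; violations raise
  naming the offending reaction.
* Exp(·) waiting times are drawn as `standard_exponential()/a0`;
  reaction choice is a linear cumulative scan (R is small in all shipped
  models).
* `N_A = 6.023 × 10²³` (the value the conversion is defined with, kept
  for consistency with B = 6023 rather than the CODATA value).
* Delay samplers returning negative or non-finite τ raise; τ = 0
  completes immediately at the firing instant.
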