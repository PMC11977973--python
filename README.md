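# delaykit

Exact stochastic simulation of biochemical reaction networks **with or
without time delays**, for systems biologists who need trajectory-level
realism that ordinary differential equations and Markovian Gillespie
simulation cannot provide. Transcription, splicing and degradation take
time; a molecule scheduled to disappear τ time units after it was made is
a non-Markovian memory that standard SSA cannot represent.

delaykit provides six interchangeable exact engines behind one driver
contract:

| Markovian | delay-capable |
|---|---|
| `direct` (Gillespie Direct) | `delay_rejection` |
| `first_reaction` | `delay_direct` (piecewise propensity integration) |
| `mnr` (Modified Next Reaction) | `delay_mnr` (MNR + completion queue) |

A reaction fires with propensity `f_r(n)` (mass-action
`c_r·Π_i C(n_i, ν_ri)` or a custom Hill-type function) and applies two
stoichiometric columns: one at firing time, one at completion time
`t + τ`. Delayed reactions are either *consuming* (reactants removed now,
products at `t+τ`) or *completion-only* (everything deferred). Pending
completions live in a time-ordered queue; when a completion becomes
infeasible because another channel consumed its targets, one conflicting
pending event is cancelled uniformly at random.

The package ships the worked model library — bursty transcription,
the three-state refractory promoter, two-phase RNA-velocity kinetics, and
the lung-cancer adeno-to-squamous transition (AST) circuit with its
concentration→molecule conversion (`X = x·V·N_A`, `B = V·N_A = 6023` at
`V = 10⁻²⁰ L`) and a SOX2-degrader intervention modelled as delayed
degradation — plus quasi-potential landscape estimation
(`U = −ln(P+ε)` over 2-D state histograms) and deterministic attractor
counting. See `docs/methods.md` for the science and the numerical
choices.

## Worked example

Bursty gene expression at the published parameters: transcription bursts
arrive at frequency α = 0.0282, burst sizes are geometric with mean
b = 3.46, and every nascent mRNA is removed exactly τ = 120 time units
after synthesis.

```python
import numpy as np
from delaykit import bursty_model, run_ensemble

net = bursty_model(alpha=0.0282, b=3.46, tau=120.0)
grid = np.arange(0.0, 6001.0, 120.0)
ens = run_ensemble(net, [0], 6000.0, grid, n_samples=200, seed=1,
                   engine="delay_rejection")
pooled = ens.pooled(grid[4:]).ravel()
print(f"stationary nascent-mRNA mean: {pooled.mean():.2f}")
print(f"analytic alpha*b*tau:         {0.0282*3.46*120.0:.2f}")
print(f"Fano factor:                  {pooled.var(ddof=1)/pooled.mean():.2f}")
```

```
stationary nascent-mRNA mean: 11.72
analytic alpha*b*tau:         11.71
Fano factor:                  8.12
```

The mean matches Little's law (arrival rate α·b times lifetime τ), and a
Fano factor ≫ 1 is the super-Poissonian fingerprint of bursty
transcription — a plain birth-death process would give 1.

## Command line

```bash
delaykit simulate --preset bursty --algorithm delay_mnr \
    --t-final 1000 --samples 100 --seed 1 --output traj.tsv
delaykit attractors --preset ast --alpha-s 0.2 --seed 1   # -> 2 attractor(s)
delaykit landscape --preset toggle --algorithm direct --t-final 50 \
    --samples 200 --seed 1 --species U V --output landscape.tsv
```

Model configs are JSON (YAML accepted): declared species, reactions with
mass-action rates or propensity expressions (`"50 / (1 + pow(V/20, 2))"`),
and optional per-reaction delays (fixed or sampled). Every preset has an
example config under `examples/`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's headline computations from scratch — the bursty
stationary mean against its analytic value and the AST bistability scan
(1 attractor at αS = 0.05, 2 at 0.2, 1 at 0.8) — logging progress to
stderr and writing the JSON report to the requested path.
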