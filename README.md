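# agrigame

A tested engine for a trilateral evolutionary game of multi-agent
co-governance of agricultural non-point-source pollution.

Agricultural non-point-source pollution — diffuse fertilizer, pesticide and
manure runoff — is a co-governance problem: within one district, **local
governments** decide whether to actively guide green production
(supervision, fines, incentives), **new agricultural operators** (family
farms, cooperatives, agro-enterprises farming a share `α` of the land
transferred from smallholders) decide between green and non-green
production, and **traditional farmers** (on the remaining `1−α`) decide
whether to cooperate — producing green themselves or denouncing polluting
operators — or to stay passive.  All three groups are boundedly rational:
strategies spread by imitation, not best response.

## The model

Let `x, y, z ∈ [0,1]` be the shares of governments, operators and farmers
playing their active strategy.  From the 8-cell payoff matrix over the pure
strategy profiles, the payoff advantage of each active strategy is

```
G(x,y,z) = yzΔSg − yαWe − z(1−α)Wh + (y−1)αzΔWh + (1−y)αPe
E(x,y,z) = α[x(We+Pe) + zLe + ΔSe − Ce + ke·be]
H(x,y,z) = x(1−y)αΔWh + (ΔSh−Ch+kh·bh)(1−α) + x(1−α)Wh
```

and the population shares follow the replicator system

```
ẋ = x(1−x)G,   ẏ = y(1−y)E,   ż = z(1−z)H .
```

Here `ΔSg` is the superior-government reward to active local governments,
`Pe`/`We` the fine/incentive they apply to operators, `Wh`/`ΔWh` the
incentive/denunciation reward to farmers, `Ce`/`Ch` the extra green-production
costs, `ΔSe`/`ΔSh` the extra green-sales incomes, `Le` the operators' loss
from contract termination, and `ke·be`, `kh·bh` each producer group's own
share of future pollution damage.

The package provides:

* **model** — parameter vector with validation, the 8-profile payoff matrix,
  expected utilities and the closed-form drivers `G, E, H`;
* **dynamics** — the replicator vector field, adaptive RK45 integration on
  the (invariant) unit cube, limit diagnosis and first-passage times;
* **equilibria** — all candidate rest points (8 corners, 5 edge candidates,
  2 interior roots of `G=E=H=0`), the analytic Jacobian, eigenvalue
  classification, and the closed-form stability conditions 1–6 (plus
  numeric 7–8 for the interior points);
* **scenarios** — six named policy presets and comparative-dynamics sweeps;
* **sampling** — seeded rejection sampling of parameter sets satisfying a
  chosen stability condition;
* a thin `agrigame` CLI (`presets`, `simulate`, `equilibria`, `conditions`,
  `sweep`) over YAML configs and CSV trajectories.

## Worked example

```sh
python examples/simulate_benchmark.py
```

```
final state at t=300: x=1.000000  y=1.000000  z=1.000000
matched vertex: E8  (residual 1.57e-10)
satisfied stability conditions: [6]
  operators    (y) reach 0.99 at t = 29.9
  governments  (x) reach 0.99 at t = 30.4
  farmers      (z) reach 0.99 at t = 76.0
```

Under the benchmark parameters the system converges to the corner
`E8 = (1,1,1)`: full co-governance.  Condition 6 — the three strict
inequalities making every Jacobian eigenvalue at `E8` negative — holds, so
the limit is an evolutionarily stable outcome.  Operators cross 99%
cooperation first (their scale effect and fine exposure give the largest
payoff advantage), then governments, then farmers.  Other presets flip the
outcome: cutting the superior reward to `ΔSg=0.01` sends the system to
`E7 = (0,1,1)` (governments drop out), and raising green costs to
`Ce=0.9, Ch=0.8` sends it to `E4 = (1,0,0)` (producers defect).  See
`examples/` for the stability census, a green-synergy policy sweep, and
condition-constrained sampling.

Equivalent from the shell:

```sh
agrigame simulate --preset baseline_prop1 --out trajectory.csv
agrigame equilibria --preset baseline_prop1
```

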