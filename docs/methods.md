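# Methods

## Model and assumptions

Three populations of bounded-rationality agents — local governments, new
agricultural operators, traditional farmers — each choose between two
strategies; `x(t), y(t), z(t)` are the shares playing the active strategy
(guide / produce green / cooperate).  Group sizes and district land area are
normalised to 1; operators farm the transferred share `α ∈ (0,1)` of the
land, traditional farmers the rest.  All 21 economic parameters are
dimensionless currency units; no calibration to a real currency is implied
or attempted.

The payoff matrix assigns each of the 8 pure profiles a payoff triple.  Two
damage terms enter only at payoff level: the complements `(1−ke)be` and
`(1−kh)bh` (pollution damage borne by the *other* side).  They are optional
fields: any payoff cell that needs an absent complement raises an explicit
"insufficient parameterization" error, while the dynamics never need them.
We store the producers' own damage shares as the lumped products `ke·be`
and `kh·bh` because nothing in the model ever needs the factors separately;
supplying `ke, be, kh, bh` individually populates both the products and the
complements.

Strategy shares evolve by two-strategy replicator dynamics: each share
grows at a rate proportional to its strategy's payoff advantage over the
alternative, `ẋ = x(1−x)(u_g − u_ḡ)` and likewise for `y` and `z`.  The
advantages have the closed forms `G, E, H` (see the README); the package
verifies on 1000 random instances that they coincide with the
mixture-weighted payoff-matrix differences to 1e-10, which is the central
internal-consistency test of the model code.

Eight "level" parameters (`Sg, Se, Sh, Pg, Dh, Cg` and the two damage
complements) shift both strategies of a player equally and cancel from
`G, E, H`; trajectories are bit-identical under arbitrary changes of them,
and a property test asserts exactly that.

## Numerical integration

The vector field is smooth and three-dimensional; we use adaptive
Runge–Kutta 4(5) (`scipy.integrate.solve_ivp`, RK45) with `rtol = 1e-8`,
`atol = 1e-10`.  Every face of the cube is analytically invariant, and a
coordinate starting at exactly 0 or 1 has exactly zero derivative in
floating point, so faces are preserved identically.  Interior orbits can
leave `[0,1]` only by solver error: excursions up to `clamp_tol = 1e-12`
are snapped to the boundary, larger ones raise an integration error rather
than being silently clipped — the cube is invariant analytically, so a real
excursion signals solver failure.  In practice orbits approach the faces
asymptotically and no overshoot is observed at these tolerances.
Halving both tolerances changes scenario endpoints by far less than 1e-6,
which is tested.

The default horizon is `t_end = 300`; scenarios whose slowest mode is weak
(low superior reward: the farmers' drift is `≈ 0.025`; high land share:
`≈ 0.03`) integrate to `t_end = 2000` so that limit claims, not timing
claims, are what the run decides.  A trajectory counts as converged when
the vector-field norm at its final state is below 1e-8; the limit is
matched to a corner within 1e-3.  "Cooperation reached" uses a 0.99
threshold with linear interpolation between stored solver points.  Crossing
times depend on this (arbitrary) threshold, so only their *ordering* and
*monotonicity* are asserted anywhere, never their values.

## Equilibrium analysis

Corners: all 8 are rest points for every parameter set (logistic factors
vanish); labels E1–E8 follow the standard ordering with E8 = (1,1,1).  At a
corner the Jacobian is diagonal, `diag((1−2x)G, (1−2y)E, (1−2z)H)`, giving
closed-form eigenvalues per corner; these are tested against numerical
eigenvalues of the analytic Jacobian on 1000 random parameter sets, and the
analytic Jacobian against central finite differences.

Edge/face candidates E9–E13 pin one coordinate and zero the two free
advantage functions; their closed-form coordinates are constructed with the
shorthand constants `A = We+Pe`, `B = Ce−ke·be−ΔSe`, `C = ΔSg+αΔWh`,
`D = ΔSh−Ch+kh·bh`, `E = (α−1)Wh−αΔWh`.  Candidates with vanishing
defining denominators are skipped with a logged note; candidates off the
open unit interval are returned flagged inadmissible rather than dropped.
Their stability is evaluated numerically from the Jacobian — no closed
eigenvalue forms are used off the corners — and sampled admissible cases
are confirmed as genuine rest points by an independent multivariate
root-finder.

Interior candidates E14/E15 solve `G = E = H = 0`.  Eliminating
`z = (B − xA)/Le` and `y = [D(1−α) − xE]/(xαΔWh)` reduces the system to
the quadratic

```
(EAΔSg)·x² + [−(1−α)CAD − BCE + AEαLe + BEαΔWh + α²ΔWh·Le·Pe]·x
            + D(1−α)(BC − AαLe) = 0 ,
```

with `F` the square root of its discriminant; a negative discriminant means
no real interior solution.  This closed form was re-derived here and
verified exact on ~10⁴ random candidates.  As a guard against algebra
errors, every returned root is still cross-checked against a numeric
root-finder started at it; on disagreement beyond 1e-6 the numeric root is
returned and a discrepancy warning logged.  Degenerate cases (leading
coefficient or a back-substitution denominator numerically zero) return the
linear root or the empty set with a logged reason.

Classification uses eigenvalue real parts with `eig_tol = 1e-9`:
stable / unstable verdicts require a strict margin, anything within the
tolerance of the imaginary axis is reported non-hyperbolic, where
linearisation proves nothing.  Complex eigenvalues are judged by real part.
The closed-form corner conditions 1–6 are evaluated as strict inequalities;
an inequality holding with equality counts as not satisfied and logs a
degeneracy note.  Conditions 7–8 (interior points) are evaluated
numerically: admissible root with all eigenvalue real parts below −1e-9.
Admissibility everywhere means strictly inside (0,1) with a 1e-9 margin.

One asymmetry is implemented as specified by the model rather than
smoothed: with a passive government and cooperating farmers, a green
operator spares the government the superior punishment `Pg` while a
non-green one incurs it, even though no regulation is active — the payoff
matrix is followed as defined.

## Scenarios and sweeps

The six presets share one benchmark parameter set (`Sg=0.85, Se=0.7,
Sh=0.4, Pg=0.2, Dh=0.1, Cg=0.1, Pe=0.2, We=0.1, Le=0.25, Ce=0.3,
ke·be=0.1, ΔSe=0.25, ΔSh=0.25, Ch=0.25, kh·bh=0.05, Wh=0.1, ΔWh=0.05,
ΔSg=0.5, α=0.5`) and initial shares (0.4, 0.2, 0.3); each variant moves
exactly one policy lever (`ΔSg=0.01`; `Ce=0.9, Ch=0.8`; `α=0.8` / `α=0.1`).
The synergy preset starts from (0.8, 0.5, 0.1) with `ΔSe=0.3`.  These
presets *are* the study conditions; they are not tuned.

Sweeps re-run a scenario across an ordered list of values of one parameter
and compare orbits on a shared 512-point uniform time grid (adaptive
solvers store different time points per run) with linear interpolation.
"Weak trajectory dominance" means the compared component is pointwise
non-decreasing across the swept values up to 1e-7.  The magnitudes of the
synergy-lever increases are not pinned down by the model, only the
direction of the effect; sweeps default to {v, 1.5v, 2v}.  The resulting
monotonicity findings (operator-side levers `ΔSg, Pe, Le, ke·be, ΔSe, We`
raise the whole y-orbit; farmer-side levers `kh·bh, Wh, ΔSh` raise the
z-orbit) are empirical properties of this parameter region verified by the
test suite, not theorems.

## Condition-constrained sampling

For property testing we need parameter sets known to make a given corner
stable.  A rejection sampler draws every parameter uniformly on [0,1]
(`α` on (0.05, 0.95) to avoid near-degenerate land splits, `Sg` shifted
above `Cg` so hard validation passes) and keeps draws satisfying the
requested condition's strict inequalities, with a budget of 100 000 draws —
ample, since the thinnest of conditions 1–6 under this proposal has
acceptance probability around 1e-4.  All randomness flows through an
explicit seed.

## What the synthetic conditions do and do not show

Everything here is a numerical study of the model itself: parameter sets
are either the benchmark presets or uniform random draws, not estimates
from field data.  Passing tests show the implementation is internally
consistent (payoffs ↔ dynamics ↔ Jacobian ↔ conditions) and that the
scenario claims hold for the stated parameter regions.  They say nothing
about whether real districts inhabit those regions: incomes, fines and
damage shares of real governance systems are not modelled, group sizes are
fixed, agents have no social preferences, and consumers of green produce
are outside the model.

## Problem sizes

Test-suite property loops use 1000 random instances for the
payoff-consistency and corner-eigenvalue identities, 200 for the Jacobian,
and a few thousand draws for interior-root cross-checks; scenario
integrations run to t=300–4000.  The whole suite completes in well under a
minute; the acceptance script integrates four deterministic scenarios and
finishes in seconds.
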