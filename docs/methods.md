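# Model and methods

`runtumble` simulates populations of *E. coli* cells as independent agents,
each carrying a dynamical model of the chemotaxis signalling pathway that
drives a run-and-tumble random walk through a static chemoattractant field.
This note records the model, its assumptions, the parameter choices, and the
limitations a user should know before trusting any simulation output.

## The per-cell model

**Receptor module.** Ligand detection follows the two-state
(Monod–Wyman–Changeux) picture: receptors operate in teams of `n_cluster`
dimers that are either kinase-active or inactive as a unit. The free-energy
difference of a team is

    F = n [ α (m₀ − m)
            + w_a ln((1 + [La]/K_off^Tar) / (1 + [La]/K_on^Tar))
            + w_s ln((1 + [Ls]/K_off^Tsr) / (1 + [Ls]/K_on^Tsr)) ]   (kT)

with `m` the mean methylation level, `[La]` MeAsp (sensed by Tar, weight
`w_a`) and `[Ls]` serine (sensed by Tsr, weight `w_s`). Team activity is
Φ = 1/(1 + e^F). Attractant binding raises F and lowers Φ; methylation does
the opposite, closing the adaptation loop. The low-affinity MeAsp–Tsr
interaction is neglected, which is valid at the concentrations the
experiments use (≤ 11 mM MeAsp).

**Adaptation and phospho-relay.** Four state variables per cell — `m` and
the phosphorylated concentrations `Ap`, `Bp`, `Yp` (μM) — evolve as

    dm/dt  = k_R [R]_T (1 − Φ) − k_B Bp Φ
    dAp/dt = k_A Φ ([A]_T − Ap) − k_y Ap ([Y]_T − Yp) − k_b Ap ([B]_T − Bp)
    dBp/dt = k_b Ap ([B]_T − Bp) − γ_B Bp
    dYp/dt = k_y Ap ([Y]_T − Yp) − k_z [Z]_T Yp − γ_Y Yp

CheR methylates inactive receptors at a constant rate while
phosphorylated CheB demethylates active ones, so the methylation balance
pins Φ at a ligand-independent set point: adaptation of CheY-P is exact as
long as `m` stays inside its physical range `[0, m_max]` (it is clamped at
the boundaries, where adaptation becomes imperfect). Both CheZ-mediated
(`k_z [Z]_T`) and spontaneous (`γ_Y`) CheY-P dephosphorylation terms are
present; either can be zeroed in configuration.

**Protein-expression variation.** Cell-to-cell variation in expression is
modelled by one scalar β multiplying all five totals
`[X]_T = β [X]_T0, X ∈ {A, B, R, Y, Z}` — the operon structure keeps the
ratios fixed. Because the bimolecular fluxes scale with β while the
unimolecular ones do not, larger β yields lower phosphorylated *fractions*
at steady state, faster adaptation, and smaller step-response amplitudes on
the fraction-of-total scale. Note that the *absolute* steady-state CheY-P
concentration is monotonically increasing in β in this model structure;
response amplitudes across β are therefore compared as fractions of total
CheY (`StepResponse.amplitude_fraction`), the scale on which cells with
different protein content are commensurable.

**Motor.** CheY-P sets the clockwise (tumble) bias through the Hill law

    Bias = 1 / (1 + 3.7 (Yp*/Yp)^5.5)

where `Yp*` is the cell's own unstimulated steady-state CheY-P, computed at
the far-field background concentration at initialization (and recomputed
when β changes). At `Yp = Yp*` the bias is 1/4.7 ≈ 0.213. Each timestep one
uniform draw `r` decides the flagellar state: tumble iff `Bias > r`.

**Swimming.** Runs translate at constant speed c = 29 μm/s along the
heading θ (measured clockwise from +y): dx/dt = c sin θ, dy/dt = c cos θ.
A tumble adds a random turn — random sign times Uniform(18°, 98°), mean
|turn| 58° — and then translates for the full timestep along the new
heading (tumbles are far shorter than a timestep, so the cell never
pauses). The domain is [−2, 2]² interpreted in millimetres (hence
c = 0.029 domain units/s); the default boundary is solid (coordinates
clamped to the wall), with periodic wrapping available.

**Per-step loop.** Each timestep (default dt = 0.0144 s; 50,000 steps ≈ 12
min): evaluate the field at the cell's position → integrate the cascade
over dt with the ligand frozen (quasi-static) → compute the bias from the
new CheY-P → Bernoulli run/tumble decision → move → apply the boundary.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| [A,B,R,Y,Z]_T0 | 5, 2, 0.3, 9.7, 1.1 | μM | literature-scale copy numbers |
| k_A | 50 | 1/s | fast receptor-coupled autophosphorylation |
| k_y, k_b | 100, 15 | 1/(μM s) | phosphotransfer branch ratio favouring CheY |
| k_z | 11.1551042 | 1/(μM s) | calibrated so background Yp* = 4.043 μM |
| γ_Y, γ_B | 0.1, 1.0 | 1/s | slow spontaneous dephosphorylation |
| k_R, k_B | 0.0075 | 1/(μM s) | adaptation ≈ 40 s (β=1), 2 s – 2.5 min across β |
| n_cluster | 54 | dimers | high-gain signalling team |
| w_a : w_s | 1 : 2 | — | measured Tar:Tsr abundance ratio |
| K_off/K_on (Tar) | 0.02 / 0.3 | mM | MeAsp sensitive range |
| K_off/K_on (Tsr) | 0.001 / 1.0 | mM | serine sensitive range |
| α, m₀, m_max | 1.7, 1.0, 4.0 | kT, —, — | standard methylation energetics |

No complete published rate-constant set is bundled with the package, so
this default set is the package's own: totals at
literature scale, `k_z` solved once so that the unstimulated steady state
at the 0.1 mM MeAsp background is exactly the 4.043 μM CheY-P level that
anchors the motor curve, and the receptor/adaptation constants chosen so
the closed loop reproduces the qualitative population phenomena the
simulator exists to study (strong accumulation at a d = 1 attractant peak
with final/initial distance ratios ≈ 0.1–0.15; complete capture by the
serine gradient at scaling υ = 0.1 in competition with MeAsp; majority
capture by MeAsp when serine is negligible). Replace the whole set via the
`cascade:` block of a config file when a transcribed published set is
available.

Single-ligand behaviour depends on the receptor constants only through the
products `n_cluster · w_a` (signal gain) and `n_cluster · α · k_R` (adaptation
speed in free-energy units) — parameter sets matching in these products
produce bit-identical trajectories, which the tests exploit as a consistency
check.

## Numerics

* **Steady states** are computed algebraically, not by time-stepping: for a
  candidate activity Φ the phospho-relay fixed point reduces to a scalar
  root in `Ap` (bracketed on [0, [A]_T]); the methylation balance then
  becomes a scalar root in Φ on (0, 1); the adapted `m` follows by
  inverting F. The result is verified against a 10⁻⁹ derivative tolerance.
* **Single-cell integration** (`integrate_cascade`, `step_response`) uses
  LSODA (stiff-capable, adaptive) at rtol 10⁻⁸/atol 10⁻¹⁰; a test checks
  one step against a fixed-step RK4 reference at dt/100 to 10⁻⁶ relative.
* **Population integration** uses a vectorised backward-Euler step with
  Newton iteration (analytic 4×4 Jacobian, batched linear solves,
  convergence 10⁻¹¹). Backward Euler is L-stable, so the fast phospho
  rates (up to ~10⁴/s at high β) pose no stability constraint at
  dt = 0.0144 s; the slow methylation dynamics that control behaviour are
  resolved accurately (tested against LSODA at 2% on CheY-P over a
  200-step transient). States are clamped to their physical ranges after
  each step.
* **RNG discipline.** One master seed spawns an initialization stream plus
  one PCG64 stream per cell (`numpy` SeedSequence). Every cell consumes
  exactly three uniforms per step — decision, turn sign, turn magnitude —
  whether or not it tumbles, so trajectories replay exactly; the
  experiment drivers derive per-simulation child seeds from the master
  seed. Ties in the tumble decision (`Bias == r`) resolve to run.
* **Paired initialization.** When a population mixes several β values the
  subpopulations share initial positions and headings block-wise (common
  random numbers). Marginally nothing changes; comparisons of final
  accumulation between β subpopulations lose the initial-position
  variance. Set `paired_init: false` for fully independent draws.
* **Hill fits** of fraction-attracted versus υ are least squares in
  (log K, n) — a logistic in ln υ — with a 25-point multi-start over log K
  and n ∈ {1, 3} to avoid local minima.
* The equilibrium diagnostic (population mean distance changing < 2% over
  the final tenth of a run) is reported in summaries, never enforced.

## What the experiments show, and scale choices

The β-sweep experiment places a mixed-β population (default eight values
1/4 … 10) in a single MeAsp bump of steepness d ∈ {10, 1, 0.1} and tracks
mean distance to the peak; the competition experiment places one
population between a MeAsp bump at (−1, 0) (scaling ω) and a serine bump
at (+1, 0) (scaling υ) and classifies cells by the sign of their final x.
The test suite runs these scaled down — 20 cells per condition, and
10,000 steps for the β-sweep — to keep the whole suite inside a normal CI
budget; the competition runs use the full 50,000 steps because crossing a
4 mm domain at 29 μm/s takes most of those 12 minutes, and the
all-cells-to-serine outcome at υ = 0.1 is unreachable in a fifth of the
time.

A structural caveat on the steep gradient (d = 0.1): its Gaussian core has
scale √(d/2) ≈ 0.22 in a 4×4 domain, so with uniform initial positions
roughly 80% of cells never encounter a detectable gradient within 12
minutes (capture diagnostics in the development history: ~20 of 100 cells
ever reach r < 0.5; for β = 4 all of those end trapped at r ≈ 0.09, for
β = 1/4 they leak back out). Mean-distance differences between β
subpopulations in the steep field are therefore small (~0.06 domain
units) relative to 20-cell sampling noise (~0.15), and the corresponding
ordering test can fail stochastically even though the effect direction is
systematic. This is a transport limitation of the physical setup, not a
tunable property of the cascade.

## What the model does *not* capture

No cell–cell interactions, growth, division, or ligand consumption; fields
are static. Swimming is two-dimensional, at constant speed, without
rotational diffusion during runs, variable run speeds, or hydrodynamic
wall effects (the ±6 μm/s and ±40° experimental spreads are treated as
measurement uncertainty, with an optional per-cell speed jitter left off
by default). Chemical kinetics are deterministic ODEs — no molecular
noise — so all population variability comes from initial conditions and
motor/turn randomness. CheW is folded into the receptor–kinase coupling;
receptor clusters have no spatial structure. Passing tests therefore
demonstrate the closed-loop logic of gradient sensing, adaptation and
accumulation under these idealisations, not quantitative agreement with
any particular experimental dataset.
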