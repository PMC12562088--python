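# Methods

## Model

Four scalar fields live on a rectangular 2D tissue domain: endothelial
density `n`, TAF concentration `c`, drug `d`, oxygen `o`. Discrete agents —
off-lattice tumor cells and lattice-bound endothelial tip cells — act on the
fields as moving sources and sinks through normalized disk indicator kernels
of radius `Rc`, and sample the fields to drive their own rules. All work is
done in nondimensional variables: lengths scaled by L = 5 mm (parent-vessel
to tumor distance), time by the diffusion time τ = L²/D = 5.76e4 s,
concentrations by (n0, c0, d0, omax). The shipped default parameter set is
the published nondimensional reference table; `params.nondimensionalize`
maps SI values onto it and `params.validate_against_reference` audits the
map against the printed values.

Field equations (nondimensional):

* TAF: `∂t c = Dc Δc − ξc c + η Σ_hypoxic φa − λ c Σ_vessel φv`
* drug: `∂t d = Dd Δd − ξd d − ρd d Σ_tumor φa + Sd(t) Σ_vessel φv`
* oxygen: `∂t o = Do Δo − ξo o − ρo Σ_tumor φa + So (1 − o) Σ_vessel φv`
* endothelium (continuum form): `∂t n = Dn Δn − ∇·(χ(c) n ∇c)` with
  saturating sensitivity `χ(c) = χ0/(1 + α c)`.

Michaelis–Menten uptake variants (`ρ d/(Kd+d)`, `ρ o/(Ko+o)`) and a
Michaelis–Menten branching intensity are selectable; they require the
half-saturation constants `Kd`, `Ko`, `Kc`, which have no reference values
and hence no defaults. Dosing is continuous or pulsed (`Sd(t)` on/off
windows).

Assumptions inherited from the model family: linear isotropic transport,
fixed per-cell consumption, no efflux, no mechanical cell–cell forces, no
vessel pruning, neutral (cost-free) mutations, 2D geometry with Neumann
(or periodic, for the spectral tools) boundaries.

## Agent rules

Tumor cells carry sensed oxygen, cumulative drug exposure, DNA damage, a
death threshold, age, cell-cycle duration, and mutable traits
(`alpha_n` proliferation rate, `th_multi` resistance factor, `rho_o_mult`
oxygen-uptake weight). Per agent step of size Δt′ a cell senses (bilinear
interpolation; nearest-node is a config option), is classified by oxygen
(normoxic `o > 0.25`, hypoxic `0.05 < o ≤ 0.25`, apoptotic `o ≤ 0.05`,
removed immediately), accumulates damage `a' = d − p_r a` and dies at once
when damage exceeds its threshold, may mutate, ages only while normoxic and
divides when age ≥ log 2/alpha_n unless more than Fmax = 10 neighbors crowd
within one cell radius (the division is then retried next step with age
retained). Daughters split damage and drug load in half, inherit traits,
and are offset by 0.1·(cos 2πθ·Δx, sin 2πθ·Δy); θ is resampled (≤ 64
attempts) while the offset coincides with an existing center. Mutation is a
time-continuous Poisson process (`P = 1 − exp(−µΔt′)`); each mutable trait
is independently rescaled by r ~ Uniform[0.7, 1.7] and clamped to
[0.5, 4] × its baseline. Motion is reflected Brownian displacement with
amplitude ε = 0.0215. The per-cell update order is sense → classify →
apoptosis/damage death → mutate → age/divide → move; death precedes
division so dead cells cannot proliferate.

Tip cells occupy lattice nodes. Each step they age, may branch (Poisson
intensity `c_br · c/max(c) · 1{age ≥ ψ}` with ψ = 1.125; both tips' ages
reset; daughter on a random vacant Moore neighbor), migrate to a von
Neumann neighbor sampled from the chemotaxis movement probabilities, and
proliferate on a fixed doubling clock τ_tip = 1.125 (stalk segment behind,
tip advances along its heading). Any move into a site holding a tip or
vessel is an anastomosis: the mover's node joins the network and the tip
retires. Vessel sites are permanent; the network is the union of all
visited sites. Tips are updated in randomized order per step so that
collisions resolve by first-claim. The initial vasculature is a
config-specified parent vessel: a line of sites along one edge with k
equally spaced tips seeded one node inward, headed into the tissue (tips
placed directly on the parent line would anastomose into it on their first
move).

## Numerics

**ADI.** TAF, drug and oxygen advance by the Douglas scheme: two tridiagonal
half-sweeps per step, reactions evaluated explicitly at the start-of-step
state in both half-sweeps. Tridiagonal systems are solved exactly
(LAPACK banded solver; Sherman–Morrison closure for periodic wrap). The
Neumann closure is the mirror ghost node. Two consequences verified by the
test suite: (i) the scheme conserves the *trapezoid-rule* mass exactly
(boundary nodes weight ½) — domain integrals and kernel normalization use
that quadrature, making source/sink bookkeeping sharp; (ii) with the
explicit start-of-step reaction the reaction integration is forward Euler:
local truncation O(Δt² + h²), global error first order in Δt for stiff
reactions and second order for pure diffusion. Oxygen is never clipped in
state; the saturating supply keeps `o ≤ 1` up to discretization error.

**Chemotaxis.** The endothelial update is the explicit probabilistic
finite-difference scheme: per-node stay/left/right/down/up weights
combining symmetric diffusion `Dn Δt/Δx²` with centered chemotactic bias
`(Δt χ0/4Δx²)(1/(1+αc_nb) + 1/(1+αc_c))(c_nb − c_c)`. The continuum step
applies these weights donor-wise — each node redistributes its own mass,
and the five weights sum to exactly one before clipping — which is
algebraically identical to the conservative flux-form update with
arithmetic-mean half-index interpolation. Raw weights are clipped at zero
and renormalized; under the CFL bounds

    Δt ≤ min( Δx²/(4 Dn), Δx/(2‖χ(c)∇c‖∞), 1/(4Dn/Δx² + 2‖χ(c)∇c‖∞/Δx) )

and the mesh constraint `Δx ≤ 2 Dn/‖χ(c)∇c‖∞` the clipping is a no-op and
the scheme is simultaneously mass-conserving (to rounding), nonnegative,
and consistent. In the nonlinear pattern regime the mesh constraint is
transiently violated (chemotaxis dominates the very small Dn); there the
clip-then-normalize step acts as a flux limiter that keeps the update
nonnegative and exactly mass-conserving at the cost of local first-order
accuracy — without it the unlimited scheme exhibits aggregation blow-up.
`cfl_dt` recomputes the admissible step from the current TAF field and
reports mesh-constraint violations; `endothelial_step` refuses steps above
the bound. Agent sampling uses the same weights at the agent's own node
with half-open cumulative intervals ([lo, hi), final interval closed at 1;
the tie has probability zero).

**Hybrid loop.** Each global iteration refreshes the agent kernels,
advances the fields by m substeps of Δt = Δt′/m (default Δt′ = 0.1), then
runs one agent pass. Two stabilisation choices are the package's own: the
PDE substep is further refined so that Δt_sub × (largest linear reaction
coefficient) ≤ 0.25 — with reference per-cell rates and kernels
concentrated on single nodes the sink coefficients reach ~1e4 and an
unrefined explicit reaction diverges — and tumor agents sample fields only
at the agent cadence, accepting O(Δt′) splitting error. The continuum `n`
field and the discrete tip agents are alternative endothelial
representations selected by `endothelial_mode`; reduced-subsystem studies
use the continuum field, full hybrid runs the agents.

## Stability toolkit

`stability` implements the dispersion relation of the reduced n–c
subsystem (see README for the formulas), the Turing band, rectangular
eigenmode tables (Neumann and periodic), critical lengths, the infinite-
and finite-domain production thresholds, bifurcation scans over admissible
discrete modes (zero below threshold by convention), and dominant-mode
prediction (`λ*` by bounded golden-section maximization of Re σ₊ — robust
near band edges — and `λ_j0` the nearest admissible eigenvalue, spacing
`2π/√λ_j0`). Band admissibility is strict: `0 < λ < λ̄`. The eigenvalue
symbol λ is kept distinct from the TAF uptake rate (`lam_uptake`) in code.

Two reference-value caveats found while validating: the printed
infinite-domain threshold 2.4281e-6 does not follow from its own formula
`Dn ξc/((χ0 − Dn α) n0)`, which evaluates to 1.5464e-5 with the reference
parameters (the returned value satisfies the marginality identity
`Dn ξc = ηn0 χeff(ηn0) n0` to 1e-12, so the formula, not the printed
number, is implemented); and the printed cell-radius row equals the cell
*diameter* in nondimensional units (2Rc = Δx = 0.005) — the reference
table value 0.005 is kept as the default, and the conversion disagreement
is surfaced by the validation report.

## Reduced-subsystem simulator and scenario presets

`turing_sim.simulate_nc` integrates the n–c subsystem from the uniform
steady state with independent uniform noise of relative amplitude 1e-2 on
n only (c starts exactly at steady state; both choices are config
options), under an adaptive CFL step with 0.9 safety. Scenario presets:
I (reference set, ηn = 1, unit square — critical length 1.6602 > domain,
no pattern), II (Dc = 0.06, ξc = 0.01, χ0 = 1.198 — critical length
0.1179, pattern), III (as II with ηn = 0 — unidirectional, no pattern, c
collapses to zero), IV (as II with Dn × 100 — critical length 1.1931, no
pattern). A pattern is flagged when the final spatial standard deviation
of n exceeds 10 × its initial value; the threshold is a package decision
(the source outcomes are reported visually). Spectra use the type-I DCT,
whose basis functions are exactly the Neumann eigenmodes at the nodes.

Mode-identity caveat: in Scenario II the dispersion curve is nearly flat
across several admissible modes (growth rates 0.246–0.276 for spacings
0.5–0.894), so which mode dominates the final pattern is noise- and
nonlinearity-driven. The prediction-vs-simulation cross-check therefore
asserts that the emergent dominant mode lies strictly inside the band and
grows at ≥ 85% of the maximal linear rate, rather than pinning the spacing
to the single nearest-to-λ* eigenvalue.

## What the synthetic conditions do and do not show

All inputs are generated in code: parameter sets, perturbed steady states,
seeded agent populations and parent vessels. Passing tests demonstrate
that the schemes have their stated conservation/positivity/consistency
properties, that the analytic pipeline reproduces the published numbers,
and that pattern onset in direct simulation agrees with linear theory.
They do not calibrate the hybrid model against biological data: the
reference per-cell rates make oxygen strongly supply-limited (tumor
populations far from vessels die out quickly), mutation intensity µ has no
published value (default 0), and the full hybrid biology (resistant-niche
emergence) is exercised through invariants — vessel monotonicity, two-way
coupling, dosing bookkeeping, inheritance conservation — rather than
numeric endpoints. Simulation sizes used in the tests (50×50 grids to
t = 30 for the dichotomy, 25×25 hybrid runs to t ≤ 10) were chosen as the
smallest at which the checked properties are clearly resolved.

## Known limitations

2D only; Neumann/periodic boundaries only; no efflux, pruning, mechanics,
flow, or immune/stromal compartments; continuum and agent endothelium are
not co-evolved; the donor-clip chemotaxis limiter is first-order where it
activates; explicit reactions make stiff full-rate hybrid runs slow
(the substep refinement trades time for stability).
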