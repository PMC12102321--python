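# Methods

## Model

`woundpde` simulates the closure of a radially symmetric diabetic dermal
wound.  The wound is the disk 0 ≤ r ≤ R(t); the annulus R(t) ≤ r ≤ B of
partially healed tissue carries twelve interacting fields (all in g/cm³):
M1 and M2 macrophages, fibroblasts F, senescent fibroblasts F_s,
endothelial cells E, extracellular matrix ρ, the cytokines PDGF, TNF-α,
TGF-β, IL-6 and VEGF, and oxygen w.  Healthy tissue beyond r = B pins
Dirichlet values (cells at their healthy steady states; each cytokine at
its half-saturation K_X, the serum steady-state assumption).

The tissue is a single-phase upper convected Maxwell fluid on the slow
healing timescale, reduced to the quasi-static scalar velocity problem

    (1/r) ∂_r(r ∂_r v) − v/r² = ∂_r Ψ,   v(B) = 0,   ∂_r v|_R = Ψ(ρ(R)),

with the ECM pressure Ψ(ρ) = 0 for ρ ≤ ρ₁ and γ(ρ/ρ₁ − 1) above the
threshold.  The wound edge moves with the tissue, dR/dt = v(R(t), t), and
the percent wound closure is PWC(t) = 100·(R(0) − R(t))/R(0).

Cell species are transported by diffusion, advection with v and — for M1
and F toward PDGF, for E toward VEGF — chemotaxis with flux χ X ∂_r A.
Cytokines and oxygen diffuse only (their advection is negligible against
their large diffusivities); ρ is advected without diffusion and needs no
wound-edge boundary value (outgoing characteristic).  At the wound edge
the chemotactic cells satisfy a zero total-flux balance, PDGF receives a
platelet influx −∂_r P = β_P R(t), and the remaining species are no-flux.

Biological age is the pair (η, A₀) ∈ [0, 1]², both decreasing with
chronological age: η scales escape from the fibroblast→senescent
conversion (the rate carries a factor 1 − η), and A₀ is the amplitude of
the decaying VEGF-production factor A(t) = A₀/(1 + t²/T_w²) applied to the
fibroblast and senescent-fibroblast VEGF sources (the M2 source is not
age-scaled).  Diabetes enters as two constant blockades: B₁ divides the
constant M1→M2 polarization rate and B₂ divides the endothelial
maturation source.  Oxygen gates the biology through G(w) = w/(w₀ + w)
(proliferation of F and M2) and the hypoxic-death switch D(w) = H(w_i − w),
with the convention H(0) = 0 and an optional logistic smoothing width for
stiff runs (default sharp).

Treatments: quercetin is a constant scalar dose Q (its 15–28 h half-life
justifies dropping pharmacokinetics for a daily pill) that boosts
fibroblast proliferation by (1 + λ_FQ Q), boosts ECM production by
(1 + μ_ρQ Q) and clears senescent fibroblasts at μ_FsQ Q.  HBOT is a
pulsed volumetric oxygen source γ_w h(t) active in a daily window
(12:00–14:00 by default) plus an elevated oxygen boundary value at r = B
that accrues the dose integral within each window (accrual restarting at
each day's window start; a switch selects the alternative reading that
accrues from the start of treatment).

## Parameter provenance

All constants live in `ModelParameters`, in g/cm³–cm–day units.  Loss
rates follow μ_X = ln 2 / t_half with half-lives quoted in days.
Production rates close the kinetic equations at the healthy steady state
(`derive_steady_state_parameters` returns each rate annotated with the
identity it solves, and a residual check).  A few published values do not
satisfy their own stated identities (the M1 influx A_M1, the PDGF rates
λ_P, μ_PF, λ_FP and the VEGF production family); the package keeps the
published numbers as simulation baselines and the derivation API exposes
the discrepancy rather than silently resolving it.  The PDGF boundary-flux
coefficient β_P is not published; the default β_P = K_P/(R(0)(B − R(0)))
= 8×10⁻⁶ g/cm⁴ makes the initial PDGF profile peak at the physiologic
scale K_P, and it is fully configurable.  An optional first-order oxygen
decay μ_w exists but is off by default, since the oxygen steady-state
identity that fixes λ_Ew was closed without it.  Table entries that are
mutually inconsistent with the surrounding text (the polarization-rate
pair λ_M1M2Tβ/λ_M2M1Tα, λ_M1M2, and the senescent-fibroblast steady state
F_s⁰ = 1.5×10⁻³) follow the tabulated values.  IL-6 lacks a published
diffusivity; it uses the VEGF value 8.64×10⁻² cm²/d (comparable size).

## Discretization

Front fixing: ξ = (r − R(t))/(B − R(t)) maps the annulus to [0, 1] with a
uniform grid of n intervals (default n = 200), adding the mesh-motion
advection term (1 − ξ)(dR/dt) ∂_r X to every field.  The velocity BVP has
an exact first integral (1/r)∂_r(rv) = Ψ + C, which yields a closed
quadrature solution evaluated with cumulative trapezoids — second order in
the spacing and exact for piecewise-linear rΨ, so the constant-pressure
closed form is reproduced to machine precision.

Transport is finite-volume in r on the mapped grid: central second-order
diffusion, first-order upwind for material advection, chemotaxis and the
mesh term.  The wound-edge node is a half cell with the physical flux
conditions imposed on its inner face (zero total flux, or the PDGF
influx); the ECM node there follows the local characteristic balance
ρ_t = −ρ(∂_r v + v/r) + F_ρ.  Time stepping is IMEX: backward Euler for
diffusion and for the stiff linear losses (cytokine degradation up to
495 d⁻¹, and the VEGF receptor sink μ_EV E/(K_V + V), lagged in the
coefficient), forward Euler for everything else, with an advective CFL
cap (Courant 0.4), step halving on positivity or finiteness failures, and
forced step boundaries plus a finer dt cap (10⁻³ d vs 10⁻² d) inside HBOT
windows.  Fields are floored at zero after each accepted step; a step is
rejected if any field dips below −10⁻⁶ of its healthy scale.  The map
degenerates as R → 0, so closure is declared at R ≤ R_min = 10⁻² cm
(1% of the initial radius) and reported as PWC = 100.

Default problem sizes: n = 200 for single runs and tables; a reduced
profile (n = 60, dt ≤ 2×10⁻² d) for dense (η, A₀) sweeps and sensitivity
screening, validated by the grid/time convergence checks in the test
suite (PWC(30) changes ≤ 0.5 percentage points under n-doubling and
dt-halving at the default profile).

## Sensitivity analysis

`lhs_sample` draws a Latin hypercube (one draw per equal-probability
stratum per dimension, seeded) over the sixteen production/transition
rates, ±50% of baseline except ±10% for the ECM production rate λ_ρ.
`prcc` rank-transforms design and output (average ranks on ties) and
correlates the residuals of each parameter and the output after linear
regression on the ranks of the remaining parameters; significance uses
the t statistic with N − 2 − (k − 1) degrees of freedom.  With one
parameter the PRCC reduces exactly to the Spearman correlation, which the
tests verify, and a Monte-Carlo null check confirms the nominal type-I
error.  The output statistic is PWC at day 30 for a configurable scenario
(default: untreated, oldest patient — the published analysis does not
state its scenario or sample size; N defaults to 200).

## What the simulations show — and a reproducibility caveat

The structural behavior of the implementation is verified against
independent oracles: the velocity solver against closed forms and a
manufactured solution, advection against characteristics, the kinetics
against steady-state identities and sign structure, LHS/PRCC against
analytic cases.  However, under the published baseline constants the
mechanics are strongly driven: healthy-density ECM (ρ₀ = 5ρ₁) carries a
pressure Ψ = 0.76 d⁻¹, which produces edge speeds of order 0.2–0.3 cm/d,
and the oxygen field equilibrates to its healthy boundary value across
the annulus within hours (D_w = 2 cm²/d against a consumption rate of
order 10⁻² d⁻¹), so the tissue never becomes hypoxic.  As a result every
scenario — treated or untreated, young or old — reaches full closure
within roughly two weeks, treatment and age shift closure times only
marginally, and the combination-only-treatable age region at day 30 is
empty.  Published results for this class of model report far slower
untreated closure and oxygen-limited healing, implying additional damping
(for example a much larger effective viscosity in the velocity problem or
much slower effective oxygen transport) not derivable from the published
constants.  The package implements the equations and constants exactly as
stated and reports what they produce; the `scripts/acceptance.py` output
is computed, never transcribed.

## Known limitations

One spatial dimension (radial symmetry, no wound depth); no neutrophil /
early-inflammation phase and no remodeling/scar phase; quercetin has no
pharmacokinetics; the hypoxia switch is discontinuous by default; the
mapping of (η, A₀) to measurable biomarkers is outside the model's scope.
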