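# woundpde

A free-boundary PDE model of diabetic wound closure under biological aging,
hyperbaric oxygen therapy (HBOT) and the senolytic quercetin (Q).

Diabetic dermal wounds (e.g. foot ulcers) are chronically inflamed,
ischemic, and heal poorly without intervention — particularly in older
patients, whose senescent fibroblasts impair tissue regeneration.  This
package is for modelers and quantitative wound-healing researchers who want
to simulate how a wound's radius R(t) responds to age and treatment, and to
reuse the model for new biological-age scenarios.

## The model

Twelve fields live on the shrinking annulus R(t) ≤ r ≤ B of partially
healed tissue: M₁, M₂ macrophages, fibroblasts F, senescent fibroblasts
F_s, endothelial cells E, extracellular matrix ρ, the cytokines PDGF (P),
TNF-α, TGF-β, IL-6, VEGF, and oxygen w.  Each species X obeys a transport
balance

    ∂X/∂t + (1/r)∂_r(r v X) − D_X (1/r)∂_r(r ∂_r X) = F_X,

with chemotaxis fluxes −χ X ∂_r A for M₁, F (toward PDGF) and E (toward
VEGF), and cytokines diffusing without advection.  The tissue velocity v
solves the quasi-static viscoelastic balance
(1/r)∂_r(r ∂_r v) − v/r² = ∂_r Ψ with the ECM pressure
Ψ = γ(ρ/ρ₁ − 1)⁺, and the wound edge moves with the tissue:

    dR/dt = v(R(t), t),     PWC(t) = 100·(R(0) − R(t))/R(0).

Biological age is the pair (η, A₀) ∈ [0, 1]²: η scales escape from
fibroblast senescence (factor 1 − η) and A₀ scales fibroblast-derived VEGF
production through A(t) = A₀/(1 + t²/T_w²).  Diabetes adds the blockades
B₁ (M₁→M₂ polarization) and B₂ (endothelial maturation).  Quercetin is a
constant dose Q enhancing F proliferation and ECM production and clearing
F_s; HBOT is a pulsed daily oxygen source γ_w h(t).  See `docs/methods.md`
for the discretization and parameter provenance (including a
reproducibility caveat about the published baseline constants).

## Worked example

```python
from woundpde import (AgingProfile, ModelParameters, TreatmentSchedule,
                      derive_steady_state_parameters, run_simulation)

params = ModelParameters()            # published baseline constants

# steady-state parameter derivation, annotated with its identity
lam_rho = derive_steady_state_parameters(params)["lam_rho"]
print(f"lam_rho = {lam_rho.value:.2f}/d   from   {lam_rho.identity}")

# untreated wound, oldest patient (eta, A0) = (0, 0)
res = run_simulation(params, AgingProfile(0.0, 0.0), TreatmentSchedule.none(),
                     horizon=30.0)
print(f"status={res.status}  R(end)={res.R[-1]:.3f} cm  PWC(30)={res.pwc_at(30.0):.1f}%")
```

prints

```
lam_rho = 21.71/d   from   lam_rho * F0 * (1 - rho0/rho_m) = mu_rho * rho0
status=closed  R(end)=0.010 cm  PWC(30)=100.0%
```

The first line recovers the published ECM production rate from its
steady-state identity.  The second line is the faithfully integrated
model under the published constants: the ECM pressure of healthy-density
tissue (Ψ(ρ₀) ≈ 0.76/d) drives edge speeds of ~0.2 cm/d, so the wound
reaches the closure radius (1% of R(0)) well before day 30 even without
treatment — much faster than published simulations of this model class;
`docs/methods.md` discusses this gap and what additional damping would be
required to reproduce slow, oxygen-limited closure.

The same workflows are available from the shell:

```sh
woundpde simulate --out out/ --horizon 30
woundpde table --roster table2 --out table2.csv
woundpde sweep --arm HBOT --eta 0:1:11 --a0 0:1:11 --out hbot.csv
woundpde region --hbot hbot.csv --qhbot qhbot.csv --out region.json
woundpde sensitivity --n 200 --seed 42 --out sens/
```

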