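# Methods

## Scope and model structure

`pmadjoint` is a desk-scale analogue of an adjoint health-burden study: a
reduced chemical-transport model small enough that every correctness claim
can be tested exactly, carrying the full methodological chain — chronic
exposure, concentration-response, adjoint forcing, backward sensitivity
accumulation, monetization, and attribution. It is not a fidelity model of
any real airshed: there is one vertical layer, a stylized three-channel
inorganic mechanism, and synthetic inputs. What transfers to real systems is
the *method* and its verification discipline, not the magnitudes.

## Forward model

State: per-species concentrations (μg/m³) on an nx×ny grid of square cells
with a single well-mixed layer of depth H (default 800 m), advanced with a
fixed operator-split sequence each sub-step:

1. **inject** — E (tons/hr) adds E·10¹²·Δt/(A·H) μg/m³ to the cell;
2. **chemistry** — forward-Euler first-order gas→particle conversion,
   per-channel base rates (SO2→pSO4 0.03/h, NOx→pNO3 0.04/h, NH3→pNH4
   0.05/h, unit yields) scaled by an hourly temperature index;
3. **deposit** — exact exponential loss, c·e^(−kΔt) per species;
4. **advect** — donor-cell upwind in flux form, face velocities the mean of
   adjacent cell-center winds;
5. **diffuse** — explicit 5-point stencil.

The order is load-bearing: the adjoint applies the transposes in exactly
the reverse order, and the closed-form box solution below depends on
injection preceding deposition within the hour.

Advection and diffusion are assembled as sparse matrices per hour, so their
adjoints are literal matrix transposes. Flux-form advection conserves mass
under the periodic boundary for *any* wind field; it leaves a uniform field
unchanged only when the discrete (central-difference) divergence of the
winds vanishes. The generators therefore derive winds from a streamfunction
by central differences, which makes that divergence identically zero; the
two properties (conservation for any wind, uniform-field invariance for
generated winds) are tested separately. Under the default zero-inflow
boundary, outflow faces use the interior donor cell and inflow faces carry
zero flux (mass non-increasing); diffusion uses no-flux walls.

Stability is checked up front: the run refuses to start unless the combined
Courant number max|u|Δt/Δx + max|v|Δt/Δx ≤ 1 (the two-dimensional
donor-cell positivity condition — slightly stronger than per-axis checks)
and KΔt/Δx² ≤ 1/4. The timestep is 1 h by default; sub-stepping is
supported, but the trajectory is stored hourly regardless, and the box-model
test confirms first-order convergence of the discretization as Δt shrinks.

### Titration chemistry

In titration mode the NOx→pNO3 channel's first-order rate coefficient
becomes k_t·max(0, O3bg − γ·[NOx]): reacted mass R = k_t·max(0, O3bg −
γ·NOx)·NOx·Δt. ∂R/∂NOx = k_t·Δt·(O3bg − 2γ·NOx) on the active branch, so
marginal NOx *increases* nitrate at low NOx and *decreases* it beyond
NOx = O3bg/(2γ) — the NOx-inhibited regime in which annual source impacts
go negative. At the kink of the max (and where the reacted fraction is
clipped at 1) the subgradient 0 is used, a deterministic tie-break. The
forward run records, per sub-step, each channel's loss fraction and its
derivative with respect to the gas — the only state the adjoint needs to
linearize about the stored trajectory (full hourly checkpointing, no
recomputation windows; at this scale memory is not a constraint).

## Cost function and adjoint forcing

Chronic exposure is the mean total PM2.5 (primary + secondary species) over
the stored end-of-hour states after a forward spin-up window (default 24 h
of 240 h). GEMM maps it to attributable deaths; the adjoint forcing is the
exact chain-rule gradient

    ∂J/∂PM̄_i = M0_i·P_i·θ·e^(−θT(z_i))·T′(z_i),
    T′(z) = ω(z)/(α+z) + log(1+z/α)·ω(z)(1−ω(z))/ν,

zero for PM ≤ C_f (the one-sided derivative from below at the threshold),
spread uniformly over the effective hours — the only time-symmetric
allocation for a cost defined on a time mean — and applied identically to
every particulate species (GEMM is mass-based; a μg is a μg). The gradient
is validated against central differences of J rather than trusted.

A `LinearCost` (J = Σ w_i·PM̄_i) exists alongside the GEMM cost: with linear
chemistry it makes the adjoint gradient, brute-force differences, and the
f-fraction burden identity exact to round-off, which turns several
acceptance checks into equalities instead of tolerances.

## Backward sweep and units

The adjoint state λ starts at zero, receives the hour's forcing, and is
propagated backward through the transposed sub-operators. Immediately before
each (reversed) injection, λ **is** ∂J/∂(pre-injection concentration); the
emission sensitivity for that hour is λ times the same tons→μg/m³ conversion
the forward injection uses. Internal units are deaths/ton (or USD/ton);
deaths/kton is a ×1000 reporting view.

In the 1×1 calm box with deposition k and constant hourly forcing φ this
telescopes to a geometric series: the sensitivity to an emission in hour n is

    conv · φ · e^(−k) · (1 − e^(−k(N−n))) / (1 − e^(−k)),

with the e^(−k) prefactor because an emission is deposited once within its
own operator-split hour before the first forced state sees it. The adjoint
matches this closed form to 1e−10 (observed: 1e−15).

Sensitivities for emission hours inside the forward spin-up window are still
computed (those emissions influence post-spin-up exposure) but flagged and
excluded from annual aggregates by default — the treatment of the backward
spin-up window was a genuinely open choice; exclusion is conservative and
explicit.

## Monetization

VSL transfer follows the OECD unit-value form with the additive growth
bracket (1 + %ΔP + %ΔY)^b exactly as printed in its source, elasticity
b = 0.8 by default. Monetization is receptor-side (the VSL where the deaths
occur), which is why a monetized sensitivity field requires a *second*
backward run with USD-valued forcing: a source affects many receptors with
different VSLs, so post-hoc rescaling of the deaths field is wrong except in
the single-receptor case — an equality the tests exploit. The base VSL has
no defensible universal default and must be supplied; the synthetic worlds
use 3.0·10⁶ USD. A uniform-global-VSL variant exists as a configuration
switch on the economics panel.

## Attribution

Marginal sensitivities make sector burdens additive: burden(f) = f·Σ sens·E
restricted to a sector/region/level, attributed to the **source** cell's
region (where the tons would be cut). With nonlinear GEMM the f = 0.1 burden
is a first-order estimate; the concave response means successive 10% cuts
from lower baselines yield *larger* per-ton burdens, which is asserted as a
direction on a monotone scenario rather than as an inequality against the
forward difference. Shares are taken over the whole inventory (seven
anthropogenic sectors plus a natural residual) so they sum to one. Seasons
are meteorological quarters; calendars shorter than a year map hours to the
four seasons proportionally.

## Synthetic worlds

The generators emulate structure, not magnitudes:

- **population** — 12 Gaussian urban clusters with log-normal amplitudes on
  a 5% rural floor, normalized to 4·10⁸ adults (heavy-tailed and clustered;
  Gini > 0.5 is a tested property);
- **baseline mortality** — constant within each Voronoi region, drawn in
  0.004–0.012 deaths/person/yr (an NCD+LRI crude-rate range for adults 25+);
- **emissions** — per-sector totals (tons per 240-h period: agriculture
  60 k, energy 50 k, residential/industry/ground-transport 40 k each,
  natural 30 k, shipping 8 k, aviation 2 k) with sector-specific species
  mixes, geographies (rural-diffuse NH3-heavy agriculture,
  population-proportional residential/transport, point-like elevated
  energy/industry, a shipping lane), diurnal shapes and seasonal
  multipliers, normalized so configured totals are recovered exactly;
- **meteorology** — divergence-free winds (uniform, rotational, or a
  seasonally drifting gyre), scaled to a combined Courant number ≤ 0.9; a
  per-channel temperature index with a winter-boosted NH3 channel and
  summer-peaking photochemical channels; an oxidant-background field in
  titration mode;
- **economics** — regional GDP ratios in 0.05–1.5 of a 40 000 reference,
  CPI change 0.1–0.4, income growth 0.1–1.5.

One integer seed feeds named substreams (population, regions, bmr,
emissions, met, econ), so adding a generator never perturbs earlier draws
and worlds are bit-reproducible. Named scenarios (`box`, `plume`,
`two_region`, `titration_demo`, `seasonal_demo`) are deterministic fixtures:
`plume`'s source is strong enough by construction that the receptor clears
the GEMM counterfactual; `titration_demo` plants a 60 tons/hr NOx megacity
under a depressed oxidant background so γ·[NOx] > O3bg in populated cells.

What the generators do **not** emulate: real geography and country masks,
realistic emission magnitudes, vertical structure (the surface/elevated tag
is carried as an attribution label only — in one layer it cannot change
dispersion), aerosol thermodynamics, VOC/secondary-organic pathways, or
correlated meteorology. Passing tests therefore demonstrate the correctness
of the machinery under controlled conditions, not predictive skill on real
data; magnitudes (e.g. benefits per ton in the plume fixture) can sit far
outside realistic ranges because the fixtures concentrate population and
emissions for clarity.

## Verification design

Three independent oracles guard the adjoint:

1. **algebraic duality** — ⟨Lx, y⟩ = ⟨x, Lᵀy⟩ per linearized step, to 1e−12;
2. **closed form** — the box-model geometric series, to 1e−10;
3. **brute force** — central differences over two full forward runs per
   probe, probes sampled ∝ |sensitivity| + floor; OLS slope and R² within
   [0.999, 1.001]/≥0.999 in linear chemistry (δ = 10⁻³ of max(local
   emission, 1) keeps the GEMM cost's curvature below the tolerance), and
   ≤1% median relative error in titration mode with an adaptive δ chosen
   per probe as the finer member of the most mutually consistent pair among
   δ ∈ {10⁻¹, 10⁻², 10⁻³}·max(local emission, 1).

Default problem sizes — the 30×30-cell, 240-hour study world for
verification statistics, 12×12/48 h for unit-level FDM tests — were chosen
as the smallest worlds that exercise multi-region, multi-season structure;
the full suite runs in under two minutes.

## Numerical choices and degenerate inputs

- Deposition is exact-exponential (unconditionally stable, self-transpose
  up to the same factor) rather than forward Euler.
- Emission-weighted primary-PM aggregation uses the unweighted species mean
  where no primary PM is emitted (the weights are then undefined and the
  species indistinguishable).
- Zero-population (hence zero-forcing) worlds make the FDM regression
  degenerate; the report refuses them explicitly.
- NaN anywhere in the forward state aborts with the offending hour.
- Files without units attributes, or gridded files without an `hour`
  dimension, are rejected at read time; unknown configuration keys and
  economics columns are named in the error.

## Known limitations

Single layer; three linear (or one piecewise-linear) chemistry channels; no
aqueous or organic pathways; first-order upwind transport is numerically
diffusive, which flattens plumes at toy resolution; the f = 0.1 burden is a
first-order extrapolation under a concave response and therefore a
underestimate of the full-reduction burden; monetization carries no
uncertainty treatment of the VSL base or elasticity.
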