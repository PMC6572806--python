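# Methods

## The model

`sednit` treats a deep-sea sediment column as a 1-D early-diagenesis system at
steady state. Two solids are buried with the sediment — reactive organic
matter (OM) and manganese oxide — and four solutes diffuse through the pore
network: O₂, NO₃⁻, NH₄⁺ and Mn²⁺. For a solute C (µM) the governing balance
at every depth z (m below seafloor) is

    0 = d/dz( φ Ds dC/dz ) + Σ ν R(z) ,      Ds = D0 / (1 − ln φ²)

and for a solid S (mol per m³ of total sediment), advected at the burial
velocity v,

    0 = − d(vS)/dz + Σ ν R(z) .

Reaction rates R1–R5 (mol m⁻³ total sediment yr⁻¹) follow the classic
inhibition-cascade kinetics of diagenetic modelling: single-pool (1-G)
first-order OM decay at k_OM, partitioned among electron acceptors by Monod
limitation and hyperbolic inhibition — O₂ inhibits denitrification with
constant h₁ (the factor h₁/(h₁+O₂) is ½ at O₂ = h₁), O₂ and NO₃⁻ inhibit Mn
reduction with h₂, h₃. Nitrification (NH₄⁺ + 2 O₂ → NO₃⁻) and Mn²⁺ oxidation
are bimolecular. Stoichiometry per mol C oxidized: R1 consumes 1 O₂; R2
consumes 4/5 NO₃⁻ (to N₂); R3 consumes 2 MnO₂ releasing 2 Mn²⁺; all three
release rN = 16/106 NH₄⁺ (Redfield). Nitrification consumes 2 O₂ per NH₄⁺,
Mn²⁺ oxidation ½ O₂ per Mn²⁺.

Assumptions: steady state over the ~8 Myr depositional history; no
bioturbation, bioirrigation or compaction; solute burial advection neglected
by default (the Péclet number at v ≈ 9 µm/yr is ~10⁻⁴; a flag enables it);
sulfur and iron chemistry out of scope. Nitrification is modeled as a single
NH₄⁺ → NO₃⁻ step, so porewater nitrite never appears explicitly.

## Numerics

The equations are discretized on a uniform node-centered grid: central
differences for diffusion, second-order (three-point backward) upwind for
solid advection. First-order upwind would be oscillation-free too, but its
O(dz) truncation error on the OM profile is what limits flux-budget closure
at practical grids; the second-order stencil restores O(dz²) closure while
remaining stable for pure advection. Boundary conditions are Dirichlet for
all solutes at both boundaries (bottom-seawater values above, crustal-fluid
values below); solids enter with a prescribed top flux (S₀ = F/v) and obey a
zero-gradient condition at the base, which the upwind stencil satisfies
automatically.

The nonlinear system (unknowns interleaved node-by-node, bandwidth 2·6) is
solved by damped Newton iteration with a finite-difference banded Jacobian
(column grouping: one Jacobian costs 24 residual evaluations at any grid
size), line search on the residual 2-norm, and two fallbacks: homotopy on the
organic-matter load (ramping the top flux from 25% with warm starts) and
pseudo-transient continuation. Residuals are scaled per species so the
convergence criterion — max-norm ≤ 10⁻¹⁰ — is meaningful across µM-scale
solutes and mol-scale solids. Monod factors are evaluated on max(c, 0)
smoothed over a 10⁻⁹ half-width; this keeps the residual differentiable when
an iterate grazes zero (raw clipping stalls the line search near the anoxic
core) while leaving converged concentrations nonnegative to well below any
measurable scale. An independent route to the same fixed point — stiff BDF
integration of the relaxational system du/dτ = residual — is used in the test
suite as an oracle.

`mass_balance` closes each species' budget with second-order one-sided
boundary gradients and trapezoid quadrature. Species that cycle internally
(NH₄⁺ is produced by mineralization and consumed by nitrification in
near-balance at every depth; Mn cycles between R3 and R5) are normalized by
their gross turnover rather than the vanishing net term, otherwise the
diagnostic would amplify quadrature noise on a difference of cancelling
integrals.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| depth_max / n_nodes | 70 m / 200 | | two-sided oxygenated column; dz = 0.35 m resolves the transition zones |
| porosity φ | 0.75 | – | typical deep-sea pelagic clay |
| temperature | 1.5 | °C | bottom-water value for the setting |
| burial velocity | depth_max / 8 Myr ≈ 8.75e-6 | m/yr | column age ~8 Myr |
| D0 (O₂, NO₃, NH₄, Mn²⁺) | 0.0372, 0.0306, 0.0318, 0.0104 | m²/yr | infinite-dilution values near 1.5 °C |
| bc O₂ top/bottom | 250 / 200 | µM | oxygenated bottom water and crustal fluid |
| bc NO₃ top/bottom | 21.0 / 21.1 | µM | bottom-seawater and crustal-fluid nitrate |
| OM top flux | 6.5e-4 | mol C m⁻² yr⁻¹ | calibration, see below |
| k_OM | 2e-7 | 1/yr | calibration; implies OM decay length v/k ≈ 44 m and TOC ~0.1 wt% |
| K_O2 | 3 | µM | high microbial O₂ affinity |
| K_NO3 | 500 | µM | apparent community-scale NO₃ affinity, see below |
| h₁ | 10 | µM | weak O₂ inhibition of denitrification (the fit target) |
| k_nit, k_mnox | 1e-2 | 1/(µM·yr) | keep NH₄⁺ and Mn²⁺ near detection limits in oxic porewater |
| wet bulk density | 1.7 | g/cm³ | cell-density conversion |
| electrons per substrate | 8 (NH₄⁺→NO₃⁻), 6 (NH₄⁺→NO₂⁻ option), 5, 4, 2 | e⁻/mol | half-reaction bookkeeping |
| C fixation yield | 10 mol NH₄⁺ per mol C | | chemolithoautotrophic nitrifier yield |
| cell carbon | 14 | fg | average prokaryotic cell |

All of these are explicit in the shipped `northpond_like.yaml` and
config-overridable.

**Calibration of the example scenario.** The OM flux, k_OM and K_NO3 were
set — once, as a range check against the qualitative anchors of the target
setting — so that the forward model produces (i) a C-shaped O₂ profile with a
sub-detection anoxic core and transition zones in the 20–45 m range, (ii) an
interior nitrate maximum of 40–50 µM mirroring the O₂ profile, and (iii)
depth-integrated nitrification concentrated in the oxic zones with the
opposite pattern for denitrification. The large K_NO3 deserves a note: with
the inhibition-cascade rate laws and h₁ = 10 µM, a half-saturation in the
tens-of-µM range would let denitrification consume nitrate as fast as
nitrification produces it and no interior nitrate maximum could form at any
OM load; an apparent affinity well above porewater concentrations —
effectively first-order denitrification, as slow carbon-limited communities
exhibit — restores the observed nitrate accumulation while keeping
denitrification active throughout the column.

**h₁ fitting.** The misfit is the mean over species (O₂ and NO₃⁻, equally
weighted) of the RMSE over observed depths normalized by each species'
observed range; the fit is a pure grid search, returning the full misfit
curve so the sensitivity structure is visible. Candidates that fail to
converge are recorded as missing. A minimum on the grid edge is flagged.

## Synthetic data

The generator emulates the study conditions, not any particular dataset:

* **Profiles** — the forward model at the scenario's true kinetics, sampled
  every 1 m with multiplicative lognormal noise (sd 2% for O₂/NO₃⁻, 5% for
  NH₄⁺/Mn²⁺ — instrument-level precision for porewater chemistry); O₂ ≤ 3 µM
  flagged below detection.
* **Abundances** — log₁₀(copies/g) falls linearly from 10⁸ at the seafloor
  (one decade per 23 m, reaching ~10⁵ at depth) with Gaussian log-space peaks
  of up to 100-fold centered in the transition zones, plus 0.15-decade
  lognormal noise; values ≤10² copies/g are flagged below detection. Marker
  offsets put archaeal amoA ~0.5 decades below total 16S and the bacterial
  nitrogen-cycle genes 2–2.5 decades lower.
* **OTU tables** — 300 OTUs with log-series surface abundances; each OTU's
  relative detectability decays as exp(−z/ℓᵢ) with ℓᵢ lognormal (median
  1.2 m, σ = 1.0) and a persistent guild (8%, tenfold longer ℓ) that comes to
  dominate at depth — this spread is what produces a gradual richness decline
  rather than an abrupt cutoff. In OATZ samples, a set of OTUs drawn once per
  table with the resurrection probability (default 0.75) regains its surface
  weight; the set is emitted as planted truth. Reads are multinomial at
  20 000 per sample, deep enough that detection is not the limiting factor
  for the reappearance statistic. Resurrection is a per-OTU (not per-sample)
  decision so that the measured fraction estimates the planted probability
  directly.

What the generator does **not** emulate: PCR/primer bias, chimeras,
contamination, compositional overdispersion beyond multinomial sampling,
horizontal heterogeneity, or transient (non-steady) geochemistry. Passing
tests therefore demonstrate the correctness of the computations under the
stated statistical model, not robustness to every artifact of real amplicon
or porewater data.

## Design choices and degenerate inputs

* Zone detection pairs threshold crossings (10 µM and the 3 µM detection
  limit, linearly interpolated; values exactly at a threshold count as at-or-
  below) through a state machine, so an excursion below 10 µM that recovers
  without reaching the detection limit opens no zone; zones narrower than one
  median sample spacing are discarded as noise (configurable). Zone kinds
  then always alternate with depth.
* Flux gradients use the 3 nearest samples by default — sparse surface
  sampling makes wider windows underestimate curved gradients — and
  below-detection values enter as limit/2 with the estimate flagged.
* Division by a zero cell density yields a flagged NaN, never infinity; a
  zero metabolic rate yields an infinite turnover flagged `inactive`;
  metabolic-state boundaries are assigned upward (on-survival-line →
  maintenance). The survival/growth threshold curves are user-supplied
  log-linear functions of temperature; no coefficients are hard-coded.
* Rarefaction excludes samples below the target depth with a log note;
  reappearance "detection" is ≥1 read after optional rarefaction, both
  configurable.
* `reaction_rates` rejects negative concentrations with a node/species
  diagnostic at the public surface; the solver path uses the smooth clamp.

## Problem sizes

The shipped scenario uses 200 nodes (analysis) and 100 nodes (repeated-solve
experiments such as the 25-candidate × 10-seed h₁ recovery); grid-refinement
tests confirm ≥ first-order convergence, and closed-form benchmarks agree to
<0.1% at 200 nodes. Community checks use 300-OTU tables and a 5-OTU toy
sample with 1000 Monte-Carlo rarefactions against the exact hypergeometric
expectation.

## Known limitations

Single-pool OM decay cannot reproduce multi-G reactivity profiles; the Mn
cycle is a minimal placeholder (no solid-phase diffusion by mixing, no
carbonate chemistry); the steady-state assumption precludes hindcasting
depositional transients; h₁ is fit by grid search only (no gradient-based
refinement or uncertainty quantification beyond the misfit curve); and
cell-specific rates inherit the usual qPCR caveats (gene copies per genome,
extraction efficiency), making them minimum estimates.
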