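# Methods

This note records the models, conventions and numerical choices behind
`arpsyn`, and what the synthetic-data presets do and do not emulate.

## Kinetic model of actin assembly

All concentrations are carried in µM and bimolecular constants in µM⁻¹s⁻¹
(1.16×10⁷ M⁻¹s⁻¹ ≡ 11.6 µM⁻¹s⁻¹).

**Spontaneous nucleation.** Monomeric actin (G) forms dimers, trimers and
tetramers through reversible steps whose on-rates (kf2–kf4) are fixed at the
barbed-end monomer on-rate, 1.16×10⁷ M⁻¹s⁻¹.  Each oligomer tier can
irreversibly convert into a filament nucleus (three parallel tiers — the
model does not force a single obligatory nucleus size), releasing its
subunits into filamentous actin (F).  A nucleus is a catalyst representing
one free barbed end: elongation is the mass-action reaction E + G → E + F at
k_on, and depolymerization is the non-mass-action rate v = k_off·[E] acting
only while F > 0.  Pointed-end dynamics are neglected.  k_off is not an
independent parameter: it is set to k_on·C_c = 1.16 s⁻¹ so the elongation
submodel equilibrates at the critical concentration C_c = 0.1 µM, the same
value used to calibrate fluorescence traces.

The oligomer off-rates and nucleation rates (kd2 = 1×10⁵ s⁻¹,
kd3 = 1×10³ s⁻¹, kd4 = 1×10² s⁻¹; kn2 = 1×10⁻⁸ s⁻¹, kn3 = 1×10⁻⁴ s⁻¹,
kn4 = 5×10⁻² s⁻¹) were calibrated once so that 2–6 µM actin-alone reactions
produce sigmoidal time courses with realistic plate-reader kinetics (3 µM
half-time ≈ 9 min, plateau within ~25 min, strong concentration dependence
through the tetramer tier), then frozen as package presets.

**Dip1 pathway.** Dip1 (D) binds Arp2/3 complex (C) reversibly (k₉/k₋₉);
0–3 actin monomers then bind the assembly reversibly (all monomer steps share
k₁₀/k₋₁₀, the fewest-parameters choice since no per-step constants are
identifiable); a final irreversible step (k₁₁) creates a Dip1-capped barbed
end, E_dip.  E_dip elongates and depolymerizes exactly like a spontaneous
end but is tracked separately so the share of Dip1-origin filaments can be
computed.  Dip1 is single turnover: D and C are consumed into E_dip.  The
package's Dip1-alone constants (k₉ = 0.5 µM⁻¹s⁻¹, k₋₉ = 2 s⁻¹,
k₁₀ = 11.6 µM⁻¹s⁻¹, k₋₁₀ = 100 s⁻¹, k₁₁ = 0.02 s⁻¹) are self-calibrated
presets chosen to give a weak-binding, monomer-limited activation pathway
with a saturation K½ of order 1 µM at 10 nM Arp2/3 — they are package
conventions, not published estimates.

**Synergy model.** Reactions containing monomeric Wsp1-VCA are modeled with
the same one-monomer Dip1 topology; Wsp1 is not an explicit species.  Its
monomer recruitment is absorbed into shifted constants: k₋₉ reduced 4-fold,
k₋₁₀ reduced 8-fold, and k₁₁ = 0.0245 s⁻¹, the last solved through the full
measurement pipeline so that the fitted saturation plateaus of paired ±Wsp1
titrations differ by the reference 1.6-fold.  Branching nucleation by Wsp1
alone is deliberately absent: fits restricted to reactions with > 0.5 µM
Dip1 justify ignoring it, which is why `fittable_traces` drops low-Dip1
reactions for synergy variants.

**Integration.** Stiff BDF with analytic Jacobian, rtol 10⁻⁸, atol
10⁻¹⁰ µM, dense output on the experimental grid.  The atol sits far below
the nM-scale nucleus pools because error there is amplified multiplicatively
into the polymer curve; at looser tolerances the solver's small negative
excursions in quasi-steady oligomer species, once clipped, visibly violate
mass conservation.  The F > 0 indicator in the depolymerization law is
smoothed as F/(F + ε), ε = 10⁻⁸ µM, keeping the right-hand side
differentiable; the induced steady-state error is O(ε).  Reported
concentrations are clipped at zero; a trajectory dipping below −10⁻³ µM
aborts with a diagnostic naming the variant and parameter set.

## Objective and global fitting

Measured traces are converted to filamentous actin via the two-point
calibration (zero filament at F_min, total − 0.1 µM at F_max).  The fit
quality is MSS = Σ_traces ω·Σ_t (x−y)², ω = 1/⟨x²⟩ per trace, divided by the
total number of fitted points.  Both normalizations are package conventions:
per-trace weights equalize traces of different amplitude, and dividing by
the point count makes objectives comparable across datasets.

Floated constants are searched in log₁₀ space with differential evolution
(seeded; latin-hypercube initialization, which is log-uniform in the
parameter) within class bounds — off-rates 10⁻⁴–10³ s⁻¹, on-rates
10³–10⁸ M⁻¹s⁻¹, k₁₁ 10⁻⁴–10² s⁻¹ — then polished with Nelder–Mead.  The
default budget (population 50, 200 generations ≈ 10⁴ evaluations) suits
overnight-quality fits; the tests and model comparison use reduced budgets
(population ~10–20, ~10–20 generations) on compact trace sets (three Dip1
concentrations, 20 s sampling, 1600 s), which the recovery tests show is
already sufficient to nail single constants to ≪1% on noise-free data.
Fitting-path simulations use looser tolerances (rtol 10⁻⁶) than reporting
ones; the objective is insensitive below the data's noise floor.

Before pathway fitting, the dimer dissociation constant (text symbol k₋₁)
can be re-anchored by a one-dimensional log-space fit against the reaction
set's actin-alone control trace, mirroring how spontaneous-nucleation
constants are fixed per reaction set.

Model comparison fits each 0–3-monomer variant with matched seeds and
budgets, floating {k₁₁, k₋₁₀, k₋₉} (minus constants a variant does not use:
the 0-monomer pathway has no monomer-binding step).  k₋₉ is included
because with only {k₁₁, k₋₁₀} the richer variants stall above the 0-monomer
floor at reduced budgets, masking the true ordering.

## Trace analysis

Slopes are estimated by ordinary least squares over a sliding 11-point
window and the maximum is taken over interior points; at ~10 s plate-reader
sampling this spans ~100 s.  A windowed slope cannot exceed roughly
(dynamic range)/(window span), so fast reactions must be sampled densely
enough — the synergy preset samples at 5 s for this reason.  The saturation
fit is plain nonlinear least squares of the three-parameter hyperbola;
designs whose rates do not respond to Dip1 are flagged non-identifiable
rather than silently fitted.  The "plateau" is y-intercept + rate_max, the
[Dip1]→∞ limit of the hyperbola.

## Filament census

percent_bound = 100·b/(b + c·(t−b)) for b bound and t total linear pointed
ends; the correction c scales only the spontaneous (undecorated) count and
defaults to 2 when a Wsp1 VCA construct is present (VCA constructs roughly
halve spontaneous nucleation) and 1 otherwise, overridable per table.
Decorated ends are treated as entirely Dip1-nucleated; the true fraction is
~97%, a ≤3% relative slack absorbed by the statistic's noise.  The
model-side prediction is 100·E_dip/(E_dip + E_spont) at 150 s.  For the
packaged TIRF-condition network (1.5 µM actin, 100 nM Arp2/3, 6 nM Dip1),
spontaneous nucleation is strengthened by dividing the oligomer off-rates by
9.39 — TIRF chambers (surfaces, methylcellulose crowding) are far more
permissive of spontaneous nucleation than plate-reader wells — calibrated
once so the predicted Dip1-origin share at 150 s equals the 3.4% census
reference.

Group statistics: two-tailed Student's t-test for two groups; one-way ANOVA
with Tukey's HSD otherwise.

## Patch metrics

Tracks are per-patch, per-frame (1 s intervals, 60 s movies, 1-based frames)
positions, ROI intensities and cytoplasmic backgrounds.  Conventions:

* **Appearance**: first frame whose background-subtracted intensity exceeds
  2× the standard deviation of the track's recorded background column (the
  noise floor available to a manual tracker).  "First appearance" is a
  visual judgment in practice; this threshold is the package's convention.
* **Assembly time**: appearance to peak of the background-subtracted trace.
  Aggregations exclude tracks already present in frame 1 and tracks still
  rising at their last frame, whose assembly is not fully observed —
  including them biases the mean low.
* **Initiation rate**: patches first seen in frames 2–21, divided by medial
  cell area and 20 s.  Frame-1 patches are excluded as already present.
* **Percent internalized**: among patches present in frame 25, the fraction
  displaced > 2 pixels from their pre-peak mean position ("original
  position" is taken as the pre-peak mean; the pixel threshold operates in
  pixels, with a configurable pixel size defaulting to 0.1 µm).
* The areal-density unit is patches·µm⁻²; initiation rates are
  patches·µm⁻²·s⁻¹.

## Synthetic data

The generators are pure functions of (preset, seed) built on one
`numpy.random.Generator`; identical seeds give byte-identical files.

**Pyrene presets** simulate each condition with the kinetic model, map F(t)
to RFU through the shared two-point calibration, and add Gaussian noise with
σ = 1.5% of the calibration's dynamic range (default).  Truth records hold
the generating constants, noiseless curves and instantaneous elongation-rate
maxima, so downstream measurements are testable as recovery problems.

**Patch presets** draw per-cell Poisson appearances (rate ρ·area, uniform in
time), include patches already underway at movie start at steady-state
abundance, give each patch a linear rise over its sampled assembly time and
a linear decay, Bernoulli internalization with an exponential displacement
ramp after the peak, and Gaussian intensity noise (σ = 10% of the patch
peak).  The strain presets carry the reference phenotypes as generative
truth: wild type ρ = 0.030 patches·µm⁻²·s⁻¹ and 5.1 s assembly; *dip1Δ*
ρ = 0.0076 with brighter, slightly faster patches; *wsp1ΔCA* ρ = 0.018 (a
40% initiation decrement), 6.7 s assembly and reduced internalization.
Medial cell areas are drawn at 32 ± 4 µm².

**Census presets** draw per-replicate totals from Poisson(2000) and bound
counts binomially at the preset fraction (3.4% for the Dip1-alone 2.5-minute
condition).  The counting depth is chosen so the per-replicate binomial
error on a 3.4% fraction is ~0.3 percentage points — a dense synthetic TIRF
field, deeper than typical manual counts.

**What the generators do not emulate** — and hence what passing tests do not
show about real data: photobleaching and illumination drift, inner-filter
effects and baseline drift in plate readers, correlated (non-Gaussian)
noise, patch merging/splitting and tracking mistakes, branched-filament
contamination of census counts, and any biology outside the encoded kinetic
scheme (no explicit Wsp1 species, no branching nucleation, no filament
length distributions).  Paper-derived preset values validate the measurement
pipeline's ability to recover a known truth; they are inputs, not findings.

## Known limitations

* Assembly-time measurement carries a small negative bias (≈ −0.25 s on the
  *wsp1ΔCA* preset, less on brighter wild-type patches) because a dim first
  frame occasionally misses the 2σ appearance threshold.
* The windowed maximum polymerization rate saturates for transitions faster
  than the window span; sampling density must match reaction speed.
* Initiation-rate estimates inherit full Poisson noise (CV ≈ 6% at 50 cells
  for the *dip1Δ* preset); single-seed values scatter accordingly.
* The multi-monomer (n = 2, 3) pathway variants reuse one monomer-binding
  constant pair; their fitted constants are effective, not per-step, values.
* Stochastic (Gillespie) simulation, filament length distributions,
  pointed-end dynamics and explicit branch junctions are out of scope.
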