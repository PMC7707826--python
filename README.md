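# arpsyn

Kinetic modeling and quantification pipeline for the co-activation of Arp2/3
complex by two nucleation promoting factors (NPFs): the WISH/DIP/SPIN90-family
protein Dip1 and the WASP-family protein Wsp1 of *Schizosaccharomyces pombe*.

Arp2/3 complex nucleates the branched actin networks that drive endocytosis.
Wsp1-activated Arp2/3 complex needs a preexisting filament to fire, so linear
"seed" filaments made by Dip1-activated Arp2/3 complex initiate each network.
This package implements, as a tested and reusable library, the quantitative
analyses used to dissect that division of labor:

* **Kinetic ODE models** (`arpsyn.reaction_model`) of pyrene-actin
  polymerization: spontaneous nucleation through dimer/trimer/tetramer
  intermediates (oligomer on-rates fixed at the barbed-end value,
  k<sub>on</sub> = 1.16×10⁷ M⁻¹s⁻¹), nuclei treated as catalysts that convert
  monomeric (G) to filamentous (F) actin, and a Dip1 activation pathway
  D + C ⇌ DC (k₉/k₋₉), followed by 0–3 reversible actin-monomer binding steps
  (k₁₀/k₋₁₀) and one irreversible activation step (k₁₁) that creates a
  Dip1-capped barbed end (single turnover).
* **Global model fitting** (`arpsyn.model_fitting`): all traces of a reaction
  set fitted simultaneously by minimizing the normalized mean square weighted
  sum of squares, MSS = Σ ω(x−y)² with ω = 1/⟨x²⟩ per trace, using a seeded
  population-based global search in log-parameter space plus local polish;
  objective-value comparison across the 0–3-monomer pathway variants.
* **Trace analysis** (`arpsyn.trace_analysis`): RFU → nM conversion anchored
  at zero filament (F_min) and 0.1 µM unpolymerized actin (F_max), maximum
  polymerization rates from sliding-window slopes, and hyperbolic Dip1
  saturation fits: rate = rate_max·[Dip1]/(K½ + [Dip1]) + y-intercept.
* **Filament census** (`arpsyn.filament_census`): percent of linear-filament
  pointed ends bound by labeled Dip1, with the two-fold spontaneous-nucleation
  correction applied in Wsp1-VCA conditions, plus the model-predicted share of
  Dip1-origin ends; t-test / one-way ANOVA with Tukey post-hoc comparisons.
* **Patch metrics** (`arpsyn.patch_metrics`): endocytic actin patch (Fim1-GFP)
  track analysis — peak-aligned mean intensity traces, assembly times,
  initiation rates (first 20 s, frame-1 patches excluded), densities, percent
  internalized (> 2 px displacement among patches present in frame 25).
* **Synthetic data** (`arpsyn.synthetic_data`): seeded generators for every
  input format, with ground truth recorded, so the whole pipeline is testable
  without any external data.

## Worked example: measuring NPF synergy

Generate a paired ±Wsp1-VCA Dip1 titration (3 µM actin, 10 nM Arp2/3,
0–30 µM Dip1), extract per-trace maximum polymerization rates and fit the
saturation hyperbola per arm:

```sh
arpsyn synth pyrene --preset synergy --seed 1 --out demo/
arpsyn maxrate --traces demo/traces.tsv --conditions demo/conditions.tsv --out demo/rates.tsv
arpsyn saturation --rates demo/rates.tsv --out demo/fits.json
cat demo/fits.json
```

```json
{
 "VCA": {
  "max_rate_max": 49.33110798574865,
  "k_half": 0.08630824247396128,
  "y_intercept": 4.752095522418167,
  "plateau": 54.08320350816682,
  "identifiable": true
 },
 "none": {
  "max_rate_max": 28.597503802241203,
  "k_half": 1.0096303401085212,
  "y_intercept": 5.4303978684253424,
  "plateau": 34.027901670666544,
  "identifiable": true
 }
}
```

The `plateau` (y-intercept + rate_max, in nM actin/s) is the fitted maximum
polymerization rate at saturating Dip1.  Adding 1 µM monomeric Wsp1-VCA
raises it from 34.0 to 54.1 nM/s — a 1.59-fold increase — and sharply lowers
K½ (the Dip1 concentration giving the half-maximal rate, in µM), the
signature of synergistic rather than additive co-activation.  The same
computation in Python:

```python
from arpsyn import synthetic_data, trace_analysis

traces, truth = synthetic_data.gen_pyrene("synergy", seed=1)
rates = trace_analysis.max_rates_table(traces)
arms = {arm: trace_analysis.fit_saturation(g[["dip1_uM", "max_rate_nM_s"]].to_numpy())
        for arm, g in rates[rates.arp23_nM > 0].groupby("wsp1")}
print(trace_analysis.plateau_ratio(arms["VCA"], arms["none"]))  # 1.587...
```

## Layout

```
src/arpsyn/        library modules (reaction_model, model_fitting,
                   trace_analysis, filament_census, patch_metrics,
                   synthetic_data, cli)
tests/             pytest suite, including end-to-end acceptance checks
scripts/           acceptance script
docs/methods.md    modeling and measurement conventions in detail
```
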