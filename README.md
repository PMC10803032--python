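# isletnet

Functional vs structural network analysis of pancreatic islet β-cells.

Islets of Langerhans are micro-organs of ~1000 electrically coupled
β-cells whose Ca²⁺ oscillations drive pulsatile insulin secretion. Two
different graphs describe an islet: the **structural network** of
physical gap-junction (Cx36) connections, weighted by coupling
conductance g_coup, and the **functional network**, whose edges connect
cell pairs with highly correlated Ca²⁺ time courses (Pearson R ≥ R_th).
A small subpopulation of cells — *β-cell hubs*, with normalized
functional degree above 60% of the islet maximum — dominates the
functional network, and a central question is whether hubs are made by
their gap-junction wiring or by intrinsic cell properties such as the
glucokinase rate k_glyc (a proxy for metabolic activity) and the K_ATP
channel conductance g_KATP.

`isletnet` provides, for people studying collective β-cell dynamics or
any comparable oscillator network:

* a seeded generator for heterogeneous multicellular islets — sphere
  packing, truncated-normal gap-junction degrees (mean 5.25, bounds
  [1, 12] in the fast-oscillation regime), per-cell parameter
  distributions, edge conductances g_ij = ½(g_i + g_j);
* a coupled ODE simulator with a pluggable single-cell model (a reduced
  reference burster is included) and the coupling current
  I_coup,i = Σ_j g_ij (V_i − V_j);
* trace metrics: pixel QC, duty cycle (time above 50% of max),
  correlation matrices, parameter–duty-cycle correlations, NAD(P)H
  response centering;
* functional-network tools: thresholding, power-law threshold tuning
  under 5 ≤ k_avg ≤ 15, normalized degrees, hub classification
  (>60% rule and top-10% rule);
* network comparison: Pr(sync), Pr(GJ), Pr(both) and conditionals,
  the calibrated k_glyc-similarity ("metabolic") network, and
  conductance-weighted least-resistance path analysis stratified by hop
  distance;
* topology: clustering, path length, global efficiency, Erdős–Rényi
  null ensembles (p = k_avg/n), coupling-reduction sweeps;
* a synthetic-trace generator with planted ground truth (duty cycles,
  wave lags, noise, hub labels) for validating every stage;
* islet-level paired statistics (Cohen's dz = t/√n, Bonferroni α).

See `docs/methods.md` for the model and all numerical conventions.

## Worked example

Simulate a reduced 260-cell islet in the fast-oscillation regime, tune
the functional threshold, and ask what distinguishes hubs:

```python
from isletnet import build_islet
from isletnet.simulate import SimulationConfig, simulate_islet
from isletnet.metrics import pearson_matrix, duty_cycles, correlate_params_with_duty
from isletnet.funcnet import tune_threshold, threshold_network, identify_hubs
from isletnet.compare import comparison_probabilities

islet = build_islet(260, model_tag="fast", seed=1)
traces = simulate_islet(islet, config=SimulationConfig(seed=1))
R = pearson_matrix(traces)
tuning = tune_threshold(R)                    # power-law fit, 5 ≤ k_avg ≤ 15
fnet = threshold_network(R, tuning.R_th)
hubs = identify_hubs(fnet, method="threshold60")
stats = comparison_probabilities(fnet, islet.structure)
duty = duty_cycles(traces)
r = correlate_params_with_duty(islet.params, duty,
                               total_conductance=islet.structure.total_conductance)
```

Output for this seed:

```
tuned R_th = 0.99145  (k_avg = 5.40, gof = 0.78)
hub fraction = 0.085
hub k_glyc = 1.365e-04  non-hub k_glyc = 1.286e-04
r(duty, k_glyc) = +0.76  r(duty, g_KATP) = -0.62  r(duty, g_coup) = +0.04
Pr(sync|GJ) = 0.241  Pr(GJ|sync) = 0.234
```

Reading it: the tuned threshold lands where the degree distribution is
scale-free-like; 8.5% of cells qualify as hubs; hubs carry a higher
glucokinase rate than non-hubs; the duty cycle is governed by k_glyc
far more than by g_KATP or coupling; and a gap junction between two
cells makes them synchronized only about a quarter of the time — the
functional network is not a picture of the wiring.

There is also a CLI (`isletnet run CONFIG -o OUT`, plus `simulate`,
`synth`, `network`, `compare`, `topology` subcommands) driving the same
library from declarative YAML/JSON configs, and writers for CSV/GraphML/
HDF5 artifacts at every stage.

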