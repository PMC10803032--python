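# Methods

`isletnet` studies how the functional network of an islet of Langerhans —
the graph of β-cell pairs whose Ca²⁺ time courses are highly correlated —
relates to the islet's structural gap-junction network and to the cells'
intrinsic parameters. The package contains a generator for heterogeneous
multicellular islets, a coupled-oscillator simulator, and the full
network-extraction/comparison/topology pipeline, plus a synthetic-trace
generator with planted ground truth so every analysis stage can be
validated without simulation or experimental data.

## Islet construction

**Geometry.** Cells are packed into a sphere by seeded uniform sampling
with minimum-separation rejection (Poisson-disc-like). The minimum
separation is the length unit; the sphere radius is set by a hard-core
packing fraction of 0.15, which leaves a typical interior cell with ≥ 12
neighbors inside the gap-junction proximity cutoff (2.35 separation
units) — enough to realize the maximum configured degree.

**Structural network.** Per-cell gap-junction counts are drawn from a
rounded truncated normal — N(5.25, 1.6) clipped to [1, 12] for the fast
(electrophysiological) regime, targeting mean 6.01 with sd 2.66 in
[1, 14] for the slow (integrated-oscillator) regime. Wiring is greedy
nearest-neighbor matching of the drawn degree sequence among proximal
pairs; if a draw is geometrically infeasible the cutoff relaxes by 10%
steps, residual deadlocks are resolved by degree-preserving edge swaps,
and as a last resort the sequence is re-drawn (all seeded, hence
deterministic). The graph is not forced to be globally connected; the
minimum degree of 1 is the only connectivity constraint.

**Heterogeneity.** The glucokinase rate `k_glyc` (the rate-limiting
glycolytic step, a proxy for metabolic activity) and the maximal K_ATP
conductance `g_KATP` are normal draws, truncated at zero by resampling:
fast regime `k_glyc` ~ N(1.26·10⁻⁴, 3.15·10⁻⁵) s⁻¹ and `g_KATP` ~
N(2.31, 0.57) pA/mV; slow regime `k_glyc` ~ N(0.0037, 0.0015) µM/ms and
`g_KATP` ~ N(19 700, 3 940) pS. The per-cell coupling parameter of the
fast regime is gamma(k = 4, θ = 4) rescaled **multiplicatively** so the
islet mean is exactly 0.12 nS (0.06 / 0.03 nS in coupling-reduction
experiments). Multiplicative rescaling preserves the gamma shape, so the
coefficient of variation stays 1/√k = 0.5 and the sd at the standard mean
is 0.06 nS; an additive shift would not reproduce that sd. The slow
regime uses `g_coup` ~ N(1, 0.5) pS. Units follow the two parameter sets
as published, which differ between regimes (nS vs pS for coupling); the
cell model consumes dimensionless ratios relative to each regime's
reference point, so the inconsistency stays confined to labels.

An edge's conductance is the mean of its endpoint parameters,
g_ij = ½(g_i + g_j), and a cell's total conductance is the sum of its
incident edge conductances.

## The reference bursting model

The published single-cell models behind the two regimes carry dozens of
ionic and metabolic state variables; they enter this package only through
a pluggable `CellModel` interface (right-hand side, state dimension, Ca²⁺
readout index). The shipped reference model is a Morris-Lecar-style
relaxation burster with four states per cell — membrane potential V, a
K⁺ gate n, a slow negative-feedback conductance s, and a low-pass Ca²⁺
readout c — with an added K_ATP-like leak:

    C dV/dt = −[g_Ca m∞(V)(V−V_Ca) + g_K n (V−V_K) + g_s s (V−V_K)
               + g_KATP_eff (V−V_K) + I_coup]

where `I_coup,i = Σ_j g_ij (V_i − V_j)` (nS·mV = pA) and
`g_KATP_eff = 0.3 · 2.31 nS · (g_KATP/ĝ_KATP) / (1 + (k_glyc/k̂_glyc)³)`
— higher glycolytic flux means more ATP, fewer open K_ATP channels and a
longer active phase. The Hill-type closure with exponent 3 is what makes
metabolic heterogeneity the dominant determinant of the duty cycle in
the fast regime, consistent with the strong flux control glycolysis
exerts on ATP in β-cells. The fixed kinetic parameters (g_Ca = 3.6,
g_K = 10, g_s = 4 nS; v_m = −24, v_s = −36 mV; τ_n = 0.5 s; effective
C = 1 nS·s) were tuned once against a behavioral contract and then
frozen:

* duty cycle (fraction of time the Ca²⁺ readout exceeds half its
  maximum) is strictly monotone increasing in `k_glyc` and decreasing in
  `g_KATP` over ±2 sd of the heterogeneity distributions;
* `k_glyc` correlates more strongly with duty cycle than `g_KATP` does
  across a heterogeneous population (r ≈ +0.75 vs −0.62);
* the slow time constant τ_s sets the burst period: 30 s gives the fast
  regime (period ≈ 34 s < 2 min), 240 s the slow regime (≈ 175 s
  > 2 min);
* islet-mean pairwise correlation is monotone in mean coupling over
  0 → 0.12 nS.

This is a plateau burster: the fast subsystem is slowed (effective
membrane time constant ~0.1 s) so the model is integrable with a 20 ms
fixed step over 500 s at islet scale; intra-burst spiking is deliberately
not resolved, since all downstream analysis operates on 1 s samples of
the smoothed Ca²⁺ readout. The model makes no quantitative claims about
currents — it exists to carry the heterogeneity→duty-cycle→synchrony
chain at the stated parameter scales. Full-scale quantitative overlap
values (e.g. Pr(Sync|GJ) = 0.39 at 1000 cells) are properties of the
complete published kinetics and are out of scope here; the test suite
checks the threshold-dependence property instead (lowering R_th drives
Pr(Sync|GJ) toward 1).

## Simulation protocol

Simulations run at 11 mM glucose for 500 s, sampled at 1 s (mirroring
1 frame/s imaging). The default integrator is fixed-step classical RK4
(dt = 20 ms; halving the step changes traces by < 10⁻⁴ relative RMS);
any `scipy.integrate.solve_ivp` method can be selected instead. The
leading 20% of the run (100 s) is discarded as the first-phase
transient; downstream metrics use the remaining window. The simulator
itself is noise-free — measurement noise belongs to the synthetic-trace
generator. Initial conditions start every cell from the same rest-like
state with a seeded uniform jitter (±0.2) on the slow variable,
emulating the staggered recruitment of cells after a glucose step;
jitter 0 reproduces exactly symmetric dynamics for identical cells.
Default sizes: 1000 cells (fast regime), 260 (slow regime); the reduced
fast-model analyses in the tests and the acceptance script use 260 cells,
the size at which the two regimes were compared.

## Network extraction and analysis

**Functional network.** Pearson correlation of each cell pair over the
analysis window; cells with zero variance (silent) are excluded rather
than failing the islet. Edges are pairs with R_ij ≥ R_th. Defaults follow
the published working points — R_th = 0.9995 (simulated fast), ~1 − 10⁻⁹
(simulated slow), 0.9 (experimental-style) — and a tuner chooses R_th per
islet by maximizing the power-law character of the degree distribution
(R² of a log-log linear fit to the 10-bin normalized-degree histogram)
subject to 5 ≤ k_avg ≤ 15, the published range for islet functional
networks. The search is a deterministic quantile grid over the feasible
threshold interval, ties toward the sparser network. Degrees are
normalized to the islet maximum; hubs are cells above 60% normalized
degree (strict inequality), or alternatively the top ⌈10%⌉ of cells by
degree with index-ordered tie-breaking.

**Comparison probabilities.** Pr(sync), Pr(GJ), Pr(both) are edge counts
over the n(n−1)/2 pairs; conditionals are intersection ratios, computed
per islet and averaged by the caller. The metabolic (k_glyc-similarity)
network connects pairs within 15% of the islet diameter whose |Δk_glyc|
falls below a cutoff calibrated so Pr(sync|Met) = Pr(sync|GJ) within
0.01 — the control that makes Pr(Met|Sync) and Pr(GJ|Sync) directly
comparable. Calibration scans candidate pairs by similarity rank, which
is exact and deterministic. "Similarity" is the pairwise difference
|k_glyc,i − k_glyc,j|, the reading consistent with comparing cells with
similar metabolic rates.

**Weighted paths.** Edge resistance is the inverse of the ½-mean weight
(coupling conductance or k_glyc); all-pairs least-resistance paths come
from Johnson's algorithm. Reported per pair: hop count, the **summed**
½-mean weights along the chosen path (cumulative conductivity), and that
sum per hop. Synchronized vs non-synchronized pairs are compared per hop
distance 1–15, normalized by the pooled mean at each distance, with
paired t-tests across islets at the Bonferroni-corrected per-test
α = 0.05/15 ≈ 0.003.

**Topology.** Clustering C_i counts edges among neighbors over k_i(k_i−1)/2
(0 for degree < 2). Average path length uses the n+1 convention for
disconnected pairs; global efficiency uses the 0-contribution convention —
the two deliberately differ, each following its stated rule. Erdős–Rényi
nulls flip an independent coin with p = k_avg/n per pair, 1000 networks
per islet; this matches expected rather than exact edge counts, and the
realized per-network k_avg is recorded so the discrepancy is visible.
Ensemble summaries report the 2.5/25/50/75/97.5% quantiles.

**Coupling sweep.** For each seed the islet is fixed and the coupling
parameter re-drawn (same seed, same gamma shape) targeting means 0.12,
0.06, 0.03 nS. The threshold is tuned on the reference level and held
fixed across levels: re-tuning would force k_avg back into [5, 15] and
hide exactly the degradation the sweep measures.

## Synthetic traces

Surrogate recordings are raised-cosine-edged square-wave burst trains:
the half-max crossings of each cycle are exactly one duty cycle apart,
so the 50%-of-max duty rule recovers the planted duty to within one
sample even under noise. Cells are phase-shifted by wave-speed × distance
from a wave origin plus optional per-cell jitter; additive white Gaussian
noise models measurement noise (the published simulations are noise-free,
which is why experimental thresholds sit lower than computational ones).
The planted-hub fixture gives hub cells a common phase and low noise
(σ = 0.05 amplitude) and the rest independent jitter (±6 s) and higher
noise (σ = 0.35), so the tuned functional network's degree ranking
recovers the planted labels. What these fixtures do **not** emulate:
photobleaching, baseline drift, realistic noise spectra, or wave-front
curvature — passing on them validates the pipeline's bookkeeping and
statistics, not its robustness to real imaging artifacts.

## Statistics

The islet is the experimental unit: per-islet hub and non-hub means feed
paired two-tailed t-tests, with Cohen's dz = t/√n as the paired-samples
effect size. Bonferroni correction divides the family α by the number of
strata. Repeated-measures layouts (islet × coupling level) are marshaled
into tidy tables for standard ANOVA routines; the package deliberately
implements no bespoke test machinery.

## Known limitations

* The reference burster reproduces the *direction* and *ordering* of
  parameter effects, not published current magnitudes; quantitative
  single-cell electrophysiology requires dropping the full published
  kinetics into the `CellModel` interface.
* At the reduced islet sizes used on a desktop (≈ 260 cells), the hub
  fraction under the tuned threshold runs above the 5–12% band observed
  at 1000 cells: synchronized communities have a roughly size-independent
  cell count, so their *fraction* inflates as the islet shrinks. The
  acceptance report states the honestly computed value.
* The geometry is a uniform sphere packing — no anatomical islet
  architecture, and β-cells only (no α/δ cells or paracrine signaling).
* Gap-junction conductances are static; dynamic coupling is out of scope.
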