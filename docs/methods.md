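# Methods

This note records the scientific and numerical choices behind `swinfo`, in
the order the pipeline runs them, together with the calibrations the model
needs and the limitations a user should know before trusting a green test.

## 1. Network generation (`swinfo.netgen`)

Point clouds are mixtures of six isotropic 2D Gaussians with centers uniform
in a 10×10 plane and per-component standard deviation drawn uniformly from
0.2 ± 0.1. Points are allocated to components as evenly as possible
(remainder by component index) and are kept even if they fall outside the
nominal square; the domain side is metadata only.

Wiring is deterministic given the cloud: all randomness lives in the point
sampling and in ensemble-level parameter draws. The two rules:

* distance rule: link i–j when α·exp(−β·dᵢⱼ/l) > P_w, with l the maximal
  pairwise distance. At α = 1 this is equivalent to a hard distance
  threshold d < l·ln(α/P_w)/β, i.e. a random geometric graph on a clustered
  cloud — short, triangle-rich, intra-cluster edges.
* density rule: link i–j when both have a density-peak score
  p₂ = exp(−(Γ_max/Γ − 1)) > P_d, Γ = ρ·d_min. ρ counts *other* points
  within δ_co (a point is not its own neighbour); d_min is the distance to
  the nearest point of strictly higher density, with ties broken by node
  index, and the globally densest point takes the maximum pairwise distance
  (the density-peak-clustering convention). Scores lie in (0, 1]; nodes with
  Γ = 0 score 0, and a cloud where every Γ is 0 signals that δ_co carries no
  density contrast (an error). This rule links cluster centers — the
  long-range shortcuts.

Parameter ranges for ensembles: β ∈ [0.2, 0.8], P_w ∈ [0.90, 1.0],
P_d ∈ [0.90, 1.0], δ_co ∈ (0, 0.4], α = 1. A literal "δ_co = 0 ± 0.4" is
ill-defined (a zero cutoff degenerates ρ), so δ_co is drawn uniformly on
(0, 0.4].

**Stratification.** Under purely uniform draws the random-like end of the SW
axis is essentially never populated: the permissive corner (β → 0.2,
P_w → 0.90, the largest distance thresholds) is a set of measure near zero,
yet it is the only region producing dense, ER-like graphs. Ensembles
therefore draw a configurable fraction (default 25%) from the lowest 5% of
the β and P_w ranges. All parameters stay inside the stated intervals.

## 2. Topology metrics (`swinfo.metrics`)

cc is the mean Watts–Strogatz local clustering (networkx), with degree-<2
nodes contributing 0 rather than being excluded, so cc stays defined on
sparse graphs. cpl is the mean shortest-path hop count over *connected*
ordered-distinct pairs (scipy BFS); disconnected pairs are excluded, a graph
without edges has undefined cpl, and such graphs report SW = 0. The ER
references are uniform G(n, m) graphs (networkx `gnm_random_graph`) with the
measured graph's own n and m; cc_rand and cpl_rand are measured empirically
on 20 replicates by default (recorded in outputs), not taken from analytic
approximations. SW = 0 when cc_graph = 0; SW = NaN when every replicate has
cc_rand = 0 (m too small for the reference to carry triangles).

Consequence worth knowing: on clustered clouds this generator's measured-SW
support is gapped — {0} ∪ [≈1.2, ∞). Sparse graphs are geometric and hence
strongly clustered (cc ≫ cc_rand, SW large, occasionally ≫ 14 when cc_rand
is tiny), while the densest reachable graphs bottom out near SW ≈ 1.2–1.4.
Binned curves therefore clip to the SW ∈ [0, 14] axis, and the SW ≈ 1
baseline (below) needs a fallback.

## 3. Stimulus (`swinfo.stimulus`)

N words of 8 letters, δt = 3 ms per letter. Random drive: i.i.d.
Bernoulli(p) letters. Periodic reference: one fixed word with round(8p)
active letters spaced evenly, repeated N times — rate-matched to the random
drive so the two differ in structure, not intensity (the reference waveform
is this package's choice). Derived quantities: Δt = 8Nδt (24 ms at N = 1,
72 ms at N = 3, 2400 ms at N = 100) and f = p/δt (33–333 Hz for
p ∈ [0.1, 1]).

## 4. LIF dynamics (`swinfo.lif`)

Forward Euler on C_m dV/dt = −g_l(V − V_o) + I_stim at dt = 0.01 ms
(= τ/300; forward Euler and trapezoidal agree to < 1e-5 relative here, and
the free decay matches the exponential to < 1e-3 mV over 3τ). Inputs are
instantaneous voltage increments; an action potential fires when V ≥ V_th,
resets V to V_o, and delivers ζ(dᵢⱼ)·gain·J/C_m to each neighbour at the
next integration step (one-step synaptic delay; no conduction delays). The
damping form ζ(d) = exp(−d/scale) with scale defaulting to l (so
ζ ∈ [1/e, 1]) is a package choice — only the existence of distance
attenuation is given. Neurons start at rest (V = V_o), which is the fixed
point of the free equation; a "null" start merely adds a transient toward
V_o and is available via `v_init`.

**Calibration — gain.** The literal parameters cannot move any neuron:
J/C_m = 0.25 mV against a 3 mV threshold gap, with τ equal to the letter
duration, sums to at most 0.25/(1 − e⁻¹) ≈ 0.40 mV. Campaigns therefore run
at `gain` = 12, the smallest gain at which a single active letter fires the
stimulated neuron (12 × 0.25 = 3 mV). This choice is made from the threshold
arithmetic, not fitted to any outcome, and it is the most conservative one
that produces propagation at all: a single action potential delivers
ζ·3 < 3 mV downstream, so recruitment of any further node requires spatial
or temporal convergence — which is exactly what network topology controls.
Every output record carries the gain.

**Calibration — refractory.** With reset-to-rest and no refractory period,
any component that ignites reverberates at the integration step forever
(each reset node is immediately re-fired by its neighbours' simultaneous
spikes), saturating every letter bin of every node and destroying the
information signal under both drives. Campaigns therefore clamp each neuron
at V_o for one letter duration (3 ms) after a spike, discarding inputs that
arrive during the clamp; a node then fires at most once per letter and the
response tracks the drive. The default `SimulationConfig` keeps
refractory = 0 (the minimal LIF), and both knobs are configurable.

## 5. Information (`swinfo.info`)

Letters: 1 iff ≥ 1 spike in [kδt, (k+1)δt). Words: consecutive,
non-overlapping, frame-aligned to t = 0. Entropy: plug-in (maximum
likelihood), base 2, no bias correction; pooling word counts across the 10
trial repetitions of a block is the only variance-reduction step. I = T − N
may come out negative at small samples (N is estimated from as few words as
T); negative values are kept and flagged, and only max(I, 0) enters I_grid
(the unclipped sum is stored for audit). I_input applies the same formula to
the drive itself; since the periodic reference is a single repeated word
(entropy 0), I_input equals the pooled word entropy of the random drive —
about 4.8 bits at N = 3, p = 0.4 with 10 trials, approaching
8·h(0.4) ≈ 7.77 bits as the word count grows.

## 6. Aggregation (`swinfo.aggregate`)

Per (network, condition) block of 10 paired (random, periodic) trials, each
from a freshly drawn seed node: AN is the per-trial count of nodes with ≥ 1
action potential under the random drive, averaged over the block; I_grid,
I_peak as above. Enhancement factors divide by the SW ≈ 1 baseline — the
mean metrics over networks with measured SW ∈ [0.8, 1.2] in the same
condition. Because that band is structurally empty here (§2), the baseline
falls back to the 5 networks with SW nearest 1, and every record carries
`baseline_fallback` and `baseline_sw_mean` so the convention is auditable.
Curves bin records by measured SW (width 0.5 over [0, 14]); sw_o is the bin
center maximising the binned mean, ties to the lowest SW; quality factors
Q^{i-f} = (η_f − η_i)/η_i are reported in percent. Gradients of η over
(Δt, f, SW) use numpy central differences on axes standardised to unit
range.

## 7. What the desk-scale campaign shows — and does not

The default campaign (60 networks × 100 nodes, 3×3 conditions, 10 trials;
about a minute on one CPU) reproduces: stimulus identities exactly; binned
η^grid(SW) curves with an interior maximum (near-empty networks transport
nothing, strongly compartmentalised ones little); grid-to-stimulus
information ratios of order tens, consistent with a fifth of the node count
of the full-scale study.

It does **not** place the optimum near SW ≈ 4.8. In this generator low SW is
synonymous with *dense* (the permissive distance-rule corner merges all
clusters), and the purely excitatory dynamics are edge-monotone, so the
SW ≈ 1 baseline networks are the strongest transporters and the binned
optimum sits at the lowest populated bin (mean sw_o ≈ 1.5). An interior
optimum at intermediate SW would require the SW ≈ 1 reference networks to be
sparse and uniform, which the mixed wiring rule cannot produce: sparse
implies geometric implies clustered. This divergence is independent of the
gain and refractory calibration (probed across gain 8–24, with and without
refractory — the ordering of I_grid across SW never inverts) and is recorded
as a known limitation rather than tuned away. The corresponding acceptance
checks are left failing by design.

Other limitations: 2D only; undirected, unweighted, purely excitatory
synapses with no noise, plasticity or conduction delays; plug-in entropy at
small word counts is biased low, so absolute I values at N = 1 are dominated
by sampling; and the synthetic generator makes no attempt to emulate
biological degree distributions, spatial boundary effects, or measured
cortical wiring lengths — a green sweep test establishes internal
consistency of the pipeline at desk scale, not biological realism.
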