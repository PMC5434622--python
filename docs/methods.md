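# Methods

## Model

The state is `X = (SAA, YAPTAZ, TUBB3, PPARG, MYOD1, RUNX2)`, all in
non-negative relative units. `S` is the substrate stiffness input in
internal units (printed kPa × 1000). With Hill terms written
`h(x; K, n) = (x/K)^n`, the non-cooperative model is

```
dSAA/dt    = Σ_{g=1..4} k_g · OR(h(S;K_sg,n_sg), h(G_g;K_gg,n_gg)) − d1·SAA
dYAPTAZ/dt = k5·SAA − d2·YAPTAZ
dG/dt      = k_G · A/(1 + A + R) − d_G·G          for each lineage gene G
```

where `OR(a, b) = (a + b)/(1 + a + b)` is a saturating OR-gate, each of
the four adhesion gates pairs a stiffness term with one gene's feedback
term (TUBB3·k1, PPARG·k2, MYOD1·k3, RUNX2·k4 with constants K1/n1…K8/n8),
and each gene equation has one activator `A` and one repressor `R`:
TUBB3 (activated by SAA, repressed by YAP/TAZ; K9–K10), PPARG (same
structure; K11–K12), MYOD1 (activated by YAP/TAZ, repressed by SAA;
K13–K14), RUNX2 (same structure; K15–K16). Default constants are the
reference table built into `ParameterSet`; all six degradation rates are
1, which defines the relative time unit. The canonical parameter indexing
used by the robustness analysis is 1–9 = k1..k9, then K_i at index
`8 + 2i` and n_i at `9 + 2i` (i = 1..16), 41 parameters in total.

Because the gene→SAA feedback gates use large exponents (up to n = 60),
all Hill terms are evaluated in log space with a shared max-shift before
exponentiation; the analytic Jacobian uses the same scaled quantities.
This keeps both finite for states across hundreds of orders of magnitude
and is verified against central finite differences to better than 1e−5.

### Variants

- **Feedback blocking** removes selected genes' terms from their OR-gates
  (numerator and denominator), equivalent to `K → ∞`. Blocking all four
  feedbacks leaves a single-valued stiffness response — up and down sweeps
  coincide to machine precision and no memory regions exist — which
  demonstrates that the feedback loops store the memory.
- **Cooperative variant** replaces the four OR-gates by one AND-like gate
  sharing a single stiffness term `h(S; K1', n1')` with all four gene
  terms in one numerator/denominator.
  `cooperative_degeneracy_report` documents why this form is degenerate:
  for `K1' < 1000` the shared stiffness gate saturates above
  S = 10 000, so the myogenic and osteogenic submodels both collapse to
  `dSAA/dt = k1 − d1·SAA` and become indistinguishable (relative steady
  gap below 1%); for `K1' > 10 000` the stiffness term vanishes below
  S = 1000 and the soft-substrate genes can never activate from the naive
  state; intermediate values are reported inconclusive.

## Steady states and continuation

`relax_to_steady` drives batches of states to stable equilibria with a
damped-Newton-first strategy: a Newton root is accepted only if it (a)
converged, (b) lies within a relative trust distance 0.25 of the current
state, and (c) is linearly stable (leading Jacobian eigenvalue below
−1e−8). Otherwise the batch is advanced by clipped fixed-step RK4
(dt = 0.05) in chunks of 12 time units and re-polished, up to 3000 time
units. The stability guard prevents the polish from converging onto the
saddle a slowly escaping trajectory shadows near a fold. Residual
tolerance is 1e−9 in the infinity norm.

Quasi-static sweeps (`sweep`) walk a strictly monotone stiffness grid,
warm-starting each point from the previous steady state — increasing
sweeps start from the naive all-low state, decreasing sweeps from the
converged top-stiffness state. Warm starts make the Newton path succeed
everywhere except across folds, where the integration fallback selects
the surviving branch. A 500-point geometric grid over 0.1–60 kPa runs in
a few seconds and matches point-by-point adaptive (LSODA) relaxation to
~1e−8.

`find_equilibria` samples uniform random initial states in the box
1.2 × the production bounds (`k_max/d` per variable), relaxes them in one
batch, and merges endpoints within a relative tolerance of 1e−4;
stability is labelled from the leading eigenvalue. Counting is
deterministic under a fixed seed.

### Memory regions

A gene is classified ON at a sweep point when its level exceeds
θ = 0.5 × that gene's maximum over both branches. A memory region is a
maximal stiffness interval where the increasing and decreasing sweeps
disagree on the classification; its endpoints are refined by bisection
(continuing the local branch to the midpoint stiffness) to 0.01 kPa.
With default parameters the detected regions are TUBB3
[0.358, 0.598] kPa, PPARG [0.617, 1.303] kPa, MYOD1 [9.779, 13.099] kPa
and RUNX2 [0.100, 16.134] kPa (ON on the decreasing sweep); RUNX2's is
the widest, and the ordering of the regions along the stiffness axis
follows the neuro → adipo → myo → osteo progression.

## Dosing protocol

`run_two_seeding` integrates the model (LSODA, analytic Jacobian,
rtol 1e−8 / atol 1e−11) at the first stiffness on `[0, first_duration]`
and at the second on `[first_duration, total_time]`, with the state
continuous across the instantaneous switch. The default
`total_time = first_duration + 200` leaves all default-condition
endpoints stationary; stationarity is checked (residual < 1e−6) and
non-stationary endpoints are flagged `transient` rather than raised.
`classify_fate` maps a unique ON marker (absolute threshold 0.4, roughly
half the smallest ON plateau) to its lineage; zero or multiple ON markers
give `undifferentiated` / `ambiguous`.

With default parameters the staged duration dependence at a first
seeding of 30 kPa is compressed in time relative to the above timescale
intuition: from the naive state, SAA crosses the MYOD1-permissive window
(SAA ≈ 3) within ~0.6 time units and RUNX2 commits by t ≈ 3, so the
neurogenic/adipogenic/myogenic/osteogenic progression occurs over priming
durations of roughly 0 / 0.5 / 2 / ≥3 rather than tens of units. The
qualitative invariants hold: the remembered (osteogenic) duration set is
upward-closed, and the number of reachable fates across durations falls
4 → 3 → 2 as the second stiffness increases through 0.4 / 0.9 / 12 kPa.

## Robustness analysis

For the stiffness sample vector (uniform on [0.2, 42] kPa), the baseline
increasing/decreasing branch levels of the four lineage genes are stacked
into `Q_lower`, `Q_upper`. Each parameter is perturbed multiplicatively
with log-normal factors (median 1, coefficient of variation 0.05 via
`σ = sqrt(log(1 + CV²))`), the perturbed branches are recomputed from the
same initial conditions, and a perturbation passes when
`‖ΔQ_upper‖₂ + ‖ΔQ_lower‖₂ < TOL = 4`. A parameter is robust when more
than half its perturbations pass. The four genes' branch vectors enter
one stacked inequality; a strictly more lenient per-gene variant is
available behind a flag. Perturbation streams are seeded per parameter
(`SeedSequence([seed, index])`), so single-parameter scores equal the
corresponding slice of the batched run. Hill exponents are perturbed as
continuous values.

At the scaled-down sampling (200 stiffness samples × 200 perturbations,
seed 0), 40 of 41 parameters are robust; the borderline parameter is k5
(R = 47.5%) and the next least robust are K15, n15, K16, n16 — all in
the RUNX2 equation — at 55–67%, far below every other parameter (≥ 97%).

## Quasi-potential landscape

Around each stable attractor `X̄` the stationary distribution of the
weak-noise Fokker–Planck equation is approximated by a Gaussian whose
covariance solves the Lyapunov equation `Aσ + σAᵀ = −2D·diag(d(X̄))`,
with `A` the Jacobian at the attractor and `d(X)` the diffusion function
(state-proportional by default, constant optionally; D = 0.01). Only the
diagonal of σ is kept (mean-field factorisation). Basin weights are the
occupancy fractions of a seeded multi-start relaxation (10 000 starts by
default). The density is the weighted mixture of these Gaussians,
marginalised onto the (SAA, YAP/TAZ) plane by coordinate deletion (exact
for diagonal Gaussians), floored at 1e−300, and reported as U = −ln P.
Local minima are counted as plateau-connected components below all
neighbours, excluding plateaus touching the grid edge.

## Stochastic extension

`simulate_sde` integrates `dX = F(X, S)dt + η·X·dW` by Euler–Maruyama
with a single scalar Wiener increment shared by all six variables
(independent increments optional), `η = sqrt(0.05)` by default,
non-negativity enforced by clipping (the clipped fraction is reported and
warned about above 0.1%), and a stability guard `η·sqrt(dt) < 0.5`.
Replicates draw from one seeded generator, making every output
reproducible. `detect_fate_switch` reports maximal single-marker-ON
episodes and the switches between consecutive distinct episodes. At
η = 0 the scheme reduces to explicit Euler and matches the deterministic
trajectory to the expected O(dt) accuracy.

## Numerical and design choices

- Internal stiffness units are Pa-like (kPa × 1000): the stiffness Hill
  constants (600, 1300, 20 000, 60 000) only place the activation
  thresholds at the observed 0.3–40 kPa fate boundaries with this
  scaling.
- Uniform stiffness sampling is used in the robustness analysis;
  geometric spacing elsewhere (the interesting structure spans two
  decades).
- Sweep classification threshold θ = 0.5 of the per-gene branch maximum;
  dosing uses the absolute threshold 0.4. Both are exposed as arguments.
- All tabular outputs are plain CSV with dot decimals and fixed column
  order; every stochastic artefact records its seed.

## Limitations

- The quasi-potential is a weak-noise, diagonal-Gaussian approximation;
  it does not capture barrier heights far from attractors, and the
  projection ignores correlations between the projected and deleted
  coordinates.
- Euler–Maruyama with clipping is first-order and biased near zero;
  results at large η or dt should be treated qualitatively.
- The model is a minimal caricature: no cell–cell coupling, no spatial
  structure, no explicit substrate remodelling; time is relative, and no
  mapping to laboratory days is asserted.
- The deterministic timescale of commitment during stiff priming is set
  by the unit degradation rates and is faster (by roughly an order of
  magnitude) than the staged progression one might expect from slow
  adhesion maturation; only the ordering of the stages, not their printed
  durations, should be relied upon.
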