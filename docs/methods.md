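# Methods

## Model

The package models S-phase replication of a linear chromosome carrying
`m` origins. Origin *i* is the triplet (*L_i*, *T_si*, *T_ei*): a position
in bp and a firing window in minutes within which its latent firing time
is uniform. Forks move bidirectionally at a constant velocity *v* (bp/min)
and do not stall; distance is |*L_i* − *x*| (no circularity). Every origin
is licensed (potential firing probability 1); an origin is *passively*
replicated — and its own initiation suppressed — whenever a fork from a
neighbour arrives before its latent time. Observed firing efficiency is
therefore an emergent property of the interaction between neighbouring
origins, the firing windows and the fork velocity, not a free parameter.

Three analytic quantities follow:

* **Replication CDF.** With independent latent times, the fork from
  origin *i* passes locus *k* before *t* with probability
  U_ik(t), the uniform CDF on (T_si + D_ik/v, T_ei + D_ik/v), and
  P{Y_k ≤ t} = 1 − ∏_i (1 − U_ik(t)).
  Degenerate windows (T_s = T_e) are unit steps — kept legal so tests can
  build deterministic scenarios and limits stay well defined.
* **T0/T100.** T0(k) = min_i of the earliest arrival bounds; T100(k) =
  min_i of the latest arrival bounds (the first of the latest forks
  finishes the locus in every cell).
* **Firing efficiency.** e_k = P(F_k < min_{j≠k} A_jk) with
  F_k ~ U(T_sk, T_ek) and A_jk = F_j + D_jk/v. The integrand
  ∏_j P(A_jk > t) is piecewise polynomial (each survival factor is
  piecewise linear), so the integral is evaluated *exactly*: the firing
  window is split at every competitor arrival bound and each segment
  integrated with a Gauss–Legendre rule whose order covers degree m − 1.
  The result is clipped to [0, 1] against last-ulp overshoot. The test
  suite cross-checks against an independent adaptive-quadrature oracle
  (agreement to 1e−6) and against the Monte-Carlo simulator.

### Monte-Carlo oracle

`simulate_cells` realises the model cell by cell: one latent firing time
per origin per cell. On a line with constant bidirectional fork speed the
replication time of a locus equals min_i (F_i + D_ik/v) *whether or not
origin i actually fired*: if origin i was passively replicated by a fork
from j, the triangle inequality along the line makes the relayed fork
from j never later than the direct one. Origin k fires actively in a cell
iff F_k < min_{j≠k}(F_j + D_jk/v). This makes the simulator an
independent check of both the CDF factorisation and the exact efficiency
integral under the suppression semantics.

## Synthetic data

`simulate_timecourse` evaluates the analytic CDF on a probe grid
(default 1 kbp spacing) and adds i.i.d. Gaussian noise, default
N(0, 0.1) on the normalised scale — a realistic noise floor for
synchronised-culture array ratios. Noise is added to the normalised
signal and deliberately **not clamped** to [0, 1], so downstream
normalisation is exercised on out-of-range values exactly as real
measurements would produce. `n_replicates > 1` averages independent
realisations.

Two packaged models define the study conditions:

* `example_two_origin`: 5 kbp chromosome, origins at 1 kbp (window
  0–10 min) and 4 kbp (2–6 min), v = 1 kbp/min, noiseless, probes every
  1 kbp, one-minute sampling. Every derived quantity is hand-checkable.
* `benchmark_nine_origin`: 100 kbp chromosome, nine origins
  (constants `NINE_ORIGIN_TRUTH`), v = 1.5 kbp/min, 100 probes, ten time
  points over 0–18 min, noise sd 0.1. The origins at 12 kbp and 70 kbp
  fire late next to early efficient neighbours (true efficiencies ≈ 0.26
  and 0.35): their timing-profile signature is weak, making them the
  designated hard cases for recovery. Sizes were chosen so the full
  recovery experiment runs comfortably on one CPU.

What the generator does *not* emulate: probe effects, dye bias,
cell-cycle asynchrony, replicate-specific artefacts, variable fork speed
or stalling. Passing tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions plus white noise,
not robustness to every failure mode of real arrays.

## Data-side estimators

* **Normalisation**: per locus, affine rescale anchored on the first and
  last time points (optionally 3-point smoothed), so curves run 0 → 1.
  Monotonicity is not enforced. Loci with dynamic range < `epsilon`
  (default 0.2, well below the unit range of a replicating locus and
  above typical noise excursions) are flagged invalid and excluded
  downstream.
* **Timing profile**: T50 is the first upward crossing of 0.5 with linear
  interpolation. T0/T100 come from the crossings of configurable
  thresholds lo = 0.05 and hi = 0.95, linearly extrapolated to levels 0
  and 1; interior thresholds are robust to tail noise and the
  extrapolation removes their bias. T50 is clipped into [T0, T100]; loci
  with missing or out-of-order crossings are flagged invalid.
* **Fork velocity**: origins are local minima of the T50 track (stored in
  minutes; plotted replication-timing profiles conventionally draw early
  replication upward, where the same loci are peaks). For each origin
  flanked by convergence valleys on both sides, v = total distance to the
  valleys / total T50 rise; the median over qualifying origins is
  returned. Extrema are detected on a 3-probe moving-median-smoothed
  track with a prominence floor of 10% of the track range (suppressing
  noise wiggles); rises are measured on the raw track because the median
  filter clips extremum values by one probe's slope. The method is
  first-order: on stochastic (wide-window) origin configurations the T50
  track flattens near extrema and the estimate is biased high — on the
  packaged nine-origin benchmark by roughly +45%. It is accurate (within
  a few percent) for near-deterministic, well-separated origins. When no
  qualifying origin exists the estimator raises and asks for a manual
  velocity; for quantitative efficiency work, an externally measured
  velocity is preferable whenever one is available.

## Inverse fit

The SSE objective sums squared differences between the normalised matrix
and the model CDF over valid loci and all time points. Search state is
the flat vector of m triplets. Simulated annealing uses: Gaussian
single-coordinate proposals (sd 2 probe spacings for locations, 5% of
the sampled span for times), reflection at bounds and swap of crossed
window bounds; initial temperature calibrated so ~80% of initial uphill
moves accept; geometric cooling 0.97; 100·m proposals per level; stop
after 150 levels or 15 without improving the best SSE; then a
zero-temperature quench (300·m proposals with step sizes × 0.2) polishes
the best state. The quench matters: without it the proposal scale leaves
fits measurably short of their local optimum, and the best-of-run SSE
fails to reach the true model's SSE on noisy benchmark data in most
runs (it reaches it in ~90% of runs with the quench).

Per search, efficiencies of the fitted origins are computed exactly and
origins with efficiency < 1e−6 (dormant) are discarded. The origin-count
sweep covers 5–15% of the valid loci with at most 10 evenly spaced
values; every (m, restart) search is weighted equally. Regional firing
efficiency at x is the capped sum Σ e_i over fitted origins within
x ± window/2 (active firings of tightly clustered origins are nearly
mutually exclusive, so the sum is the natural aggregate; the
complement-product 1 − ∏(1 − e_i) is available via `combine="product"`),
averaged over all searches. The curve grid extends one window beyond the
probed range so near-end plateaus remain detectable.

Origins are called at curve peaks above 0.05 (strict), with minimum peak
separation window/2. Plateaus resolve to their midpoint: an isolated
origin yields a window-wide rectangular plateau centred on it, so the
midpoint is the unbiased location. The call's firing window is the
median over the windows of contributing fitted origins across all
searches; its efficiency is the peak height. All randomness flows from a
single master seed through spawned child sequences, so the whole
pipeline is reproducible.

`region_window` defaults to 3 kbp (yeast probe scale; use ~50 kbp for
human-scale data) and `peak_threshold` to 0.05.

## Known limitations

* Constant fork velocity; no stalling, no direction-resolved dynamics.
* Uniform firing-time distributions only.
* The velocity estimator's first-order bias above; quantitative
  efficiency estimates inherit any velocity error.
* Capped-sum regional aggregation can merge origins closer than the
  window; choose the window below the expected inter-origin distance.
* Single-chromosome fits; no joint model selection across origin counts
  beyond the pooled curve.
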