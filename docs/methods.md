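# Methods

This note documents the models, conventions and numerical choices behind
`spikesync`: what the synthetic generators simulate, how each measure is
defined where its original publication leaves freedom, and how the
evaluation machinery (benchmark, bias/variability sweeps, fingerprinting,
decoding, intrinsic dimension) is put together.

## Synthetic spike-train generators

Both generators produce a multivariate point process: `N` neurons over a
half-open window `[0, T)`, with a hard neuronal refractory period
`t_refr_neu = 4 ms` enforced after all stochastic steps (the earlier spike
always wins). All rate equations are evaluated on a `dt = 0.01 ms` grid and
spikes are drawn per step as Bernoulli events with probability `r(t)·dt`
(an error is raised if `r(t)·dt` would exceed 1). One master seed drives
everything; grids derive one child stream per train by position, so trains
are independent and any train can be regenerated in isolation.

### Single-scale family (inhomogeneous Poisson)

The instantaneous rate is a sinusoid of a phase variable,
`r(t) = r0·[1 + m·sin(phase)]`, with mean rate `r0` and modulation
amplitude `m` (the synchrony parameter: `m = 0` is a homogeneous Poisson
population, `m = 1` full-depth co-modulation).

* **Pseudo-rhythmic** trains use the linear phase `2*pi*f0*t + phi_n(t)`,
  where `phi_n` is Ornstein–Uhlenbeck phase noise with time constant
  `tau_OU = 10 ms` and stationary SD `sigma_OU = 0.4*pi*f0/1000` rad.  The
  OU series uses the exact discrete transition (mean `phi·exp(-dt/tau)`,
  SD `sigma·sqrt(1-exp(-2dt/tau))`), so its stationary statistics are exact
  at any step size.  All neurons of a train share one phase-noise
  realization — they sample the same inhomogeneous rate.
* **Non-rhythmic** trains replace the linear phase by a piecewise-linear
  phase that advances by `pi` between nodes; inter-node intervals follow a
  refractory exponential (shift `t_refr_pop = 0.1/(2 f0)`, rate
  `lambda = 2 f0 ·exp(2 f0 t_refr_pop)`; the factor 2 equates the peak-rate
  cadence of the two branches).  The initial phase `phi_ic` is drawn
  uniformly per train.  The node sequence starts one interval before `t = 0`
  so the window carries no onset artifact.
* **Sequential structure**: neuron `j` (1-based, `j = 1` the leader) gets a
  phase offset `2*pi*Dc*(1/2 - (j-1)/(N-1))` (pseudo-rhythmic) or a
  per-cycle node compression `t_{i+1,j} = t_{i,N} + INI_i·(1 - Dc·(N-j)/(N-1))`
  (non-rhythmic), where the duty cycle `Dc` is the active fraction of a
  cycle spanned by the leader-to-follower progression.  `Dc = 0` reproduces
  the non-sequential generator bit-for-bit under the same seed (single code
  path, identical RNG consumption).

### Dual-scale family (doubly stochastic)

Population events come first; spikes are jittered copies of the events.

* **Pseudo-rhythmic** events are the upward crossings of
  `(2*pi*f0*t + phi_n(t)) mod 2*pi` through the reference phase `pi/2`, at
  least `t_refr_pop` after the previous event.
* **Non-rhythmic** events form a renewal process with refractory-exponential
  inter-event intervals (rate `lambda = f0·exp(f0·t_refr_pop)`), started at
  `t = 0`.
* Every neuron emits one candidate spike per event at
  `t_event + bias_j + Delta`, `Delta ~ N(0, sigma)` with `sigma = Sigma/f0`
  (`Sigma` is the synchrony-tightness parameter, a fraction of the mean
  inter-event interval); the sequential bias is
  `(Dc/f0)·((j-1)/(N-1) - 1/2)`.  Spikes are then deleted independently with
  probability `p_fail`, clipped to `[0, T)`, sorted, and refractory-filtered.

### Benchmark grid

The full grid crosses, for each family, rhythmicity (2) x duty cycle
{0, 0.2, 0.4} x the two family-specific parameter grids
(`r0 ∈ {1,4,8,12,36}` Hz x `m ∈ {0,…,1}` for single-scale;
`Sigma ∈ {0.1,…,0.5}` x `p_fail ∈ {0,…,0.8}` for dual-scale) x
`f0 ∈ {4,12,36}` Hz: 450 + 450 = 900 trains (150 non-sequential and 300
sequential per family). The reference conditions are `N = 100` neurons and
`T = 10 s`; the grid can be scaled down in `N` and `T` without changing its
size. The library's own desk-scale evaluations (acceptance script and the
geometry tests) use `N = 20`, `T = 10 s` — chosen so a full 900-train
extended run completes in minutes on one core while preserving the
between-train structure that the geometry analyses probe.

## The measure library

46 core measures: 9 univariate (averaged across neurons), 11 timescale-free
bivariate (averaged over all unordered neuron pairs), 4 timescale-free
multivariate, 10 spectral, and 12 timescale-dependent measures (11
bivariate + the Golomb–Rinzel chi) at `tau = 1 ms`. The extended set (131)
evaluates the timescale-dependent measures at
`tau ∈ {1,2,4,8,16,32,64} ms` and adds the 13 dual-peak spectral
parameters. Antisymmetric delay-asymmetry measures (`S_qq`, `S_qqa`) are
averaged signed over ordered pairs `i < j`, preserving sequential sign
structure. Values a measure cannot produce (too few spikes, empty trains,
no significant spectral peak) are NaN; downstream statistics are
pairwise-complete, and PCA/MDS/ID impute at the median.

Conventions where the original publications leave choices open (each is a
package convention, stated here once):

* **LvR** uses the refractoriness constant `R = 5 ms`.
* **Log-ISI entropy** is the Shannon entropy (bits) of the log2-ISI
  histogram with fixed 0.25-octave bins anchored at integer multiples of
  the bin width.
* **IR** and the Miura irregularity use natural logarithms;
  `S_M = mean of -0.5·log(4·I_i·I_{i+1}/(I_i+I_{i+1})^2)`.
* **Victor–Purpura** shift cost is `2|dt|/tau` per spike, so a shift of
  exactly `tau` costs the same as delete+insert; `D_VPN = D_VP/(n_a+n_b)`
  removes the linear spike-count dependence.
* **van Rossum** uses the causal exponential kernel with decay `tau` and
  `D^2 = (E_aa + E_bb - 2E_ab)/2` in units where one unpaired spike has
  unit cost; `D_vRn = D_vR/sqrt(n_a+n_b)`.
* **Schreiber correlation** is the normalized Gaussian-filtered inner
  product (kernel SD `tau`); the **Kruskal correlation** is its
  mean-subtracted counterpart, i.e. the Pearson correlation of the two
  filtered rate functions, computed in closed form (kernel tails beyond 8
  SD are truncated; relative error < 1e-6).
* **Event synchronization** counts follower spikes within `tau` (ties
  count 1/2 for each direction); the adaptive variants use
  `tau_ij = min(four surrounding ISIs)/2`.
* **Phase measures** (MPC, PPC) assign each spike of one train a linear
  phase within the containing ISI of the other train and average the two
  reference directions; PPC is the unbiased square of the resultant length.
* **EMD**: `D_EMDN` is the 1-D Wasserstein distance between the two
  normalized spike-time distributions; `D_EMD` multiplies it by the mean
  spike count, restoring the intensity dependence of unnormalized
  transport. Distances to an empty train are defined for D_VP and D_vR
  (pure deletion cost / self norm) and NaN for the EMD pair.
* **Modulus metric** integrates `|d_a(t) - d_b(t)|` (nearest-spike
  distance functions) exactly over `[0, T]` by piecewise-linear segments;
  `D_MMN = D_MM/T`.
* **LZ distance** binarizes each train at the 4 ms refractory width (bins
  hold at most one spike, so the word is near-lossless) and uses
  exhaustive-history Lempel–Ziv production complexity
  (`d = max(C(xy)-C(x), C(yx)-C(y)) / max(C(x), C(y))`), computed in O(L)
  with an incremental suffix automaton.  The self-distance of a finite word
  is the parsing overhead O(1/C), small but not exactly zero — the one
  distance in the library whose self-comparison identity is approximate.
* **ISI- and SPIKE-distance** profiles use auxiliary edge spikes at 0 and T
  and are integrated exactly (piecewise-constant / trapezoid on the merged
  event breakpoints).
* **Tiesinga–Sejnowski synchrony** is `(CV_pooled - 1)/sqrt(N)` of the
  pooled train's ISIs; **Golomb–Rinzel chi** is the ratio of
  population-rate variance to mean single-neuron variance of
  Gaussian-smoothed (SD `tau`) rate functions, with the grid step adapted
  to `tau` (at most `tau/4`, never finer than 0.5 ms).
* **SPIKE-synchronization** is the fraction of spikes with an
  adaptive-window coincident partner, pooled over all pairs.
* **Spike-contrast** sweeps half-overlapping bins from `T/2` down to 1 ms
  by factors of 2 and reports the maximum of contrast x active-neuron
  fraction.
* **Synfire indicator** `F_S` is the mean signed adaptive delay asymmetry
  over ordered pairs, maximized over neuron orderings (exact permutation
  search for N ≤ 8, row-sum seriation above; the indicator is therefore
  invariant to neuron relabeling).

## Spectral parameterization

The population rate is the across-neuron mean of per-neuron Gaussian kernel
estimates (SD 2 ms on a 1 ms grid; reflection at the edges keeps the rate
integral exactly `spike count / N`). Its Welch spectrum (2 s Hann segments,
50% overlap, band 1–100 Hz) is summarized by `PSD_max`/`f_max` and by an
aperiodic-plus-peaks decomposition of the log spectrum:
`log10 P = b_L - chi_L·log10 f` plus one or two Gaussians fit in log-power.
The aperiodic baseline is fit robustly (iteratively discarding
top-quartile positive residuals so peaks cannot bias it); a peak is
assigned only when its amplitude exceeds `2x` the SD of the aperiodic-fit
residuals with an absolute floor of 0.05 log10 units. Under this standard
relative rule an occasional noise excursion can pass threshold, which is
why non-rhythmic trains yield a small but nonzero peak fraction. The peak
"beta coefficient" is defined as `beta_G = A_G/sigma_G`. In the dual-peak
model, peak 1 is the peak whose center is closer to the single-peak
model's center (amplitude order decides if the single-peak model found no
peak), and `R2_ratio = R2_2p/R2`. Segment length was chosen to resolve the
benchmark's `f0 ∈ {4, 12, 36}` Hz within 10 s trains at 0.5 Hz resolution.

## Finite-sample bias and variability

For each measure S and each sample-size point (window length, or neuron
count), `N_st` independent trains give `S_bar` (mean), `sigma_S` (SD,
ddof 1), variability `V_S = |sigma_S/S_bar|` and bias
`B_S = (S_bar - S_hat)/sigma_S`, where the ground-truth proxy `S_hat` is
the mean at the largest point of the sweep. `N_st = 50` by default. When
`sigma_S = 0`, `B_S` is 0 if the means agree and signed infinity otherwise.
Purely asynchronous single-scale trains (`m = 0`) carry no synchrony signal
and are rejected from sweeps.

## Profiling, clustering, and geometry

Measure-parameter profiles use |Spearman rho| with a large-sample p-value
(permutation fallback below n = 20, uncorrected alpha 0.05). The
inter-measure distance is `D = 1 - |rho|` (pairwise-complete; measures
missing on more than half the rows are excluded with a warning; measure
pairs with no comparable rows are placed at the maximal distance 1 for
clustering). Hierarchical clustering is average linkage; leaves are
reported in increasing order of the height of the first non-singleton
cluster they join. Window-space analyses use signed Spearman similarity
(`D_w = 1 - rho`), classical metric MDS, and silhouette fingerprinting with
a label-permutation null (default 1000 permutations, threshold at the
1 - alpha quantile of permuted means).

Intrinsic dimension is estimated two ways. The PCA count is the number of
components needed to reach a cumulative explained-variance threshold
(0.95/0.99) of the per-measure z-scored matrix; because the spectrum of a
z-scored matrix is the same for either orientation, this number does not
depend on whether measures or trains are treated as rows. The
nearest-neighbor estimators treat the trains (or windows) as points in the
standardized measure space: TWO-NN is the Pareto maximum-likelihood
estimate from first/second-neighbor distance ratios, reported across
subsampling decimations; Gride generalizes to neighbor ranks
`(n1, 2*n1)` with a numerically maximized likelihood and an
observed-information standard error, reported across `n1 = 1, 2, 4, …`
(small `n1` probes the most local scale). Duplicate points are removed
(zero ratios are outside the likelihood's support). This train-cloud
orientation is what makes the estimate interpretable: the synthetic
families vary along about five generative parameter dimensions, and the
estimator reads that dimensionality off the measure space. On the
benchmark grid the estimates at intermediate scales land near 3–4 — the
parameters are not all independent in measure space — with the most local
scale of the single-scale family the highest, approaching the number of
spanned parameters.

## Decoding

A' is the held-out ROC area of a logistic readout on z-scored features,
averaged over folds (stratified 5-fold within recordings, or
leave-one-recording-out), so single-feature A' is exactly invariant under
strictly monotone feature transforms. Pair synergy is the normalized
improvement over the better constituent,
`S_A'(X,Y) = 100·(A'_XY - max(A'_X, A'_Y)) / (max(A'_X, A'_Y) - 0.5)`
percent; a duplicated feature has zero synergy by construction, and
negative synergies occur when a weak feature drags a linear readout down.
Significance thresholds come from label permutations.

## What the synthetic benchmark does and does not show

The generators produce stationary trains, homogeneous across neurons up to
the deterministic sequential offsets, with Poisson or
Gaussian-around-events microstructure. They span synchrony, rate or
reliability, population frequency, rhythmicity and sequentialness, but not
heterogeneous per-neuron rates, non-stationarity, bursting, or
oscillation-waveform asymmetries — so passing the benchmark says a measure
tracks the controlled parameters under these idealized conditions, not
that it is unbiased on biological data. The windowed/fingerprinting/
decoding pipeline is exercised end-to-end on synthetic "recordings";
applying it to real datasets only requires reading spike times from the
supported text/JSON formats.

## Known limitations

* `S_QQ` with a fixed timescale larger than typical ISIs can exceed 1
  (multiple follower matches per spike), a property inherited from the
  original counting rule.
* The STTC denominator `1 - P·T` can degenerate when a train tiles the
  whole window at large `tau`; such entries are NaN.
* The dual-peak spectral parameters are frequently unassigned on
  non-rhythmic trains by design; analyses treat them pairwise-complete or
  imputed, and they dominate the missing-value budget of the extended set.
* `F_S` above 8 neurons uses a seriation heuristic; orderings within ties
  are resolved by index.
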