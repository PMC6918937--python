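# Methods

This note documents the models, estimators and numerical choices behind
`fatiguenet`, and what the synthetic study can and cannot demonstrate.

## The analysis chain

The package re-implements the analysis workflow of sustained-attention
fatigue EEG studies as a tested pipeline:

1. **Rhythm decomposition.** Each 5-s, 256-Hz, 19-channel epoch is split
   into δ (2–4 Hz), θ (4–8), α1 (8–10), α2 (10–13) and β (13–30 Hz) by a
   brick-wall filter in the discrete Fourier domain: all DFT bins with
   |f| outside the band are zeroed and the epoch inverse-transformed.
   Band edges are half-open `[lo, hi)` so adjacent rhythms never share a
   bin (4 Hz belongs to θ). Filtering is per epoch; the Gibbs ringing this
   implies at 5-s window edges is accepted — it is small relative to the
   stochastic signals analysed, and the idempotence and band-confinement
   properties are exact by construction. Recordings at other rates are
   brought to 256 Hz by polyphase rational resampling (1000→256 Hz reduces
   to the exact factor 32/125).

2. **Fatigue index.** Power is the time-domain mean square of the
   band-filtered signal (equal to the PSD integral over the band, by
   Parseval, for brick-wall filtering). The index
   (θ + α1 + α2)/β is formed per epoch and channel and then averaged over
   epochs and the nine central channels F3, C3, P3, F4, C4, P4, Fz, Cz,
   Pz. Forming ratios before averaging makes the index robust to
   single-epoch outliers; δ is excluded because it marks drowsiness/sleep
   and overlaps with artifacts.

3. **Connectivity.** Dependence between channel pairs is the plug-in
   mutual information of a 2-D equal-width histogram, in nats, with the
   Miller–Madow correction `(K_xy − K_x − K_y + 1)/(2N)` subtracted
   (K = occupied bins/cells) and negative results clamped to zero. The
   default bin count per axis is `ceil(sqrt(N/5))` — 16 bins at N = 1280.
   One 19×19 adjacency matrix is produced per (subject, time point,
   condition) cell by averaging per-epoch estimates across the cell's
   epochs (averaging, rather than concatenating samples, keeps the
   per-epoch sample size matched to the bin rule and makes epochs
   exchangeable).

   Note on units and thresholds: histogram MI of *narrowband* signals
   carries a serial-correlation bias the Miller–Madow term does not
   remove; for α1-band noise at N = 1280 the independence floor is
   ≈ 0.14 nats (it is < 0.05 for white noise, which is what the
   calibration tests assert). Absolute thresholds therefore only have
   meaning relative to this estimator; the default sweep 0.15–0.35
   brackets the floor-to-strong-coupling range.

4. **Networks.** Adjacencies are binarized either by weight threshold
   (edge iff w ≥ T; ties survive) or by fixed mean degree K (keep the
   `m = round(nK/2)` largest weights, half-up rounding — n = 19, K = 5
   gives 48 edges; ties break lexicographically for determinism).
   Isolated nodes are a *flagged* outcome, never silently repaired:
   thresholds that isolate any node in any cell are excluded from group
   comparisons. On each binary graph we compute
   - `C`: mean over nodes of `2E_i/(K_i(K_i−1))` (degree < 2 contributes 0),
   - `L`: mean hop distance over ordered pairs, via BFS (unit-weight
     Dijkstra equivalent); for a disconnected graph the mean runs over
     reachable pairs only and a flag is set,
   - `σ = (C/C_rand)/(L/L_rand)` with `C_rand, L_rand` ensemble means over
     degree-preserving Maslov–Sneppen rewirings (default 250 nulls,
     10·|E| accepted double-edge swaps each, null i seeded from the
     master seed and i). σ uses ensemble-mean C_rand and L_rand, not
     per-null ratios. If the nulls are triangle-free (C_rand = 0) σ is
     reported as undefined rather than infinite.

   Dense graphs (density > 1/2) are rewired through their complement —
   the double-edge swap on the complement preserves the original degrees
   equally well and keeps proposal acceptance high, so near-complete
   graphs mix instead of stalling. A complete graph is returned unchanged
   (its degree sequence has a unique realization), which makes σ = 1
   exact there.

5. **Statistics.** One-way fixed-effects ANOVA across the five time
   points, computed from sums of squares, with the subject as the unit of
   analysis. Rhythm selection: ANOVA on mean MI (mean of the 171
   upper-triangle entries) per (rhythm, condition); pairs with p < 0.05
   enter network analysis. Pairwise time-point comparisons are two-group
   ANOVAs. Deliberate caveats, matching the workflow being
   re-implemented: repeated measures are treated as independent groups,
   and no multiple-testing correction is applied. Degenerate inputs are
   flagged: all-constant groups give an undefined F; zero within-group
   variance with non-zero between gives p = 0 with a flag.

## The synthetic generator

No public recordings exist for this kind of study, so the generator
produces 19-channel epochs with known ground truth; every default lives in
`fatiguenet/data/default_trajectory.yaml`.

Each channel is a sum over the five rhythms of band-limited Gaussian noise
(white noise through a zero-phase 4th-order Butterworth band-pass,
rescaled to unit RMS, then scaled by the rhythm's amplitude). Three
structural ingredients create the ground truth:

- **Spectral fatigue state.** θ/α1/α2 amplitudes are multiplied by the
  per-time-point `slow_fast_gain` (default 1.00, 1.12, 1.24, 1.36, 1.30),
  so the (θ+α1+α2)/β ratio rises to T3 and dips at T4. Baseline RMS
  amplitudes (δ 8, θ 6, α1 9, α2 6, β 5, arbitrary µV-scaled units)
  follow the usual resting dominance of slow rhythms over β.

- **Stationary spatial background.** Within every rhythm the channel
  noises carry a fixed correlation `ρ0(d) = 0.85·exp(−(d/1.1)²)` over
  schematic 10–20 head coordinates (implemented by mixing independent
  band-limited noises with the Cholesky factor of the correlation
  matrix, which leaves the spectrum untouched). Nearby electrodes thus
  share activity, as scalp recordings do, and thresholded baseline graphs
  are spatially clustered — the source of the σ > 1 small-world baseline.
  An RBF kernel is used because it is positive definite by construction.

- **α1 task coupling.** In the task state each α1 channel is the
  variance-preserving mixture `y = √(1−c_ch)·x_ch + √(c_ch)·s` with a
  single shared α1-band source `s` and `c_ch = c_t·u_ch`, where `c_t` is
  the per-time-point coupling (default 0.10, 0.22, 0.34, 0.46, 0.38) and
  `u_ch ~ U(0.5, 1.5)` are fixed per-subject channel weights. The resting
  state uses the constant baseline coupling 0.10, so only α1/task carries
  a time effect. A *uniform* mixture weight would leave all pairs
  exchangeable and the thresholded graphs Erdős–Rényi-like (σ ≈ 1 at
  every stage); the per-channel heterogeneity is what lets rising global
  coupling progressively override the spatial ranking of pair weights,
  reproducing the empirical signature of deepening fatigue: denser
  networks (C up, L down under thresholding) whose small-world index
  declines towards — but stays above — 1, under both binarization rules.
  An optional `coupling_disorder` ingredient can route part of the
  coupling through several shared sources with random per-subject
  loadings; it is off by default (it weakens the mean-MI rise).

Seed policy: a master seed spawns one child stream per
(subject, time point, condition) cell and one per subject (coupling
topography) through `numpy.random.SeedSequence` spawn keys on disjoint
stream tags, so any cell can be regenerated in isolation and cells are
mutually independent.

**What the generator does not emulate:** eye/muscle/cardiac artifacts,
1/f broadband background, volume-conduction forward physics,
non-stationarity within epochs, and any quantitative effect sizes of real
recordings (the literature reports only qualitative shapes; defaults were
chosen once to reproduce those shapes at realistic magnitudes). Passing
tests therefore demonstrate that the pipeline recovers a known ground
truth of this qualitative form — not that it would detect the effect in
any particular real dataset.

## Numerical choices and degenerate inputs

- MI term summation is performed in sorted order, which makes
  MI(x, y) = MI(y, x) exact to the last bit; marginals are summed as
  integer counts for the same reason.
- Constant (zero-range) inputs have MI defined as 0, with a warning.
- Histograms span each vector's observed min–max; MI is therefore
  invariant under affine rescaling of either channel.
- `resample` trims the polyphase output to `round(n·target/fs)` samples.
- Rewiring budgets: 10·|E| accepted swaps per null, with an attempt cap of
  100× that; hitting the cap (star graphs, cliques) returns the
  best-mixed graph with a warning.
- The fixed-degree tie rule and the half-up `round(nK/2)` edge count are
  arbitrary but frozen, making every graph construction deterministic.

## Scaled study sizes

The packaged acceptance checks run the full pipeline at a reduced size
chosen to keep a complete run on one CPU within minutes while preserving
every qualitative feature: 6 subjects, 5 epochs per cell, 50 nulls for
the threshold sweep (250 for the fixed-degree bound recomputed by
`scripts/acceptance.py`), against the full design's 18 subjects,
10 epochs, 250 nulls. The ANOVA type-I calibration uses 1000 simulated
null datasets at 4 channels × 1 s × 128 Hz with homogeneous constant
coupling 0.6 — strong enough that bias-corrected MI estimates sit clear
of the non-negativity clamp, whose mass at zero otherwise makes the test
conservative at tiny sample sizes.

## Known limitations

- The histogram MI estimator is biased for serially correlated signals;
  comparisons are valid within this estimator but MI values are not
  comparable across epoch lengths or bin rules.
- Independent-groups ANOVA on repeated measures and the absence of
  multiplicity control are reproduced deliberately (see above); a
  repeated-measures or mixed model would be the statistically preferable
  analysis of such a design.
- EDF files can be read (via MNE) but not written; epoch exchange uses
  CSV.
- Graph metrics target small dense networks (tens of nodes); the BFS and
  rewiring implementations are not tuned for large sparse graphs.
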