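# Methods

This note documents the models, statistics and numerical conventions behind
each module, the parameters that matter, what the synthetic generators do and
do not emulate, and the design choices taken where the design was genuinely
open.

## 1. The one-cycle rhythm-detection problem (`rhythms`)

### Design assumptions

The module targets a deliberately hard design: a free-running tissue sampled
over a *single* circadian cycle at CT0, 6, 12, 18 and 24 h with ~3
replicates per timepoint, where the CT24 samples are an independently
collected repeat of the CT0 phase. Because each explant free-runs without
registration to external time, cycles cannot be pooled, so the data carry no
information beyond the ordering of ~15 observations across 5 slots. Under
these conditions parametric rhythm tests are fragile; the module therefore
uses two rank tests with an exact permutation null.

### Statistics

* **JTK-style test.** For each candidate peak lag φ in the lag grid
  (default {0, 6, 12, 18} h), Kendall's τ_b is computed between the
  observations and the reference cos(2π(CT − φ)/period) evaluated at each
  observation's timepoint, with CT taken mod 24 so CT24 observations are
  referenced at the CT0 phase while still permuting as independent values.
  Reference values are rounded to 9 decimals so quarter-phase points tie
  exactly at zero. The test statistic is max_φ τ.
* **Umbrella test.** For each candidate peak k, every folded phase is mapped
  to a height equal to minus its distance from k on the 24 h circle, so the
  implied trough sits at the antipodal phase — the ordering of any cosine
  peaking at k. The statistic sums Mann–Whitney counts (ties at half weight)
  over all observation pairs whose heights strictly increase, centered at its
  permutation mean; the test statistic is the max over candidates. The
  *cyclic* height mapping matters: a linear umbrella anchored at CT0 cannot
  see waveforms peaking in the last sampled phase, whose rise begins mid
  cycle. When candidates tie (e.g. every trailing umbrella on a monotone
  trend), the latest candidate — the boundary umbrella — is reported.

### Permutation engine

Both statistics are linear in the pairwise comparison matrix
G[i,j] = 1{v_i < v_j} + ½·1{v_i = v_j}: the τ numerator is ⟨G, S_φ⟩ with
S_φ the antisymmetric sign matrix of the reference, and the umbrella
statistic is ⟨G, W_k⟩ − ½ΣW_k. The engine therefore permutes G's rows and
columns once per draw and evaluates every candidate of both tests by tensor
contraction. p-values are tail probabilities of the max statistic:

* exhaustive over all distinct assignments of observations to timepoint
  slots when their number (the multinomial coefficient) is within
  `exhaustive_bound` (default 20 000), giving p = (#{stat ≥ observed})/total;
* otherwise Monte-Carlo with a caller-supplied seed and the add-one estimate
  p = (1 + hits)/(B + 1), which is valid (P(p ≤ x) ≤ x up to Monte-Carlo
  error) by construction. Default B = 10 000.

Because the null distribution of either statistic depends on the data only
through the slot layout and the tie pattern, complete tie-free features in a
table share a single null sample; `call_circadian` exploits this, so a
1000-feature screen at B = 2000 runs in about a second. Reusing one null
sample across features leaves each feature's p-value marginally valid but
makes calls weakly dependent across features; at the default B this moves
realized table-wide call rates by at most a fraction of a percent.

### Calling convention

`is_circadian` requires p < α from *both* tests (default α = 0.05, raw
p-values). No across-feature multiplicity correction is applied — the dual
criterion is itself the conservativeness device, and the operating
characteristics (null call rate ≤ α, sensitivity ≈ 1 at amplitude 4× noise)
are verified by simulation in the acceptance suite. The reported peak phase
is the best JTK lag. Constant series return p = 1 with τ reported as 0 and
an undefined (NaN) phase.

### Scaling and phase clustering

Heatmap-style summaries rescale each feature's timepoint profile to [0, 1]
by min–max (constant rows map to 0.5) and k-means cluster the scaled rows
(default k = 4, one cluster per expected collection phase; fixed seed,
10 restarts). Clusters are renumbered by the timepoint of their centroid
maximum so labels are stable across runs.

## 2. SILAC proteome assembly (`proteome`)

The quantification filter retains a feature iff every timepoint has at least
two non-missing replicate ratios (configurable), then log2-transforms. The
decision uses only the missingness mask — never the values — so the filter is
idempotent and value-scrambling invariant (both property-tested). No CV or
variance filter is applied. Non-positive ratios are rejected naming the
offending cell. Labeling efficiency is reported both as heavy/(heavy+light)
(an incorporation fraction bounded by 1) and as the literal heavy/light count
ratio, since both conventions circulate.

## 3. Cell-type analytics (`cells`)

* **Cluster annotation**: per-gene cluster means are z-scored across
  clusters; a type's score is the mean z over its markers; argmax wins unless
  the top score is ≤ 0 or tied ("unclassified"). This scoring is this
  package's convention — annotation is often done manually — and the default
  marker map covers the common SCN cell types (astrocyte: Gfap, Aldh1l1,
  Aqp4, Sox9; SCN neuron: Slc32a1, Nms, Avp, Vip; ...).
* **Cluster-defining genes**: one-sided (greater) Mann–Whitney cluster vs.
  rest per gene, BH within cluster, adjusted p < 0.05, ordered by
  (adjusted p, raw p, symbol) for determinism, truncated to `top_n`
  (default 250).
* **Co-expression partition**: a cell expresses a gene iff its raw count ≥ 1
  (threshold configurable); the four joint categories are exclusive and
  exhaustive and are tallied overall and per type with the per-type
  percentage co-expressing both.
* **Day/night differential expression**: log2 fold change of label means
  with pseudocount 1 (stable on sparse counts), two-sided Mann–Whitney,
  BH. Requires ≥ 3 cells per label. Note the pseudocount shrinks the
  estimated fold change toward zero for genes whose mean count is small
  relative to 1.
* **Set intersection**: protein identifiers map through an optional
  protein→gene table, then case-insensitive symbol match.

## 4. Over-representation (`enrich`)

Hypergeometric upper-tail p per set, BH across sets, symbols case-folded
before matching. The default universe is the union of all set genes and the
query — stated explicitly because enrichment backends often hide this
choice; pass an explicit universe for anything quantitative. The term–gene
network is the bipartite edge list over the top-k terms; a gene's degree
counts the terms it bridges (nexus detection).

## 5. Trace metrics (`traces`)

### Preprocessing

* **Detrend**: a least-squares line fitted to the last 72 h (configurable)
  of the baseline epoch, subtracted from the fit-window start onward —
  projecting the baseline trend through treatment and washout.
* **Smooth**: centered moving average with shrinking end windows. The
  convention is a 2.5 h window — 5 points at 0.5 h imaging-like sampling,
  25 points at 0.1 h PMT-like sampling. Under-smoothing costs peak-time
  precision: near a 24 h cosine peak the signal curvature is shallow, so the
  residual noise sets a peak-time jitter of roughly ±0.5 h at a 0.5 h
  smoothing window versus ±0.2 h at 2.5 h.

### Peaks and peak-derived metrics

Extrema come from prominence- and separation-filtered local maxima/minima
(defaults: separation 16 h, prominence 0.2× the interquartile range of the
signal — both configurable; strongly suppressed epochs need a lower
prominence, e.g. 0.02, to keep their residual cycles detectable).
Same-kind neighbours are reduced to the more extreme one so peaks and troughs
alternate, and extremum times are refined to sub-grid precision by a
three-point parabola. Detection is normally run on the smoothed trace; the
raw trace can be passed instead.

* **Period**: mean consecutive peak spacing within an interval; ΔPeriod =
  treatment − baseline mean.
* **Cycle amplitude**: |peak − preceding trough| normalized to the last
  complete pre-treatment cycle.
* **Phase shift**: predicted minus observed second post-treatment peak,
  where predicted = last pre-treatment peak + 2× baseline period. The second
  peak is used so first-cycle waveform transients do not contaminate the
  sustained shift; the sign convention makes advances positive and delays
  negative.
* **B/A ratio**: rising amplitude (preceding trough → peak) over falling
  amplitude (peak → following trough). Stationary cycles give 1; a rhythm
  growing back after washout gives < 1, rising toward 1 as the oscillation
  re-establishes. The steady-state value is read at the second post-washout
  peak (the preceding trough of the first is often unrecorded).

### Cosine fit and RAE

The fit is offset + slope·t + A·cos(2π(t − φ)/τ) with τ bounded to a
circadian window (default 18–30 h) and (A, τ, φ) initialized from the
dominant discrete-Fourier component inside the window. RAE follows the
FFT-NLLS convention: half the width of the 95 % confidence interval on A
(t quantile × curvature-based standard error) divided by A, clipped to
[0, 1]. This is a single-component simplification of multi-component
FFT-NLLS tooling, so its guarantees are property-based — ≈ 0 for a noiseless
cosine, ≥ 0.8 on pure noise, monotone in the noise level — rather than
numeric equivalence to any external tool. A diverged fit reports RAE = 1
with a warning.

### Circular statistics and cohort summaries

The Rayleigh test maps CT to angles (2πCT/24), computes the mean resultant
length R and the standard series approximation of the tail probability of
Z = nR²; its type-I error at α = 0.05 is calibrated to within Monte-Carlo
error in the acceptance suite. Circadian time is assigned by anchoring a
reference peak (by convention the neuronal calcium peak at CT6) and
advancing 24 CT-hours per period. 24 h integrals are trapezoidal with
interpolated window edges; trailing partial windows are dropped.
Pseudo-alignment shifts each trace so its reference peak sits at t = 0,
resamples onto a grid at the coarsest input step by linear interpolation
(excluded samples wider than 1.5 steps propagate as gaps rather than being
bridged), and reports mean ± SEM with per-point n.

## 6. Synthetic data (`synthetic`)

### What is emulated

* **Traces**: drift + damped cosine + Gaussian noise, sampled at 0.1 h
  (PMT-like) or 0.5 h (imaging-like). Treatment epochs scale amplitude,
  shift phase (advance positive, persisting after the epoch) and offset
  level; washout recovery restores amplitude exponentially with a
  half-life. Ground truth (true period, analytic peak times of the
  noise-free oscillation) rides along on the trace.
* **Proteome tables**: 5 timepoints × 3 replicates; a chosen fraction of
  features (rounded count) follow an additive cosine on the log2 scale with
  peak phases assigned round-robin over {0, 6, 12, 18}; CT24 re-evaluates
  the CT0 phase with an independent noise draw, mirroring an independently
  repeated CT24/0 sample; missingness is i.i.d. Bernoulli.
* **Cell matrices**: negative-binomial counts (variance = μ + μ²/θ), marker
  genes scaled by a fold in their own type, a planted two-gene joint
  expression partition with per-type probabilities (the sampled category is
  enforced on the counts, so truth and data never disagree), and day/night
  labels applying half the log2 fold either side of baseline.

Defaults (3 replicates, ~10 % rhythmic, 24–25 h periods, treatment epochs
spanning a few cycles) reflect the study conditions the analysis modules
target. Noise magnitudes of real recordings are not published for this kind
of data; the defaults (e.g. trace noise 2 % of amplitude in the recovery
battery, log2 noise SD 0.1 in proteome tables) are exposed parameters
representing clean recordings, not claims about any instrument.

### What is not emulated

Raw spectra, peptide-level effects and ratio compression; read-level
scRNA-seq (library size variation, dropout beyond NB sparsity, doublets);
imaging artifacts and background. Passing tests therefore demonstrate the
statistical machinery under the assumed noise model, not robustness to
instrument-specific systematics.

### Reproducibility

One integer seed per generator call; every random draw derives from it, and
equal seeds give bit-identical outputs (tested).

## 7. Problem sizes in the test and acceptance runs

Simulation sizes were chosen as the smallest that make the statistical
assertions sharp: 1000 features for the null call rate and 500 (10 %
rhythmic) for sensitivity at 2000 permutations; 10 + 10 seeded instances at
10 000 permutations against the brute-force oracles; 100 seeds for the
white-noise RAE limit and 50 for the noise ladder; 10 000 draws for the
Rayleigh type-I calibration; ~300 h single traces for the recovery battery.

## 8. Known limitations

* The permutation tests are exchangeable-null tests: batch structure within
  replicates would violate the null and is not modelled.
* With 5 × 3 designs the attainable p floor under Monte-Carlo is
  1/(B + 1); screens wanting FDR control across many features need larger B
  than the 2000 used for operating-characteristic checks.
* The umbrella statistic's per-candidate variance differs slightly between
  boundary and interior peaks; the max-statistic permutation null absorbs
  this for validity, but best-peak identification near ties is
  convention-bound.
* RAE is not numerically comparable to multi-component FFT-NLLS outputs,
  only rank-comparable.
* `pseudo_align` linearly interpolates within traces; strongly non-uniform
  gaps bias the SEM at gap edges (points bridging wide gaps are dropped
  instead).
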