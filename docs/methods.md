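# Methods

## Data model

Expression data are best-latency points: at most one point per (hexel,
transform, hemisphere), each carrying a latency in milliseconds and a
surprisal. Surprisal is −log₁₀ *p* by default; the literature writes
only "−log(p)", and base 10 is the convention of expression-plot axes,
so conversion from a `pvalue` column uses log₁₀ (p = 0 underflow is
capped at surprisal 350 with a warning rather than rejected, since
exported datasets commonly contain it). Hexel ids are 0-based; on
hemisphere merging, right-hemisphere ids are offset by
`n_hexels_per_hemisphere` (default 10 242) so ids stay unique.
Significance thresholding corrects over the family hexels ×
hemispheres × transforms × latency steps, Bonferroni by default (Šidák
and uncorrected available); points at exactly the threshold are kept.

A candidate transform list maps each transform to its parents (other
transforms or declared input streams). It must be acyclic over
transforms, every parent must be declared, and every transform needs at
least one parent; validation returns a lexicographic topological order.

## Temporal denoising

All five strategies cluster on latency only — surprisal is dropped as a
clustering dimension but kept as point metadata because the focus of
each cluster is its most significant point. Focus ties break to the
earlier latency, then the lower hexel id, so output is deterministic.
Cluster labels are canonicalized to 0..k−1 by ascending mean latency.
Negative latencies are legal throughout (pre-stimulus artifacts).

- **Max pooling** uses half-open bins `[anchor + k·b, anchor + (k+1)·b)`
  with anchor 0 by default; bins with fewer than θ points are
  anomalous. The default bin of b = 50 ms is chosen to cover one full
  expression cluster at the characteristic latency jitter of these
  data (±2σ with σ = 10 ms); a narrower default fragments single
  effects across bin boundaries once clusters are well populated.
  Default θ = 2, so isolated high-surprisal points are discarded.
- **Adaptive max pooling** merges significant bins with consecutive
  indices transitively, giving variable-width clusters; b acts as a
  minimum width. Its output is always a coarsening of max pooling on
  the same grid.
- **GMM** fits 1-D Gaussian mixtures for K = 1..min(N_K, n) with
  scikit-learn (n_init initializations, near-zero covariance
  regularization) and selects K by minimal AIC. A fitted component
  whose variance falls below the covariance floor is treated as
  singular and the fit is retried with fresh seeded initializations, up
  to `max_retries`, after which that K is dropped from the grid; if
  every K is singular (e.g. a lone point, or all points coincident) the
  strategy falls back to a single cluster with a warning. The floor
  default is 1.0 ms²: with a 1 ms latency grid, a component narrower
  than the sampling resolution is a degenerate splinter rather than a
  real effect, and such splinters otherwise flip AIC selection on
  near-ties. Note that on freshly sampled blob data AIC itself
  occasionally prefers an extra non-degenerate component — a known
  small-sample property of AIC, not an implementation artifact.
- **Mean shift** delegates to scikit-learn's kernel mode seeking; mode
  merging follows the library's bandwidth-based convention.
- **DBSCAN** runs on |Δlatency| with noise labelled anomalous.

Anomaly criteria are only inherent to MP/AMP/DBSCAN; for GMM and mean
shift the notion is extended uniformly as "clusters smaller than
`min_cluster_points` are anomalous" (default 1, i.e. no anomalies).
One configuration is applied to every transform (transform-agnostic
denoising); per-transform hyperparameters are deliberately out of
scope.

## Map construction

The builder follows CTL direction regardless of latency — a child focus
earlier than its parent's final focus yields a backwards edge on
purpose, because causality violation must be measurable on the result.
"Final node of the parent" means its latest-latency focus and "initial
node of the child" its earliest, which fixes the semantics for
multi-focus transforms. Input-stream nodes are materialized once per
stream actually referenced, all at latency 0. A detected transform
whose parent was not detected is, under the default `bypass` policy,
connected to the parent's nearest detected ancestors (transitively,
falling back to the input stream); `prune` omits such edges instead.
Node ids are `transform@latency#hexel` strings for diff-able exports;
JSON export is lossless, DOT and GraphML carry latency, transform and
edge kind for visualization tools.

## Metrics

CV counts edges with strictly `l(dst) < l(src)`; equal latencies are
legal. An edgeless graph scores 0, matching the zero-signal limit.
Input-stream edges (which can never violate) and identity edges (which
are latency-ordered by construction) are included by default, with
toggles. TR's default denominator is the *detectable* transforms —
those with at least one significant point in the raw expression data —
because a generator cannot recover what the data do not contain; the
literal all-CTL denominator (`ctl_total`) is available and is the
default in the simulation sweep, where the ground truth is known to
contain every transform. An empty denominator yields TR = 0. The
merged-hemisphere ("both") evaluation merges first, then denoises.

## Hyperparameter search

The grid search enumerates the Cartesian product in sorted order;
failing combinations are recorded as (TR 0, CV 0) with a warning. The
frontier is the non-dominated set under (maximize TR, minimize CV) and
the selected point maximizes TR, breaking ties by minimal CV and then
by sorted parameter order. "Then CV" is read as *minimize* CV, the only
direction consistent with its definition. By default tuning scores the
same set being analysed — the data regime this pipeline operates in —
with a held-out mode (`eval_set`) provided for hygiene. Shipped default
grids include bin sizes up to the full latency axis so that a single
global pooling bin is reachable.

## Simulation harness

### Expression tier

`simulate_expression` emits points directly from a ground-truth map:
each transform contributes `n_sources` (default 10) points at latency
`true + N(0, σ²)` with σ = 10 ms by default, each detected with
probability `relative_strength`. Surprisal is `threshold +
Exp(scale)·exp(−jitter²/2σ²)`: the exponential gives a realistic
heavy-tailed evidence axis, and the damping makes the most significant
point tend to the true latency, as real expression clusters peak at
their center. Spurious significant points are added per transform at a
Poisson rate with uniform latencies. The bundled ground truth has three
input streams feeding `step_1..3` at 60 ms, null transforms
`null_1..3` at 100 ms, an early merge `step_4` at 70 ms and parallel
`step_5/6` at 125 ms — the 60→70 ms parent-child gap is deliberately
smaller than the jitter spread, so causality errors appear under noise.

### Signal tier

`simulate_recordings` replaces the anatomical forward model of a real
M/EEG simulation with a deliberately generic surrogate: each source
(ground truth or competing) is a delayed copy of its band-passed
(5–100 Hz Butterworth, zero-phase) white-noise signal, peak-normalized
to 1, inserted into one uniformly chosen channel, plus white
measurement noise (sd 0.3 of peak amplitude, comparable to a single
competing source). Competing activity is 500 insertions — 10 each of 50
distinct signals — at uniform 0–500 ms latencies, similarly jittered.
Absolute source amplitudes therefore become the dimensionless
`relative_strength ∈ [0, 1]` of the competing sources' unit amplitude.
Defaults are 30 s at 1 kHz over 64 channels (64 standing in for a
~300-sensor MEG array); the sweep experiments and the acceptance script
run 10 s at 250 Hz, which preserves the band and the detection physics
at a fraction of the cost.

What this surrogate does *not* emulate: anatomical lead fields and
their spatial correlations, sensor covariance structure, source
localization error, inter-subject variability. Passing recovery tests
therefore demonstrates the pipeline's logic under controlled noise, not
performance on real recordings.

### Detector

`detect_expression` correlates every channel with every candidate
transform signal at every lag on the sample grid within 0–500 ms and
takes the maximum (one-sided: entrainment is a positive match). The
p-value of the max comes from a no-association null in one of two
ways. The default analytic null treats the lagged-correlation sequence
as a stationary Gaussian process whose variance and second spectral
moment follow from the two power spectra, and bounds the tail of its
maximum by the Rice upcrossing rate — essentially the extreme-value
argument familiar from random-field thresholding. The permutation null
phase-randomizes the cross-spectrum (a spectrum-preserving surrogate
that keeps both autocorrelation structures while destroying phase
alignment; a plain circular shift is not used because the true peak
remains inside the 0–500 ms search window for a fifth of all shifts,
contaminating the null under signal). The analytic bound is slightly
conservative and agrees in rank with the surrogates; tests verify both
the agreement and a family-wise false-positive rate at or below α over
200 null runs. Significance is Bonferroni-corrected over the channel ×
transform family (the latency dimension is already absorbed into the
max statistic); each significant pair yields one expression point at
its best lag with surprisal −log₁₀ *p*.

### Strength sweep

`strength_sweep` runs the full simulate → detect → denoise → build →
evaluate pipeline per (strength, replicate) with fresh re-randomization
of source assignment, jitter, competing signals and noise, seeded
deterministically from a single master seed. At the default scaled
sizes the observed behaviour reproduces the expected shape: TR is zero
through 10–20%, a majority of transforms is recovered by ~30%, and TR
saturates at 1; CV is zero while nothing is recoverable, peaks at
intermediate strengths (where latency estimates are noisy and the
60/70 ms nodes invert), and declines at high strength.

## Numerical and degenerate-input conventions

- Tie-breaks: focus ties by latency then hexel id; Pareto ties by CV
  then sorted parameters; topological order lexicographic.
- Empty inputs: empty expression sets denoise to empty maps, build to
  empty graphs, and score TR = CV = 0.
- Determinism: MP/AMP/DBSCAN are deterministic; GMM and the simulators
  are deterministic given a seed (per-transform and per-replicate
  sub-seeds are derived from the master seed and stay below 2³¹);
  scikit-learn's mean shift is deterministic by construction.
- Floats are serialized with shortest-round-trip representation so
  write → read of an expression table is field-exact.

## Known limitations

- The signal tier's one-hot source-to-channel mixing understates the
  spatial blending of real sensor arrays; quantitative sweep curves are
  therefore not comparable to recordings, only the qualitative shape.
- CV is not comparable across different CTLs (different edge-count
  denominators), and the metric pair rewards single-node transforms, so
  tuned solutions tend toward global pooling and identity edges vanish.
- The detector is a stand-in for a full model-selection procedure; its
  latency estimates are grid-limited (one sample step).
- Per-transform hyperparameters, spatial denoising, and richer
  serial/parallel DAG semantics beyond the four canonical builder
  scenarios are out of scope.
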