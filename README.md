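# ippm

Automatic generation and objective evaluation of **Information
Processing Pathway Maps** (IPPMs) from M/EEG transform-expression data.

## The problem

An IPPM is a directed acyclic graph describing how sensory information
is transformed as it travels through cortex: nodes are significant
expression foci — a *transform* (a hypothesized mathematical function of
the stimulus or of upstream transform outputs), the cortical *hexel*
where its output is entrained, the *latency* of the best match, and the
evidence for it as surprisal, −log₁₀ *p* — and edges follow the
dependency structure of a *candidate transform list* (CTL). Because
M/EEG source estimation blurs activity (point spread), a single
underlying effect appears as a cluster of significant points jittered
along the latency axis, and pathway maps have traditionally been drawn
by eye. This package automates the process for researchers working with
expression data: it denoises the expression plot by temporal
clustering, builds the DAG, and scores the result objectively.

## The method

1. **Temporal denoising.** Per transform, significant points are
   clustered on latency alone by one of five strategies — max pooling
   (`mp`), adaptive max pooling (`amp`), a 1-D Gaussian mixture with
   AIC model selection and a singularity retry loop (`gmm`), mean shift
   (`meanshift`), or DBSCAN (`dbscan`). Points outside any cluster are
   anomalies; each cluster is reduced to its most significant point,
   the *focus*.
2. **DAG construction.** One node per focus; consecutive foci of the
   same transform are linked by *identity* edges; each CTL parent→child
   pair is linked from the parent's final (latest) focus to the child's
   initial (earliest) focus; input streams enter as nodes at latency 0.
   Undetected mid-chain transforms are bypassed (or pruned).
3. **Evaluation.** Two complementary metrics on the generated map
   *M = (V, E)* with node latencies *l(·)*:

   - Causality violation — information cannot travel backwards in time:

     CV = |{(u, v) ∈ E : l(v) < l(u)}| / |E|

   - Transform recall — the proportion of detectable transforms (those
     with significant evidence in the expression data) retained in the
     map:

     TR = |T_D| / |T_C|

4. **Hyperparameter selection.** Grid search over each strategy's
   hyperparameters, scored on (TR, CV); the Pareto frontier is
   extracted and the operating point first maximizes TR, then
   minimizes CV.
5. **Simulation harness.** Ground-truth recovery experiments at two
   tiers: direct synthesis of expression points with Gaussian latency
   jitter (σ = 10 ms) and spurious points, and a scaled-down
   signal-level simulation (band-passed 5–100 Hz white-noise
   computational signals mixed into generic channels with 500 competing
   source insertions) with a lagged-correlation detector.

## Worked example

Simulate a noisy expression dataset from the built-in three-stream
ground truth and fit a map with max pooling:

```python
from ippm import IPPM, SimConfig, simulate_expression, three_stream_preset

gt = three_stream_preset()
cfg = SimConfig(jitter_sd_ms=10.0, relative_strength=1.0)
sets, _ = simulate_expression(gt, cfg, spurious_rate=2.0, seed=0)
model = IPPM(sets["left"], gt.to_ctl(), strategy="mp")
res = model.fit(seed=0)
print(res.summary())
```

```
Information Processing Pathway Map
==================================================
Denoising strategy:     mp
Configuration:          {'bin_size_ms': 50.0, 'min_points': 2, 'bin_anchor_ms': 0.0}
Seed:                   0
Expression points:      107
Transforms in CTL:      9
Detectable transforms:  9
Recalled transforms:    9
Anomalous points:       12
Graph: 19 nodes, 18 edges
--------------------------------------------------
Transform recall (TR):      1.000  [detectable]
Causality violation (CV):   0.111  (2/18 edges)
--------------------------------------------------
Foci:
transform  cluster  hexel hemisphere  latency_ms      logp
   null_1        0   3921       left  102.847161  8.620373
   ...
   step_6        0   8398       left  132.349268 11.461719
```

All nine transforms were recovered (TR = 1) but 2 of the 18 edges face
backwards in time (CV = 0.111): under 10 ms jitter, foci of the early
merge node (true latency 70 ms) can precede those of its 60 ms parents,
and a spurious cluster at 325 ms extends `step_4`'s chain. At zero
jitter and no spurious points the fitted map is exactly the ground
truth (TR = 1, CV = 0).

The same pipeline is available from the shell:

```sh
ippm --seed 0 simulate --strength 1.0 --out sim/
ippm denoise --expression sim/expression_left.tsv --strategy mp --out sim/foci.tsv
ippm build --foci sim/foci.tsv --ctl sim/ctl.json --formats json,dot --out sim/graph
ippm --seed 0 search --expression sim/expression_left.tsv --ctl sim/ctl.json \
     --strategy mp --out sim/pareto.json
```

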