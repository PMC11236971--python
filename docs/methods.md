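# Methods

## The spatiotemporal connectome model

The pipeline characterizes resting-state brain dynamics as transient,
structurally constrained co-activation events.

**Point process.** Each region's parcellated BOLD series is z-scored
against its own mean and sample SD (ddof = 1, configurable to the
population estimator) and binarized at z >= 2 (inclusive; threshold
configurable). Only positive deflections count: the point-process
literature this framework builds on treats supra-threshold peaks as the
events of interest, and de-activations are ignored. Regions with zero
variance across frames are everywhere inactive. No detrending, filtering
or nuisance regression happens here — input series are assumed
preprocessed and trimmed of non-steady-state frames.

**Multilayer graph.** Nodes are active (region, frame) cells. Two nodes
are joined when the frames are identical or consecutive and the regions
are either identical (temporal self-continuity) or joined by a binarized
structural connection (weight > `sc_threshold`, default 0). The
self-continuity edge is not strictly implied by the co-activation rule for
region *pairs*, but without it a persistently active region with no active
structural neighbours would fragment into single-frame pieces; it can be
switched off (`temporal_self_edges=False`). Frames (not sliding windows)
are the temporal unit throughout.

**Connected components (CCs).** Weakly connected components of this graph
are the objects of analysis. Per CC: the spatial activation vector
x (x_i = number of frames in the CC in which region i is active),
`size` = node count = sum(x), `length` = inclusive frame span
t_max − t_min + 1 (this equals the number of distinct active frames for
temporally contiguous CCs and is never smaller), and
`height` = (#regions with x_i > 0) / N. Components below `min_cc_size`
(default 2) are discarded but counted, so retained + discarded nodes
always partition the active cells; a single-node "component" carries no
connectivity information, but every group statistic can be recomputed at
`min_cc_size=1` to check sensitivity.

Extraction is backed by `scipy.sparse.csgraph.connected_components` over a
vectorized edge enumeration; tests verify exact agreement with a
brute-force BFS over explicitly enumerated nodes and edges on hundreds of
random instances.

## Diversity metrics

Each CC is embedded as the 8-vector of activation mass per functional
system (VIS, SM, DA, VA, LIM, FP, DM, CBL): mass[f] = sum of x over
regions labeled f. Mass is conserved (sum = CC size).

**System diversity (SD)** is the per-CC Shannon entropy of the mass
distribution in nats, normalized by ln 8 into [0, 1], averaged without
weighting over the pool ("mean of per-CC entropies" — a pooled-histogram
variant is available via `sd_variant="pooled_hist"`). SD = 0 iff every
pooled CC is confined to one system; SD = 1 requires uniform mass over all
8 systems. Higher SD = more cross-system integration.

**Spatiotemporal diversity (STD)** is region-anchored: for every region
participating in >= 2 pooled CCs, take 1 − mean pairwise cosine
similarity between the L2-normalized embeddings of those CCs, then average
over qualifying regions. Because embeddings are nonnegative, cosines lie
in [0, 1] and STD does in [0, 1]. Lower STD = the region keeps a stable
system composition over time. The mean pairwise cosine is computed in
closed form, (||Σu||² − n) / (n(n−1)) for n unit vectors u, which tests
verify against the explicit all-pairs average to 1e−10. An all-CC-pairs
variant (ignoring region anchoring) is available via
`std_variant="all_pairs"`.

STD is implemented as a *dissimilarity* (1 − cosine) so that "lower STD"
corresponds to "higher stability", which is the only orientation that
makes the metric's computation and its interpretation consistent.

Both metrics are group-level. They need a pool of CCs concatenated across
subjects; per-subject values are deliberately not offered because single
subjects rarely produce enough CCs to cover the system vocabulary.

**System scale.** A CC is attributed to every system containing at least
20% (`attribution_frac`) of its involved regions — multiple attribution is
allowed whenever two or more systems reach the threshold. The
maximal-share system is always attributed (ties broken by the canonical
system order) so no CC is orphaned. SD and STD are then recomputed on each
system's sub-pool; sub-pools failing a metric's preconditions yield
flagged NaNs, not errors.

## Group inference

**Permutation test.** The unit of exchangeability is the subject: whole CC
sets move together, because CCs within a subject are dependent. Each of
`n_perm` (default 1000) permutations reassigns subjects to groups
preserving group sizes, re-pools, and recomputes the pooled metric
difference; two-tailed p = (1 + #{|Δ_perm| >= |Δ_obs|}) / (n_valid + 1),
so p >= 1/(n_valid + 1) and the test is valid at finite n_perm.
Permutations on which a pooled metric is undefined are dropped and
counted. A with-replacement bootstrap variant exists behind
`method="bootstrap"` but is not the default. The implementation evaluates
permutations from per-subject sufficient statistics (entropy sums and
per-region embedding sums), which tests verify against direct sub-pool
recomputation.

**FDR.** Benjamini–Hochberg step-up over the 8 per-system tests, applied
separately per metric family (8 tests for SD, 8 for STD), via
`statsmodels.stats.multitest.multipletests`; verified against a textbook
step-up loop.

**ANCOVA.** Per-subject CC summaries (count, mean length, mean height)
are modeled as response ~ group + age + group:age by OLS with effect-coded
group (sum contrasts) and mean-centered age, Type-III F tests
(statsmodels `anova_lm(typ=3)`); with both terms and the interaction the
residual df is n − 4 regardless of imbalance. Subjects with undefined
summaries (no retained CCs) are excluded and reported. A constant response
returns F = 0, p = 1 for every term. Tests verify the F statistics against
drop-column projection-matrix GLM computations to 1e−8 relative error.

## Synthetic cohort generator

The generator emulates what the pipeline consumes, with ground truth:

- **Parcellation**: N regions (default 506, the scale the pipeline is
  dimensioned for) randomly assigned to the 8 systems with fixed
  per-system counts (near-equal by default).
- **Structural template**: a stochastic block model; within-system pairs
  connect with `p_in` (default 0.30), between-system with `p_out`
  (default 0.02); present edges carry 1 + Poisson(15) streamline-count
  weights. One template is shared by every subject, matching the
  mean-connectome design of the pipeline.
- **Activity**: unions of *cascades*. Seeds arrive as a Poisson process
  (`event_rate` per frame, default 0.3) at uniform random regions. Each
  frame, every active region survives with `persist_prob` (0.5) and
  propagates along each binarized structural edge with `spread_prob`
  (0.25), damped by `cross_system_coupling` eta (default 0.1) on
  between-system edges — except edges into the cascade's current *partner
  system*, which propagate undamped. The partner starts as the seed's own
  system and is redrawn uniformly among the other systems with
  probability `drift_prob` rho per frame (default 0.1). A cascade stops
  recruiting new regions once it has touched `max_extent` distinct
  regions (default N/8) and dies when its active set empties. Because
  recruitment only ever crosses structural edges, every cascade is
  confined to one structural connected component by construction — the
  planted events necessarily form CCs of the downstream graph.
- **Age**: each subject's extent cap is multiplied by
  1 − `age_effect` × (age − age_ref) (floored at 5%), so mean CC height
  declines linearly with age — a plantable ANCOVA signal. Ages are
  uniform on [4.6, 18] years unless given explicitly; `age_ref` defaults
  to the mid-range.
- **BOLD mode**: the binary raster is convolved per region with a fixed
  gamma-difference kernel normalized to unit peak at lag 0 (causal,
  immediate peak, small late undershoot) and Gaussian noise of SD
  `noise_sd` is added. Placing the peak at lag 0 makes the point process
  recover planted cells at their own frames without lag correction —
  hemodynamic delay realism is deliberately sacrificed, since only the
  peak-recovery property matters here. Per-subject cascade and noise
  streams are split from the master seed, so the underlying raster is
  identical across modes and independent of other subjects.

**Dial semantics and regime.** Higher eta ⇒ more cross-system CCs ⇒
higher SD. Higher rho ⇒ regions join cascades whose partner systems vary
⇒ higher region-anchored STD. Higher spread ⇒ taller CCs. These
monotonicities hold in the generator's default *sparse* regime
(event_rate 0.3, p_out 0.02, eta ≈ 0.1), chosen deliberately: in denser
regimes independent cascades frequently collide and merge through
cross-system edges, baseline composition variance is large, and
additional mixing *homogenizes* embeddings — STD then saturates or even
decreases with either dial. The defaults are fixed once; tests assert the
monotone behaviour as Spearman rank correlations over 5-point grids with
10 seeds per point.

**What the generator does not emulate**: hemodynamic delay and
variability, head motion, physiological noise, spatially smooth
parcellation geometry, hub structure or distance-dependent connectivity,
subject-specific structural variation. Passing tests therefore show the
*pipeline* behaves correctly on data whose generative structure matches
its assumptions — not that real acquisitions satisfy those assumptions.

## Problem sizes used in tests and the acceptance script

Simulation-backed checks run at reduced dimensioning chosen to keep the
whole suite at desk scale while preserving the relevant regimes: null
calibration at N = 40, T = 120, 10 subjects/group, 200 permutations, 500
replicate studies; planted-contrast recovery at N = 80, T = 400, 20
subjects/group (eta 0.8 vs 0.1 for SD; rho 0.6 vs 0.0 for STD); ANCOVA
power at N = 40, T = 120, 100 subjects/group, 200 replicates with
age_effect = 0.08 — a standardized age–height association (r ≈ −0.2)
comparable to a moderate developmental effect. The acceptance script runs
single seeded studies at the contrast dimensioning with 1000
permutations.

## Numerical and degenerate-input conventions

- Threshold comparisons are inclusive (z >= threshold, share >= frac).
- Entropy uses natural log normalized by ln 8; 0 log 0 = 0.
- Cosine values are clipped to [0, 1] against floating-point drift before
  the 1 − cosine transform.
- Empty pools / no qualifying region raise `InsufficientDataError` for
  direct metric calls; inside `scale_metrics` and permutation loops they
  become flagged NaNs / dropped permutations respectively.
- All RNGs are `numpy.random.default_rng` seeded from explicit
  parameters; identical config + seed reproduces byte-identical outputs
  (reports contain no wall-clock timestamps).

## Known limitations

- `length` uses the inclusive frame span; a CC active at t=0 and t=2 only
  through different regions structurally linked across consecutive frames
  can have span > number of distinct active frames.
- SD's unweighted per-CC mean gives small CCs the same influence as large
  ones; use `sd_variant="pooled_hist"` when mass-weighting is wanted.
- The permutation test assumes subject exchangeability under the null;
  confound imbalance between groups (e.g., age) is not adjusted in the
  SD/STD tests, only in the ANCOVA on CC summaries.
- STD requires regions shared across enough CCs; sparse pools (few
  subjects, strict attribution) can leave system-scale STD undefined.
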