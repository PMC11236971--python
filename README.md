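# stconnectome

Structure-constrained spatiotemporal brain network analysis: extract
transient co-activation events from parcellated resting-state fMRI, measure
how widely they integrate across functional systems and how stable their
composition is over time, and compare two groups of subjects.

## Who this is for

Researchers with (i) per-subject regional time series (N regions × T
frames, plain TSV), (ii) a structural connectome template (N × N streamline
counts, TSV) shared across the study, and (iii) a label table assigning
each region to one of eight functional systems — visual (VIS), somatomotor
(SM), dorsal attention (DA), ventral attention (VA), limbic (LIM),
frontoparietal (FP), default mode (DM), cerebellar (CBL). A synthetic
cohort generator is included so every stage can be exercised, calibrated
and power-checked without imaging data.

## The method

1. **Point process** — each region's series is z-scored and binarized at
   z ≥ 2 SD, yielding an N × T activation raster.
2. **Multilayer graph** — nodes are active (region, frame) cells; nodes are
   linked when their regions are structurally connected (or identical) and
   their frames are the same or consecutive.
3. **Connected components (CCs)** — weakly connected clusters of the graph:
   transient spatiotemporal events. Each CC has a spatial activation vector
   x (x_i = frames region i is active inside the CC), a *length*
   (t_max − t_min + 1 frames) and a *height* (fraction of all regions
   involved).
4. **Diversity metrics** (group-level, on CCs pooled across a group's
   subjects; each CC embedded as its 8-vector of per-system mass):
   - *System diversity* SD = mean over CCs of the normalized entropy
     −Σ p_f ln p_f / ln 8 of the system-mass distribution. Higher SD =
     more cross-system integration.
   - *Spatiotemporal diversity* STD = mean over regions (in ≥ 2 CCs) of
     1 − mean pairwise cosine between the unit embeddings of their CCs.
     Lower STD = more stable system composition.
   Both are evaluated globally and per system (a CC belongs to every
   system holding ≥ 20% of its involved regions).
5. **Inference** — two-tailed subject-permutation tests (default 1000
   permutations) for SD/STD at every scale with Benjamini–Hochberg FDR
   across the 8 systems per metric; Type-III ANCOVA of per-subject CC
   count / mean length / mean height on group + age + group×age.

## Worked example

```python
import stconnectome as st

# synthetic study: group A couples across systems more than group B
labels = st.generate_parcellation(80, seed=0)
sc = st.generate_structural_connectome(labels, p_in=0.3, p_out=0.02, seed=1)
params = st.SimParams(
    n_regions=80, n_frames=400, n_subjects_a=20, n_subjects_b=20,
    cross_system_coupling=(0.6, 0.1),  # (group A, group B)
    seed=2,
)
cohort = st.generate_cohort(params, labels, sc, mode="raster")

components = []
for subj in cohort.subjects:
    raster = st.ActivationRaster(active=subj.data, threshold_used=float("nan"))
    graph = st.build_graph(raster, sc)
    components.extend(st.extract_components(graph, 2, subj.subject_id).components)

pool = st.CCPool(components, labels)
groups = {s.subject_id: s.group for s in cohort.subjects}
res = st.permutation_test(pool, groups, metric="SD", scale="global",
                          n_perm=1000, seed=3)
print(f"SD A={res.observed_a:.3f}  SD B={res.observed_b:.3f}  "
      f"p={res.p_two_tailed:.4f}")
```

prints

```
SD A=0.312  SD B=0.113  p=0.0010
```

Group A's pooled components spread their activation mass across more
functional systems (normalized entropy 0.312 vs 0.113), and no label
permutation among the 1000 drawn produced a difference as large, so the
smoothed two-tailed p-value is 1/1001 ≈ 0.001.

The same analysis runs from the shell on a study directory:

```
stconnectome simulate --out study/ --n-regions 80 --n-frames 400 \
    --subjects-per-group 20 --eta-a 0.6 --eta-b 0.1 --seed 2
stconnectome run --config study/study.yaml
```

(`stconnectome --help` documents every subcommand, flag and coordinate
convention.)

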