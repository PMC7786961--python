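# fctopo

Graph-theoretic topology analysis of functional brain connectomes, built
for group studies that contrast patients and controls on network
integration, segregation, and modular organization — e.g., Alzheimer's
disease (AD) and behavioral-variant frontotemporal dementia (bvFTD)
against healthy controls (HC).

`fctopo` implements the full analysis chain from regional BOLD time series
to group statistics:

1. **Motion scrubbing** — frames with framewise displacement FD > 0.5 mm or
   DVARS > 0.5 % are censored; subjects with less than 4 min of clean data
   are excluded.
2. **Connectome construction** — the FC matrix is the pairwise Pearson
   correlation of regional time courses, `w_ij = max(0, r_ij)`, with a zero
   diagonal (141 × 141 for the packaged atlas of 114 cortical + 27
   subcortical nodes).
3. **Cost thresholding** — at each cost `c` (fraction of possible edges),
   the `⌊c·N(N−1)/2⌋` strongest edges are retained, keeping their weights;
   the grid spans 0.09–0.40 (step 0.01 for metrics, 0.001 — 311
   thresholds — for community detection). Cost-range validity is checked
   by small-worldness σ > 1, largest-component coverage ≥ 80 %, and mean
   degree > ln N.
4. **Integration metrics** — degree centrality `D_i = Σ_j w_ij` and nodal
   efficiency `E_i = (1/(N−1)) Σ_j 1/L_ij` (shortest paths with edge
   length `1/w`), computed per cost and integrated across the grid
   (trapezoidal AUC) into one composite per node.
5. **Two-stage consensus communities** — Louvain at resolution γ per cost,
   a co-classification matrix across the 311 partitions, and consensus
   clustering into one subject partition (γ_subject = 3); subject
   partitions aggregate into a group allegiance matrix that is consensus
   clustered into the group partition (γ_group = 2).
6. **Module distinctiveness** — within-module degree
   `z_i = (k_ni − k̄_n)/σ_kn` and participation coefficient
   `P_i = 1 − Σ_n (k_ni/k_i)²` against the group partition, cost-integrated.
7. **Partition similarity** — adjusted Rand index (ARI) of 20 bootstrap
   subgroups (10 subjects drawn with replacement) per group against the
   all-HC reference partition, whole-brain and restricted to the
   default/control (DN-CN), salience/ventral-attention (SVAN), and
   subcortical communities of interest.
8. **Statistics** — per-node OLS group contrasts with
   education/scanner/frames covariates (p ≤ .05 uncorrected, FDR column
   supplied), one-way ANOVA + Bonferroni post hoc t-tests on ARI
   distributions, and brain–behavior Pearson correlations after
   residualizing age, gender, education, and scanner.

Because connectome datasets of this kind are rarely shareable, the package
ships a synthetic-cohort generator (`fctopo.synthetic`) that plants block
community structure with group-specific module lesions and
behavior-coupled scores, so the entire pipeline can be exercised and
validated end to end with known ground truth.

## Worked example

```python
import numpy as np
from fctopo import synthetic, scrub, connectome, graphs, communities, similarity

cfg, atlas = synthetic.default_config(n_per_group=(6, 6, 6), seed=7)
subjects, cohort, planted = synthetic.generate_cohort(cfg)

kept, mask = scrub.scrub_frames(subjects[0])
print(f"{subjects[0].subject_id}: kept {mask.n_kept}/{len(mask)} frames, "
      f"included: {scrub.check_inclusion(mask, tr_seconds=2.0)}")

fc = connectome.build_fc(kept.data)
grid = graphs.CostGrid.coarse()
print(f"FC matrix: {fc.shape}, integrated mean FC = "
      f"{connectome.integrated_mean_fc(fc, grid):.4f}")

rng = np.random.default_rng(7)
parts = {g: [] for g in ("HC", "AD", "bvFTD")}
for ts in subjects:
    s, _ = scrub.scrub_frames(ts)
    part, _ = communities.subject_consensus(
        connectome.build_fc(s.data), fine_grid=grid, gamma=3.0,
        seed=int(rng.integers(2**31)))
    parts[ts.subject_id.rsplit("_", 1)[0]].append(part)

reference, _ = communities.group_partition(parts["HC"], gamma=2.0, seed=1)
print(f"HC group partition: {reference.n_communities} modules, "
      f"ARI vs planted = {similarity.adjusted_rand(reference, planted):.2f}")

results = similarity.resample_group_similarity(
    parts, reference, atlas, n_subgroups=20, subgroup_size=6, seed=2)
for r in results:
    if r.scope in ("DN_CN", "SVAN"):
        print(f"{r.group:6s} {r.scope:6s} mean ARI = {r.mean:.2f}")
```

Output:

```
HC_001: kept 234/240 frames, included: True
FC matrix: (141, 141), integrated mean FC = 0.1349
HC group partition: 9 modules, ARI vs planted = 1.00
HC     DN_CN  mean ARI = 1.00
HC     SVAN   mean ARI = 1.00
AD     DN_CN  mean ARI = 0.09
AD     SVAN   mean ARI = 1.00
bvFTD  DN_CN  mean ARI = 1.00
bvFTD  SVAN   mean ARI = 0.00
```

The two-stage consensus recovers the nine planted modules exactly in
controls (ARI 1.0), and the bootstrap similarity analysis isolates each
patient group's planted disruption: the AD-like group (fragmented
default-mode/control system) loses modular similarity only within the
DN-CN scope, the bvFTD-like group only within SVAN — the double
dissociation the method is designed to detect.

A `fctopo` console command exposes the same stages for shell pipelines
(`fctopo simulate`, `scrub`, `validate-costs`, `metrics`, `communities`,
`compare`); all intermediate artifacts are tab-delimited text.

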