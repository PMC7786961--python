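# Methods

This note documents the models, algorithmic choices, and defaults behind
`fctopo`, and what its synthetic validation does and does not establish.

## Connectome construction and thresholding

The functional connectome is the Pearson correlation matrix of regional
BOLD time courses with the diagonal and all negative entries set to zero.
No Fisher z-transform is applied: thresholding is rank-based, so any
monotone transform of r leaves the retained edge set unchanged, and the
retained weights are reported on the familiar correlation scale.

Cost thresholding retains the `⌊c·N(N−1)/2⌋` largest-weight edges
(`floor`, not `round`, so the realized density never exceeds the nominal
cost). Ties are broken by ascending (i, j) node index; this makes
threshold sets deterministic and nested across costs. When a matrix has
fewer positive edges than a cost requests, all positive edges are kept and
the graph is flagged `truncated` with a warning rather than failing.

Cost-range validity is assessed per subject and cost by three criteria:
small-worldness σ > 1, largest-connected-component coverage ≥ 80 % of
nodes (our reading of "fully connected" for most nodes; the fraction is
the `lcc_frac` parameter), and binary mean degree 2m/N > ln N (natural
log, configurable base). σ = (C/C_rand)/(L/L_rand) is computed on the
binarized graph — clustering over all nodes, characteristic path length on
the largest component — against the mean of `n_null` (default 20)
degree-preserving double-edge-swap rewirings, seeded. The report carries
both subject-level pass flags and cohort pass fractions, since the
criteria can reasonably be applied at either level.

## Nodal metrics

Degree centrality is the weighted degree on the thresholded graph. Nodal
efficiency uses weighted shortest paths with edge length `1/w` (the
standard convention for correlation-weighted graphs; stronger edges are
shorter); unreachable pairs contribute zero, so isolated nodes have
E = 0. Metrics are computed at every cost of the coarse grid (0.09–0.40,
step 0.01) and combined by trapezoidal area under the metric-vs-cost
curve. The raw AUC is stored; dividing by the grid width 0.31 rescales it
to a mean level if desired.

## Two-stage consensus community detection

Louvain modularity maximization runs through igraph's C implementation
with the resolution parameter γ entering both the optimization and the
reported Q. Greedy Louvain is sweep-order dependent, so each call runs 10
seeded restarts and keeps the best-modularity partition.

Stage 1 clusters each subject's weighted thresholded graph at every cost
of the fine grid (0.09–0.40, step 0.001; 311 thresholds), builds the
co-classification matrix (frequency of node-pair co-assignment across the
311 partitions), and consensus-clusters it: entries below τ = 0.5 are
zeroed, the matrix is re-clustered 10 times, and the procedure iterates on
the runs' own co-classification until all 10 agree up to relabeling
(iteration cap 20; non-convergence returns the last partition flagged
`converged=False`). Stage 2 averages the subject consensus partitions'
co-assignment indicators into a group allegiance matrix — normalized to
[0, 1], which is scale-equivalent to summing for clustering purposes — and
applies the same consensus procedure. Defaults γ_subject = 3,
γ_group = 2; τ and the re-clustering count are configurable because the
consensus literature fixes no single value.

A resolution caveat that the test suite exercises explicitly: for a
network of B similar planted blocks, γ ≳ B makes splitting blocks
modularity-optimal, so γ = 3 cannot recover a two-block structure (it
returns singletons) while it cleanly recovers the 9-module default
atlas structure. Choose γ with the expected module count in mind.

## Module distinctiveness

Within-module degree z and participation coefficient P score each node
against a fixed group-level partition using **binary** degrees on the
thresholded graph (the intra-module degree is a count of edges); a
weighted variant exists behind a `weighted=True` flag for sensitivity
analysis. Modules with zero intra-degree spread (including singletons,
which are flagged) get z = 0; isolated nodes get P = 0. Each group is
scored against its own group partition by default. Both metrics are
cost-integrated on the coarse grid like the nodal metrics.

## Partition similarity and resampling

Partition agreement uses the permutation-model adjusted Rand index.
Sub-network scopes restrict both partitions to a node subset before
computing ARI; the DN-CN, SVAN, and subcortical node sets come from the
atlas's community-of-interest column. Group similarity is estimated by
resampling 20 subgroups of 10 subjects with replacement per group,
building each subgroup's partition with the stage-2 procedure (repeated
subjects count with multiplicity in the allegiance matrix), and scoring
each against the all-HC reference; HC's own subgroups quantify sampling
variability around the reference.

## Statistics

Nodal group contrasts are OLS fits of each node × metric composite on
group indicators (HC reference) plus covariates (education, scanner,
frames retained by default; integrated FC and node-matched gray-matter
volume as optional extras). Categorical covariates are dummy-coded; the
design is checked for full rank. All pairwise contrasts, including
AD-vs-bvFTD, are linear contrasts on the one fitted model — algebraically
identical to re-referencing. Nodal p-values are reported uncorrected at
p ≤ .05 by design (a Benjamini–Hochberg column is emitted alongside).
ARI distributions are compared by one-way ANOVA per scope with all
pairwise two-sample t-tests, Bonferroni-corrected within scope (family =
3 contrasts). Brain–behavior association residualizes both the metric and
the score on age, gender, education, and scanner before a Pearson
correlation; the reported p uses the residuals' nominal df, which is
slightly liberal when many covariates are removed at small n.

## Synthetic cohort model

Node i of module m follows

    x_i(t) = a_m·s_m(t) + ρ_between·g(t) [+ ρ_merge·s_pair(t)] + σ_noise·e_i(t)

with per-subject latent module signals s_m, a shared global signal g, and
i.i.d. Gaussian noise; a_m = ρ_within, reduced by `lesion_delta` in a
group's lesioned modules; module pairs in `merge_pairs` share an extra
latent at coupling `merge_rho` (default ρ_within/2). Defaults: ρ_within
0.9, ρ_between 0.05, σ_noise 0.6, 240 frames at TR 2 s, giving empirical
within-module correlations ≈ 0.68 against a between-module floor near 0.
The default planted partition merges the atlas's split network labels into
nine modules (visual, somatomotor, dorsal attention, salience/ventral
attention, limbic, control, default, temporoparietal, subcortical), which
is the granularity γ_subject = 3 / γ_group = 2 recovers.

`lesion_delta` defaults to 0.8 in the study-like configuration: the
lesioned modules' signal coefficient drops to 0.1, pushing their
within-module correlations to the noise floor so the modules genuinely
fragment across costs and subjects. Weaker lesions lower within-module FC
without changing detected community structure — a useful regime for the
nodal-metric contrasts but invisible to partition similarity.

Motion traces are uniform sub-threshold baselines (FD, DVARS ∈
[0.05, 0.35]) with Bernoulli spike frames exceeding both 0.5 thresholds;
behavior scores are linear in the cohort-standardized mean connectivity
strength of each subject's own data plus noise (NPI negatively coupled);
gray-matter volumes are node-wise Gaussians with optional lesion-linked
atrophy. These exist to exercise the scrubbing, correlation, and covariate
pathways with known ground truth.

What the generator does **not** emulate: hemodynamics, autocorrelated
BOLD noise, spatially graded (non-block) connectivity, hub structure, or
realistic score distributions. One consequence worth knowing: because
between-module correlations are essentially zero, below cost ≈ 0.12 every
retained edge is within-module and the thresholded synthetic graphs
decompose into the planted blocks — the largest-component criterion then
fails at the low end of the 0.09–0.40 grid even though the same criterion
passes on real connectomes, whose strongest edges are not exclusively
within-system. Passing tests therefore validate the pipeline's mechanics
and sensitivity, not the empirical validity of any particular cost range
on real data.

## Validation experiments and problem sizes

`fctopo.experiments` (driven by `scripts/acceptance.py` and the test
suite) runs: oracle cross-validation of degree, efficiency, z, P,
modularity Q, and ARI against naive loop-based reference implementations
on graphs of ≤ 12 nodes (agreement to 1e−10); planted-partition recovery
on 141-node, 20-subject cohorts with the fine-grid step relaxed to 0.01
(3 seeds, ARI ≥ 0.9 expected); lesion-direction recovery on a reduced
40-node atlas with a 7-cost grid over 10 simulation replicates; and
type-I calibration of the nodal GLM and ARI ANOVA over 200 null
replicates at n = 15 per group (rates expected in [0.03, 0.07] at nominal
.05). These sizes were chosen to keep a full validation run in the
minutes range on a single core while leaving each experiment statistically
informative.

## Known limitations

- Louvain restarts tame but do not eliminate greedy instability on weakly
  modular matrices; non-converged consensus partitions are flagged, not
  repaired.
- The consensus threshold τ and re-clustering count are conventions, not
  estimated quantities; strongly ambiguous co-classification matrices can
  be sensitive to them.
- DVARS is consumed as given (percent units); the package never recomputes
  it from voxel data, and censoring is applied to the supplied ROI series
  as-is.
- Sub-network ARI scopes use atlas community-of-interest labels; if a
  group partition diverges wildly from the atlas systems, scope
  restriction still compares within those fixed node sets.
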