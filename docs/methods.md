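# Methods

This note documents the models and procedures implemented in `netaging`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that matter when
comparing outputs across implementations.

## Synthetic longitudinal cohorts

`cohort.CohortSpec` describes a study: subjects per (sex, cohort) cell,
cohorts with a trajectory-group assignment (X or Y), target scan ages in
days (default 365/548/730, i.e. ~12/18/24 months), sessions per wave
(default 2), usable volumes per scan (default 415), 72 bilateral ROIs in 6
equal planted modules (ROI pairs 2k−1/2k are left/right partners with
identical labels, enabling bilateral averaging downstream).

Connectivity ground truth is a block correlation matrix: `within_r0`
(default 0.5 ≈ tanh 0.55) inside modules and `between_r0` (default 0.1)
across. Aging acts **linearly in days on the correlations before the
Fisher transform** — the downstream mixed models are linear in exact age,
so a linear generative trend makes slope-recovery checks interpretable.
Group X defaults to `within_slope = −1e−4/day` and `between_slope =
+1e−4/day`; group Y is flat. These values were calibrated once so the
ground-truth SI declines by ≈0.1 between the 12- and 24-month waves (0.82
→ 0.72), the order of magnitude a de-differentiating cohort shows; no
per-edge effect sizes are published for the real study, so these are
configurable conventions, not reference values. Each subject carries a
Gaussian random offset (sd 0.02) added to both correlations, producing a
random-intercept structure in SI; correlations are clipped to [0, 0.95].

Sessions are i.i.d. Gaussian draws through the Cholesky factor of the
target matrix, so the population lag-0 correlation is exact and the sample
correlation converges at the usual 1/√n rate. **No temporal
autocorrelation is simulated by default** (the pipeline consumes only
Pearson correlations; autocorrelation would only inflate estimator
variance) — an AR(1) knob (`ar1`, default 0) exists for robustness
experiments and leaves the lag-0 correlation unchanged. Block correlation
matrices with 0 ≤ b ≤ w < 1 are provably positive definite, so the
nearest-PD repair (eigenvalue flooring at 1e−6 + renormalisation to unit
diagonal) only engages for user-supplied degenerate targets; it is exposed
and tested separately.

What the generator does **not** emulate: hemodynamics, motion/scanner
artifacts, anesthesia effects, spatially varying module sizes, negative
true correlations, and heavier-than-Gaussian noise. Passing tests
therefore demonstrate the *analysis chain* is correct and well calibrated
under its own assumptions, not that real mouse data meet them.

Dropout removes a subject before each later wave with probability 0.1
(cumulative, subjects never return), matching the order of attrition a
2-year mouse study sees; exact ages are jittered ±14 days uniformly.
Everything derives deterministically from (spec, seed) through
`numpy.random.SeedSequence` spawning.

## Connectivity

Pearson correlation across volumes; Fisher z = atanh(r) with |r| ≥ 1−1e−7
clipped (duplicated series must not produce infinities; the clip count is
logged); diagonal stored as 0 and excluded everywhere; session matrices
averaged element-wise. The group edge test is a **one-sample** t of mean z
against zero per edge, one-sided toward positive connectivity, with BH-FDR
over the n(n−1)/2 unique (upper-triangle) edges — the family never counts
a symmetric edge twice. Edges with zero across-subject variance get a
degenerate p (0 if the mean is positive, else 1) and a warning rather than
a crash.

## Consensus module detection

`community.louvain_once` is a dense-matrix two-phase Louvain for the
resolution-adjusted quality Q(γ), with seed-randomised sweep order, greedy
single-node moves (ties keep the current community; an empty community is
a candidate so high γ can split nodes off), and aggregation that carries
double-counted internal weight on the diagonal so Q is invariant across
levels. `finetune` re-runs single-node moves on the *original* graph from
a given partition until no move improves Q — output Q ≥ input Q by
construction. Kernels are numba-compiled; a repetition on a 72-node matrix
costs well under a millisecond, which is what makes 100–1000-repetition
consensus sweeps practical.

Consensus clustering: the agreement matrix D over repetitions is
re-partitioned until all repetitions agree (or D is exactly binary, in
which case its connected components are returned). Before each
re-clustering pass, D is **null-corrected** by subtracting the mean
off-diagonal co-assignment and flooring at zero — the permutation-null
expectation used in standard consensus practice; a fixed τ threshold is
not applied but the correction is isolated in `null_corrected` for easy
substitution. Re-partitioning uses the same γ as the originating sweep
point, keeping each sweep point self-consistent. The iteration cap is 50,
with a diagnostic error on non-convergence.

γ is swept over 1.0–2.0 in steps of 0.1 (11 values). For each γ: subject
consensus partitions → group consensus; the **selected γ maximises the
mean pairwise NMI between its group partition and every other γ's**, with
ties broken toward smaller γ. "Mean pairwise" is one reading of
"greatest NMI between solutions"; it is the symmetric, aggregation-free
choice and is isolated in `gamma_sweep` should another aggregation be
preferred. NMI uses the arithmetic-mean normalisation
2·I/(H₁+H₂) — the most common convention, cross-checked against
scikit-learn in the tests — with the zero-entropy case (two single-module
partitions) defined as 1.

Module numbering is canonical: descending size, then lowest contained node
index. Classification consistency matches each repetition's modules to the
consensus modules by maximal overlap (Hungarian assignment on the
contingency table) and counts the fraction of repetitions in which a node
lands in its consensus module. The "first three" modules used by SI3 are
the three with the highest mean consistency — the most reliable modules.
Module flow across waves reports shared-node counts and Jaccard overlaps
between consecutive partitions, flagging each source module's dominant
successor.

## Segregation index

SI = (W̄ − B̄)/W̄ over positive z only, each unique pair once. The
`exclude` policy (default) drops non-positive edges from both means;
zeroing them into the denominator count (`zero` policy, provided) would
deflate the means with non-edges. An empty positive between-edge set means
B̄ = 0 and SI = 1 (logged boundary convention); no positive within edges
makes SI undefined — the row is flagged, never dropped silently. SI is
scale-invariant and ≤ 1 by construction. SI3 is a **subgraph restriction**:
only pairs inside the three selected modules count, and the between term
only spans two selected modules (the selected-to-all alternative is a
one-line change at the call site via `module_subset`). Both the all-module
SI and SI3 reuse the baseline 12-month partition at every wave, fixing the
edge sets across age. The exclusion rule flags a subject whose SI3 is
**strictly below 0.43** at all of the listed waves it attended (12 and 18
months by default; subjects missing a wave are judged on what exists);
0.43 exactly is not flagged.

## Graph metrics

Density thresholding keeps the ⌈density·n(n−1)/2⌉ strongest positive
edges; cutoff ties break by ascending (i, j) for determinism, and the grid
is 16 evenly spaced densities from 0.10 to 0.25 (step 0.01 — the grid that
honours both the count and the endpoints; the step is configurable).
Sweeps are nested (lower-density edge sets are prefixes of higher ones).

Globals: mean nodal clustering; CPL as the mean shortest-path length over
*connected* ordered pairs, with a flag when the graph disconnects (real
data chose 0.10 as the lowest fully connected density; synthetic graphs
may disconnect, and disconnected pairs are excluded rather than
imputed); local efficiency as the mean over nodes of the global efficiency
of each node's neighbourhood subgraph; small-world σ = (C/C_rand)/(L/L_rand)
against 10 degree-preserving double-edge-swap rewirings (the null model is
a convention — GRETNA-style toolboxes differ here, a comparability
caveat); modularity as the best Q over 10 seeded fine-tuned Louvain
restarts at γ = 1; assortativity as the Pearson correlation of degrees
over directed edge endpoints, undefined (NaN) for degree-regular graphs.
Nodal: raw degree, unnormalised Brandes betweenness with endpoints
excluded (normalisation would only rescale the units of downstream
t-statistics), nodal efficiency E(i) = (1/(n−1)) Σⱼ 1/d(i,j) with 1/∞ = 0,
and nodal clustering. Undefined values are excluded from the threshold
average with the contributing count recorded. Bilateral combination means
the `_L`/`_R` partners per region; unpaired ROIs pass through with a
warning.

## Mixed-effects trajectory models

`models.fit_lme` fits y ~ 1 + age·f + factor + age×factor with a random
per-subject intercept by **maximum likelihood** (statsmodels MixedLM). Age
is centred at the grand mean (so the factor main effect is evaluated at
the average age) and scaled to months for conditioning; slopes are
reported per month and per day. Wald t uses **residual degrees of freedom**
(observations − fixed effects), the convention matching df values reported
alongside such models (e.g. df = 129 for 133 observations and 4 fixed
effects); Satterthwaite adjustment is out of scope. Factors are treatment-
coded with female / group X as reference. The fixed-effects covariance is
computed analytically at the fitted variance components (GLS information
matrix), which stays well defined when the random-intercept variance is
estimated at the zero boundary — where the optimiser's Hessian can be
singular; the optimiser itself falls back from L-BFGS to Powell in that
case. Non-convergence is flagged on the result, never silent. On balanced
designs with zero random-effect variance the fixed effects reduce to OLS
(verified to 1e−6).

The time contrast averages the age slope over both factor levels with
weight ½ (age + ½·interaction), with variance c'Σc. Mass-univariate
application fits one model per edge/node/region, controls the family
(upper-triangle edges, or regions) with BH-FDR at α = 0.05, and also emits
the uncorrected p < 0.01 mask used for sub-threshold display; units whose
fit fails are excluded from the family and counted. Slope distributions
are compared with the asymptotic two-sample KS test.

## Pipeline and determinism

`pipeline.run_pipeline` executes simulate → connectivity → modules →
segregation → metrics → stats against one run directory, each stage
re-runnable alone (the CLI subcommands are thin wrappers). All statistics
are long-format CSVs; matrices are square TSVs with ROI headers, read back
with round-trip float parsing so write→read is exact. A manifest records
the config (and its hash), library versions and per-stage row counts.
Every random choice flows from the single master seed via SeedSequence
spawning; rerunning an identical config byte-reproduces every numeric
output (this is asserted in the test suite).

## Problem sizes used in verification

The packaged checks run at desk scale, chosen once: consensus recovery
uses 20 synthetic subjects, 100 Louvain repetitions (the consensus scheme
is conventionally run at 1000; 100 is ample for a 72-node planted
structure and keeps sweeps fast) over the full 11-point γ grid and 10
master seeds; trajectory power/type-I use 16 subjects × 3 waves × 20
replicates; LME calibration uses 30 subjects × 3 visits × 200 replicates;
metric oracles cover every connected graph with ≤ 7 nodes from the graph
atlas. Exhaustive-search comparisons for modularity accept the heuristic's
nature: Q must never exceed the exhaustive maximum and must attain it on
at least 95% of graphs; σ has no deterministic oracle (stochastic null)
and is instead sanity-checked at ≈1 on Erdős–Rényi and >1 on
Watts–Strogatz graphs.

## Known limitations

Overlapping/hierarchical communities, weighted-graph metric variants,
rich-club and participation coefficients are out of scope. The group edge
test models subjects as exchangeable (no session-level nesting below the
averaged matrix). Real-data idiosyncrasies (anesthesia depth, motion,
vendor effects) are not represented in the generator, so calibration
results transfer to real cohorts only to the extent the Gaussian
block-structure assumptions hold.
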