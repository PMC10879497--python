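# netaging

Longitudinal functional-connectome aging analysis for small-animal
resting-state fMRI, built as an importable Python library with a thin
`netaging` command-line front end.

## The problem

Aging blurs the modular organisation of the mammalian brain: connectivity
*within* functional modules falls while connectivity *between* modules
rises ("de-differentiation"). Quantifying this longitudinally requires a
chain of steps — ROI connectivity matrices, robust module detection,
a segregation statistic, density-matched graph metrics, and repeated-
measures statistics that tolerate dropout. `netaging` implements that chain
as tested, reusable components, and ships a synthetic-cohort generator that
emulates a longitudinal mouse study design (72 bilateral ROIs in 6 modules,
scan waves near 12/18/24 months with exact ages in days, 1–2 sessions per
wave, 415 usable volumes per scan, several cohorts of both sexes, dropout,
and group-dependent aging of within/between-module correlation) so the
whole pipeline can be exercised, calibrated and verified without any data
download.

## Methods at the core

* **Connectivity.** Pearson correlation r between ROI time series,
  Fisher-transformed: z = atanh(r), giving a symmetric 72×72 matrix **Z**
  per subject and wave (sessions averaged); **Z+** keeps positive edges.
* **Consensus Louvain modules.** Repeated fine-tuned Louvain maximising
  Q(γ) = (1/2m) Σᵢⱼ [Wᵢⱼ − γ kᵢkⱼ/2m] δ(cᵢ,cⱼ); an agreement matrix D
  (fraction of runs co-assigning each node pair) is re-clustered until
  unanimous, per subject and then across subjects. The resolution γ is
  swept over 1.0–2.0 (step 0.1) and selected by the greatest mean pairwise
  normalised mutual information between the group partitions.
* **Segregation index.** SI = (W̄ − B̄)/W̄ with W̄, B̄ the mean positive-z
  within- and between-module edges; SI3 restricts to the three most
  reliably classified modules; subjects with SI3 < 0.43 at the first two
  waves are flagged for exclusion. Later waves reuse the baseline
  (12-month) partition.
* **Graph metrics.** **Z+** density-thresholded at 16 densities from 0.10
  to 0.25 (equal edge counts across subjects); clustering coefficient,
  characteristic path length, local efficiency, small-world σ, modularity
  and assortativity globally, plus degree, betweenness, nodal efficiency
  and clustering per node, averaged over the sweep and combined across
  hemispheres.
* **Trajectory statistics.** Linear mixed-effects models
  `y ~ 1 + Age * Factor + (1 | subject)` (ML, exact age in days, Wald t on
  residual df), an equal-weight time contrast, Benjamini–Hochberg FDR for
  mass-univariate families, and two-sample Kolmogorov–Smirnov comparisons
  of slope distributions.

## Worked example

`examples/` holds one short narrative script per capability. For instance
module detection on a planted connectome (`examples/02_module_detection.py`):

```text
selected gamma: 1.0
modules found:  6
NMI vs planted: 1.000
```

The sweep recovers the six planted modules exactly and, because every
resolution agrees, the tie rule picks the smallest γ. Segregation
trajectories (`examples/03_segregation_trajectories.py`) on a de-segregating
synthetic group print:

```text
                 si_all    si3
timepoint_label
12mo              0.828  0.827
18mo              0.778  0.775
24mo              0.730  0.729

SI3 age slope: -0.0080/month (t = -12.03, p = 8.3e-16)
```

i.e. the planted ~0.1 SI decline over 12→24 months is recovered with a
strongly negative mixed-model age slope.

A full run (simulate → connectivity → modules → segregation → metrics →
stats, with TSV/CSV/JSON artifacts and a manifest) is:

```bash
netaging run --out run1 --seed 7
```

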