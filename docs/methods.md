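# Methods

## Model

`bnec` models effective connectivity between brain regions as a linear
Gaussian Bayesian network over ROI mean time series. Given nodes
X = {X₁, …, Xₙ} (one per region of interest) and a directed acyclic graph G,
the joint density factorizes as

    P(X₁, …, Xₙ) = ∏ᵢ P(Xᵢ | Pa(Xᵢ)),

with each conditional a linear regression on the node's parents:

    Xᵢ | Pa(Xᵢ) ~ N( μᵢ + Σ_{p ∈ Pa(Xᵢ)} b_p (x_p − μ_p), σᵢ² ).

The connection weight b_p quantifies the directed influence of parent p on
child i; the joint distribution is multivariate normal with covariance
(I − W)⁻¹ Σ_ε (I − W)⁻ᵀ, where W collects the weights row-wise and Σ_ε is the
diagonal of residual variances. Time points are treated as exchangeable
samples — the model captures a static snapshot of conditional dependence, not
temporal causality.

## Structure learning

Structures are scored by the Bayesian information criterion

    BIC(G | D) = log P(D | G, Θ*) − (d/2) log m,

where Θ* is the maximum-likelihood parameter set, m the number of samples
(all subjects' rows concatenated), and d = 2n + #edges the number of free
parameters (mean and residual variance per node, one coefficient per edge).
Natural logarithms throughout. Because the Gaussian family likelihood
depends on the data only through the cross-product matrix Z′Z (Z = [1 | X]),
family scores are computed from that matrix and cached, making each
candidate evaluation independent of m.

The search is greedy hill-climbing over single-edge additions, deletions and
reversals, with two refinements:

- **L1 candidate restriction.** For each node, the lasso regularization path
  of the node on all other nodes (100 penalties, log-spaced from the
  data-derived λ_max down to 10⁻³ λ_max) yields a nested family of candidate
  parent sets; an edge u → v may only be *added* if u appears in some
  candidate set for v. On standardized data this rarely excludes true
  parents while shrinking the move space.
- **Covered-edge plateau walks.** When no strictly improving move exists,
  the climber reverses a covered edge (u → v with Pa(v) = Pa(u) ∪ {u}) — a
  score-neutral move that travels within the Markov equivalence class — and
  resumes climbing, up to a bounded number of plateau steps. This escapes
  the misorientation traps that pure greedy search falls into; in the
  validation battery it eliminated every case where the climber's optimum
  scored below the true structure.

One deterministic empty-graph start plus 10 random restarts (random DAG
starts, per-restart randomized move order, all derived from one seed); the
best-BIC local optimum wins, ties broken by fewest edges then lexicographic
edge list. An exhaustive enumerator over all labeled DAGs (25 on 3 nodes,
543 on 4) provides the global optimum on small problems and is used
throughout the tests as the optimality oracle.

Linear Gaussian networks are identifiable only up to Markov equivalence, so
results are also reported as CPDAGs (skeleton + v-structures completed under
Meek rules R1–R3, which suffice for patterns derived from a DAG; the
implementation is validated against brute-force enumeration of equivalence
classes). Edge directions beyond the compelled ones are not statistically
forced and should be interpreted cautiously.

## Edge pruning

The fitted network is equivalent to a set of linear regressions, so weights
are regression coefficients and can be t-tested. Pruning is backward
elimination per node: refit the OLS of the node on its current parents, and
while any coefficient's two-sided p-value (m − |parents| − 1 degrees of
freedom) exceeds α = 0.05, remove the worst parent and refit. No forward
re-entry (the candidate set comes from structure learning, which already
searched additions) and no multiple-testing correction by default (a
Bonferroni flag exists). Surviving weights are refitted on the final parent
set; the significance table records both the final statistics of retained
edges and the elimination-step statistics of removed ones.

## Condition comparison

Two conditions measured on the same subjects (e.g. rest and task) are
compared edge-wise: the statistic is the difference of post-pruning
connection weights between the two groups' independently learned networks,
with edges absent from a group's network contributing weight 0. The
reference distribution comes from a paired permutation: each permutation
independently swaps each subject's pair of condition labels with probability
½ and recomputes the statistic; one-sided empirical p-values in both
directions use the (count + 1)/(B + 1) correction, so attainable p-values
are exactly {k/(B+1)}. Default B = 1000 permutations; an unpaired
full-relabeling mode exists behind a flag.

Two permutation modes:

- **full** — every permutation re-learns and re-prunes both networks, the
  complete pipeline applied to the rearranged groups.
- **fixed** (speed mode, default) — the two observed structures are held
  fixed and each permutation re-estimates weights and reruns the backward
  elimination on the fixed parent sets, assembled from cached per-subject
  cross-product matrices. This reduces a permutation to small linear solves
  and makes large calibration studies feasible.

A selection caveat, measured in the validation battery: edges reported only
by one group's network were *selected* by the observed data, so their
one-sided p-values are anti-conservative (~0.09 at nominal 0.05), while
edges present in both networks are well calibrated (~0.056). Full
re-learning does not remove this effect (it is slightly stronger there,
because per-permutation BIC selection zeroes borderline edges more
aggressively). Comparisons should weight conclusions toward edges that both
conditions' networks contain.

## Preprocessing

Per-subject conditioning, in order: discard of initial volumes (default 5,
scanner equilibration), linear detrending (least-squares line per segment),
zero-phase band-pass (order-2 Butterworth run forward–backward,
reflect-padded; default 0.01–0.08 Hz, the standard resting-state band, at
TR = 2 s), nuisance regression (OLS residualization on an intercept plus
user-supplied regressors such as motion, global, white-matter and CSF
signals), and per-segment standardization (mean 0, variance 1 with
denominator m − 1; standardized data make the learned weights standardized
coefficients, comparable across edges — a flag disables it).

Nuisance regressors are passed through the same detrend/band-pass as the
data before the regression. Regression can only remove what is collinear
with the regressor as supplied; filtering the data but not the design leaves
the filtered-away portion of each confound in the data. This mismatch
measurably corrupts downstream structure learning, so conditioning the
design is the default.

## Synthetic data

The generator draws multi-subject, two-condition ROI series from a known
network so that every stage can be validated against ground truth. The
default scenario mirrors a desk-scale two-condition study: 8 nodes carrying
default-mode-network region names (PCC, MPFC, bilateral IPC/ITC/HC), 14
subjects per condition, 127 volumes per subject at TR = 2 s, edge
probability 0.25 over a random topological order, signed weights with
|b| ∈ [0.3, 0.8] (negative connections occur in real effective-connectivity
networks, so signs are random), residual variance 1, zero means. Condition B
applies configurable per-edge weight offsets. Seeding is counter-based per
(scenario seed, condition, subject), so growing the subject count never
reshuffles existing subjects, and identical scenarios reproduce bitwise.

Optional artifacts exercise preprocessing: a per-subject linear trend
(uniform slope in ±0.02 signal units per volume) and a shared low-frequency
sinusoidal confound (0.002–0.008 Hz, amplitude 1, random per-node loadings
0.2–1.0). Both are removed exactly by detrend + (conditioned) nuisance
regression, verified end-to-end.

What the generator does **not** emulate: hemodynamic convolution,
physiological noise spectra, spatial structure, and — deliberately —
temporal autocorrelation: samples are i.i.d. across time, matching the
network model's exchangeability assumption (an AR(1) contamination mode
exists for robustness probes, default off). One consequence: band-pass
filtering i.i.d. samples *induces* serial correlation, which the
exchangeable-sample likelihood then miscounts (nominal m overstates the
effective sample size several-fold), flooding the learner with false edges.
The structure-recovery calibration therefore runs the pipeline stages that
correspond to the generator's artifact model (discard, detrend, nuisance
regression, standardization) with the band-pass off; the filter's frequency
response is validated separately by FFT contract tests. On real fMRI data,
where noise is temporally structured, band-pass filtering remains standard —
but the same effective-sample-size caveat applies to the BIC's m there too.

## Validation battery and problem sizes

`bnec.experiments` packages the Monte-Carlo checks the test suite and
`scripts/acceptance.py` run; sizes were chosen to keep the full battery in
the minutes range on one CPU:

- oracle equivalence: 50 datasets (3 and 4 nodes, m = 1000) — hill-climb BIC
  equals the exhaustive optimum;
- weight recovery: 50 scenarios at m = 14 × 127 = 1778, true structure
  fixed — mean absolute weight error ≈ 0.02;
- CPDAG recovery: 100 artifact-injected scenarios through the full
  pipeline. Measured ~70–78% exact-CPDAG recovery: residual failures are
  not search failures (the learned structure always scores ≥ the truth) but
  genuine small-margin BIC preferences — with 28 candidate pairs at
  m = 1778 the probability that at least one noise edge clears the penalty
  is ~16%, plus occasional near-cancellation of signed path weights
  (faithfulness violations);
- pruning calibration: 400 fits with one spurious parent — retention ≈ 0.04
  at α = 0.05;
- permutation type-I: 200–400 null scenarios × 200 permutations (speed
  mode; full mode spot-checked) — pooled one-sided rejection ≈ 0.06–0.07 at
  α = 0.05, with the edge-selection decomposition described above;
- permutation power: 100 scenarios with a 0.5 weight offset on one edge —
  detected in ≈ 97% of runs;
- exact identities: joint-density factorization to < 10⁻⁶; DAG counts 25
  and 543 by enumeration.

## Known limitations

- Directionality is identified only up to the Markov equivalence class;
  report CPDAGs when direction matters.
- The BIC counts concatenated rows as independent samples; autocorrelated
  or filtered data inflate the effective likelihood and produce extra edges.
- Group-level concatenation assumes a shared network and homogeneous
  weights across subjects; subject-level heterogeneity is not modeled.
- Reciprocal and self connections are outside the DAG family; dynamic
  (time-lagged) networks are out of scope.
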