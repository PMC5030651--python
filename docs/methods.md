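# Methods

## Model

A group's metabolic connectivity network is the matrix of Pearson
correlations r_ij of regional uptake across that group's subjects. The
analysis assumes (i) uptake values are cerebellum-normalized so global
signal differences between subjects are largely removed, (ii) subjects
within a group are exchangeable draws from one population, and (iii) the
interesting group difference lives in the *covariance* structure, not the
regional means — which is why all inference is on correlation-derived
quantities and the group labels are the unit of permutation.

Correlations are mapped to distances before filtration. The package
implements two maps and tags every output with the one used
(`metric_tag`): `one_minus_r` (default; the display grid ε = 0.1…0.6 then
corresponds to correlation cutoffs 0.9…0.4, the conventional range for
correlation networks) and `sqrt_one_minus_r`. Negative correlations give
d > 1 under the default map and are kept: the filtration is threshold-free
and truncation would silently delete structure.

## Filtration quantities

`beta0_at(d, ε)` counts connected components of the graph with edge set
{(i,j): d_ij ≤ ε} by union-find. Thresholds are **closed** (an edge with
d_ij = ε is present), which makes β₀(ε) right-continuous and merge heights
attained. `filtration_profile` returns β₀ as a step function whose
breakpoints are exactly the deduplicated single-linkage merge heights, plus
the component barcode: one bar per region, all born at ε = 0 (components
exist from the start in degree-0 homology), n−1 finite deaths and one
immortal bar.

`single_linkage` runs Kruskal's algorithm over the condensed edge list
sorted by (weight, sorted label pair); each accepted edge merges two
clusters at its weight, and that weight is the single-linkage distance
between every cross-cluster pair — equivalently the minimax path distance.
The resulting SLM is an ultrametric, entrywise ≤ the input matrix. Ties are
broken by the lexicographic order of the *sorted* label pair, so dendrograms
are bit-reproducible and independent of matrix storage order. Merge events
store full member sets, making the Newick export lossless (branch lengths
are height differences; every root-to-leaf path length equals the final
merge height).

A conservation law ties the pieces together and is asserted in tests: the
multiset of finite barcode deaths = merge heights = MST edge weights; and
the MST of the SLM has the same total weight as the MST of the raw distance
matrix. Note the SLM is saturated with exact ties (an ultrametric on n
points has at most n−1 distinct values), so *which* minimal edge set its
MST picks is an arbitrary deterministic choice; analyses that care about
MST topology (e.g. the basal-ganglia subtree statistic in
`analysis/04_mst.py`) therefore build the tree from the raw distance
matrix. Both inputs are accepted and the choice is recorded in the tree's
`source` tag.

## Permutation inference

For each region pair the observed statistic is the lesion−control
difference of either Fisher z(r) (clipped at |r| = 1 − 1e-7 before atanh to
keep degenerate inputs finite) or the SLD. The null is built by B
label permutations: each replicate draws `rng.permutation(n_subjects)` from
`numpy.random.default_rng(seed)` and assigns the first n_control shuffled
rows to the pseudo-control group, so the null stream is a deterministic
function of (seed, B, subject row order). The full pipeline is recomputed
per pseudo-group — there is one code path for observed and null statistics.
Replicates containing a zero-variance region are redrawn and counted, never
silently dropped.

p-values use the add-one estimator (k+1)/(B+1), which is valid (never zero)
under exchangeability; exceedance comparisons carry a 1e-12 tolerance so a
permutation that recreates the observed split counts as a tie regardless of
floating-point summation order. Sidedness is explicit: `greater` (lesion
statistic larger — the loosening direction for SLDs), `less` (the loosening
direction for correlations/z), or `two_sided` on |delta| (default).
Benjamini–Hochberg FDR (via statsmodels) is reported alongside raw p over
the 190 pairs of the default 20-region scheme; Bonferroni is deliberately
not offered, being far too conservative for 190 strongly dependent tests.
The headline analysis driver uses B = 2000 and the pipeline default is
B = 10000.

## Synthetic cohorts

The generator emulates the study geometry: 10 control and 14 lesion
subjects over 20 bilateral VOIs of the cortico-striatal-thalamic loop (five
subcortical structures — caudoputamen, globus pallidus, substantia nigra,
subthalamic nucleus, thalamus — and five cortical areas, split L/R). Each
group is drawn from a multivariate normal with mean 1.0 and per-region sd
0.1 (normalized-SUV scale; draws are clipped at 1e-6, a measure-zero event
at these defaults). The target correlation matrix is block-structured:
`base_corr` (default 0.7) within an anatomical module, `cross_corr`
(default 0.35) across, values chosen to give clearly separated but
non-degenerate blocks at the study's sample sizes. The lesion group
additionally applies `disrupted_pairs` overrides;
`lesion_disruption()` provides a set shaped like the reported pathology
(right auditory cortex decoupled from bilateral frontal, right motor,
bilateral visual cortex and the left caudoputamen).

Assembled block matrices need not be positive semi-definite; they are
repaired by eigenvalue clipping at 1e-8 and re-normalization to unit
diagonal (a congruence, so one pass preserves PSD). The repair can move
extreme overrides substantially — zeroing six edges of a node that stays
strongly coupled elsewhere lands near 0.06–0.09, not exactly 0 — and the
*repaired* matrix is the ground truth that convergence tests check against.

What the generator does **not** model: voxel-level images and
partial-volume effects, non-Gaussian uptake distributions, inter-subject
global-signal residue, or regional mean differences. Passing tests
therefore certify the statistical machinery under a Gaussian,
block-correlated world, not fidelity to any particular biological dataset.

## Numerical and design choices

- Determinism everywhere: one `default_rng(seed)` per simulation (control
  drawn before lesion), a documented permutation stream, lexicographic tie
  breaks, no timestamps in outputs; identical configs produce byte-identical
  result bundles.
- The MST layout is an own SMACOF (stress-majorization) implementation on
  tree path distances — the Guttman update never increases stress, giving a
  checkable descent contract (stop at relative change < 1e-6 or 1000
  iterations). It is cosmetic; no claim is made about matching any published
  figure geometry.
- Pajek export is pinned to a narrow dialect (1-based indices, quoted
  labels, `*Vertices`/`*Edges`, whitespace-separated, CRLF-tolerant reader)
  so files round-trip exactly and remain readable by networkx.
- Calibration checks treat the *simulation replicate* as the independent
  unit: the 190 pair-level tests within one replicate share both the data
  and the permutation stream, so pair-level rejection indicators are
  positively dependent and any envelope assuming 38,000 independent
  Bernoulli trials would be invalid. The test suite uses a 99% binomial
  envelope with n = 200 replicates.
- Problem sizes in the test suite (200 calibration replicates at B = 500;
  50 power replicates at B = 200; oracle sweeps at n ≤ 7 regions and
  exhaustive tree enumeration at n ≤ 6) are chosen so the whole suite runs
  in about a minute on one core while keeping every Monte-Carlo assertion
  comfortably inside its envelope.

## Known limitations

- With only 10 + 14 subjects, single-pair effects are near the edge of
  detectability (the worked example finds 2 of 6 planted disruptions at
  p < 0.05); the filtration/SLD quantities are global by design and trade
  per-edge sensitivity for threshold-freeness — a destroyed edge inside a
  redundant block hardly moves the minimax distance.
- The correlation→distance map is a modelling choice, not a canonical fact;
  both provided maps are monotone, so β₀ curves are reparametrizations of
  each other, but numeric thresholds (the display grid) read differently.
- FDR-adjusted q-values over 190 dependent tests are reported as
  Benjamini–Hochberg, whose control under this dependence is approximate.
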