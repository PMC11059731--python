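# Methods

## Scope and data model

The package operates on three tables: a samples × features count table of
non-negative integers (reads per amplicon variant), a per-feature ranked
lineage (domain … genus), and per-sample metadata carrying design factors
(station, depth, month, season, layer), abiotic variables (Temp, Sal,
NO₃⁻, NO₂⁻, NH₄⁺, DIN, NTOT, PO₄³⁻/SRP, PTOT, SiO₄²⁻, Chl a), biotic
variables (UHB, HNA, SYN, PROCHL, PE, HNF, BP and total AAP abundance in
cells mL⁻¹) and FISH-IR probe percentages (ALF968, GAM42a, ROS537, % of
AAP cells). Tab-separated text is canonical; count files are
features-as-rows on disk (a flag accepts the transposed layout) and
samples-as-rows in memory. Writers sort both axes lexicographically so
outputs diff cleanly. Missing environmental values are allowed and are
skipped (and counted) wherever averages are formed.

## Compositional treatment

Count data are compositional: only relative information is meaningful, so
all multivariate analysis happens in centered log-ratio (CLR) space.

* **Filtering order is fixed**: taxa first (kept when they reach ≥ 2
  reads in at least ⌈0.05 · n⌉ samples; boundary counts qualify), then
  samples (kept at depth ≥ 2000 reads; the boundary is kept because the
  exclusion rule is depth < 2000). A test pins this order, since a sample
  can drop below the depth threshold only after rare taxa are removed.
* **Agglomeration** sums integer counts over lineages truncated at the
  requested rank, conserving per-sample totals exactly. Output ids are
  full ';'-joined lineage strings, so same-named genera under different
  orders never collide. CLR always happens *after* agglomeration.
* **Zero replacement**: δ = (global minimum nonzero relative
  abundance)/2, one value for the whole matrix. A single δ preserves
  perturbation invariance across samples; a per-sample variant exists
  behind a flag. After replacement rows are *not* re-closed — the log-mean
  centering absorbs the closure constant; this is documented because it
  changes values slightly versus re-closure. δ is computed after
  filtering, on the table actually being transformed.
* Unclassified taxonomy ranks receive the deterministic placeholder
  `<rank-initial>:<deepest-classified-name>_unclassified`, which is
  injective per parent lineage, so "unclassified" children of different
  parents stay separate during agglomeration.

Aitchison distance is plain Euclidean distance between CLR rows, held in
a scikit-bio `DistanceMatrix` (symmetry and zero diagonal validated on
construction).

## Neural gas

Rank-based online vector quantization: K units are initialised at K
distinct data rows drawn by the seeded generator (guaranteeing the
codebook starts inside the data's axis-aligned bounding box), and every
presentation of a sample x updates all units by
w_i ← w_i + ε(t)·exp(−r_i/λ(t))·(x − w_i) with r_i the Euclidean distance
rank of unit i for x (stable sort; ties go to the lower unit index).

* **Schedules**: ε(t) = ε₀·(ε_f/ε₀)^(t/t_max), λ(t) = λ₀·(λ_f/λ₀)^(t/t_max),
  with t counted in *sample presentations* (t_max = epochs × n) so the
  annealing is smooth even for small n.
* **Defaults**: K = 5 units, 1000 epochs, ε₀ = 0.5, λ₀ = 4.5 — the
  standard settings for this analysis family. The annealing endpoints are
  not part of those settings; ε_f = 0.005 and λ_f = 0.01 are chosen as
  typical neural gas endpoints that make late training nearly
  winner-only, and both are exposed in `NGConfig`. With λ₀ = λ_f ≤ 1e−6
  the update reduces exactly (to float underflow) to online k-means on
  the winner, which a test exploits as an independent oracle.
* Because 0 < ε·e^(−r/λ) ≤ 1, every update is a convex combination, so
  the codebook can never leave the data bounding box; this is asserted
  after every training run.
* A unit that ends with zero members is reported as empty, never
  reseeded mid-training.
* Units are renumbered by decreasing membership for reporting (ties keep
  the original order). Identical data + config ⇒ bit-identical codebooks.

BMU profiles are unweighted arithmetic means over member samples — of
environmental variables in their original units (missing values skipped,
non-missing counts recorded) and of CLR taxon values. The long-format
export (unit, kind, name, mean, n) is sorted deterministically and is the
machine-readable form of the usual red-green heatmap; rendering is left
to downstream tools.

## Diversity

Rarefaction draws exactly `depth` reads without replacement
(multivariate hypergeometric; a multinomial with-replacement flag exists
but is off by default). Observed richness counts nonzero features;
Shannon H′ uses natural logs (J′ = H′/ln S is base-free either way, but
H′'s base must be fixed for comparability); J′ is undefined (NaN, with a
warning) at S = 1. Defaults: depth 2000, 100 repeats, computed on the
unagglomerated ASV table. Repeat streams are spawned per sample from one
master seed, so results are independent of sample order and reproducible.

## Permutation tests

One-way PERMANOVA uses Anderson's pseudo-F from raw squared distances:
SS_T = N⁻¹ Σ_{i<j} d²ᵢⱼ, SS_W = Σ_g n_g⁻¹ Σ_{i<j∈g} d²ᵢⱼ,
F = [(SS_T − SS_W)/(a − 1)]/[SS_W/(N − a)]. When the number of distinct
relabelings (multinomial coefficient) is ≤ 10,000 the test enumerates
them all and p is the exact exceedance fraction; otherwise p =
(b + 1)/(m + 1) over m seeded permutations, so p can never be zero and is
bounded below by 1/(m + 1). Perfectly separated groups give SS_W = 0 and
F = +inf, matching standard implementations.

PERMDISP embeds the distance matrix by principal coordinates
(eigendecomposition of the double-centered Gram matrix), keeps positive
and negative eigenvalue axes separately, and computes each sample's
deviation from its group centroid as √(d²₊ − d²₋) clipped at zero (the
standard correction for non-Euclidean inputs; for Aitchison distances all
eigenvalues are non-negative and the correction is inert). The statistic
is the one-way ANOVA F on deviations; the permutation scheme holds
deviations fixed and shuffles their group labels. Only one-way designs
are implemented; nested or multi-factor designs with conditional sums of
squares are out of scope — run one factor at a time.

The pipeline excludes factor levels with fewer than two members from the
permutation tests (logged), since neither statistic is defined for
singleton groups.

## Concordance

The pseudoabundance of a taxon in a sample is (relative abundance % ×
total AAP cells mL⁻¹)/100. The concordance statistic correlates, per
probe, FISH-IR probe *counts* (probe % × total AAP/100 — microscopy
percentages refer to counted cells, so both series are placed on the
absolute cells mL⁻¹ scale with the shared total) against the
pseudoabundance of the probe's mapped taxon, by Spearman rank correlation
with average-rank ties. The probe→taxon mapping is configuration; the
default maps the Alphaproteobacteria probe to a class, the
Gammaproteobacteria probe to a class, and the Roseobacter-clade probe to
the Rhodobacterales-like order nested in the first class (in the
synthetic taxonomy: C1, C2 and C1.O1). For n ≤ 9 the Spearman p-value is
exact by full permutation; above that, the usual t-approximation is used
and the method is recorded in the result.

## Synthetic data generator

The generator is first-class, tested code that defines the study
conditions for every downstream test:

* **Scale defaults** mirror a year-round coastal survey: 81 samples, 661
  ASVs in 86 genera / 8 orders / 2 classes, log-normal library sizes
  (median ≈ 58,000 reads) floored at 2000, total AAP abundance
  log-normal with mean ≈ 1.43 × 10⁴ and sd ≈ 0.75 × 10⁴ cells mL⁻¹.
* **Composition model** is logistic-normal (Gaussian in CLR space):
  each of five planted clusters has a center vector; samples draw a CLR
  vector around their cluster's center (within-cluster sd 1.0 by
  default, centers drawn with coordinate sd 2.0 when not supplied
  explicitly), invert through softmax to a composition, and draw integer
  counts multinomially at the sampled depth. Gaussian-in-CLR is chosen
  because the downstream analysis operates in CLR space, so effect sizes
  have direct geometric meaning. The within-cluster sd is a free knob,
  not an estimate of any real community's overdispersion.
* **Cluster labels** are drawn uniformly at random so unbalanced units
  are exercised; `balanced_labels=True` gives fixed blocks.
* **Environment**: each cluster has a mean vector of realistic values
  for an oligotrophic temperate sea (e.g. per-cluster temperatures 16,
  24, 20, 12, 14 °C; salinities 36.5–38.7); per-variable noise sd
  defaults to 10 % of the across-cluster range. DIN is computed as
  NO₃⁻ + NO₂⁻ + NH₄⁺, never drawn independently. Seasons attach to
  clusters (months drawn from the cluster's dominant season with
  probability 0.8), so seasonal permutation tests have signal exactly
  when compositional clusters exist.
* **FISH fractions** are the *true* (pre-multinomial) class/order-level
  percentages plus Gaussian noise (default sd 2 percentage points),
  clipped to [0, 100] — giving the concordance stage a tunable true
  correlation.

What the generator does **not** emulate: sequence content and error
profiles, chimeras, primer bias (real *pufM* surveys over-represent some
classes), spatial/vertical autocorrelation beyond the cluster structure,
overdispersion beyond the logistic-normal, or correlated environmental
noise. Passing tests therefore demonstrate correctness of the
computations and recoverability of planted structure — not that any real
community will cluster this cleanly.

## Problem sizes in tests

The module tests run on reduced scales (tens of samples/features, dozens
of epochs) chosen to exercise every code path; the end-to-end smoke test
runs the full survey scale (81 × 661, three ranks, 1000 epochs, 100
rarefactions, 9999 permutations) and verifies byte-identical
reproduction on a rerun. The acceptance script uses the full default
scale throughout.

## Known limitations

* Exact numeric replication of codebooks produced by other neural gas
  implementations is not attempted: toolboxes differ in their annealing
  clocks and endpoint conventions, and only the algorithm family and the
  stated hyperparameters are fixed here.
* The prevalence filter implements the standard keep-rule (≥ 2 reads in
  ≥ 5 % of samples). The common verbal phrasing of the exclusion rule
  ("occurring less than 2 times in at least 5 % of samples were
  excluded") is ambiguous under literal negation; the standard rule is
  implemented and the thresholds are exposed.
* At the order rank (8 features) planted clusters overlap substantially
  after projection, so cluster recovery there is typically partial —
  an inherent property of low-dimensional agglomeration, not a defect.
* No automatic selection of K, no topology edges, no SOM grid.
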