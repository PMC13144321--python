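# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of the package. Parameter
defaults are listed with the stage that owns them; every empirical
statement here is one the test suite or `scripts/acceptance.py`
computes.

## Study design emulated

A melanoma-like cell-line study: two genotypes (wild-type and knockout
of a chromatin remodeler) × four treatments (untreated, two kinase
inhibitors, their combination) × 3 replicates = 24 samples, profiled as
mRNA counts, protein log-abundances and phosphosite log-abundances.
Three latent factors structure the data: a treatment-shared response
(all drugged samples), a combination-specific response, and a genotype
response. The default sample grid is 2×4×3; replicate count and all
effect/noise levels are configurable.

## Synthetic data generator

* **Interactome** — Barabási–Albert preferential attachment (default
  150 nodes, 3 edges/node; heavy-tailed degrees), edge confidences
  uniform(0.3, 1]; the Steiner edge cost is `1 − confidence` (monotone,
  bounded, the standard interactome convention).
* **Planted truth** — receptor→effector paths of a requested length
  traced through the graph; the first two share an interior convergence
  hub. Planted edges get confidence ≥ 0.9. Path interiors are labelled
  kinases, endpoints receptors/TFs. Factor feature support is either
  `shared` (each factor's support spans all views, disjoint across
  factors so the axes stay identifiable) or `view_confined` (factor *k*
  lives only in view *k*; pools are denser, |V|/6 per factor, because
  one view carries the whole factor). Receptor support features are
  always signed upward (receptor induction), other supports ±1 at
  random.
* **Omics** — mRNA: gamma-Poisson (negative binomial, dispersion 0.05)
  around `2^(base + signal)`, base log₂-mean uniform(3, 9). Protein: a
  latent level = base + signal + biological variation
  (`bio_sd` = 0.35) observed with measurement noise (`noise_sd`,
  default 0.5). Phospho: the parent's latent level + site-specific
  signal + its own measurement noise — so a site with no site-specific
  signal correlates with its parent at
  `bio²/(bio² + noise²)` (≈ 0.92 at noise 0.1), and net-phosphorylation
  residualization removes the shared component exactly. `bio_sd` was
  fixed once at the smallest value giving that correlation > 0.9 while
  keeping 3-factor recovery attainable at noise 0.5. Missingness in
  protein/phospho is logistic in abundance (left-censored-like) with
  the requested mean rate, calibrated by root finding.
* **Regulons** — disjoint signed-weight target sets per TF, drawn away
  from planted-path members, receptors and genotype-factor support so
  that (a) background TFs are truly null under the knockout contrast
  and (b) receptor differential expression is not confounded by
  TF-target shifts. Planted-active TFs shift their targets by
  `sign(weight) × activity × effect_size` in knockout samples.
* **Annotations** — every node draws `terms_per_node` (8) of `n_terms`
  (500) uniformly; nodes of one planted path share a fixed core of
  ⌈2·8/3⌉ = 6 path terms, guaranteeing pairwise Jaccard ≥ 0.5 within a
  path. A convergence hub keeps the union of its paths' cores, so its
  pairwise Jaccard with neighbors dilutes to ≈ 0.4 — still an order of
  magnitude above the ≈ 0.02 background.
* **Kinomics / viability** — planted kinases get |median activity
  change| ∈ (1.5, 3); background N(0, 0.3), which crosses the ±1 filter
  with probability < 10⁻³. Viability: 25 timepoints (0–96 h, 4-h
  steps); logistic decline under drug (knockout slower than wild type;
  receptor-targeting gRNA restores the decline), logistic growth under
  vehicle, 2 % multiplicative noise, optional single-point spikes.

What the generator does **not** emulate: batch effects beyond a batch
label (no systematic offsets by default), peptide-level artifacts,
compositional library effects, dropout structure of real TMT runs, or
interactome topology beyond heavy-tailed degrees. Passing tests
therefore demonstrate algorithmic correctness and recoverability under
the planted model, not performance on real acquisitions.

## Numerical and algorithmic choices

* **TMM** — reference sample = upper quartile closest to the mean upper
  quartile; genes positive in both samples; 30 % trim per tail on M,
  5 % per tail on A; factor = 2^mean(M); factors normalized to
  geometric mean 1. Pure rescaling of a sample is absorbed by its
  library size (M ≡ 0).
* **log-CPM** — `log2((count + 0.5) / (libsize × factor + 1) × 10⁶)`;
  precision weights are deliberately out of scope (nothing downstream
  consumes them).
* **Welch t + BH** replace moderated tests: the empirical-Bayes
  moderation machinery is out of scope; thresholds keep their meaning
  under the ordinary t. Zero-variance two-group comparisons with equal
  means get t = 0, p = 1; with unequal means p = 0 and a `degenerate`
  flag (never NaN).
* **Imputation** — deterministic condition-mean (genotype × treatment)
  when ≥ 3 replicate values are observed; otherwise left missing. The
  sample-QC threshold 50 is inclusive (≥ 50 retained).
* **ANOVA selection** — effect size = max |group mean − grand mean|;
  the phospho criterion uses BH-adjusted p (< 0.1), the stricter
  protein/mRNA criterion raw p (< 0.001) with a config switch, since
  only the phospho wording specifies FDR adjustment.
* **Factorization** — deterministic concatenated-SVD stand-in for
  variational multi-omics factor analysis, with the same output
  contract (scores, per-view loadings, VE, sign convention); externally
  fitted loadings can be imported through the same TSV layout. Missing
  values must be imputed upstream. Reconstruction is Eckart–Young
  optimal by construction (verified against direct SVD). Note the
  treatment and combination indicators are correlated by design
  (combination ⊂ treated), so fitted factors are rotations of the
  planted axes; factor identity is resolved by score–design
  correlation where needed.
* **Cross-view weight aggregation** — signed max-|weight| within the
  phospho view (per protein) and then across views, ties broken toward
  the canonical view order (mrna, protein, phospho); mean aggregation
  available. Seed sets are the top/bottom ⌈q·n⌉ proteins (q = 0.05),
  ID-ordered on ties.
* **RWR** — damping 0.95 is the continuation probability (restart
  0.05). The iteration `p ← d·W·p + (1−d)·p₀` stops at L1 change
  < 10⁻⁹ (default) and the result is renormalized to sum 1 (the
  symmetric operator is not stochastic). Stopping at tolerance τ bounds
  the distance to the fixed point by ≈ τ·d/(1−d), so equivalence checks
  against the closed form `(1−d)(I−dW)^{-1}p₀` run the iteration at
  τ = 10⁻¹². For the thousands of null networks the same closed form is
  solved densely (identical result, far cheaper at ≤ a few hundred
  nodes).
* **Null model** — double-edge swaps (10×|E| attempts, self-loops and
  multi-edges rejected) with confidences travelling on their edges;
  degree sequence exactly preserved, connectedness not. Empirical p is
  add-one: `(1 + #{null ≥ observed}) / (1 + n_null)`. Note the
  degree-preserving null deliberately makes *seed nodes themselves*
  non-significant — their scores are dominated by restart mass and
  degree-dependent return probability, both preserved under the null.
  That is the hub correction working as intended.
* **RWR retention threshold** — 0.01 is interpreted as a fraction of
  the maximum node score (configurable to absolute). Retained nodes
  additionally need empirical p ≤ 0.05; seeds are always retained.
* **KDE filter** — candidates' mean Jaccard similarity to the seed set
  is modelled by a 1-D Gaussian KDE (Silverman bandwidth); candidates
  at or above the distribution's cutoff quantile (0.5) survive. An
  enrichment-test gate used by the original ego-network decomposition
  requires an annotation-enrichment backend that is out of scope; the
  empirical-p + KDE pair is the documented stand-in, and the
  decomposition is seed-restricted rather than per-seed ego-split.
* **PCSF** — objective `Σ cost(F) − β·Σ prize(V(F))`, β = 1 by default;
  each connected component contributes at most one tree (possibly a
  singleton, possibly nothing), which is the only reading consistent
  with prized-but-isolated nodes being worth collecting. The solver is
  strong pruning — an exact best-subtree dynamic program — applied to
  the component's minimum spanning tree and to shortest-path trees from
  the highest-prize roots; it can only return feasible solutions, so it
  is never better than the exhaustive optimum and matches it on ≥ 90 %
  of enumerable instances. Robustness: multiplicative uniform
  (1 ± noise) cost jitter, consensus at frequency ≥ 0.5, cycle-breaking
  by keeping a maximum-frequency spanning forest.
* **Cross-talk score** — geometric mean of the two stationary
  distributions (min and product available); hub ranking excludes seed
  nodes. Receptor seed vectors: adjusted p < 0.01, sign-matched
  direction, |LFC| normalized to sum 1. Kinase vectors: strict
  |change| > 1.
* **Max flow** — each undirected edge becomes two opposite arcs with
  capacity = Jaccard similarity + 10⁻⁶ floor; exact max flow; per-edge
  net flow reported. Feasibility and conservation are asserted on every
  run. The flow percentile (95) is computed over positive-flow edges
  only and applied inclusively (≥), so percentile 0 keeps all
  positive-flow edges; the component containing source and sink is
  returned (or their two components, flagged).
* **ULM** — OLS of the per-gene statistic on the regulon weight vector
  (weight for targets, 0 elsewhere, intercept); activity = slope
  t-value, equal to `r·√((n−2)/(1−r²))`; TFs with < 5 covered targets
  are skipped with a flag. The per-gene statistic defaults to the Welch
  t (LFC available), computed after a summed-count ≥ 10 filter and
  log-CPM.
* **Viability smoothing** — Hampel rule per point (window of 3,
  extended one-sided at the boundaries): flag
  `|x − median(window)| > 3 × MAD(window)`, replace by linear
  interpolation, then a centered window-3 rolling median and t₀
  subtraction. Window-3 filters cannot remove two adjacent spikes; the
  generator's spike rate keeps such pairs rare and the tests tolerate
  them.

## Pipeline scale and reproducibility

All stochastic stages draw child seeds spawned deterministically from
one master seed; rerunning any stage with its recorded seed reproduces
its artifact bit-for-bit (asserted in the pipeline test). The
validation suite runs reduced problem sizes chosen to keep each check
sharp: null counts 100–1000, permutation counts 200–500, 200 PCSF
iterations and 150-node interactomes in the 20-replicate end-to-end
recovery, and a 900-node interactome for 3-factor recovery — at 24
samples the < 5° subspace bound needs on the order of 100+ support
features per view (standard perturbation scaling, confirmed by
simulation), which the view-confined pools provide. Production-scale
defaults (1000 nulls, 10,000 permutations, 4000 PCSF iterations) remain
the `RunConfig` defaults.

## Known limitations

* The factorization is a deterministic SVD stand-in: no automatic
  relevance determination, no missing-value handling inside the model,
  no factor-number selection.
* Moderated differential statistics, batch correction, GO
  DAG-information-content similarities and enrichment-based gating are
  out of scope; Jaccard similarity treats all annotation terms as
  exchangeable.
* PCSF is an approximation; on large dense networks with many near-tied
  routes the consensus forest depends on the noise model.
* Empirical p-values are bounded below by 1/(1 + n_null); hub-corrected
  significance cannot distinguish a seed's own importance from its
  degree.
* The viability endpoint test assumes ≥ 2 replicate wells per group and
  errors on degenerate (zero-variance, unequal-mean) comparisons.
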