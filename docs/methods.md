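# Methods

This note documents the statistical model, the defaults and the numerical
choices behind `mirlink`, and what the synthetic test bed does and does not
establish about real data.

## Study design assumed

The package models a two-group contrast (exposure vs control) of paired
mRNA and miRNA profiles measured on the same subjects, on a log2 intensity
scale. The default parameterization throughout emulates a small-animal
array study: 8 exposure and 8 control arrays, ~2000 unique genes after
probe collapsing, a few hundred miRNA probes, and gene-set collections of
a few hundred sets of 15–50 genes. All identifier matching is
case-sensitive and string-based; mapping probes, gene-set members and
predicted targets into one namespace is the caller's responsibility.

## Preprocessing

* **Detection filter.** Features detected in fewer than `min_fraction` of
  arrays are removed. The miRNA default is 1.0 — a probe undetected on any
  array is excluded — reflecting the all-or-nothing detection convention of
  one-color miRNA arrays; the mRNA default is 0 (no filter).
* **Quantile normalization.** Every column is replaced by the across-array
  mean of order statistics, jointly over all arrays of both groups. Tied
  values within a column receive the mean of the quantile means their rank
  slots span, so ties remain ties. Two consequences worth knowing: on
  tie-free data the transform is exactly idempotent and all columns share
  one multiset; on tied data the tie-averaging perturbs the reference of a
  second pass, so exact idempotency holds only up to the within-block value
  spread. Arrays that fail QC should be dropped (`drop_samples`) *before*
  normalization; QC itself is out of scope.
* **Probe collapse.** `max_mean` (default) keeps the probe with the highest
  mean intensity per gene — the standard collapse convention for enrichment
  analysis — `mean` averages probes.

## Moderated differential expression

The two-group statistic is a Cyber-T-style regularized t. For feature *i*
with pooled variance s²ᵢ and overall mean intensity x̄ᵢ, the background
variance σ₀²ᵢ is the mean pooled variance of the `window_size` (default
101) features nearest to x̄ᵢ in mean-intensity rank (window shifted inward
at the edges so it always holds exactly w features). The posterior variance
is

    s̃²ᵢ = (ν₀ σ₀²ᵢ + (n₁+n₂−2) s²ᵢ) / (ν₀ + n₁+n₂−2)

and tᵢ = Δx̄ᵢ / √(s̃²ᵢ (1/n₁ + 1/n₂)) is referred to a t distribution with
ν₀ + n₁ + n₂ − 2 degrees of freedom (two-sided). Defaults ν₀ = 10,
w = 101 (clipped to the feature count). ν₀ = 0 recovers the ordinary
pooled-variance t-test exactly.

**Calibration.** With ν₀ = 0 the null p-values are exact. With ν₀ > 0 the
reference distribution is the conventional approximation; under a
homoscedastic null the shrunk statistic has *lighter* tails than the
reference, so the test is mildly conservative (measured ≈4.6% rejections at
nominal 5% with ν₀ = 10 on 8 vs 8 Gaussian data). It is never
anticonservative in this regime, and BH FDR control holds a fortiori. The
shrinkage buys stability when per-feature variances are noisy (n of 8 per
group), at this small power cost for well-behaved features.

Q-values use the Benjamini–Hochberg step-up rule (input order preserved);
an optional Storey-style π₀ (λ = 0.5 estimator) can rescale them. Folds are
reported in the signed-ratio convention: fold = r = 2^Δlog2 when r ≥ 1,
else −1/r, with ratio 1 reported as +1.0 (so −1.68 is a 1.68-fold decrease
under exposure). qPCR confirmation folds use 2^−ΔΔCt with replicate Ct
values averaged before ΔCt, expressed exposure-relative-to-control.

## Gene set enrichment

* **Ranking metric.** Signal-to-noise by default — Δmean over the sum of
  group standard deviations, each floored at max(0.2·|mean|, 0.2) — the
  standard metric for this analysis; `t_stat` and `log_fold` are
  alternatives. Ties in score break by gene ID ascending, making the ranked
  list fully deterministic.
* **Running sum.** Walking the ranked list, members advance the sum by
  |score|ᵖ / Σ_hits |score|ᵖ (p = 1 default; p = 0 is the classic
  unweighted KS statistic) and non-members retreat by 1/(N − N_hit). ES is
  the deviation of maximal magnitude; the peak index is 1-based and takes
  the first occurrence on exact ties. If all hit scores are zero (possible
  only with degenerate data) hit mass falls back to uniform. ES is clamped
  to [−1, 1] against accumulation round-off (≤2 ulp).
* **Null distribution.** Gene-set permutation: `n_perm` (default 2000)
  uniformly drawn sets of matched size are rescored against the fixed
  ranked list. The permutation ES is computed from sorted hit positions
  only (the running sum is piecewise linear between hits, so extrema occur
  immediately before or after hits), which makes the null loop O(k) per
  draw rather than O(N). A test pins this fast path to the full walk.
  Phenotype permutation (relabelling arrays and re-ranking) is available as
  an option for designs with enough samples.
* **NES, p, Q.** NES = ES / mean(|same-sign null ES|); p uses add-one
  smoothing, (1 + #{null ≥ obs}) / (1 + #null), so p is never zero at
  finite n_perm. FDR Q compares, within each sign stratum, the fraction of
  pooled null NES at least as extreme against the fraction of observed NES
  at least as extreme, clipped to [0, 1] and then monotonized BH-style
  (each set takes the minimum raw Q over sets of smaller-or-equal |NES|),
  so Q never decreases as |NES| grows. Sets with no same-sign null draw get
  p = 1 and are excluded from NES ranking.
* **Set-size bounds.** Post-intersection sizes outside [5, 500] are
  skipped (conventional bounds; both configurable).
* **Leading edge and modules.** The leading edge is the member subset at or
  before (ES > 0) / at or after (ES < 0) the peak, in rank order.
  Significant same-direction sets are merged into modules either by an
  explicit user mapping (the analyst's statement of functional similarity,
  e.g. combining insulin-regulation and diabetes pathways) or automatically
  by transitive leading-edge Jaccard overlap (threshold 0.5). Merging
  opposite-direction sets via an explicit mapping is an error. Per-gene
  directions inside a module come from the ranked-list score sign at module
  construction time and are the single source of direction truth
  downstream.

## miRNA–module linkage

A DE miRNA links to a module when the module's leading edge contains ≥1 of
its predicted targets with direction opposite to the miRNA's. Direction is
compared at the DE-sign level (miRNA fold sign vs gene score sign), which
is the contract the integration is defined on; an optional stricter mode
additionally requires sample-level Pearson r below a threshold (default
−0.3) between the miRNA and the gene across shared arrays. Target
predictions are consumed as data (a miRanda/MicroCosm-style table); the
package does not predict targets. A miRNA absent from the target table
warns and yields no links; DE miRNAs with zero links are reported
separately rather than treated as errors — whether every DE miRNA links to
some pathway is a property of a dataset, not a guarantee of the method.

## Network analysis

The module interactome keeps the user-supplied interaction edges whose
endpoints both lie in the module's leading edge (plus declared anchor
molecules, e.g. insulin); module genes touching no retained edge are
excluded with a logged count. Linked miRNAs are overlaid as regulator nodes
with targeting edges to their linking genes. Hub ranking counts
protein-interaction edges only — the overlay never changes hub ranks — and
the most-targeted gene ranking counts incident targeting edges, ties
sharing the head group. "Motifs" are reported as connected components of
the gene-gene subgraph after anchor removal: the functional groupings
visible in curated module networks are approximated by components once the
universally connected anchor is taken out, rather than by a community
detection algorithm.

## Synthetic test bed

`simulate.generate` draws log2 intensities iid Normal(8, noise_sd) and
plants: (a) 10 of 200 gene sets as enriched, shifting 70% of each planted
set's members by ±1.0 log2 units in the exposure group, directions
alternating so both enrichment tails are exercised; (b) one DE miRNA per
planted set, shifted 0.8 log2 units in the opposite direction, with 30
predicted targets of which half are drawn from the planted set's shifted
genes and half are decoys; (c) a random interaction graph (edge probability
0.1) over planted-set genes plus decoy edges; (d) truth tables, including
the links expected under the anti-correlation rule (derived by exhaustive
enumeration at generation time). A small number of null miRNA probes are
flagged undetected on all arrays to exercise the detection filter.

What the defaults imply: at noise sd 1.0 the *module-level* signal is
strong (a planted set aggregates ~20 shifted genes, and recovery at Q<0.05
is essentially complete with ≤5% null calls), but the *single-miRNA* DE
stage is underpowered — the expected moderated |t| for a 0.8 shift at sd 1
and n = 8/8 is ≈1.6, far below the ≈3.5 needed at Q<0.05 over ~300 probes.
This mirrors a real contrast between set-level and feature-level testing.
End-to-end tests that need the DE stage powered therefore use noise sd 0.4
(the per-array noise level at which a ~1.7-fold miRNA change reaches
p ≈ 10⁻³–10⁻⁴ at n = 8/8, as in the emulated study class); linkage
correctness itself is always verified against truth tables, independent of
DE power.

The generator does not emulate probe-level replication, intensity-dependent
variance, batch or dye effects, correlated genes within samples, or
hybridization artifacts. Passing tests therefore establish algorithmic
correctness and statistical calibration under idealized Gaussian
conditions, not robustness to array-specific artifacts.

## Problem sizes used in the checks

The calibration and recovery checks run at the emulated design (2000
features, 8 vs 8): 200 replicates for null calibration, 20 seeds for FDR
control and planted-module recovery (permutations scaled to 500 for the
recovery sweep), 50 seeds at a reduced design (300 genes, 20 sets) for the
exact linkage enumeration, and 200 random graphs for the network oracles.
`scripts/acceptance.py` re-runs the full method at the defaults with the
standard 2000 permutations.

## Known limitations

* The moderated-test hyperparameters (ν₀, w) are conventions, not fitted;
  the p-value reference is approximate for ν₀ > 0 (conservative under
  homoscedasticity, see above).
* Gene-set permutation tests set membership against a fixed ranked list; it
  does not propagate between-sample correlation the way phenotype
  permutation does.
* The sign-based anti-correlation rule cannot distinguish direct from
  coincidental opposite movement; the optional correlation mode tightens
  but does not validate regulation.
* Interaction tables and target predictions are taken at face value; their
  coverage bounds what the network stage can reveal.
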