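# Methods

This note records the models, conventions and design choices behind
`modcomm`, in the order the pipeline applies them.

## Module grammar and completeness scoring

Definitions follow the KEGG DEFINITION conventions that custom biosynthesis
module collections imitate. Operator binding, loosest to tightest: space
(sequence; at the top level, the step separator), comma (OR over
alternatives), `+`/`-` (complex chain, with `-` marking the following
component optional). Parentheses group, and a parenthesized multi-step
sequence used as an OR alternative is an AND over its internal steps: the
alternative route counts only when complete (binary) or contributes its
mean (fractional). The `--` placeholder (a step with no known enzyme)
always counts as satisfied. Step identifiers are `<module_id>_NN`,
zero-padded, 1-based.

Two scoring modes are exposed because pathway completeness is genuinely
two-faced. Binary mode (the default) asks whether each step's expression is
satisfiable from the genome's KOs and reports the fraction of satisfied
steps; it is the mode used for community-level step profiles, makes printed
threshold ranges exact, and its values are always multiples of 1/n_steps.
Fractional mode gives recursive partial credit (leaf → presence, OR → max,
AND → mean over required components), on the view that a genome holding
most of a complex is biologically closer to competent than one holding none
of it; fractional ≥ binary always. Degenerate conventions: an expression
whose required parts are all optional is vacuously satisfied (fractional
1.0), and a step that is a bare optional component is likewise ignored
rather than failing.

Numerical behavior is exact: all scores are ratios of small integers (or
means of such ratios); no tolerance enters the evaluator. Both modes, and
the parser in front of them, are checked against an exhaustive
tuple-tree oracle over all 2⁶ subsets of a six-KO alphabet, and against a
render→re-parse round trip.

## Genome-level analysis

The completeness matrix (genomes × modules, values in [0, 1]) is scored
deterministically and is invariant to input order. Category averages are
unweighted means within the amino-acid and vitamin module sets; `avg_all`
is the mean over the union of modules (with 18 + 9 modules, the 27-module
mean, *not* the midpoint of the two category means — the two differ when
category sizes differ, and the single-number-per-genome usage favors the
union mean). Modules for metabolites whose biosynthesis runs through
generic, poorly annotating transaminations (alanine, asparagine, aspartate)
can be excluded at library load by name, not hard-coded id.

Quality gates use strict inequalities exactly as conventionally printed:
high-quality = completeness > 90% and contamination < 5%; the looser
MAG-admission gate (> 45%, < 10%) is recorded as metadata only. Per-genome
comparisons use high-quality genomes; community-level analysis deliberately
uses genomes of any quality, since even partial genomes witness individual
steps.

The QC regression fits ordinary least squares of each module's completeness
on genome completeness (%); a mean R² near zero across modules indicates
the biosynthetic signal is not an assembly-quality artifact. Zero variance
in genome completeness flags the slope NaN rather than guessing.

## Community-level analysis

A community's step profile counts, per module step, the proportion of
members whose KO set satisfies the full step expression (not merely any one
KO of the step — the expression semantics is kept consistent with
genome-level scoring). Collective completeness is, definitionally, the
binary completeness of the union KO set, and the package computes it that
way; the identity is still asserted against independent union scoring in
tests. Complementarity gain (collective − best individual) is the summary
statistic of stepwise interdependency; it is non-negative and zero for
communities of clones.

## Ecology

Relative abundance is `q2q3_cov / sample mean coverage`. Missing
(genome, sample) coverage pairs are read as zero, not missing: under
competitive read mapping every genome receives a coverage in every sample,
and absence of a row means no reads mapped. Mean relative abundance
averages over *all* samples including zeros — occupancy is captured
separately by prevalence (fraction of samples with abundance strictly > 0,
no minimum-breadth screen), so the mean must not condition on detection.

Accumulation curves shuffle culture order uniformly (default 100
permutations, seeded) and report the per-k mean ±1 SD of cumulative
distinct species. Resampling with replacement is available behind a flag
(`method="bootstrap"`), and full enumeration of orderings
(`method="enumerate"`, ≤ 9 cultures) replaces sampling with the exact
expectation; the method used is recorded in the curve output. Tests pin
the estimator to an independent closed-form occupancy expectation,
E[count after k] = Σ_s [1 − C(n−m_s, k)/C(n, k)].

## Statistics

The rank statistics are implemented from their formulas with midranks and
the standard tie corrections: Wilcoxon rank-sum (exact enumeration of the
conditional rank-sum distribution when both n ≤ 8, tie- and
continuity-corrected normal approximation otherwise), Kruskal–Wallis H with
χ²(k−1) p-values, Dunn's pairwise z on pooled midranks with Bonferroni
correction over the pairs of one family (one Kruskal–Wallis test), two-sided
throughout, adjusted p capped at 1. The compact letter display uses the
insert-and-absorb algorithm and is deterministic given group order; its
defining invariant — two groups share a letter exactly when their adjusted
p ≥ α — is property-tested on random significance patterns. Spearman's ρ is
the Pearson correlation of midranks with the t approximation on n − 2 df.
The Shapiro–Wilk screen delegates to SciPy's implementation of Royston's
approximation. α = 0.05 everywhere. Degenerate inputs (constant pooled
samples, zero rank variance) return flagged p = 1 / NaN results instead of
raising mid-pipeline.

Null calibration is tested by simulation: at three groups of 30, both
Kruskal–Wallis and Wilcoxon reject at 5% ± 1% over 2,000 seeded draws, and
the familywise error of the gated Kruskal–Wallis → Dunn procedure stays
below 5%.

## Grouping

PCA operates on the mean-centered, *unscaled* completeness matrix — all
modules already share the [0, 1] scale, so variance scaling would only
amplify near-constant modules. Components carry a deterministic sign
convention (largest-magnitude loading positive). k-means (default k = 3,
10 restarts, seeded) runs on the first five components; clusters are
relabeled by ascending mean `avg_all` so labels are stable and comparable
to the threshold groups. Threshold groups partition [0, 1] with half-open
intervals, boundaries assigned upward: Low [0, 0.30), Medium [0.30, 0.625),
High [0.625, 1] — chosen to honor the one strict inequality conventionally
printed for the High group ("> 62.5%"). The High-group subcluster split is
k-means with k = 2 restricted to High members in the same PC space (an
embedding such as UMAP is a visualization, not the finding, so none is
used); subcluster "A" is the larger-completeness side.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
sequences or reads — every in-scope computation consumes KO presence only.

* **Library**: 27 modules (18 amino-acid, 9 vitamin) of 2–10 steps; steps
  contain OR alternatives, `+` complexes and occasional optional
  components, and draw globally disjoint KO ids so satisfying a chosen
  step never leaks into another. Consolidated ids carry `_00`, variants
  `_01`.
* **Genomes**: per module, exactly `round(target × n_steps)` randomly
  chosen steps are satisfied (one full alternative each), making binary
  completeness exact by construction. Estimated genome size increases in
  the target with Gaussian noise (1 + 4·target Mbp, σ 0.3); quality
  metadata passes the high-quality gate with probability 0.9.
* **Communities**: one culture per entry of the size list (default 50
  singles, 25 pairs, 17 triples and nine 4–8-species cultures ≈ 50 genomes
  per complexity class). Completeness strata are tied to complexity —
  classes 1/2 draw targets of 0.80, class 3 of 0.45, >3 of 0.15 — which
  embeds the lower-completeness-in-complex-cultures effect. With the
  complementarity flag (default on), each ≥4-species culture partitions
  every module's steps across members (shuffled, dealt round-robin) so the
  union covers all steps: collective completeness is exactly 1.0. When the
  members' step quotas sum to less than the step count, quotas are bumped
  +1 round-robin until coverage is possible — the minimal deviation from
  the stratum target that keeps the mosaic property exact. A fraction
  (0.2) of single-species cultures reuse species from group cultures,
  producing the Both growth category.
* **Coverage**: species abundance is log-normal with a Gaussian-copula
  coupling (strength 0.7) *against* a blended rank score of genome size and
  completeness target, and detection probability falls with the same
  score — so small, streamlined, biosynthetically dependent genomes come
  out more abundant and more prevalent, as the analysis expects to detect.
  Coverage is abundance × per-sample mean coverage, so the relative
  abundance computation inverts the construction exactly. Coupling 0 is the
  null control.

What the generator does **not** emulate: assembly/binning noise and chimeric
bins, MDA amplification bias, shared KOs between pathways (real pathways
overlap; the disjoint-KO choice isolates the evaluator from leakage but
understates cross-module correlation), taxonomic covariance beyond a
cosmetic phylum label, and compositionality of real coverage data. Passing
end-to-end tests therefore demonstrates that the pipeline recovers effects
of the stated kinds at realistic sizes — not that real Baltic-Sea-style
data would show them.

## Problem sizes and determinism

Default analysis sizes — ~200 species (≈ 50 genomes per complexity class),
27 modules, 20 samples, 100 rarefaction permutations, 2,000 null
simulations for calibration — are chosen so every effect is detected with
wide margin while the whole suite runs in well under a minute of compute.
Every stochastic step takes an explicit seed (default 1) through
`numpy.random.default_rng`; identical seeds give byte-identical outputs,
including written fixture and pipeline files.

## Known limitations

* The Wilcoxon exact path enumerates C(n₁+n₂, n₁) assignments and is
  limited to n ≤ 8 per group; above that the normal approximation is used.
* `accumulation_curve(method="enumerate")` is capped at 9 cultures (9!
  orderings).
* The module grammar covers the operator set used by biosynthesis module
  collections (`,`, `+`, `-`, `--`, parentheses, spaces); it does not
  implement KEGG's rare directionality annotations.
* Threshold-group boundaries are conventions at exactly 0.30 and 0.625;
  data falling on a boundary is assigned upward.
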