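# Methods

## Model

The Gut Microbiome Health Index (GMHI) classifies a stool-metagenome
sample as healthy or nonhealthy from the balance of two species sets:
health-prevalent species `M_H` and health-scarce species `M_N`. The
per-sample statistic is

    h = log10( (psi_H + eps) / (psi_N + eps) )

with collective abundances

    psi_M = (R_M / |M|') * sum_{j in M, present} |n_j ln n_j|

`R_M` is the within-set richness (species at relative abundance
≥ presence threshold), and the sum is the Shannon-style weighted
geometric-mean term over the *present* set members; absent members
contribute nothing. The `|n ln n|` weighting is what makes the geometric
mean appropriate for abundances spanning several orders of magnitude; a
species at proportion 1.0 contributes zero (ln 1 = 0), which is the
natural boundary of that weighting, not an error. Natural log inside
`psi`, base-10 for `h`.

### Effective set sizes

Dividing by the raw cardinality `|M|` biases `h` when the two sets have
very different sizes, because full richness is rarely attained. The
effective size `|M|'` substitutes what extreme samples actually attain:
all healthy and nonhealthy samples are ranked by `R_{M_N}` ascending,
then `R_{M_H}` descending (a stable two-key sort; residual ties keep
input order). `|M_H|'` is the median `R_{M_H}` of the top `k_H` samples,
`|M_N|'` the median `R_{M_N}` of the bottom `k_N`, where `k` is the
closest integer to 1% of the respective group (half rounds away from
zero; floored at 1 so tiny cohorts remain usable). For group sizes 2636
and 1711 this yields k = 26 and 17. If an extreme median is 0 the data
are too degenerate for the adjustment; the estimator raises, with an
explicit opt-in fallback to the cardinality.

### Signature discovery

Per species, prevalence within each group is the fraction of samples
where it is present (inclusive ≥ threshold). Species satisfying both
`p_H/p_N ≥ θ_f` and `p_H − p_N ≥ θ_d` enter `M_H`; the mirrored
criteria give `M_N`. With `θ_d > 0` the sets are provably disjoint. A
fold change with zero denominator and positive numerator is +inf (it
passes any finite `θ_f` — the limiting behaviour of the criterion);
0/0 makes a species ineligible. The threshold pair is selected by
maximizing balanced accuracy

    chi = [ P(h > 0 | healthy) + P(h < 0 | nonhealthy) ] / 2

over a grid; `h = 0` counts as incorrect for both groups. Cells whose
candidate sets are empty record chi as undefined rather than aborting.
Exact ties in chi are broken toward larger `θ_f`, then larger `θ_d`,
preferring the more parsimonious signature deterministically.

Cross-validation is stratified by group with seeded shuffling
(scikit-learn `StratifiedKFold`); the signature *and* the effective set
sizes are refitted on each training split only, since reusing
full-data set sizes would leak information and inflate chi.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| presence threshold | 1e-5 (proportion) | minimum relative abundance for "present", used in prevalence, richness R, and QC feature prevalence |
| pseudo-count eps | 1e-5 | added symmetrically to both psi terms so `h` is finite when one set is absent; 0 restores the literal ratio (then psi_N = 0 yields ±inf with a warning). Symmetric placement preserves the antisymmetry h → −h under set exchange |
| θ_f grid | 1.1 … 2.0 step 0.1 | candidate fold-change minimums (includes the published optimum 1.4) |
| θ_d grid | 0.025 … 0.20 step 0.025 | candidate difference minimums (includes 0.10) |
| max unclassified fraction | 0.05 | samples strictly above are removed |
| min feature prevalence | 0.01 | features present in fewer than 1% of samples are removed |
| BMI cuts | 18.5 / 25 / 30 | underweight / overweight / obese regrouping of nominally healthy subjects |

The exact grid used in the original optimization was never published;
the defaults above are this package's declared choice, config-driven,
and bracket the published optimum.

## Quality control

Filter order follows the data-processing narrative: (1) regroup
nominally healthy samples by BMI; (2) remove samples with > 5%
unclassified taxonomy; (3) per phenotype (≥ 4 samples, else skipped with
a warning), flag Bray–Curtis outliers against the feature-wise median
profile — the median "hypothetical sample" is used as-is, not
renormalized, since renormalizing would change every distance; fences
are 1.5×IQR beyond either quartile, quartiles by linear interpolation;
(4) remove viral-kingdom, unclassified, and rarely observed features
(each removal recorded under exactly one reason). After feature removal
rows are renormalized to sum 1 — the index's derivation assumes
per-sample proportions summing to 1 — switchable off for users who want
raw subcomposition values. Prevalence in the rare-feature filter reuses
the 1e-5 presence threshold for consistency with discovery; a
"detected at any positive abundance" mode is available.

## Packaged 50-species model

`load_packaged_signature()` returns the published signature (7
health-prevalent, 43 health-scarce species, discovered at θ_f = 1.4,
θ_d = 0.10) with its discovery prevalences attached as provenance and a
checksum guard on the data file. **The fitted effective set sizes of
this model were never published.** Scoring with the default
cardinality fallback is the literal unadjusted ratio and will differ
from size-adjusted scores; supply `size_h_eff`/`size_n_eff` estimated
from a comparable training cohort for the adjusted index. Species names
are stored as printed; a normalization map handles MetaPhlAn-style
`s__` forms including the composite
`Streptococcus mitis/oralis/pneumoniae`.

## Synthetic cohorts

The generator plants the exact structure discovery assumes: species are
present in a sample with a group-specific Bernoulli probability
(planted-healthy species: base + gap in the healthy group, base in the
nonhealthy; mirrored for planted-nonhealthy; background species: base
in both), present species draw log-normal abundances (location −7,
scale 1.5 on the log scale — producing the multi-order-of-magnitude
spread the geometric-mean term is designed for), and each sample is
closed to sum 1. Defaults: 500 samples per group, 100 species, 10
planted per direction, base prevalence 0.30, gap 0.25. Nonhealthy
samples are spread over 3 pseudo-phenotype labels so per-phenotype
operations are exercisable. These sizes keep the full suite under a few
seconds while giving the selection rule ~3 SE of separation per planted
species.

What the generator deliberately omits: inter-species correlation and
phylogenetic structure, study/batch effects, compositional dependence
between presence and abundance, and realistic phenotype-specific
effect heterogeneity. Passing recovery tests therefore demonstrate the
*procedure* is correct under its own assumptions, not that real cohorts
will yield 95% precision/recall; on real data the attainable balanced
accuracy is far lower (the heterogeneity is the point of the
prevalence-based design).

Permutation null: applying the two-threshold selection to
label-permuted cohorts almost surely yields empty species sets (a 0.10
prevalence difference sits ~3.4 SE from zero at 500/group), leaving the
end-to-end score undefined. The null check therefore permutes the
evaluation labels against the true-label-trained scores — the standard
permutation null for a classifier's balanced accuracy — which must stay
within Monte-Carlo error of 0.5.

## Numerical conventions

- "Closest integer" for k: round half away from zero (both published
  k values, 26 and 17, are insensitive to the half rule).
- `h` antisymmetry under exchanging the sets holds to ~1e-15 relative
  (floating-point log of reciprocal ratios), and exactly when both psi
  are equal: `log10(1.0)` is exactly 0, so the equal-balance fixed
  point is exact, not approximate.
- Coverage80 uses an inclusive ≥ 0.80 cutoff with a 1e-12 relative
  slack so that e.g. eight species of abundance 0.1 reach 0.8 despite
  binary-float accumulation.
- Mann–Whitney switches to exact enumeration when the smaller group has
  ≤ 8 observations (desk-enumerable; matches brute-force label
  enumeration in tests); larger samples use the tie-corrected normal
  approximation.
- Shannon uses the natural log (configurable base).
- MetaPhlAn ingest auto-detects percent vs proportion scale by column
  sum (> 1.5 ⇒ percent) and divides by 100 without renormalizing, so a
  profile summing to 100 ± 0.1 yields proportions summing to 1 ± 1e-3.
- Rank extraction keeps rows whose *deepest* rank equals the requested
  rank, so species rows are never double counted through strain
  children.

## Known limitations

- The packaged model cannot reproduce the published cohort-scale
  accuracies here; those required thousands of external metagenomes.
  The packaged signature is shipped for scoring new samples, and its
  integrity (membership, thresholds, printed prevalences) is what the
  tests assert.
- Pathway or other generic feature tables are accepted by all
  operations unchanged, but no pathway-specific semantics exist.
- Read-level processing (quality trimming, host-read removal, the
  taxonomic profiler itself) is out of scope; inputs are profiles.
- BIOM and other binary formats are not supported; I/O is TSV.
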