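# Methods

## Similarity construction

The ontology is a DAG of terms with child → parent edges, multiple
parents allowed, and a designated set of top-level headings (disease
areas). Information content uses natural logarithms: the base cancels in
Lin, and in Resnik it only changes the scale, which the rescaling
multiplier absorbs. A term's probability is its cumulative annotation
count (itself plus all descendants, each counted once regardless of how
many paths reach it) over the corpus total.

By default every term's direct count receives Laplace add-one smoothing
(`smooth=False` disables it). This guarantees a defined IC for every
term, so the similarity matrix covers the whole vocabulary; without
smoothing, terms with zero cumulative count are excluded from the IC map
and similarity involving them is undefined.

The combined score follows a fixed recipe: both scores are clamped below
at 0; the multiplier `m` is the zero-intercept least-squares slope of Lin
on Resnik over all term pairs (upper triangle, diagonal included),
`m = Σ(lin·resnik)/Σ(resnik²)`; rescaled Resnik is `min(1, m·resnik)`;
the combined score averages the two. The published construction does not
state the regression's direction or intercept handling, so this is a
design choice of the package: regressing Lin (already in [0, 1]) on
Resnik with no intercept is the smallest transformation that puts both
scores on a shared slope-1, [0, 1] scale. Degenerate corpora in which
every Resnik value is 0 are rejected with an instruction to enrich the
corpus.

Two 0/0 conventions: `Lin(root, root) = 1` (self-similarity), while any
other zero-IC pair scores 0; term pairs in disjoint trees (no common
ancestor) score 0. A term below several top-level headings belongs to
every one of them, and per-area analyses count its pairs in each area.

## Pair universe and evidence

The universe is the cross product of retained drugs (≥ 1 human target,
≥ 1 approved indication; violators are dropped with a logged count) with
the distinct SE terms appearing anywhere in the SE table — not the whole
ontology vocabulary, matching how label corpora are actually tabulated.
`best_assoc_sim` is the maximum similarity between the SE and any trait
associated to any target of the drug; `best_indic_sim` the maximum over
approved indications. Both are 0 when no candidate exists.

The evidence flag applies the confounder rule per association, before
the maximum: an association whose trait is ≥ `theta_indic` (default 0.9)
similar to one of the drug's indications is disqualified, and the flag
requires the best *qualified* similarity to reach `theta_assoc` (default
0.9). Both thresholds are inclusive. This ordering matters: a trait can
match the SE perfectly yet be disqualified because it also matches the
indication, leaving the pair evidence-free even though the pair itself
survives the similar-indication removal.

Genetic insight is a property of terms, not pairs: a trait qualifies
with ≥ 1 distinct OMIM/IntOGen gene or ≥ 3 GWAS hits (Open Targets
Genetics, PICCOLO) at distinct loci, a locus being (chromosome, position
rounded — not floored — to the nearest megabase). A term has insight if
it or any trait with similarity ≥ 0.8 qualifies. Gene-burden evidence
(Genebass) has no locus and confers no insight by default; the source
sets are configurable. Both filters commute, and each is monotone:
raising `theta_indic` removes fewer pairs, raising `theta_assoc` yields
fewer evidence flags, and adding associations never removes insight.

## Statistics

`fisher_or` is implemented in-package as a vectorized noncentral
hypergeometric engine: the two-sided p sums the probability of all
tables (fixed margins) no more probable than the observed one (with the
customary 1 + 1e-7 tie tolerance); the odds ratio is the conditional MLE
obtained by solving `E_ψ[a] = a`; the CI inverts the conditional tail
probabilities at α/2 per side. These are the conventions of R's
`fisher.test`, which this field's analyses report. Root-finding is
safeguarded Newton on log ψ with bracket fallback (40 iterations,
convergence ~1e-11 on log ψ), batched over tables so that exhaustive
verification against a brute-force enumeration oracle — and against
scipy's independent implementation — is cheap. Zero-cell tables yield OR
0 or +∞ with the corresponding one-sided CI bound; tables with an empty
margin are errors; single-point supports return OR NaN.

Sensitivity sweeps re-threshold the stored qualified similarities (for
`theta_assoc`) or recompute disqualification and removal per grid point
(for `theta_indic`, which affects both). Grid points whose 2×2 table is
degenerate report counts with NaN statistics.

Logit models (`observed ~ evidence * covariate` on the universe;
`evidence ~ covariate` on observed pairs for modifiers that only exist
when an SE is observed) are binomial GLMs fitted by IRLS via
statsmodels. Rank-deficient designs are refused, and complete separation
aborts the unpenalized fit with a clear error. Frequency words are
handled either as numeric ranks (single linear term) or as ordered
factors with orthogonal polynomial contrasts (linear plus higher-order
terms); the vocabulary and its order are configuration, since published
orderings come from external human-perception studies.

The cross-area analysis reports the Mantel–Haenszel pooled OR, the CMH
association test, and a Breslow–Day homogeneity test with Tarone
correction. The CMH statistic proper tests common association rather
than heterogeneity, and published wording often conflates the two, so
both tests are always emitted.

The per-(target, SE) screen uses the drug as the unit: drugs with and
without the target crossed with drugs reporting and not reporting the
SE. Targets carried by a single drug (or by all drugs) are structurally
untestable and reported as such. BH adjustment runs over all tested
combinations; enrichment requires OR ≥ 2 and FDR < 0.05.

PPV and NPV are always direct counts (observed-with-evidence over
evidence; unobserved-without over without): no odds-ratio identity is
assumed, since the reported OR is a conditional MLE.

## Synthetic data

The generator emulates the joined structure of a label-corpus study:
a layered random DAG (default 300 terms, 12 top-level headings, depth 5,
1–2 parents per term), a long-tailed lognormal annotation corpus, 200
genes with ~3 associations each drawn from a five-source mix (25% OMIM,
35% Open Targets Genetics, 15% PICCOLO, 15% Genebass, 10% IntOGen,
GWAS-type sources with uniform random loci), and 150 drugs with 1–3
targets and 1–3 indications. SE observation follows

    logit P(observed) = α + β·E + γ·I

with `E` the qualified-evidence indicator and `I` the
indication-similar indicator, both defined by the package's own combined
similarity at the 0.9 thresholds — the generator and the pipeline mean
the same thing by "similar". Planting on the *qualified* indicator (the
estimand the evidence flag targets) is deliberate: it makes the
filtered-universe Fisher OR a direct estimate of `exp(β)`, so estimator
calibration can be tested without an estimand mismatch. β defaults to
ln 2 (the headline-scale effect), γ to ln 3 (nontrivial confounding by
indication), and α is solved by bisection so the realized marginal base
rate hits its 5.4% target.

Modifiers are sampled for observed pairs only: a latent Beta(0.8, 6)
frequency, tilted upward when evidence is present (so a
frequency–evidence trend exists to recover), reported numerically for
45% of records and as one of five ordered words for 50%; a placebo flag
for 60%; and a per-SE severity rank coupled to drug specificity with a
negative slope (−0.5 on log counts), assigned to 75% of SE terms — the
rest form the explicit "unassigned" bin. A small indication-support
table marks ~15% of drugs as having genetic support for an indication.

The truth record stores every planted parameter and the per-pair latent
flags, enabling exact confusion accounting and replicate-based recovery:
`replicate_enrichment` fixes the design and redraws only the observation
Bernoullis, which is what makes 200-replicate calibration runs take
seconds.

What the generator does *not* emulate: real MeSH topology and term
co-occurrence, the empirical SIDER frequency spectrum, drug-class
structure (correlated targets and shared off-target liabilities), and
any off-target biology. Passing tests therefore establish that the
pipeline's statistics are correct and calibrated for the stated model —
not that real label data satisfy that model.

## Problem sizes and defaults

Default desk scale is 150 drugs × ~287 SE terms ≈ 43,000 pairs, which
generates in well under a second. Calibration runs use 175 drugs
(~50,000 pairs) and 200 observation replicates; the false-discovery
check uses five smaller universes (60 drugs, 150 terms) under a global
null (β = γ = 0). Exhaustive Fisher verification covers every 2×2 table
with positive margins and total n ≤ 60 (628,055 tables; p to 1e-10, CI
endpoints to 1e-6 against the enumeration oracle).

## Known limitations

* The similarity multiplier depends on the corpus; two ontologies with
  the same topology but different annotation tails get different
  combined scales. Thresholds (0.8, 0.9) are meaningful relative to a
  fixed similarity construction, as in the source analyses.
* Self-similarity of shallow terms is below 1 (Lin is 1 but rescaled
  Resnik is small), so a generic term may fail to be "similar" even to
  itself at 0.9. This mirrors the intended behavior — matches on
  uninformative terms should not count — but users supplying external
  matrices should be aware of it.
* The conditional-MLE OR is NaN for single-point supports and the CMH /
  Breslow–Day tests require ≥ 2 non-degenerate strata; degenerate strata
  are dropped with that accounting exposed.
* `logit_conditional` treats modifier values as exchangeable across
  records of the same pair; the generator never produces conflicting
  modifiers for one (drug, SE), but real extracts can.
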