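# Methods

This note records the models, conventions and design choices behind
`protadapt`, in the spirit of a statistical software appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

An *annotated alignment* is a set of equal-length aligned protein
sequences over the 20 standard residues plus a gap state. Gap symbols
`-`, `.`, `~` are accepted on input and normalized internally to `-`;
substitution outputs render the indel state as `~`. Two optional
per-site annotations ride along as extra FASTA records keyed by header
suffix, so files stay valid FASTA for other tools:

* `>id|2D` — secondary structure over {H, E, C} (+ gap at gap sites);
* `>id|3D` — relative accessible surface area (RSA), either decimal
  values in [0, 1] (values in [0, 100] are divided by 100) or a digit
  string of deciles, digit *d* mapping to the bin midpoint
  (*d* + 0.5)/10 — the midpoint is unbiased within the bin.

Several alignments share one file, separated by `#`-comment lines that
carry the alignment identifiers. Phenotypic groups are ordinal codes
1..K taken from an ordered label list in a YAML config, which also maps
each sequence id to its group and optional taxonomic stratum; group
membership lives in configuration, never in code. Column coordinates in
all reports are 1-based and refer to the original alignment.

### Structural site filtering

A site filter restricts analyses to columns in a secondary-structure
class and/or exposure regime (surface: RSA ≥ threshold, default 0.25;
core: RSA < threshold). Sequences disagree at a column, so a consensus
rule decides: the column passes when, among sequences that are
*annotated and non-gap* there, the fraction satisfying the constraint
is ≥ `consensus_rule` (default 0.5, with ≥ so an exact half passes).
Columns with no evaluable sequence are dropped. Surviving original
column numbers are kept as metadata, so repeated filtering composes.

## Statistical kernels

**Mann-Kendall.** S = Σ_{i<j} sgn(x_j−x_i)·sgn(y_j−y_i). The variance
uses the standard Kendall tie treatment for ties in *both* variables —
the (n(n−1)(2n+5) − Σ_t t(t−1)(2t+5) − Σ_u u(u−1)(2u+5))/18 term plus
the two cross-product correction terms — because the ordinal group
codes guarantee heavy ties in x (the variance matches the one behind
`scipy.stats.kendalltau`'s asymptotic p, which the tests cross-check).
Z applies the continuity correction (S − sgn S)/√Var, standard for the
discrete S distribution; constant x or y yields S = 0, p = 1 with a
degenerate flag rather than an error, since such families occur in real
screens.

**Cumulative (blocked) Mann-Kendall.** Each alignment is one block;
S and the variances sum over blocks and a single corrected Z is formed
(the seasonal-Kendall construction). Blocks violating the
preconditions (fewer than 3 observations, constant x or y) are skipped
with a warning; zero contributing blocks is an error.

**Wilcoxon signed-rank** drops zero deltas, uses the exact
null distribution (computed by convolution) for n ≤ 25 when the
magnitudes are untied, and the tie-corrected normal approximation
otherwise; two-sided p is twice the smaller tail, capped at 1.

**ANOVA** for the 2-group composition design: one-way F, or additive
two-way (group + stratum, no interaction) with Type II sums of squares
for unbalanced data — Type II is the standard choice when no
interaction is modelled.

**Ordinal regression.** The parallelism model Y = β₀ + β₁X + Σ β_s I_s
is fit by OLS with treatment-coded stratum dummies; the baseline
stratum is the lexicographically first label (deterministic and
documented). Rank-deficient designs (x constant within strata that
exhaust the x variation) raise an error naming the offending strata.

**Mid-p Fisher exact.** The hypergeometric null with fixed margins is
enumerated. The two-sided p follows probability ordering: the sum of
tables strictly less probable than the observed one plus *half* the
probability of tables tied with it, ties detected at relative tolerance
1e−7 (the same convention scipy uses for the conventional two-sided
exact test, which therefore equals "tied mass counted in full" — the
identity mid-p = exact p − ½·P(tied) holds by construction). Doubling
of the one-sided p is deliberately not used. Tables with an empty
margin report p = 1 with a not-testable flag, never NaN, so
proteome-wide scans cannot abort on sparse cells.

**Pearson chi-square** (1 df, no Yates correction) is the large-count
alternative; discreteness is already handled by the mid-p route.

**Mantel–Haenszel** combines per-stratum 2×2 tables with the
continuity-corrected MH chi-square and the pooled odds-ratio estimator
Σ(a_k d_k/n_k)/Σ(b_k c_k/n_k) (delegated to statsmodels'
`StratifiedTable`).

**Benjamini–Yekutieli** step-up adjustment with the harmonic inflation
c(m) = Σ 1/k, valid under arbitrary dependence — appropriate because
the 20 per-residue tests (or 420 substitution-pair tests) are anything
but independent. NaN p-values (not-testable cells) are excluded from m
and propagated.

## Substitution counting

Cross-group pairing is greedy: repeatedly take the remaining pair with
the highest identity (identity = matches over columns where both
sequences are non-gap; ties broken lexicographically by id pair),
remove both sequences, stop when a group is exhausted — min(|M|,|P|)
disjoint pairs. Greedy can miss the assignment optimum; an optimal
(Hungarian) variant is exposed as a non-default option, but the greedy
procedure is the documented default because it mirrors the procedural
"pair the most similar, once each" rule. The within-group background
uses the same greedy procedure inside one group, giving ⌊n/2⌋ disjoint
pairs and a symmetric (direction-free) matrix.

Columns where both residues are gaps are skipped; a single gap counts
as a substitution to/from the indel state. The representative
SP-matrix accumulates over *all* ordered cross-group pairs and divides
by G_MP; it is intended for dependence-robust description, so its
fractional entries are kept, and if it is fed into the exact test the
counts are rounded half-to-even with a warning — the default test path
always uses the integer pairing counts. Pairs with an empty forward
row are reported not-testable rather than p = 1, distinguishing absence
of data from absence of effect.

Direction calls ("favoured" / "non-favoured", the up/down triangles in
the bubble plot) compare forward odds a·d vs background odds b·c; equal
odds give an undefined direction.

## Property scales

Five scales ship with the package, pinned to published values so
results are reproducible: Kyte–Doolittle hydropathy, Zamyatnin residue
volume, formal net side-chain charge at pH 7 (H treated as neutral),
Grantham polarity, and Vihinen flexibility. Users may supply a 20-line
`AA<TAB>value` file or AAindex1 records. Gaps carry no property value
and are excluded from the per-sequence mean. Per-family slopes are
OLS β₁ (matching the plotted regression model); significance always
comes from the rank-based cumulative Mann-Kendall test, which is
invariant under monotone rescaling of the property.

## Dependent sequences

The models assume independent sequences within each group and stratum.
When phylogenetic dependence is suspected, the `collapse_dependent`
mode averages values within each (group, stratum) cell first and treats
the means as representative observations, trading power for validity.

## Synthetic data generator

The generator emulates a comparative screen of orthologous families.
Per family, an ancestral sequence is drawn from a base composition
(SwissProt-like frequencies); each descendant resamples every site
independently with probability `divergence` from a group-specific
distribution constructed so the *marginal* composition of group g is
exactly base + (g−1)·shift — the shift mass is compensated
proportionally from unshifted residues, keeping a valid distribution
(infeasible shifts raise an error). Property slopes are injected as a
composition shift along the centered scale vector Δ = β₁(v−v̄)/Σ(v−v̄)²,
which makes the expected per-step change of the mean property exactly
β₁. Substitution bias converts residue x to y at ancestral-x sites at
a rate scaling linearly from a 0.05 baseline in group 1 to
`multiplier`×0.05 in the top group. Gaps are injected i.i.d. at 2% per
site; secondary structure comes from a sticky 3-state Markov chain and
RSA digits are i.i.d. deciles.

Defaults are the scale of the motivating study design: 65 families, 6
sequences each from 3 ordered groups, 150 aligned columns (the size of
a compact membrane-protein alignment), 30% per-site divergence
(orthologues at ~70% identity). Everything is deterministic given the
seed.

What the generator does **not** emulate: within-group phylogeny (sites
and sequences are conditionally independent given the ancestor),
alignment error, site-rate heterogeneity, or correlated structure
between annotation and residue content. Passing power/calibration
tests therefore demonstrate correctness of the statistics under the
models' own assumptions, not robustness to phylogenetic dependence —
that is what the collapsing mode and the representative matrix are for.

## Simulation studies and problem sizes

The bundled studies (also run by `scripts/acceptance.py`) use: 1000
null simulations of 50 families for type-I calibration of the
cumulative Mann-Kendall test (the rejection rate is compared to α=0.05
within 3 binomial standard errors); 200 simulations of 30 families with
a +0.05/step lysine shift for power; one 65-family set for slope
recovery (mean β̂₁ within 2 standard errors of the injected 0.05); and
100 simulations of 65 families with a 3× K→R bias for scan-ranking
behaviour. These sizes give stable rates while keeping a full run
around a minute on one CPU.

## Known limitations

* Greedy pairing is order-dependent through its tie-break; the optimal
  variant exists but changes counts only marginally in practice.
* The exact Wilcoxon branch requires untied magnitudes; tied data fall
  back to the approximation even at small n.
* The Mantel–Haenszel implementation is asymptotic; no exact
  conditional version is provided.
* Figures are deterministic in content but not guaranteed byte-stable
  across matplotlib versions (tables are byte-stable).
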