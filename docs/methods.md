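# Methods

## Scope and model of the data

The package re-implements, as a tested pipeline, the desk-side
computations of a case-control gut-microbiome study linking a bacterial
gene function — the ATP-dependent disaggregase chaperone ClpB (KEGG
ortholog K03695), whose E. coli form carries an epitope mimicking the
anorexigenic host peptide alpha-MSH — to host adiposity. Four analysis
stages are covered: functional read-count profiling of annotated
metagenomic ORFs, a molecular-mimicry screen of predicted protein
sequences against the epitope motif, O-PLS association between a
metabolite matrix and the gene-function response, and cohort-level
statistics. Upstream wet-lab and assembly steps (sequencing QC,
assembly, gene prediction, homology search, taxonomy) are out of scope;
the package consumes their tabular/FASTA output formats. Because the
study's raw data are not deposited, a first-class synthetic-data module
generates every input with planted ground truth, and all validation is
recovery- and calibration-based.

## Mimicry screen

**Alignment model.** Each ORF is aligned to the reference region around
the epitope by semi-global pairwise alignment: reference overhang at
the query's ends is free, all other gaps are affine-penalised. Scoring
is BLOSUM62 with gap open 11 / extend 1 (a length-k gap costs 11 + k,
the BLAST convention); a gap "opens" whenever the previous column is of
a different type. Traceback ties are resolved diagonal → up → left and
end-column ties keep the leftmost placement, so alignments are fully
deterministic. The original workflow ran a multiple aligner externally;
a deterministic internal pairwise aligner was chosen instead so that
tie-breaking is specifiable and the optimum can be verified against an
exhaustive-recursion oracle (and against Biopython's `PairwiseAligner`
configured for the same model).

**Windowing and identity.** The motif (default RWGKPV) is located by
exact substring search (first occurrence; an optional fuzzy mode takes
the best ungapped placement). The alignment is trimmed to the motif ±30
reference residues, clipped at the reference ends. Two identities are
reported per ORF because they answer different questions: *motif
identity* over the motif columns alone (denominator = all motif
columns; a gap in either row is a mismatch) and *window identity* over
the trimmed window (denominator = reference-residue columns; gaps in
the query count as mismatches). An ORF must place query residues in all
motif columns by default (`min_motif_cols`, configurable down to
partial coverage) or it is discarded with a reason code. Family
summaries report sequence counts, the number of sequences at exactly
100% motif identity, and mean window identity; the homology
distribution bins window identities into half-open bins with the last
bin closed.

**Degenerate inputs.** Empty ORF sets and non-standard residues are
rejected; a query aligned wholly outside the window yields a discard,
not an error.

## Functional profiling

Best annotation per ORF = minimal e-value, then maximal bitscore, then
lexicographically smallest KO. Reads are assigned to the ORF on their
contig covering ≥ 50% of the read's aligned length (1-based inclusive
coordinates, strand-agnostic); overlap ties go to the smaller ORF
start, then smaller ORF id. The ≥ 50% rule and the tie order are design
choices fixed to make boundary behaviour unambiguous. Counts are rolled
into a sample × annotation table; a KO contributes its full count to
*every* functional category it belongs to, so category totals may
exceed annotation totals. Relative abundance divides by the per-sample
total of annotated reads; the denominator choice (all annotated reads)
is a convention, and no attempt is made to match any particular
published "arbitrary units" scale. The low-abundance taxa filter keeps
a taxon with strictly more than 10 reads in at least two samples.

## Metabolome association

**PQN.** The reference spectrum is the feature-wise median over
samples; each sample is divided by the median of its feature-wise
quotients against the reference. Non-positive entries (and features
with non-positive reference) are excluded from the quotient but still
rescaled. PQN is exactly idempotent on dilution-only matrices (rows
that are scalar multiples of one spectrum) — the case it models — but
not on arbitrary matrices; tests assert exact idempotence only in the
dilution case.

**O-PLS.** With y centered and X unit-variance scaled (SD with
denominator n − 1; zero-variance features are an error), the fitter
iterates: w ∝ X'y (unit norm), t = Xw, p = X't/(t't), w_o ∝ p − (w'p)w
(unit norm), t_o = Xw_o, p_o = X't_o/(t_o't_o), X ← X − t_o p_o'.
Because t_o'y = 0 by construction, deflation leaves the predictive
weight vector unchanged, so w ⊥ w_o holds exactly and the columns of
T_o are pairwise orthogonal. The default is one orthogonal component
(configurable). With none, the model reduces to single-component PLS1
(verified against scikit-learn's PLSRegression).

**Validation.** Q²Y = 1 − PRESS/TSS from 7-fold cross-validation with
folds formed by a seeded shuffle; scaling/centering are re-estimated
inside each training fold, and orthogonal filtering is applied to test
rows before projection. The permutation test permutes y, recomputes
Q²Y, and uses the add-one estimator p = (1 + #{Q²_perm ≥ Q²_obs}) /
(n_perm + 1), so p can never be zero (minimum 1/1001 at the default
1000 permutations). Feature correlations are Pearson r against the
predictive scores t by default (optionally raw y), with t-distribution
p-values and Benjamini-Hochberg q-values; constant features are
reported as r = 0, p = 1 with a warning.

## Cohort statistics

Group comparisons dispatch from the data: chi-square without continuity
correction for categorical variables; for continuous variables,
Shapiro-Wilk per group at α = 0.05, then Levene (median-centered) at
α = 0.05 choosing Student vs Welch, otherwise two-sided Mann-Whitney U.
Groups with n < 3 skip normality testing and fall back to Mann-Whitney
with a warning. Summaries follow the dispatch: mean (SD) when
parametric, median [IQR] otherwise. Both α thresholds and the test
choices are conventions; the dispatch is a pure function of the data.

Partial "adjustment" is rank-based: x, y and covariates are
rank-transformed (average ranks), the ranked x and y are residualised
on the ranked covariates by least squares, and the residuals are
Pearson-correlated with n − 2 − k degrees of freedom (cross-checked
against pingouin's rank partial correlation). With no covariates this
is bit-identical to plain Spearman. Multiple regression is OLS with
optional standardized coefficients (z-scored response and predictors).
BH adjustment delegates to statsmodels' step-up implementation and is
verified against a literal transcription of the step-up formula.

## Synthetic data: what it emulates, and what it does not

The generators plant exactly the structures the pipeline is supposed to
recover. ORF populations copy the reference epitope window (motif ± 30
residues) with a chosen number of motif substitutions and an
independent per-residue flank match probability; substitutions always
change the residue, so motif identity is exactly (6 − mismatches)/6 and
mean window identity has an analytic binomial expectation. The toy
metagenome gives every real ORF a best hit to the target KO plus, with
probability 0.3, a strictly worse decoy hit (ties are never planted;
tie-breaking is tested with hand-built fixtures); decoy ORFs receive
reads but no hits. The metabolome is X = t p' + Σ t_o p_o' + E with
y = t + noise and t_o exactly orthogonalised against t by projection.
The cohort draws (function abundance, BMI) from a bivariate normal with
a planted correlation (default −0.35, echoing the magnitude of the
reported adiposity association), BMI ~ N(32, 8) spanning the ≥ 30
obesity threshold, and function abundance on the ~0.15 relative-
abundance scale.

Not emulated: nucleotide-level reads, sequencing error, quality scores,
host contamination, compositional count noise, metabolite
missingness/LOD effects, and correlated clinical covariates. Passing
recovery tests therefore demonstrates correctness of the computations
under the planted model, not robustness to every artefact of real
survey data.

## Problem sizes and numerical conventions

Default driver sizes were chosen as the smallest at which sampling
error is negligible relative to the asserted tolerances: 500 random
pairs for the alignment oracle; 40/30/10 ORFs across three families for
mimicry recovery (mean window identity asserted within 3 binomial
standard errors); 20 seeds for count conservation; n = 60 samples ×
40 features for O-PLS recovery (199 permutations for the headline p,
99 per replicate × 200 replicates for null calibration); 1000 random
vectors for the BH oracle; n = 500 for deconfounding; 2000 replicates
for dispatcher calibration; n = 131 subjects for the cohort, matching
the study design (55 + 76). Orthogonality invariants are asserted at
1e-8; identity comparisons at 1e-9; all stochastic checks are run under
fixed seeds, and every generator draws from a single named
`numpy.random.Generator`.

## Known limitations

* The aligner is O(nm) pure Python; it is intended for epitope-window
  regions (≲ 100 residues), not whole-proteome alignment.
* PQN assumes most features are not associated with the dilution
  factor; with very few features the median quotient is noisy.
* The O-PLS permutation p is bounded below by 1/(n_perm + 1); with the
  default 1000 permutations the smallest reportable p is ~0.001.
* The rank-residual partial correlation is one of several "adjusted
  Spearman" conventions; alternatives (e.g. Pearson on raw residuals)
  give slightly different values.
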