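# gutclpb

Analysis toolkit for linking a gut-bacterial gene function to host
phenotype. The motivating biology: the bacterial disaggregase chaperone
ClpB (KEGG ortholog **K03695**) carries, in *E. coli*, an epitope
mimicking the anorexigenic host peptide α-MSH (hexapeptide **RWGKPV**),
and the abundance of ClpB-like gene function in fecal shotgun
metagenomes is negatively associated with adiposity in humans. The
package implements the four computational stages such a study needs,
each exercisable end-to-end on synthetic data with planted ground
truth:

* **`gutclpb.profiling`** — functional read-count profiling: best
  homology annotation per ORF (e-value → bitscore → KO tie-break), read
  assignment to ORFs (≥ 50% overlap), sample × KO contingency tables
  with per-category roll-ups and relative abundances, and the
  low-abundance taxa filter (> 10 reads in ≥ 2 samples).
* **`gutclpb.mimicry`** (+ `gutclpb.alignment`) — molecular-mimicry
  screen: deterministic semi-global BLOSUM62 alignment (gap open 11 /
  extend 1) of each ORF to the reference epitope region, trimming to
  the motif ± 30 residues, percent identity over the motif columns and
  over the trimmed window, family-level summaries and homology
  distributions.
* **`gutclpb.opls`** — metabolite association: probabilistic quotient
  normalization (PQN), unit-variance scaling, O-PLS with one predictive
  plus configurable orthogonal components, 7-fold cross-validated
  Q²Y = 1 − PRESS/TSS, permutation validation
  p = (1 + #{Q²ₚₑᵣₘ ≥ Q²ₒᵦₛ})/(n + 1), and BH-FDR-adjusted feature
  correlations.
* **`gutclpb.cohort`** — cohort statistics: group comparisons with
  data-driven test dispatch (χ² / Student / Welch / Mann-Whitney via
  Shapiro-Wilk and Levene), Spearman and covariate-adjusted rank
  partial correlations, OLS with standardized β, Benjamini-Hochberg
  adjustment.
* **`gutclpb.synthetic`** — generators for every input (reference
  protein, per-family ORF populations with controlled motif mismatches
  and flank identity, annotated toy metagenomes with decoy hits,
  latent-structure metabolomes, case-control cohorts), each returning
  its planted truth.

## Worked example

The numbered scripts under `analysis/` form the full pipeline; each
reads the previous step's outputs from `results/` and prints what it
found:

```sh
python analysis/01_simulate.py          # inputs + planted truth
python analysis/02_profile_functions.py # KO read-count tables
python analysis/03_mimicry_screen.py    # epitope screen + family summaries
python analysis/04_metabolome_opls.py   # PQN + O-PLS + permutations
python analysis/05_cohort_stats.py      # group tests + associations
```

Output of the mimicry step on the default simulation (five families
whose flank identities echo the 0.81–0.95 range typical of real
ClpB-like proteins):

```
169 ORFs cover the epitope, 0 discarded
na_Firmicutes: n=48, 100%-motif=48 (planted 48) [OK], mean window identity 85.13% ...
Rikenellaceae: n=40, 100%-motif=40 (planted 40) [OK], mean window identity 92.31% ...
Clostridiaceae: n=35, 100%-motif=35 (planted 35) [OK], mean window identity 83.16% ...
Prevotellaceae: n=26, 100%-motif=0 (planted 0) [OK], mean window identity 94.41% ...
Bacteroidaceae: n=20, 100%-motif=0 (planted 0) [OK], mean window identity 88.64% ...
```

Every family's count of perfect-motif sequences matches the planted
truth exactly; mean window identity tracks the planted flank identity
(diluted toward the motif's own identity over the 66-residue window).
The O-PLS step prints, for a planted single-component signal at
n = 60 × 40 features:

```
O-PLS (1 predictive + 1 orthogonal): R2Y=0.983, 7-fold Q2Y=0.981
permutation test (1000 permutations): p=0.000999
34/40 metabolites significant at q<0.05 against the predictive scores
```

i.e. near-perfect cross-validated prediction and the smallest p-value
the add-one permutation estimator can produce (1/1001). The cohort step
recovers the planted function/BMI association (r = −0.35) via Spearman
and as a standardized regression β.

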