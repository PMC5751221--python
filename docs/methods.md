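# Methods

`melcoev` detects inter-gene molecular coevolution driven by positive
selection on a fixed species phylogeny.  The pipeline has three scientific
layers — per-codon selection classification, pairwise coevolution scoring,
and gene-level integration — sitting on a shared phylogenetic likelihood
engine.  This note records the models, the estimators, the defaults and the
design decisions, and what the synthetic benchmarks do and do not show.

## Phylogenetic engine

Nucleotide likelihoods use HKY85 with empirical base frequencies and
Yang's equal-probability discrete-Gamma rate heterogeneity (4 categories,
category-mean rates, mean normalised to 1).  JC69 is the kappa = 1,
uniform-frequency special case.  All generators are scaled to one expected
substitution per site per unit time, so branch lengths are in substitutions
per site.  Site likelihoods come from Felsenstein pruning with per-node
rescaling (stable beyond 100 taxa); gaps and IUPAC ambiguity codes are
missing data (partial likelihood 1 on every compatible state).  The
likelihood is cross-checked in the test suite against R/phangorn's `pml`
(HKY and HKY+Gamma agree to printed precision) and against brute-force
enumeration over internal states on all trees with up to four leaves.

Branch lengths are estimated on the fixed species topology by coordinate
ascent: Brent's method on each branch in turn (bounds 1e-8 to 20), then on
kappa and the Gamma shape, cycling until the log-likelihood improves by
less than 1e-6.  The trace is non-decreasing by construction.  Under a
reversible model the two branches meeting at the root are only jointly
identifiable; downstream analyses use the unrooted tree, and the recovery
test compares that pair by its sum.  An alignment of identical sequences
returns all branches at the lower bound with a warning rather than an
error.  In simulation (10 taxa, 3,000 sites, kappa 2, alpha 0.5) branch
lengths above 0.05 are recovered within 16% relative error, kappa within
1% and alpha within 3%.

## Trimming and conservation

Before analysis each gene alignment is trimmed: columns with identity
exactly 1.0 and columns whose ambiguity fraction (non-ACGT, non-gap
symbols) exceeds 0.2 are removed, codon-wise (a codon is dropped when any
of its three columns qualifies) so the frame survives for the codon model.
Gaps are retained through trimming — they are missing data, not ambiguity.
A provenance table maps every trimmed column back to its original column
and codon, which the integration layer needs to decide codon membership.
Column identity is the frequency of the majority residue among informative
residues (gaps and ambiguity codes excluded from numerator and
denominator; a column with no informative residue has identity 0 and is
flagged).  The per-gene conservation report uses a strict cutoff: identity
> 0.95 marks a highly conserved position.  The trimming rule removes
*columns*, not windowed regions; the original procedure's region rule is
not published, and per-column removal is the declared choice here.

## Episodic selection (MEME-style)

Each codon site is fitted with an MG94-style codon model on HKY85
exchangeabilities: 61 sense codons (universal code), one-step codon changes
only, uniform codon frequencies, stop codons treated as missing.  The
generator is normalised so the neutral model (omega = 1) evolves at one
nucleotide substitution per site per unit time, making nucleotide-level
branch lengths directly usable.

The alternative model mixes two dN/dS classes per branch: independently on
every branch the site draws omega_minus <= 1 (weight p_minus) or
omega_plus >= 0 (weight 1 - p_minus).  Marginalising the independent
assignments gives a per-branch mixture transition matrix inside the
pruning recursion.  The null constrains omega_plus <= 1.  The LRT p-value
uses the boundary-corrected 50:50 chi2_0 : chi2_2 mixture; this differs
slightly from the mixture published with MEME and is the declared,
conservative convention here.  Benjamini–Hochberg controls the FDR across
a gene's testable sites (Storey's q-value with lambda = 0.5 is available
as an option).  Classification: *positive* when the positive test rejects
(q < 0.05) with fitted omega_plus > 1; otherwise *purifying* when a second
LRT (single-class omega <= 1 versus omega = 1, 50:50 chi2_0 : chi2_1)
rejects; otherwise *neutral* when the site shows at least one inferred
substitution (Fitch parsimony count, missing codons as wildcards);
otherwise *ambiguous*.  Sites with fewer than three usable codons are
ambiguous without fitting.  The minimum-substitution rule is this
package's proxy for "enough signal to classify" and is recorded in output
metadata.

Branches carrying an episode are attributed by empirical Bayes at the
fitted site parameters: the Bayes factor of a branch is the posterior over
prior odds of the omega_plus assignment, which reduces to the likelihood
ratio of forcing that branch into the plus versus the minus class.
Branches with BF > 1 are counted (strict inequality; BF is undefined when
the fitted weight is degenerate, and such sites contribute no branches).

Likelihood maximisation is a profile over a fixed grid shared by all
sites of a gene: omega in {0, 0.0625, 0.125, 0.25, 0.5, 0.75, 1, 1.5,
2.5, 4, 8, 16} and p_minus in 13 equal steps on [0, 1], evaluated with
batched pruning (one BLAS pass over all sites per grid combination).  The
null maximum is taken over the exact subset of the same grid with
omega_plus <= 1, so the LRT is non-negative by construction and the test
cannot be anti-conservative through optimiser asymmetry.  Grid profiling
trades a little power (the LRT is never overstated) for speed,
reproducibility, and exact nesting.

Benchmarks (conditions stated here are the package's study conditions):
on a 24-taxon tree with 0.4-substitution branches, neutral (omega = 1)
columns yield a positive-call rate of 0 out of 200 at q < 0.05, and for
sites detected positive, omega = 5 episodes planted on 30% of branches are
recovered with BF > 1 on 80–90% of their episode branches.  Branch lengths
matter: at 0.2 substitutions per branch, 10–30% of episode branches carry
no substitution at the tested codon and cannot be flagged by any method —
pooled recovery then caps near 72%.

## Coevolution scoring

A pair of nucleotide positions (one per gene) is modelled as a single
16-state Markov chain over dinucleotides.  The *profile* is a pair of
dinucleotide states differing at both positions; single-position changes
into a profile state occur at rate s, all other single-position changes at
rate d, double changes are forbidden, and the root distribution is uniform
over the 16 states.  The profile is chosen per pair as the two most
frequent observed dinucleotide states that differ at both positions (ties
broken lexicographically); pairs with no such state pair are infeasible
and keep a -inf score, never counting as coevolving.

The null is independent evolution of the two sites under unit-rate JC69
with branch lengths fixed from the concatenated two-gene alignment: zero
free parameters (k_indep = 0), against k_coev = 2 for (s, d).  Support is

    delta_AIC = AIC_indep - AIC_coev = 2 (lnL_coev - lnL_indep) - 4,

so larger values support coevolution.  The central correctness oracle is
the reduction identity: at s = d = 1/3 the 16-state chain factorises into
two unit-rate JC69 sites, and the log-likelihoods agree to better than
1e-12 on random pairs, trees and missing-data patterns.

(s, d) are profiled on a fixed logarithmic grid.  Writing Q = d (rho A + B)
with rho = s/d shows the eigensystem depends only on rho, and every
profile is a per-position nucleotide relabelling of the canonical {AA, CC},
so one family of eigensystems (31 rho values, 2^-6..2^9) x (27 d values,
2^-9..2^4) serves every pair on a tree.  Transition matrices are
precomputed once per tree and the scan runs as batched single-precision
matrix products with per-node rescaling (the exact per-pair evaluator
stays in double precision; grid and exact values agree to ~1e-6).  A full
200-site calibration (19,900 pairs) takes about a minute on one core.

Significance is calibrated by simulation, per gene pair: one 200-site
alignment is simulated under the independent JC69 model on the pair's
tree, delta_AIC is computed for all unordered site pairs with the same
grid estimator, and the empirical 90th/95th/97.5th percentiles of that
sample become the thresholds.  Percentiles are taken over the full sample
with infeasible pairs retained as -inf, so by construction a nominal
fraction of all null pairs exceeds each threshold.  Because estimator bias
(grid profiling, fixed null rate) affects the calibration sample and the
data identically, the thresholds remain internally consistent — verified
by held-out null exceedance within three binomial standard deviations of
10/5/2.5% (held-out pairs are drawn column-disjoint so their indicators
are effectively independent).  The calibration sample size is a
Monte-Carlo choice only; a subsample option exists for quick runs.

Power, under the study conditions (30 taxa, 0.1-substitution branches):
planted pairs at the generator default (s, d) = (10, 1) are detected at
the 95th-percentile threshold in ~98% of cases, and detection is monotone
non-decreasing in s/d over {1, 3, 10} at fixed d = 1/3 (where s/d = 1 is
exactly the simulated null).

## Integration

A *response pair* is a coevolving pair (delta_AIC above threshold) with at
least one nucleotide inside a positively selected codon; it is attributed
to the gene carrying the selected codon (possibly both).  Codon membership
uses the trimming provenance (codon = floor((original column - frame
offset)/3)).  Per gene the pipeline reports: response pairs per partner
gene (row sums equal the gene's pair total), distinct selected sites and
their percentage of the trimmed length (one decimal), and the percentage
of tree branches where an episode branch of a selected codon (BF > 1)
coincides with an inferred substitution at the partner site of one of its
response pairs.  Partner-site substitutions come from marginal ancestral
reconstruction under the fitted pair model (up-down algorithm; a branch
carries a substitution when the marginally most probable state changes at
the partner position).  Published descriptions of this branch statistic
leave its operational definition open; this rule is one defensible
implementation and is labelled as such.  Branch overlap is computed on the shared species tree
with branch lengths averaged over the per-gene fits.

Enrichment labels compare each gene against the pooled rest of the system
with a 2x2 Pearson chi-square (no continuity correction): counts are
response pairs (exposure: scanned inter-molecular pairs involving the
gene) or distinct sites (exposure: trimmed length).  When an expected cell
drops below 1 the test falls back to Fisher's exact test.  Labels
('above'/'below'/'ns') follow BH correction at 0.05.  The contingency
construction (which exposure pairs with which count) is a declared choice
of this package.

The influence ordination is a PCA of the correlation matrix of three
per-gene metrics (response pairs, distinct sites, branch percentage):
components with eigenvalue > 1 are retained, and signs are fixed so PC1's
loadings are non-negative, making PC1 a coevolutionary-influence axis.

## Synthetic data

The generator emulates the statistical structure of a multi-gene system on
one shared species tree: a pure-birth ultrametric tree scaled to a target
height; per-gene conservation differences via branch-length scalers;
background codons with omega drawn from {0.1, 1} at the study-like
composition (2.6% positive, 6.7% neutral, the rest purifying); planted
positive codons with their own episode branch subsets (default omega_plus
= 5 on 30% of branches); and planted coevolving pairs simulated under the
16-state chain and spliced into third codon positions of both genes.
Host codons of planted pairs evolve neutrally so conserved-codon trimming
cannot silently delete the planted signal and the two signal types stay
separable.  The planted pair default (s, d) = (10, 1) represents strongly
coupled, fast-evolving sites — each position substitutes at roughly the
rate of a fast neutral site; weaker coupling degrades detection smoothly
(the monotonicity benchmark).  A truth ledger (JSON) records every planted
effect and is the single source of truth for end-to-end tests.

The `melanocortin_fixture` builds a deterministic 10-gene scenario with
the study's gene names and trimmed lengths (396–2,256 nt), 30 taxa at desk
scale (a 138-taxon variant exists for long runs), slower ligand/convertase
genes and faster antagonists.

What the synthetic benchmarks do not show: real coding alignments have
codon-position rate structure, indels, alignment error, lineage-specific
composition and incomplete taxon overlap between genes; none of these are
simulated.  Passing tests demonstrate the estimators recover what the
models define on clean data, not that the biological conclusions of any
particular study are robust to those violations.

## Problem sizes and determinism

Default test and acceptance sizes are desk scale: 30-taxon trees for
coevolution (200-site null, 19,900 calibration pairs), 24 taxa for
selection (200 neutral and 60 planted columns), three-gene end-to-end
systems.  All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the pipeline writes per-stage checkpoints
keyed by a configuration hash, and identical configurations produce
byte-identical outputs.
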