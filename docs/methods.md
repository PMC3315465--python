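# Methods

This note documents the models implemented in `codonbalance`, the
parameters that matter, the synthetic-data generators used to validate the
pipeline, and the numerical and design choices made where the procedure was
genuinely open.

## CST estimation

**Model.** In a snapshot of elongating ribosomes, the probability that a
codon occupies the A site is proportional to how often it is translated
times its selection time (the waiting time for the cognate ternary
complex). Let c_ij be the A-site count of codon i in gene j from footprint
data and C_ij the codon count from matched mRNA-Seq. The observed A-site
frequency is

    f_i = sum_j c_ij / sum_ij c_ij,

and the expected frequency under equal selection times, weighting each
gene's mRNA-Seq codons by its translational initiation rate R_j, is

    F_i = sum_j R_j C_ij / sum_ij R_j C_ij.

The relative selection time is CST_i = f_i / F_i. Because R_j is unknown,
the estimator iterates: starting from R_j = 1 for all genes, it computes
CSTs, then per gene the elongation rate e_j = L_j / sum_i D_ij CST_i
(L_j the gene length in codons, D_ij the codon composition of one mRNA
molecule), the ribosome density d_j = (footprint count)/(mRNA-Seq count)
per gene, and updates R_j = d_j * e_j (normalized to mean 1; the scale
cancels in F). Ten iterations are the default, with early stopping when the
maximum relative CST change drops below 1e-8; both the iteration count and
the convergence flag are reported. CSTs are relative and are rescaled so
the maximum defined value is 1.

D_ij is taken from the mRNA-Seq counts rescaled to sum to L_j per gene,
which is exact when coverage is uniform within genes (as in the generative
model); a measured composition matrix can be supplied instead. Codons with
F_i = 0 have undefined CST and are reported as missing; genes with all-zero
counts on either side are excluded with a warning; no pseudocounts are
used. When the input is so sparse that no codon has a positive estimate,
the estimator warns and returns the unscaled vector rather than failing.

**A-site extraction.** Footprint reads are used only if they are exactly
28 nt with no ambiguous bases and lie fully inside the CDS; read positions
16–18 (1-based) are the A site, and the assignment is kept only when those
nucleotides fall in frame 0. CDS offsets are 0-based, read positions
1-based. Per-category drop counts and the in-frame fraction are reported.

**Properties.** The estimates are invariant to rescaling all footprint (or
all mRNA) counts; a uniform-occupancy input yields CST = 1 everywhere; on
generative-model data at depth 10^6 (61 codons, 200 genes) planted CSTs are
recovered with Spearman rho > 0.99 and planted initiation rates with
Pearson r > 0.99 up to scale; and the fixed point is independent of the
initial R (uniform, CAI-proportional, and inverse-CAI starts agree to
machine precision after convergence).

**Bootstrap.** Standard errors come from resampling genes with replacement
(default 1000 replicates) and re-running the estimator. Each replicate is
normalized to unit geometric mean over its defined codons before the
per-codon standard deviation is taken; rescaling each replicate by its own
maximum would couple every SE to a single codon's noise. The SDs are then
mapped onto the max = 1 scale of the point estimate (a single constant
factor). Codons undefined in a replicate contribute nothing there, and the
number of informative replicates per codon is reported.

## Codon-usage statistics

RSCU_i is the count of codon i in a reference set of highly expressed genes
divided by the mean count of its synonymous family; RSCU' = RSCU/n sums to
1 within each family. The reference set is chosen by protein abundance
(top 200 by default), dropping genes without mRNA data or with mRNA below
4x the genomic mean (default 2.7 mRNA/cell). Preferred codon = highest
RSCU' per family; exact ties break lexicographically and are flagged. CAI
is the geometric mean over codon positions of RSCU divided by the family
maximum, excluding Met/Trp positions; positions whose codon has undefined
(or zero) reference RSCU are excluded by default, or can be made fatal.

Transcriptomic usage weights each gene's codon counts by mRNA copies per
cell; unweighted counting gives genomic usage. (mRNA-copy weighting is the
natural operationalization of "transcriptomic" usage and is the package's
documented convention.)

**D_ncu.** For each multi-codon amino acid i present in a query gene, the
within-family Euclidean distance between the gene's codon fractions Y_ij
and the host's X_ij is normalized by its maximum sqrt(2):

    D_i = sqrt( sum_j (Y_ij - X_ij)^2 / 2 )  in [0, 1],

and D_ncu = prod_i D_i^(m_i/l), with m_i the count of amino acid i and l
the protein length excluding Met and Trp. The normalization guarantees the
documented [0, 1] range for any family size. If any D_i = 0 the geometric
mean is 0; no epsilon is added, and a warning lists the zero families. The
host usage should exclude the query gene itself; at genome scale the
difference is negligible.

## Balance rules and their tests

Under ternary-complex shortage the local concentration of tRNA i scales as
q_i/p_i, so the expected selection time is t = sum p_i^2/q_i, minimized at
p = q (value 1 in units of the kinetic constant). The package verifies the
optimum numerically (SLSQP over the simplex from a uniform start) rather
than trusting the algebra. The alternative optima without shortage are the
square rule (p proportional to q^2, renormalized) and the truncation rule
(exclusive use of the codon with the most abundant tRNA; ties break
lexicographically with a flag).

Monte-Carlo nulls draw each family's usage flat on its simplex (normalized
iid exponentials, equivalent to a symmetric Dirichlet) — the natural
reading of "uniform with the sum-to-one constraint". The test statistic is
the SUM of per-family distances to the rule's prediction (per-family
distances and P-values are also emitted; the aggregation across families is
a package choice). P = fraction of null replicates with a *smaller*
statistic, so small P means closer-than-chance agreement. Both directions
are available: random codon usage against fixed predictions, or fixed
observed usage against predictions from random tRNA fractions. Default
10^6 replicates, seedable, overridable for speed. Calibration: on data
drawn from the null the P-values are uniform (checked by KS at 10^3 draws x
10^4 replicates).

Likelihood comparisons treat (possibly real-valued, expression-weighted)
family counts as multinomial under each rule's predicted frequencies, with
log-gamma generalized coefficients; counts are rescaled to a fixed
effective total (default 10^4) so the ratio's magnitude does not depend on
arbitrary count units — consequently only signs and orderings of log10
ratios are comparable across analyses, not magnitudes. A rule placing zero
frequency on an observed codon has likelihood zero (the truncation rule
always does, off its modal codon), encoded as an infinite log ratio.

Synonymous codons read by the same tRNA species should be merged (via the
codon→tRNA assignment) before rule testing, since their relative usage
cannot affect tRNA demand. The assignment is an input table; the built-in
wobble-rule generator is labelled approximate and organism-specific
best-match tables are preferred.

## Evolutionary simulation

A haploid asexual Wright–Fisher population. Each individual carries ten
genes of 12 codons, all encoding one amino acid with four synonymous
codons read by four tRNA species at fixed relative concentrations 1:2:4:8;
gene expression levels are 2^0..2^9 (mRNA = protein). The selection time
of codon k is its total translational usage divided by its tRNA
concentration, so the generation time is T = sum_k usage_k^2 / trna_k with
usage_k = sum_g expr_g n_gk. Fitness is 1/T when selection is on (any
monotone decreasing map preserves the ranking; an exponential map is
provided), uniform when off. Each offspring picks a parent with
probability proportional to fitness and receives Poisson(1) synonymous
mutations per genome (deterministic-1 mode available), each changing a
uniformly chosen codon position to one of the other three codons
uniformly. Populations start from exactly equal usage (3 of each codon per
gene). Per-gene codon usage bias is summarized as sum_k (p_k - 1/4)^2 — a
package-defined surrogate, zero at uniform usage and 3/4 at exclusive use.

Full-scale conditions are N = 10^4, 500 generations, 1000 replicates; the
package's scaled-down conditions for routine runs are N = 500, 200
generations, 100 replicates.

**Endpoint behavior (known limitation).** With selection on, usage moves
toward the proportional rule in the correct order, the codon of the most
abundant tRNA rises most and fastest in the most highly expressed gene,
and bias grows with expression among the effectively selected genes; with
selection off, fractions stay at 1/4 and bias is unrelated to expression.
However, the *exact* proportional endpoint (1,2,4,8)/15 is not reached:
the population settles at a mutation–selection balance near
(0.11, 0.17, 0.27, 0.45) in translation-weighted fractions. The
per-position mutation rate implied by one change per genome per generation
(1/120 per position) is large relative to the selection differentials
(|dT|/T is ~1e-2 for the top gene and far below 1/N for the bottom genes),
so the extreme per-gene compositions that an exactly proportional
aggregate requires cannot be maintained. This balance is not a finite-size
artifact: the same equilibrium holds at N = 10^4 and at 1000 generations.
Relatedly, the expected usage bias of the bottom ~5 genes is equal (they
are selectively neutral at these population sizes), so the rank
correlation of mean bias with expression across all ten genes plateaus
around 0.6–0.8 rather than 1. The corresponding strict endpoint assertions
in the acceptance suite document this honestly and fail; the qualitative
dynamics are asserted (and pass) in the unit suite.

## Synthetic data

The profiling generator inverts the estimator's model: footprint sampling
weight for codon position (j, c) is mRNA_j * R_j * CST(codon at c), and
mRNA-Seq weight is mRNA_j, uniform within genes; sampling is multinomial
at the requested depth (a gamma overdispersion knob adds
negative-binomial-like noise for robustness checks, off by default to match
the estimator's implicit model). Reads are emitted as 28-nt placements
whose positions 16–18 cover the sampled codon; only codons with full read
context (indices 5..L-5) are sampled, and the direct-counts path is
bit-identical to reducing the emitted placements under the same seed. Gene
sequences draw amino acids uniformly (or from given frequencies) and
codons from per-family usage vectors; mRNA abundances are log-normal with
mean 2.7 mRNA/cell (a rapidly growing culture's genomic average) and
log-SD 1.2; protein abundance is mRNA times log-normal noise.

The alignment generator labels each position conserved with a stated
probability (optionally excluded, as a gap) and draws the synonymous codon
from the family's base usage multiplied by per-codon accuracy weights at
conserved positions, so each codon's planted conserved/non-conserved odds
ratio is available in closed form.

What the generators deliberately do not emulate: sequence-composition
library biases (they cancel between matched footprint and mRNA-Seq
libraries), ribosome traffic jams and 5' ramps, positional coverage decay,
and real phylogenetic correlation structure in conservation labels.
Passing tests therefore demonstrate correctness of the estimators under
their own model assumptions, not robustness to every artifact of real
libraries.

## Accuracy odds ratios

For a focal codon, each gene contributes the 2x2 table
[[focal@conserved, other synonyms@conserved], [focal@non-conserved,
other synonyms@non-conserved]]; gap-aligned positions are excluded. The
Mantel–Haenszel common odds ratio is OR = sum(a_i d_i/n_i) /
sum(b_i c_i/n_i) with the 1-df chi-square test, no continuity correction;
a Haldane–Anscombe 0.5 is appropriate only for per-stratum display, never
inside the MH sums. Strata with an empty margin are counted but carry no
information. The most accurate codon per family (highest OR) is compared
with the preferred codon (highest RSCU'); per-codon deviation from OR = 1
is flagged at 5%, uncorrected. Conservation calls come from an upstream
pairwise alignment; the package does not align.

## Supply-budget arithmetic

tRNA molecules per ribosome = (tRNA fraction of RNA / tRNA length) /
(rRNA fraction / rRNA length per ribosome); with the yeast defaults
(0.15, 72 nt, 0.80, 5469 nt) this is 14.2, so at 32.6 codons/s each tRNA
is used 2.3 times per second (once per 0.44 s). Molar concentrations use
the fixed Avogadro value 6.02e23 so the printed 2–3-significant-figure
chain reproduces exactly; full-precision values are always returned
alongside the rounded report.

## Problem sizes and determinism

The validation suite uses 61 codons x 200 genes x 10^6 reads for
estimator recovery, 10^3 draws x 10^4 replicates for null calibration,
10^3 random families for the optimality check, 10^4 positions for planted
odds-ratio recovery, 10^4 gene/host pairs for the D_ncu contract, and
N = 500 x 200 generations x 100 replicates for the simulation — sizes at
which every Monte-Carlo tolerance above is comfortably resolved. All
randomized components accept explicit seeds; the simulation derives one
child generator per replicate from a master seed, so replicate sets are
reproducible regardless of recording options.
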