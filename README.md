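# codonbalance

Tools for analysing the balance between synonymous codon usage and cognate
tRNA concentrations, and its consequences for translational efficiency.

## The scientific problem

Eighteen of the twenty amino acids are encoded by two or more synonymous
codons, and genomes use those codons unequally. A long-standing view holds
that "preferred" codons are translated faster because their cognate tRNAs
are more abundant. Ribosome-profiling data allow a direct test: the
probability that a codon sits at the ribosomal A site in a snapshot of
elongating ribosomes is proportional to its *codon selection time* (CST) —
the waiting time for the cognate ternary complex (aminoacyl-tRNA +
elongation factor + GTP). Comparing observed A-site codon frequencies
(footprints) with their expectation from matched mRNA-Seq isolates the CSTs
from transcript abundance.

If available ternary complexes are scarce — as the cellular arithmetic of
tRNA, ribosome, and ternary-complex budgets suggests — then the codon usage
that minimizes the expected selection time

&nbsp;&nbsp;&nbsp;&nbsp;*t* = Σᵢ *pᵢ*² / *qᵢ*

(with *pᵢ* the relative usage of synonymous codon *i* and *qᵢ* the relative
concentration of its cognate tRNA) is the **proportional rule** *pᵢ = qᵢ*,
under which every synonymous codon is selected equally fast. This package
implements the full analysis around that idea, exercisable end to end on
synthetic data with planted ground truth. Intended users are computational
biologists studying codon usage, translation, and molecular evolution.

## What is implemented

* **CST estimation** (`codonbalance.cst_estimation`): reduction of 28-nt
  footprint reads (A site at read nucleotides 16–18) to in-frame A-site
  codon counts; the iterative estimator of relative CSTs, per-gene
  translational initiation rates *Rⱼ*, elongation rates *eⱼ*, and ribosome
  densities *dⱼ* (CSTᵢ = *fᵢ*/*Fᵢ* with *Fᵢ* the *R*-weighted mRNA-Seq codon
  frequency; *Rⱼ* = *dⱼ·eⱼ*; 10 iterations by default); gene-bootstrap
  standard errors; the per-read-position RSCU′ profile; and the
  Mantel–Haenszel preferred/unpreferred A-site ratio.
* **Codon-usage statistics** (`codonbalance.codon_metrics`): codon counting
  (genomic or mRNA-abundance-weighted), RSCU and RSCU′ from a
  highly-expressed reference set, CAI, usage distances and correlations, and
  the *D*ₙcᵤ index (distance to native codon usage, a weighted geometric
  mean over amino acids of normalized within-family Euclidean distances,
  bounded in [0, 1]).
* **Balance-rule tests** (`codonbalance.balance_tests`): predictions of the
  proportional, square (*pᵢ* ∝ *qᵢ*²), and truncation rules; expected
  selection time and its numeric minimization over the simplex; Monte-Carlo
  null tests (flat-Dirichlet sampling, both directions) with empirical
  *P*-values; multinomial likelihood ratios between rules; the
  tRNA-availability/CST permutation test; and the per-amino-acid sign test.
* **Evolutionary simulation** (`codonbalance.evo_sim`): Wright–Fisher
  evolution of synonymous codon usage in a haploid asexual population (ten
  genes at expression 2⁰…2⁹, four synonymous codons with tRNA concentrations
  1:2:4:8, one synonymous mutation per genome per generation, fitness ∝ 1/T
  with T the total translation time).
* **Accuracy odds ratios** (`codonbalance.accuracy_odds`): per-gene 2×2
  tables of focal-codon use at conserved vs non-conserved amino acid
  positions, combined by the Mantel–Haenszel procedure; comparison of each
  family's most "accurate" codon with its preferred (highest-RSCU′) codon.
* **Supply-budget arithmetic** (`codonbalance.supply_budget`): tRNA per
  ribosome from bulk RNA composition, tRNA turnover, molar concentrations,
  and ternary-complex scarcity fractions.
* **Synthetic data** (`codonbalance.synthetic_data`): generators for genes,
  profiling reads/counts (footprint sampling weight ∝ mRNA × *R* × CST), and
  conservation-labelled alignments, all with planted, closed-form ground
  truth.
* **I/O and CLI** (`codonbalance.io`, `codonbalance.cli`): FASTA CDS and TSV
  readers/writers and the `codonbalance` command with subcommands
  `estimate-cst`, `balance-test`, `dncu`, `simulate-evolution`,
  `accuracy-odds`, `supply-calc`, `synth`, and `run`.

## Worked example

Estimate CSTs from synthetic profiling data with known truth:

```sh
codonbalance synth profiling --out demo --seed 1 --n-genes 200 \
    --footprint-depth 1000000 --mrna-depth 1000000
codonbalance estimate-cst --counts demo/counts.tsv --cds demo/genes.fasta \
    --expression demo/expression.tsv --out-prefix demo/cst
```

which logs

```
[codonbalance] 200 genes, 5 iterations (converged=True), 0.1s
```

and writes `demo/cst.codons.tsv` (codon, amino acid, relative CST with the
maximum rescaled to 1, bootstrap SE) plus `demo/cst.genes.tsv` (per-gene
*R*, *e*, *d*). Comparing against `demo/truth.json`, the estimated CSTs
recover the planted values with Spearman ρ ≈ 0.999 at this depth, and the
estimates are bit-identical whichever initial initiation rates are used.

The deterministic supply arithmetic:

```sh
codonbalance supply-calc
```

prints (abridged) `trna_per_ribosome: 14.24`, `trna_uses_per_second: 2.29`,
`seconds_per_trna_use: 0.44`, `phe_trna_conc_nM: 2764`,
`lys_trna_conc_nM: 6494`, `ternary_fraction_of_trna: 0.043`,
`ternary_to_ribosome_ratio: 0.22` — i.e. each tRNA must be recycled roughly
every half second, and only ~4% of tRNAs are ternary complexes at any
moment, the quantitative core of the tRNA-shortage argument.

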