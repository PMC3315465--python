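"""Wright-Fisher simulation of synonymous codon usage evolution.

A haploid asexual digital organism carries ten genes of 12 codons each,
all encoding one amino acid with four synonymous codons read by four
distinct tRNA species of fixed relative concentration (1, 2, 4, 8 by
default). Genes have relative expression levels 2**0 .. 2**9 (mRNA =
protein). The selection time of a codon is its total translational
usage divided by its cognate tRNA concentration, so the generation time
of a genotype is

    T = sum_k usage_k**2 / trna_k,   usage_k = sum_genes expr_g * n_gk,

which is minimized when usage is proportional to tRNA concentrations
(the proportional rule). Fitness is 1/T when selection is on (any
monotone decreasing map gives the same ranking; an exponential map
exp(-s*T) is provided as an alternative), uniform when off. Each
generation, offspring draw parents with probability proportional to
fitness, then receive Poisson-distributed synonymous mutations (mean 1
per genome per generation by default), each changing one uniformly
chosen codon position to one of the other three codons uniformly.

Populations start from exactly equal codon usage in every gene (3 of
each codon). With selection, transcriptome-wide codon usage evolves
toward the proportional rule and highly expressed genes develop the
strongest codon usage bias; without selection, usage stays at 1/4 per
codon on average and bias is unrelated to expression level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimConfig", "Trajectory", "generation_time", "cub_statistic", "evolve"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the codon-usage evolution simulation.

    Defaults are the full-scale study conditions (population of 10^4 for
    500 generations, 1000 replicates); pass smaller values for quick
    runs.
    """

    population_size: int = 10_000
    generations: int = 500
    replicates: int = 1000
    n_genes: int = 10
    codons_per_gene: int = 12
    family_size: int = 4
    expression_levels: tuple[float, ...] | None = None  # default 2**0..2**(n-1)
    trna_concentrations: tuple[float, ...] | None = None  # default 2**0..2**(k-1)
    mutation_rate: float = 1.0  # synonymous changes per genome per generation
    selection: bool = True
    fitness: str = "inverse"  # "inverse" (1/T) or "exponential" (exp(-s*T))
    selection_scale: float = 1.0  # s for the exponential map
    deterministic_mutations: bool = False  # exactly round(rate) per genome
    record_every: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.expression_levels is None:
            object.__setattr__(
                self,
                "expression_levels",
                tuple(2.0**i for i in range(self.n_genes)),
            )
        if self.trna_concentrations is None:
            object.__setattr__(
                self,
                "trna_concentrations",
                tuple(2.0**i for i in range(self.family_size)),
            )
        if min(self.population_size, self.generations, self.replicates) < 1:
            raise ValueError("population size, generations, replicates must be >= 1")
        if len(self.expression_levels) != self.n_genes:
            raise ValueError("need one expression level per gene")
        if len(self.trna_concentrations) != self.family_size:
            raise ValueError("need one tRNA concentration per codon")
        if any(x <= 0 for x in self.expression_levels + self.trna_concentrations):
            raise ValueError("expression levels and tRNA concentrations must be > 0")
        if self.codons_per_gene % self.family_size:
            raise ValueError(
                "codons_per_gene must be divisible by family_size for the "
                "equal-usage starting genotype"
            )
        if self.fitness not in ("inverse", "exponential"):
            raise ValueError("fitness must be 'inverse' or 'exponential'")
        if self.mutation_rate < 0:
            raise ValueError("mutation rate must be >= 0")


def generation_time(counts: np.ndarray, cfg: SimConfig) -> float:
    """Generation time T of one genotype (total translation time, m = 1 ribosome).

    ``counts`` is an (n_genes, family_size) array of per-gene codon
    counts. T = sum_k usage_k**2 / trna_k with usage_k the
    expression-weighted total use of codon k.
    """
    counts = np.asarray(counts, float)
    expr = np.asarray(cfg.expression_levels)
    usage = expr @ counts
    if usage.sum() == 0:
        raise ValueError("no codon used")
    return float(np.sum(usage**2 / np.asarray(cfg.trna_concentrations)))


def cub_statistic(fractions: np.ndarray) -> float:
    """Codon usage bias of one gene: sum of squared deviations from uniform.

    Zero for equal usage; (K-1)/K (0.75 for K = 4) for exclusive use of
    one codon. The plotted quantity summarizing how far a gene's codon
    usage has moved from uniform.
    """
    f = np.asarray(fractions, float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    return float(np.sum((f - 1.0 / f.size) ** 2))


@dataclass
class Trajectory:
    """Recorded output of one simulation replicate.

    ``overall_usage[t, k]``: population-mean translation-weighted codon
    fractions at recorded generation t. ``gene_usage[t, g, k]``:
    population-mean per-gene codon fractions. ``gene_cub[t, g]``:
    population-mean codon-usage-bias statistic per gene.
    ``generations[t]`` gives the generation index of each record
    (0 = the founding population).
    """

    generations: np.ndarray
    overall_usage: np.ndarray
    gene_usage: np.ndarray
    gene_cub: np.ndarray
    config: SimConfig = field(repr=False, default=None)


def _fitness(T: np.ndarray, cfg: SimConfig) -> np.ndarray:
    if not cfg.selection:
        return np.ones_like(T)
    if cfg.fitness == "inverse":
        return 1.0 / T
    return np.exp(-cfg.selection_scale * (T - T.min()) / T.mean())


def _record(pop: np.ndarray, expr: np.ndarray, cpg: int):
    """(overall weighted fractions, mean per-gene fractions, mean per-gene CUB)."""
    k = pop.shape[2]
    usage = np.tensordot(pop, expr, axes=([1], [0]))  # N x K
    overall = (usage.sum(axis=0) / usage.sum())
    gene_frac = pop.mean(axis=0) / cpg  # G x K
    frac = pop / cpg
    cub = np.mean(np.sum((frac - 1.0 / k) ** 2, axis=2), axis=0)  # G
    return overall, gene_frac, cub


def _evolve_one(cfg: SimConfig, rng: np.random.Generator) -> Trajectory:
    n, g, k, cpg = (
        cfg.population_size,
        cfg.n_genes,
        cfg.family_size,
        cfg.codons_per_gene,
    )
    expr = np.asarray(cfg.expression_levels)
    trna = np.asarray(cfg.trna_concentrations)
    pop = np.full((n, g, k), cpg // k, dtype=np.int32)

    rec_gens = list(range(0, cfg.generations + 1, cfg.record_every))
    if rec_gens[-1] != cfg.generations:
        rec_gens.append(cfg.generations)
    records = {t: None for t in rec_gens}
    records[0] = _record(pop, expr, cpg)

    for gen in range(1, cfg.generations + 1):
        usage = np.tensordot(pop, expr, axes=([1], [0]))  # N x K
        T = np.sum(usage**2 / trna, axis=1)
        fit = _fitness(T, cfg)
        parents = rng.choice(n, size=n, p=fit / fit.sum())
        pop = pop[parents].copy()

        if cfg.deterministic_mutations:
            n_mut = np.full(n, int(round(cfg.mutation_rate)))
        else:
            n_mut = rng.poisson(cfg.mutation_rate, size=n)
        total = int(n_mut.sum())
        if total:
            ind = np.repeat(np.arange(n), n_mut)
            gene = rng.integers(0, g, size=total)
            u = rng.random(total)
            shift = rng.integers(1, k, size=total)
            # the mutated position is picked by current codon composition;
            # events hitting the same gene copy are applied in successive
            # conflict-free rounds so later events see updated counts
            pending = np.arange(total)
            while pending.size:
                key = ind[pending] * g + gene[pending]
                _, first = np.unique(key, return_index=True)
                batch = pending[first]
                rows = pop[ind[batch], gene[batch]]  # B x k
                cum = np.cumsum(rows, axis=1)
                src = (u[batch, None] * cpg >= cum).sum(axis=1)
                src = np.minimum(src, k - 1)
                dst = (src + shift[batch]) % k
                pop[ind[batch], gene[batch], src] -= 1
                pop[ind[batch], gene[batch], dst] += 1
                mask = np.ones(pending.size, bool)
                mask[first] = False
                pending = pending[mask]
        if gen in records:
            records[gen] = _record(pop, expr, cpg)

    gens = np.array(sorted(records))
    overall = np.stack([records[t][0] for t in gens])
    gene_usage = np.stack([records[t][1] for t in gens])
    gene_cub = np.stack([records[t][2] for t in gens])
    return Trajectory(
        generations=gens,
        overall_usage=overall,
        gene_usage=gene_usage,
        gene_cub=gene_cub,
        config=cfg,
    )


def evolve(cfg: SimConfig) -> list[Trajectory]:
    """Run ``cfg.replicates`` independent replicates; deterministic under seed."""
    master = np.random.default_rng(cfg.seed)
    # one child generator per replicate keeps replicates independent and
    # reproducible regardless of recording options
    seeds = master.integers(0, 2**31 - 1, size=cfg.replicates)
    return [_evolve_one(cfg, np.random.default_rng(int(s))) for s in seeds]
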