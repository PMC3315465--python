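"""Synthetic inputs with planted ground truth for every pipeline stage.

The profiling generator inverts the CST estimator's model: the
probability that a footprint's A site sits on codon position (j, c) is
proportional to mRNA_j * R_j * CST(codon at c), while mRNA-Seq reads
land uniformly within a gene with probability proportional to mRNA_j
alone. Sampling is multinomial at a given depth (no overdispersion by
default, matching the estimator's implicit model; a negative-binomial
knob adds extra-multinomial noise for robustness checks).

Reads are 28 nt with the A site at nucleotide positions 16-18, so a
read whose A site covers codon index c (0-based) starts at CDS
nucleotide 3c - 15; only codons with a full read context inside the CDS
(c in [5, L-5]) are sampled.

The alignment generator emulates a pairwise ortholog comparison:
positions are independently conserved with a stated probability, and
the synonymous codon at conserved positions is drawn with
accuracy-weighted usage so each codon's planted conserved/non-conserved
odds ratio is known in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from codonbalance.accuracy_odds import AlignedGenePair
from codonbalance.cst_estimation import (
    ASITE_OFFSET_NT,
    READ_LENGTH,
    CodonCountMatrix,
    FootprintPlacement,
)
from codonbalance.genetic_code import (
    SENSE_CODONS,
    CodonTable,
    Gene,
    GeneSet,
    UsageVector,
    warn_data,
)

__all__ = [
    "GenerativeModel",
    "ConservationModel",
    "generate_genes",
    "generate_profiling_counts",
    "generate_profiling_placements",
    "generate_alignments",
    "planted_odds_ratio",
]

_MIN_CODON = ASITE_OFFSET_NT // 3  # first codon with a full upstream context
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


def generate_genes(
    n_genes: int,
    length_range: tuple[int, int] = (150, 500),
    codon_usage: dict[str, UsageVector] | None = None,
    seed: int | None = None,
    table: CodonTable | None = None,
    aa_freq: dict[str, float] | None = None,
    mean_mrna: float = 2.7,
    mrna_sigma: float = 1.2,
) -> GeneSet:
    """Random coding sequences with expression levels.

    Per position an amino acid is drawn (uniformly over the 20 unless
    ``aa_freq`` is given), then a codon from the family's usage vector
    (uniform within family by default). mRNA abundances are log-normal
    with mean ``mean_mrna`` mRNA/cell (the genomic average of a rapidly
    growing yeast culture) and log-SD ``mrna_sigma``; protein abundance
    is mRNA times a log-normal translation factor.
    """
    rng = np.random.default_rng(seed)
    table = table or CodonTable.standard()
    aas = sorted(table.families)
    if aa_freq is None:
        aa_p = np.full(len(aas), 1.0 / len(aas))
    else:
        aa_p = np.array([aa_freq.get(a, 0.0) for a in aas])
        aa_p = aa_p / aa_p.sum()
    fam_codons = {aa: list(table.families[aa]) for aa in aas}
    fam_p = {}
    for aa in aas:
        codons = fam_codons[aa]
        if codon_usage and aa in codon_usage:
            fam_p[aa] = np.array([codon_usage[aa][c] for c in codons])
        else:
            fam_p[aa] = np.full(len(codons), 1.0 / len(codons))
    lo, hi = length_range
    genes = []
    # mean of lognormal(mu, s) is exp(mu + s^2/2); anchor the mean
    mu = math.log(mean_mrna) - mrna_sigma**2 / 2.0
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        aa_seq = rng.choice(len(aas), size=length, p=aa_p)
        codons = [
            fam_codons[aas[a]][rng.choice(len(fam_p[aas[a]]), p=fam_p[aas[a]])]
            for a in aa_seq
        ]
        mrna = float(rng.lognormal(mu, mrna_sigma))
        protein = mrna * float(rng.lognormal(5.0, 0.8))
        genes.append(
            Gene(id=f"g{i:04d}", codons=tuple(codons), mrna=mrna, protein=protein)
        )
    return GeneSet(genes)


@dataclass
class GenerativeModel:
    """Planted truth for the profiling generator.

    ``cst``: relative selection time per sense codon; ``R``: per-gene
    initiation rate (defaults to 1); depths are total read counts.
    ``overdispersion``: 0 for pure multinomial sampling, otherwise the
    per-cell gamma noise variance of a negative-binomial-like model.
    """

    cst: dict[str, float]
    footprint_depth: int = 1_000_000
    mrna_depth: int = 1_000_000
    R: dict[str, float] | None = None
    overdispersion: float = 0.0
    seed: int | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.footprint_depth < 1 or self.mrna_depth < 1:
            raise ValueError("depths must be >= 1")
        if any(v <= 0 for v in self.cst.values()):
            raise ValueError("planted CSTs must be positive")


def _eligible_slice(length: int) -> tuple[int, int]:
    """0-based [first, last] codon index with a full 28-nt read inside the CDS."""
    # read start 3c-15 must satisfy start + 28 <= 3*length
    last = (3 * length - (READ_LENGTH - ASITE_OFFSET_NT)) // 3
    return _MIN_CODON, last


def _position_weights(model: GenerativeModel, genes: GeneSet):
    """Per-gene eligible codon indices and (footprint, mrna) position weights."""
    out = []
    for gene in genes:
        lo, hi = _eligible_slice(len(gene))
        if hi < lo:
            warn_data(f"gene {gene.id} too short for 28-nt reads; excluded")
            continue
        idx = np.arange(lo, hi + 1)
        csts = np.array([model.cst[gene.codons[c]] for c in idx])
        r = 1.0 if model.R is None else model.R[gene.id]
        mrna = gene.mrna if gene.mrna is not None else 1.0
        out.append((gene.id, idx, mrna * r * csts, np.full(idx.size, float(mrna))))
    if not out:
        raise ValueError("no gene long enough for footprint reads")
    return out


def _sample_counts(
    rng: np.random.Generator, weights: np.ndarray, depth: int, overdispersion: float
) -> np.ndarray:
    w = weights.astype(float)
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        w = w * rng.gamma(shape, overdispersion, size=w.shape)
    return rng.multinomial(depth, w / w.sum())


def generate_profiling_counts(
    model: GenerativeModel, genes: GeneSet
) -> CodonCountMatrix:
    """Sample footprint and mRNA-Seq A-site codon counts directly.

    Equivalent in distribution to generating read placements and
    reducing them, but avoids materializing one object per read; use
    this for large depths.
    """
    rng = np.random.default_rng(model.seed)
    per_gene = _position_weights(model, genes)
    fp_w = np.concatenate([w for _, _, w, _ in per_gene])
    mr_w = np.concatenate([w for _, _, _, w in per_gene])
    fp_n = _sample_counts(rng, fp_w, model.footprint_depth, model.overdispersion)
    mr_n = _sample_counts(rng, mr_w, model.mrna_depth, model.overdispersion)
    gene_ids = [gid for gid, _, _, _ in per_gene]
    fp = np.zeros((len(per_gene), len(SENSE_CODONS)))
    mr = np.zeros_like(fp)
    lengths = np.zeros(len(per_gene))
    offset = 0
    for j, (gid, idx, _, _) in enumerate(per_gene):
        gene = genes[gid]
        lengths[j] = len(gene)
        codon_rows = np.array([_CODON_INDEX[gene.codons[c]] for c in idx])
        np.add.at(fp[j], codon_rows, fp_n[offset : offset + idx.size])
        np.add.at(mr[j], codon_rows, mr_n[offset : offset + idx.size])
        offset += idx.size
    return CodonCountMatrix(
        gene_ids=gene_ids, footprint=fp, mrna=mr, lengths=lengths
    )


def generate_profiling_placements(
    model: GenerativeModel, genes: GeneSet
) -> tuple[list[FootprintPlacement], list[FootprintPlacement]]:
    """Sample 28-nt read placements (footprint list, mRNA-Seq list).

    Each sampled A-site codon index c becomes a read starting at CDS
    nucleotide 3c - 15, so read positions 16-18 cover the codon.
    """
    rng = np.random.default_rng(model.seed)
    per_gene = _position_weights(model, genes)
    fp_w = np.concatenate([w for _, _, w, _ in per_gene])
    mr_w = np.concatenate([w for _, _, _, w in per_gene])
    gene_of = np.concatenate(
        [np.full(idx.size, j) for j, (_, idx, _, _) in enumerate(per_gene)]
    )
    codon_of = np.concatenate([idx for _, idx, _, _ in per_gene])
    gene_ids = [gid for gid, _, _, _ in per_gene]

    def emit(weights, depth):
        counts = _sample_counts(rng, weights, depth, model.overdispersion)
        reads = []
        for flat in np.flatnonzero(counts):
            start = 3 * int(codon_of[flat]) - ASITE_OFFSET_NT
            pl = FootprintPlacement(
                gene_id=gene_ids[int(gene_of[flat])], start=start
            )
            reads.extend([pl] * int(counts[flat]))
        return reads

    return emit(fp_w, model.footprint_depth), emit(mr_w, model.mrna_depth)


@dataclass
class ConservationModel:
    """Planted conservation structure for alignment generation.

    Each codon position is labelled conserved with probability
    ``conservation_prob`` (or excluded, as if aligned to a gap, with
    probability ``gap_prob``). The synonymous codon written at a
    position is drawn from the family's base usage, multiplied by
    ``accuracy_weights`` (and renormalized) at conserved positions.
    """

    conservation_prob: float = 0.5
    gap_prob: float = 0.0
    accuracy_weights: dict[str, float] = field(default_factory=dict)
    base_usage: dict[str, UsageVector] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.conservation_prob <= 1 or not 0 <= self.gap_prob < 1:
            raise ValueError("probabilities must lie in [0, 1]")


def planted_odds_ratio(
    model: ConservationModel, table: CodonTable, codon: str
) -> float:
    """Closed-form conserved/non-conserved odds ratio planted for a codon."""
    family = table.family_of(codon)
    aa = table.aa_of(codon)
    if model.base_usage and aa in model.base_usage:
        base = np.array([model.base_usage[aa][c] for c in family])
    else:
        base = np.full(len(family), 1.0 / len(family))
    w = np.array([model.accuracy_weights.get(c, 1.0) for c in family])
    cons = base * w
    cons = cons / cons.sum()
    i = family.index(codon)
    odds_c = cons[i] / (1.0 - cons[i])
    odds_n = base[i] / (1.0 - base[i])
    return float(odds_c / odds_n)


def generate_alignments(
    genes: GeneSet,
    model: ConservationModel,
    seed: int | None = None,
    table: CodonTable | None = None,
) -> list[AlignedGenePair]:
    """Simulated ortholog-alignment conservation labels with planted odds ratios.

    Amino acid identity at each position is taken from the input gene;
    the synonymous codon written at the position is re-drawn according
    to the conservation model, so the per-codon enrichment at conserved
    positions is known (see :func:`planted_odds_ratio`).
    """
    rng = np.random.default_rng(seed)
    table = table or CodonTable.standard()
    pairs = []
    for gene in genes:
        positions = []
        for codon in gene.codons:
            u = rng.random()
            if u < model.gap_prob:
                positions.append((codon, "X"))
                continue
            conserved = rng.random() < model.conservation_prob
            family = table.family_of(codon)
            aa = table.aa_of(codon)
            if len(family) == 1:
                positions.append((codon, "C" if conserved else "N"))
                continue
            if model.base_usage and aa in model.base_usage:
                base = np.array([model.base_usage[aa][c] for c in family])
            else:
                base = np.full(len(family), 1.0 / len(family))
            if conserved:
                w = np.array(
                    [model.accuracy_weights.get(c, 1.0) for c in family]
                )
                p = base * w
            else:
                p = base
            drawn = family[rng.choice(len(family), p=p / p.sum())]
            positions.append((drawn, "C" if conserved else "N"))
        pairs.append(AlignedGenePair(gene_id=gene.id, positions=tuple(positions)))
    return pairs
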