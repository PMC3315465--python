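"""Codon-usage statistics: counts, RSCU, RSCU', CAI, distances, D_ncu.

Conventions
-----------
* RSCU of codon *i* is its count divided by the mean count of its
  synonymous family in a reference set of highly expressed genes; the
  family mean of RSCU is 1 by construction.
* RSCU' = RSCU / n (family size n) is the codon's share of use within
  its family; RSCU' sums to 1 within each family.
* Transcriptomic usage weights each gene's codon counts by its mRNA
  abundance (mRNA copies/cell); unweighted counting gives genomic usage.
* D_ncu compares a gene's within-family codon fractions to the host's,
  family by family, and combines the per-family distances into a single
  index in [0, 1] by a weighted geometric mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from codonbalance.genetic_code import CodonTable, GeneSet, UsageVector, warn_data

__all__ = [
    "RSCUTable",
    "count_codons",
    "select_highly_expressed",
    "rscu",
    "cai",
    "usage_distance",
    "usage_correlation",
    "dncu",
    "family_usage",
]

SQRT2 = math.sqrt(2.0)


def count_codons(
    genes: GeneSet, weights: dict[str, float] | None = None
) -> dict[str, float]:
    """Tally codon occurrences over a gene set, optionally gene-weighted.

    ``weights[g]`` multiplies every codon occurrence in gene ``g``
    (e.g. mRNA abundance for transcriptomic usage). Unweighted counting
    (weights=None) is genomic usage. Weights, if given, must cover every
    gene and be non-negative.
    """
    if weights is not None:
        missing = [g.id for g in genes if g.id not in weights]
        if missing:
            raise ValueError(f"weights missing for genes: {missing}")
        if any(weights[g.id] < 0 for g in genes):
            raise ValueError("gene weights must be non-negative")
    counts: dict[str, float] = {}
    for gene in genes:
        w = 1.0 if weights is None else float(weights[gene.id])
        if w == 0.0:
            continue
        for codon in gene.codons:
            counts[codon] = counts.get(codon, 0.0) + w
    return counts


def select_highly_expressed(
    genes: GeneSet,
    top_n: int = 200,
    min_mrna_multiple: float = 4.0,
    genomic_mean_mrna: float = 2.7,
) -> list[str]:
    """Pick reference genes for RSCU: highest protein abundance, mRNA-backed.

    The ``top_n`` genes by protein abundance are taken, then genes
    lacking mRNA data are dropped, then genes whose mRNA abundance falls
    below ``min_mrna_multiple`` times the genomic mean (default 4 x 2.7
    mRNA/cell) are dropped.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ranked = [g for g in genes if g.protein is not None]
    if not ranked:
        raise ValueError("no genes carry protein abundance for ranking")
    ranked.sort(key=lambda g: (-g.protein, g.id))
    if len(ranked) < top_n:
        warn_data(
            f"only {len(ranked)} genes available for top_n={top_n}; using all"
        )
    top = ranked[:top_n]
    threshold = min_mrna_multiple * genomic_mean_mrna
    return [g.id for g in top if g.mrna is not None and g.mrna >= threshold]


@dataclass
class RSCUTable:
    """Per-codon RSCU and RSCU' with the preferred codon of each family.

    ``preferred`` maps each multi-codon amino acid to its highest-RSCU'
    codon (ties broken lexicographically and recorded in ``ties``).
    Families whose reference counts were all zero are listed in
    ``undefined_families`` and carry no entries.
    """

    rscu: dict[str, float]
    rscu_prime: dict[str, float]
    preferred: dict[str, str]
    table: CodonTable
    undefined_families: tuple[str, ...] = ()
    ties: tuple[str, ...] = ()
    family_max_rscu: dict[str, float] = field(default_factory=dict)

    def is_preferred(self, codon: str) -> bool:
        aa = self.table.aa_of(codon)
        return self.preferred.get(aa) == codon


def rscu(genes: GeneSet, reference_ids: list[str], table: CodonTable) -> RSCUTable:
    """Relative synonymous codon usage over a reference gene set.

    RSCU_i = count_i / mean(counts of the family); RSCU' = RSCU / n.
    Computed for every family (including the single-codon Met/Trp
    families, whose RSCU is trivially 1). A family never observed in the
    reference set is reported undefined and excluded.
    """
    if not reference_ids:
        raise ValueError("reference gene set is empty")
    counts = count_codons(genes.subset(reference_ids))
    rscu_vals: dict[str, float] = {}
    prime: dict[str, float] = {}
    preferred: dict[str, str] = {}
    fam_max: dict[str, float] = {}
    undefined: list[str] = []
    ties: list[str] = []
    for aa, family in table.families.items():
        fam_counts = np.array([counts.get(c, 0.0) for c in family], float)
        total = fam_counts.sum()
        if total == 0:
            undefined.append(aa)
            continue
        n = len(family)
        vals = fam_counts / (total / n)
        for codon, v in zip(family, vals):
            rscu_vals[codon] = float(v)
            prime[codon] = float(v / n)
        fam_max[aa] = float(vals.max())
        if n >= 2:
            best = vals.max()
            winners = [c for c, v in zip(family, vals) if v == best]
            preferred[aa] = min(winners)
            if len(winners) > 1:
                ties.append(aa)
    if undefined:
        warn_data(f"RSCU undefined for families with zero counts: {undefined}")
    return RSCUTable(
        rscu=rscu_vals,
        rscu_prime=prime,
        preferred=preferred,
        table=table,
        undefined_families=tuple(undefined),
        ties=tuple(ties),
        family_max_rscu=fam_max,
    )


def cai(
    gene_codons,
    rscu_table: RSCUTable,
    on_undefined: str = "exclude",
) -> float:
    """Codon adaptation index of a gene.

    Geometric mean, over codon positions, of the gene codon's RSCU
    divided by the highest RSCU in its synonymous family. Positions in
    single-codon families (Met, Trp) carry no information and are
    excluded. Positions whose codon has undefined RSCU are excluded by
    default (``on_undefined="exclude"``) or raise (``"fail"``).
    """
    if on_undefined not in ("exclude", "fail"):
        raise ValueError("on_undefined must be 'exclude' or 'fail'")
    table = rscu_table.table
    log_sum = 0.0
    n_used = 0
    for codon in gene_codons:
        aa = table.aa_of(codon)
        if len(table.families[aa]) < 2:
            continue
        if codon not in rscu_table.rscu:
            if on_undefined == "fail":
                raise ValueError(f"codon {codon} has undefined RSCU")
            continue
        w = rscu_table.rscu[codon] / rscu_table.family_max_rscu[aa]
        if w <= 0:
            # a codon absent from the reference set: conventionally a hard
            # zero would void the whole gene; treat like undefined instead
            if on_undefined == "fail":
                raise ValueError(f"codon {codon} has zero RSCU in the reference")
            continue
        log_sum += math.log(w)
        n_used += 1
    if n_used == 0:
        raise ValueError("gene has no informative codon positions for CAI")
    return math.exp(log_sum / n_used)


def usage_distance(a: UsageVector, b: UsageVector, metric: str = "euclidian") -> float:
    """Euclidian sqrt(sum (p_i-q_i)^2) or Manhattan sum |p_i-q_i| distance."""
    if set(a.values) != set(b.values):
        raise ValueError("usage vectors cover different item sets")
    if a.scope and b.scope and a.scope != b.scope:
        raise ValueError(f"scope mismatch: {a.scope!r} vs {b.scope!r}")
    diffs = np.array([a[k] - b[k] for k in a.values])
    if metric == "euclidian":
        return float(np.sqrt(np.sum(diffs**2)))
    if metric == "manhattan":
        return float(np.sum(np.abs(diffs)))
    raise ValueError(f"unknown metric {metric!r}")


def usage_correlation(a: dict[str, float], b: dict[str, float]) -> float:
    """Pearson correlation between two 61-codon usage vectors."""
    if set(a) != set(b):
        raise ValueError("usage vectors cover different codon sets")
    keys = sorted(a)
    x = np.array([a[k] for k in keys])
    y = np.array([b[k] for k in keys])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(x, y).statistic)


def family_usage(
    counts: dict[str, float], table: CodonTable, min_family_size: int = 2
) -> dict[str, UsageVector]:
    """Within-family codon fractions from a codon count map.

    Families with zero total count are omitted.
    """
    out: dict[str, UsageVector] = {}
    for aa, family in table.families.items():
        if len(family) < min_family_size:
            continue
        fam = {c: counts.get(c, 0.0) for c in family}
        if sum(fam.values()) > 0:
            out[aa] = UsageVector.from_counts(fam, scope=f"family:{aa}")
    return out


def dncu(
    gene_codons,
    host_usage: dict[str, UsageVector],
    table: CodonTable,
) -> float:
    """Distance to native codon usage (D_ncu) of a gene, in [0, 1].

    For each multi-codon amino acid *i* present in the gene, the
    Euclidean distance between the gene's within-family codon fractions
    Y_ij and the host's X_ij is normalized by its maximum sqrt(2), so
    each per-family distance D_i lies in [0, 1]:

        D_i = sqrt( sum_j (Y_ij - X_ij)^2 / 2 )

    D_ncu is the weighted geometric mean of the D_i with weights m_i / l,
    where m_i is the count of amino acid i in the protein and l the
    protein length excluding Met and Trp. If any D_i is exactly 0 the
    geometric mean is 0 (a warning lists the zero families).
    """
    fam_counts: dict[str, dict[str, float]] = {}
    for codon in gene_codons:
        aa = table.aa_of(codon)
        if len(table.families[aa]) < 2:
            continue
        fam_counts.setdefault(aa, {})
        fam_counts[aa][codon] = fam_counts[aa].get(codon, 0.0) + 1.0
    if not fam_counts:
        raise ValueError("gene has only Met/Trp residues; D_ncu undefined")
    total_m = sum(sum(d.values()) for d in fam_counts.values())
    log_sum = 0.0
    zero_fams: list[str] = []
    for aa, counts in fam_counts.items():
        family = table.families[aa]
        if aa not in host_usage:
            raise ValueError(f"host usage missing for amino acid {aa}")
        host = host_usage[aa]
        if set(host.values) != set(family):
            raise ValueError(f"host usage for {aa} covers wrong codons")
        m_i = sum(counts.values())
        y = np.array([counts.get(c, 0.0) for c in family]) / m_i
        x = np.array([host[c] for c in family])
        d_i = math.sqrt(float(np.sum((y - x) ** 2)) / 2.0)
        if d_i == 0.0:
            zero_fams.append(aa)
        else:
            log_sum += (m_i / total_m) * math.log(d_i)
    if zero_fams:
        warn_data(f"D_ncu: zero per-family distance for {zero_fams}; D_ncu = 0")
        return 0.0
    return math.exp(log_sum)
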