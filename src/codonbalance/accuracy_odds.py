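"""Conserved-site codon enrichment: stratified odds ratios for translational accuracy.

A codon that is over-represented at evolutionarily conserved amino acid
positions, relative to its synonymous alternatives, is a candidate
"accurate" codon: selection against mistranslation is strongest where
the residue matters. For each focal codon, each gene contributes a 2x2
table (focal vs other synonyms) x (conserved vs non-conserved
positions); genes are combined into a common odds ratio by the
Mantel-Haenszel procedure. Comparing each family's highest-odds-ratio
codon with its highest-RSCU' (preferred) codon asks whether preferred
codons are also the accurate ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from codonbalance.codon_metrics import RSCUTable
from codonbalance.genetic_code import CodonTable, warn_data

__all__ = [
    "AlignedGenePair",
    "build_strata",
    "mantel_haenszel",
    "accuracy_vs_preference",
    "alignment_identity",
]

CONSERVED, NONCONSERVED, EXCLUDED = "C", "N", "X"


@dataclass
class AlignedGenePair:
    """Per-codon conservation labels for one focal-species gene.

    ``positions`` is a sequence of (codon, label) pairs where the label
    is "C" (identical amino acid in the orthologous alignment), "N"
    (different amino acid), or "X" (aligned to a gap; excluded).
    """

    gene_id: str
    positions: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        self.positions = tuple((c, l) for c, l in self.positions)
        bad = {l for _, l in self.positions} - {CONSERVED, NONCONSERVED, EXCLUDED}
        if bad:
            raise ValueError(f"gene {self.gene_id!r}: unknown labels {bad}")


def build_strata(
    pairs: list[AlignedGenePair], table: CodonTable, focal_codon: str
) -> list[tuple[str, np.ndarray]]:
    """Per-gene 2x2 tables [[focal@C, others@C], [focal@N, others@N]].

    Only positions encoding the focal codon's amino acid count; gap
    positions and other amino acids are ignored. Genes without any
    informative position are skipped.
    """
    family = set(table.family_of(focal_codon))
    if len(family) < 2:
        raise ValueError(f"{focal_codon} has no synonymous alternatives")
    strata = []
    for pair in pairs:
        a = b = c = d = 0
        for codon, label in pair.positions:
            if label == EXCLUDED or codon not in family:
                continue
            if label == CONSERVED:
                if codon == focal_codon:
                    a += 1
                else:
                    b += 1
            else:
                if codon == focal_codon:
                    c += 1
                else:
                    d += 1
        if a + b + c + d > 0:
            strata.append((pair.gene_id, np.array([[a, b], [c, d]], float)))
    return strata


def mantel_haenszel(strata) -> tuple[float, float]:
    """Mantel-Haenszel common odds ratio and chi-square P over 2x2 strata.

    ``strata`` is a sequence of 2x2 arrays (or (label, array) pairs).
    OR = sum(a_i d_i / n_i) / sum(b_i c_i / n_i); the chi-square
    statistic (1 df, no continuity correction) compares sum(a_i) with
    its conditional expectation. Strata with an empty row or column
    margin carry no information and are counted but harmless (their
    terms are zero).
    """
    tables = []
    for s in strata:
        t = np.asarray(s[1] if isinstance(s, tuple) else s, float)
        if t.shape != (2, 2) or (t < 0).any():
            raise ValueError("each stratum must be a non-negative 2x2 table")
        tables.append(t)
    if not tables:
        raise ValueError("no strata")
    num = den = 0.0
    sum_a = sum_e = sum_v = 0.0
    n_empty = 0
    for t in tables:
        (a, b), (c, d) = t
        n = t.sum()
        if n == 0 or min(a + b, c + d, a + c, b + d) == 0:
            n_empty += 1
        if n == 0:
            continue
        num += a * d / n
        den += b * c / n
        sum_a += a
        sum_e += (a + b) * (a + c) / n
        if n > 1:
            sum_v += (a + b) * (c + d) * (a + c) * (b + d) / (n * n * (n - 1))
    if den == 0.0:
        warn_data("Mantel-Haenszel denominator is zero: infinite odds ratio")
        odds = np.inf
    else:
        odds = num / den
    if sum_v == 0.0:
        p = float("nan")
    else:
        chi2 = (sum_a - sum_e) ** 2 / sum_v
        p = float(stats.chi2.sf(chi2, df=1))
    return float(odds), p


@dataclass
class FamilyAccuracyReport:
    """Per-amino-acid comparison of accurate vs preferred codons."""

    amino_acid: str
    odds_ratios: dict[str, float]
    p_values: dict[str, float]
    most_accurate: str
    preferred: str
    mismatch: bool
    significant: dict[str, bool]


def accuracy_vs_preference(
    pairs: list[AlignedGenePair],
    table: CodonTable,
    rscu_table: RSCUTable,
    gene_subset: list[str] | None = None,
    alpha: float = 0.05,
) -> dict[str, FamilyAccuracyReport]:
    """Per-family odds ratios, most-accurate codon, and preferred-codon match.

    For each multi-codon amino acid, every codon's Mantel-Haenszel odds
    ratio (conserved vs non-conserved enrichment, combined over genes)
    is computed; the codon with the highest odds ratio is called most
    accurate and compared to the highest-RSCU' (preferred) codon.
    Per-codon deviation from OR = 1 is flagged at ``alpha``
    (uncorrected). ``gene_subset`` restricts to the named genes (e.g.
    the most highly expressed decile).
    """
    if gene_subset is not None:
        keep = set(gene_subset)
        pairs = [p for p in pairs if p.gene_id in keep]
    out: dict[str, FamilyAccuracyReport] = {}
    for aa, family in sorted(table.multi_codon_families.items()):
        ors: dict[str, float] = {}
        ps: dict[str, float] = {}
        for codon in family:
            strata = build_strata(pairs, table, codon)
            if not strata:
                continue
            ors[codon], ps[codon] = mantel_haenszel(strata)
        if not ors:
            warn_data(f"amino acid {aa} absent from all aligned genes; omitted")
            continue
        most_accurate = min(ors, key=lambda c: (-ors[c], c))
        preferred = rscu_table.preferred.get(aa, "")
        out[aa] = FamilyAccuracyReport(
            amino_acid=aa,
            odds_ratios=ors,
            p_values=ps,
            most_accurate=most_accurate,
            preferred=preferred,
            mismatch=(most_accurate != preferred),
            significant={
                c: (np.isfinite(ps[c]) and ps[c] < alpha) for c in ps
            },
        )
    return out


def alignment_identity(seq_a: str, seq_b: str, gap: str = "-") -> float:
    """Fraction of identical residues over aligned (gap-free) columns.

    E.g. two fluorescent-protein paralogs sharing 71 of 220 aligned
    residues have identity 71/220 = 0.3227 (32%).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    aligned = ident = 0
    for x, y in zip(seq_a, seq_b):
        if x == gap or y == gap:
            continue
        aligned += 1
        if x == y:
            ident += 1
    if aligned == 0:
        raise ValueError("no aligned columns")
    return ident / aligned
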