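"""Genetic-code bookkeeping: codons, synonymous families, genes, usage vectors.

All statistics in this package operate on the 61 sense codons of the
standard nuclear genetic code; stop codons are excluded everywhere.
Eighteen amino acids have two or more synonymous codons, while Met (ATG)
and Trp (TGG) are encoded by a single codon each and therefore carry no
synonymous-usage information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "CodonTable",
    "Gene",
    "GeneSet",
    "UsageVector",
    "wobble_trna_assignment",
]

_STD = _BioCodonTable.unambiguous_dna_by_id[1]

#: The 61 sense codons of the standard code, lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STD.forward_table))
STOP_CODONS: tuple[str, ...] = tuple(sorted(_STD.stop_codons))

_SENSE_SET = frozenset(SENSE_CODONS)


def wobble_trna_assignment() -> dict[str, str]:
    """Approximate codon->tRNA assignment from simplified wobble pairing.

    Codons sharing the first two nucleotides and a pyrimidine (T/C) third
    position are read by a single tRNA (G at the anticodon wobble
    position); third-position A and G codons each get their own species.
    This is an *approximation*: organism-specific best-match tables (e.g.
    curated from tRNA gene complements) are more accurate and should be
    supplied as input whenever available.
    """
    assignment: dict[str, str] = {}
    for codon in SENSE_CODONS:
        prefix, third = codon[:2], codon[2]
        if third in "TC":
            key = prefix + "Y"
        else:
            key = prefix + third
        # never merge across amino acids (e.g. ATA Ile vs ATG Met)
        aa = _STD.forward_table[codon]
        assignment[codon] = f"tRNA-{aa}-{key}"
    return assignment


@dataclass(frozen=True)
class CodonTable:
    """The sense-codon map: codon -> amino acid, synonymous families, tRNAs.

    Parameters
    ----------
    codon_to_aa:
        Map from each of the 61 sense codons to its one-letter amino acid.
    codon_to_trna:
        Map from each sense codon to the identifier of the single
        best-matching tRNA species that decodes it.
    """

    codon_to_aa: dict[str, str]
    codon_to_trna: dict[str, str]
    families: dict[str, tuple[str, ...]] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != _SENSE_SET:
            missing = _SENSE_SET - set(self.codon_to_aa)
            extra = set(self.codon_to_aa) - _SENSE_SET
            raise ValueError(
                f"codon table must cover exactly the 61 sense codons; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        if set(self.codon_to_trna) != _SENSE_SET:
            raise ValueError("codon_to_trna must assign every sense codon")
        fams: dict[str, list[str]] = {}
        for codon in SENSE_CODONS:  # lexicographic within family
            fams.setdefault(self.codon_to_aa[codon], []).append(codon)
        object.__setattr__(
            self, "families", {aa: tuple(c) for aa, c in fams.items()}
        )
        n_multi = sum(1 for f in self.families.values() if len(f) >= 2)
        n_single = sum(1 for f in self.families.values() if len(f) == 1)
        if n_multi != 18 or n_single != 2:
            raise ValueError(
                f"expected 18 multi-codon and 2 single-codon families, "
                f"got {n_multi} and {n_single}"
            )

    @classmethod
    def standard(cls, codon_to_trna: dict[str, str] | None = None) -> "CodonTable":
        """Standard nuclear code; wobble-rule tRNA assignment if none given."""
        return cls(
            codon_to_aa=dict(_STD.forward_table),
            codon_to_trna=codon_to_trna or wobble_trna_assignment(),
        )

    @property
    def multi_codon_families(self) -> dict[str, tuple[str, ...]]:
        """The 18 synonymous families with >= 2 codons."""
        return {aa: f for aa, f in self.families.items() if len(f) >= 2}

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]

    def aa_of(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def trna_families(self) -> dict[str, dict[str, tuple[str, ...]]]:
        """Per amino acid: tRNA species -> codons it decodes (iso-synonymous)."""
        out: dict[str, dict[str, list[str]]] = {}
        for codon in SENSE_CODONS:
            aa = self.codon_to_aa[codon]
            out.setdefault(aa, {}).setdefault(self.codon_to_trna[codon], []).append(codon)
        return {
            aa: {t: tuple(c) for t, c in d.items()} for aa, d in out.items()
        }


@dataclass
class Gene:
    """A coding sequence held as a list of sense codons plus expression data.

    ``mrna`` is mRNA abundance in mRNA/cell; ``protein`` is an arbitrary
    protein-abundance measure used only for ranking.
    """

    id: str
    codons: tuple[str, ...]
    mrna: float | None = None
    protein: float | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.codons = tuple(self.codons)
        for pos, codon in enumerate(self.codons):
            if codon not in _SENSE_SET:
                raise ValueError(
                    f"gene {self.id!r}: unknown codon {codon!r} at codon "
                    f"position {pos}"
                )
        if self.mrna is not None and self.mrna < 0:
            raise ValueError(f"gene {self.id!r}: negative mRNA abundance")

    def __len__(self) -> int:
        return len(self.codons)


class GeneSet:
    """An ordered collection of :class:`Gene` with unique identifiers."""

    def __init__(self, genes: list[Gene] | tuple[Gene, ...]):
        ids = [g.id for g in genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene identifiers: {dupes}")
        self._genes: dict[str, Gene] = {g.id: g for g in genes}

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self):
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> Gene:
        return self._genes[gene_id]

    @property
    def ids(self) -> list[str]:
        return list(self._genes)

    def subset(self, ids) -> "GeneSet":
        return GeneSet([self._genes[i] for i in ids])

    def without_flags(self, *flags: str) -> "GeneSet":
        """Drop genes carrying any of the given flags (e.g. transposon)."""
        bad = set(flags)
        return GeneSet([g for g in self if not (g.flags & bad)])


class UsageVector:
    """A probability vector over codons, tRNAs, or amino acids.

    ``scope`` is a free-text label ("family:Glu", "codon61", "aa20", ...)
    used only to guard comparisons between incompatible vectors.
    Fractions must sum to 1 (tolerance 1e-9); an all-zero count vector is
    rejected.
    """

    __slots__ = ("scope", "values")

    def __init__(self, values: dict[str, float], scope: str = ""):
        total = float(sum(values.values()))
        if any(v < 0 for v in values.values()):
            raise ValueError("usage fractions must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"usage fractions sum to {total!r}, not 1")
        self.values = dict(values)
        self.scope = scope

    @classmethod
    def from_counts(cls, counts: dict[str, float], scope: str = "") -> "UsageVector":
        total = float(sum(counts.values()))
        if total <= 0:
            raise ValueError(f"cannot normalize all-zero counts (scope={scope!r})")
        return cls({k: v / total for k, v in counts.items()}, scope=scope)

    def items(self):
        return self.values.items()

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __len__(self) -> int:
        return len(self.values)

    def __repr__(self) -> str:  # pragma: no cover
        return f"UsageVector(scope={self.scope!r}, {self.values!r})"


def warn_data(msg: str) -> None:
    """Uniform warning channel for recoverable data issues."""
    warnings.warn(msg, UserWarning, stacklevel=3)
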