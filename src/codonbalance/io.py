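"""Readers and writers for the package's plain-text interchange formats.

CDS input is FASTA; tabular inputs are tab-separated UTF-8 with a
header row and optional ``#`` comment lines. Every writer emits a
commented preamble naming the columns and their units.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from codonbalance.cst_estimation import (
    CodonCountMatrix,
    CSTEstimate,
    FootprintPlacement,
)
from codonbalance.genetic_code import (
    SENSE_CODONS,
    STOP_CODONS,
    CodonTable,
    Gene,
    GeneSet,
    UsageVector,
)

__all__ = [
    "read_fasta_cds",
    "write_fasta_cds",
    "read_expression_table",
    "read_trna_table",
    "read_placements",
    "read_counts",
    "write_cst_table",
    "write_gene_table",
]

_SENSE = set(SENSE_CODONS)
_STOPS = set(STOP_CODONS)


def read_fasta_cds(
    path, expression: pd.DataFrame | None = None
) -> GeneSet:
    """Read coding sequences from FASTA into a validated GeneSet.

    Sequences must be a multiple of 3; a trailing stop codon is
    stripped; an internal stop or a non-codon triplet is an error
    naming the record. If an expression table (from
    :func:`read_expression_table`) is given, mRNA/protein abundances
    and flags are attached by gene id.
    """
    genes = []
    errors = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if len(seq) % 3:
            errors.append(f"{rec.id}: length {len(seq)} not a multiple of 3")
            continue
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in _STOPS:
            codons = codons[:-1]
        bad = None
        for pos, codon in enumerate(codons):
            if codon in _STOPS:
                bad = f"{rec.id}: internal stop {codon} at codon {pos}"
                break
            if codon not in _SENSE:
                bad = f"{rec.id}: invalid codon {codon!r} at codon {pos}"
                break
        if bad:
            errors.append(bad)
            continue
        kwargs = {}
        if expression is not None and rec.id in expression.index:
            row = expression.loc[rec.id]
            kwargs["mrna"] = None if pd.isna(row.get("mrna_per_cell")) else float(
                row["mrna_per_cell"]
            )
            prot = row.get("protein_abundance")
            kwargs["protein"] = None if pd.isna(prot) else float(prot)
            flags = row.get("flags")
            if isinstance(flags, str) and flags:
                kwargs["flags"] = frozenset(flags.split(","))
        genes.append(Gene(id=rec.id, codons=tuple(codons), **kwargs))
    if errors:
        raise ValueError("invalid CDS records:\n" + "\n".join(errors))
    return GeneSet(genes)


def write_fasta_cds(genes: GeneSet, path) -> None:
    records = [
        SeqRecord(Seq("".join(g.codons)), id=g.id, description="")
        for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_expression_table(path) -> pd.DataFrame:
    """gene_id, mrna_per_cell [, protein_abundance, flags] -> indexed frame."""
    df = _read_tsv(path)
    if "gene_id" not in df or "mrna_per_cell" not in df:
        raise ValueError("expression table needs gene_id and mrna_per_cell")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_id in expression table: {dupes}")
    if (df["mrna_per_cell"].dropna() < 0).any():
        raise ValueError("negative mRNA abundance in expression table")
    return df.set_index("gene_id")


def read_trna_table(
    path, table: CodonTable | None = None
) -> tuple[CodonTable, dict[str, float], dict[str, UsageVector]]:
    """tRNA table TSV: trna_id, amino_acid, gene_copies, codons (comma-sep).

    Returns (codon table with the file's codon->tRNA assignment, gene
    copies per tRNA species, per-family tRNA fractions q keyed by the
    assigned codons).
    """
    df = _read_tsv(path)
    need = {"trna_id", "amino_acid", "gene_copies", "codons"}
    if not need <= set(df.columns):
        raise ValueError(f"tRNA table needs columns {sorted(need)}")
    if df["trna_id"].duplicated().any():
        raise ValueError("duplicate trna_id in tRNA table")
    codon_to_trna: dict[str, str] = {}
    copies: dict[str, float] = {}
    for _, row in df.iterrows():
        n = float(row["gene_copies"])
        if n < 0:
            raise ValueError(f"{row['trna_id']}: negative gene copies")
        copies[row["trna_id"]] = n
        for codon in str(row["codons"]).split(","):
            codon = codon.strip().upper()
            if codon not in _SENSE:
                raise ValueError(f"{row['trna_id']}: unknown codon {codon!r}")
            if codon in codon_to_trna:
                raise ValueError(f"codon {codon} assigned to two tRNA species")
            codon_to_trna[codon] = row["trna_id"]
    base = table or CodonTable.standard()
    full = CodonTable(codon_to_aa=dict(base.codon_to_aa), codon_to_trna=codon_to_trna)
    q: dict[str, UsageVector] = {}
    for aa, by_trna in full.trna_families().items():
        fam_copies = {t: copies[t] for t in by_trna}
        total = sum(fam_copies.values())
        if total > 0 and len(by_trna) >= 1:
            q[aa] = UsageVector(
                {t: c / total for t, c in fam_copies.items()},
                scope=f"trna-family:{aa}",
            )
    return full, copies, q


def read_placements(path) -> list[FootprintPlacement]:
    """Placement TSV: gene_id, read_start_0based, read_length, n_ambiguous."""
    df = _read_tsv(path)
    need = {"gene_id", "read_start_0based", "read_length", "n_ambiguous"}
    if not need <= set(df.columns):
        raise ValueError(f"placement table needs columns {sorted(need)}")
    return [
        FootprintPlacement(
            gene_id=row.gene_id,
            start=int(row.read_start_0based),
            length=int(row.read_length),
            n_ambiguous=int(row.n_ambiguous),
        )
        for row in df.itertuples()
    ]


def read_counts(path, genes: GeneSet) -> CodonCountMatrix:
    """Pre-tabulated counts TSV: gene_id, codon, footprint_count, mrna_count."""
    df = _read_tsv(path)
    need = {"gene_id", "codon", "footprint_count", "mrna_count"}
    if not need <= set(df.columns):
        raise ValueError(f"counts table needs columns {sorted(need)}")
    if (df[["footprint_count", "mrna_count"]] < 0).any().any():
        raise ValueError("negative counts in counts table")
    fp: dict[str, dict[str, float]] = {}
    mr: dict[str, dict[str, float]] = {}
    for row in df.itertuples():
        codon = str(row.codon).upper()
        if codon not in _SENSE:
            raise ValueError(f"{row.gene_id}: unknown codon {codon!r}")
        fp.setdefault(row.gene_id, {})
        mr.setdefault(row.gene_id, {})
        fp[row.gene_id][codon] = fp[row.gene_id].get(codon, 0.0) + row.footprint_count
        mr[row.gene_id][codon] = mr[row.gene_id].get(codon, 0.0) + row.mrna_count
    return CodonCountMatrix.from_gene_counts(fp, mr, genes)


def _write_with_preamble(df: pd.DataFrame, path, preamble: list[str]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in preamble:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_cst_table(est: CSTEstimate, table: CodonTable, path) -> None:
    """codon, amino_acid, cst (max = 1), se, n_boot."""
    df = pd.DataFrame(
        {
            "codon": list(est.codons),
            "amino_acid": [table.aa_of(c) for c in est.codons],
            "cst": est.cst,
            "se": est.se if est.se is not None else np.nan,
            "n_boot": est.se_n if est.se_n is not None else 0,
        }
    )
    _write_with_preamble(
        df,
        path,
        [
            "relative codon selection times, maximum rescaled to 1",
            "se: gene-bootstrap standard error (unit-geometric-mean "
            "normalization, mapped to the max=1 scale)",
        ],
    )


def write_gene_table(est: CSTEstimate, path) -> None:
    """gene_id, R (initiation rate), e (codons/time), d (ribosomes/codon)."""
    df = pd.DataFrame(
        {"gene_id": est.gene_ids, "R": est.R, "e": est.e, "d": est.d}
    )
    _write_with_preamble(
        df,
        path,
        ["per-gene relative translation parameters: R = d * e"],
    )
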