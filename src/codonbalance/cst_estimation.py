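"""Codon selection time (CST) estimation from ribosome profiling data.

The A site of an elongating ribosome dwells on a codon for a time
proportional to how long it takes to capture the cognate ternary
complex. In a snapshot of ribosome-protected footprints, the frequency
with which a codon is observed at the A site is therefore proportional
to how often it is translated times its selection time. Dividing the
observed A-site codon frequency (footprint data) by the expected
frequency under equal selection times (mRNA-Seq codon frequency,
weighted by per-gene translational initiation rates) yields the
relative CST of each sense codon.

Initiation rates are themselves unknown, so the estimator iterates:
starting from R_j = 1 for every gene, it computes CSTs, derives each
gene's elongation rate e_j (codons per unit time, from its codon
composition and the CSTs), its ribosome density d_j (footprint density
over mRNA-Seq density), updates R_j = d_j * e_j, and repeats. The
estimates converge within a few iterations and are insensitive to the
initial R.

All CSTs are relative; the maximum observed value is rescaled to 1.

Footprint reads are reduced to A-site codon counts beforehand: only
28-nt reads with no ambiguous bases are used, nucleotides 16-18 of the
read (1-based) are taken as the A site, and only in-frame assignments
are kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from codonbalance.accuracy_odds import mantel_haenszel
from codonbalance.codon_metrics import RSCUTable
from codonbalance.genetic_code import SENSE_CODONS, GeneSet, warn_data

__all__ = [
    "READ_LENGTH",
    "ASITE_OFFSET_NT",
    "FootprintPlacement",
    "PlacementStats",
    "CodonCountMatrix",
    "CSTEstimate",
    "extract_asite_counts",
    "estimate_cst",
    "bootstrap_cst",
    "position_rscu_profile",
    "asite_preference_ratio",
]

READ_LENGTH = 28
#: 0-based nt offset of the A-site codon within a footprint read
#: (read positions 16-18, 1-based).
ASITE_OFFSET_NT = 15
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


@dataclass(frozen=True)
class FootprintPlacement:
    """One sequencing read placed on a CDS.

    ``start`` is the 0-based nucleotide offset of the read's first base
    within the CDS; ``length`` the read length in nt; ``n_ambiguous``
    the number of ambiguous base calls in the read.
    """

    gene_id: str
    start: int
    length: int = READ_LENGTH
    n_ambiguous: int = 0


@dataclass
class PlacementStats:
    """Bookkeeping of why placements were kept or dropped."""

    used: int = 0
    wrong_length: int = 0
    ambiguous: int = 0
    out_of_frame: int = 0
    past_end: int = 0
    unknown_gene: int = 0

    @property
    def total(self) -> int:
        return (
            self.used
            + self.wrong_length
            + self.ambiguous
            + self.out_of_frame
            + self.past_end
            + self.unknown_gene
        )

    @property
    def in_frame_fraction(self) -> float:
        frame_assessed = self.used + self.out_of_frame
        return self.used / frame_assessed if frame_assessed else float("nan")


def _asite_codon_index(placement: FootprintPlacement) -> int | None:
    """0-based codon index covered by read nt 16-18, or None if out of frame."""
    nt = placement.start + ASITE_OFFSET_NT
    if nt % 3 != 0:
        return None
    return nt // 3


def extract_asite_counts(
    placements, genes: GeneSet
) -> tuple[dict[str, dict[str, int]], PlacementStats]:
    """Tally A-site codons per gene from footprint placements.

    A placement is used only if it is exactly 28 nt, has no ambiguous
    bases, lies fully within the CDS, and its nt 16-18 fall in frame 0.
    Returns (per-gene codon counts, drop statistics).
    """
    counts: dict[str, dict[str, int]] = {}
    stats = PlacementStats()
    for pl in placements:
        if pl.gene_id not in genes:
            stats.unknown_gene += 1
            continue
        if pl.length != READ_LENGTH:
            stats.wrong_length += 1
            continue
        if pl.n_ambiguous != 0:
            stats.ambiguous += 1
            continue
        gene = genes[pl.gene_id]
        if pl.start < 0 or pl.start + pl.length > 3 * len(gene):
            stats.past_end += 1
            continue
        idx = _asite_codon_index(pl)
        if idx is None:
            stats.out_of_frame += 1
            continue
        codon = gene.codons[idx]
        gene_counts = counts.setdefault(pl.gene_id, {})
        gene_counts[codon] = gene_counts.get(codon, 0) + 1
        stats.used += 1
    return counts, stats


@dataclass
class CodonCountMatrix:
    """Paired footprint and mRNA-Seq codon counts per gene.

    ``footprint[j, i]`` (c_ij) counts codon i at the A site in gene j;
    ``mrna[j, i]`` (C_ij) counts codon i in the gene's mRNA-Seq reads;
    ``lengths[j]`` (L_j) is the gene's length in codons. ``composition``
    (D_ij, codons per mRNA molecule) defaults to the mRNA-Seq counts
    scaled to sum to L_j per gene, which is exact when mRNA-Seq coverage
    is uniform within genes.
    """

    gene_ids: list[str]
    footprint: np.ndarray
    mrna: np.ndarray
    lengths: np.ndarray
    codons: tuple[str, ...] = SENSE_CODONS
    composition: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.footprint = np.asarray(self.footprint, float)
        self.mrna = np.asarray(self.mrna, float)
        self.lengths = np.asarray(self.lengths, float)
        g, k = self.footprint.shape
        if self.mrna.shape != (g, k) or len(self.gene_ids) != g:
            raise ValueError("footprint/mrna/gene_ids shapes disagree")
        if len(self.codons) != k:
            raise ValueError("codon axis length mismatch")
        if (self.footprint < 0).any() or (self.mrna < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_gene_counts(
        cls,
        footprint_counts: dict[str, dict[str, float]],
        mrna_counts: dict[str, dict[str, float]],
        genes: GeneSet,
        exclude_flags: tuple[str, ...] = ("transposon", "uncharacterized"),
    ) -> "CodonCountMatrix":
        """Assemble the matrix from per-gene codon-count dicts.

        Genes carrying any of ``exclude_flags`` are dropped; so are
        genes present in only one of the two datasets.
        """
        usable = [
            g.id
            for g in genes.without_flags(*exclude_flags)
            if g.id in footprint_counts and g.id in mrna_counts
        ]
        if not usable:
            raise ValueError("no genes with both footprint and mRNA counts")
        fp = np.zeros((len(usable), len(SENSE_CODONS)))
        mr = np.zeros_like(fp)
        lengths = np.zeros(len(usable))
        for j, gid in enumerate(usable):
            lengths[j] = len(genes[gid])
            for codon, n in footprint_counts[gid].items():
                fp[j, _CODON_INDEX[codon]] = n
            for codon, n in mrna_counts[gid].items():
                mr[j, _CODON_INDEX[codon]] = n
        return cls(gene_ids=usable, footprint=fp, mrna=mr, lengths=lengths)

    def subset(self, indices) -> "CodonCountMatrix":
        indices = np.asarray(indices)
        return CodonCountMatrix(
            gene_ids=[self.gene_ids[i] for i in indices],
            footprint=self.footprint[indices],
            mrna=self.mrna[indices],
            lengths=self.lengths[indices],
            codons=self.codons,
            composition=None
            if self.composition is None
            else self.composition[indices],
        )


@dataclass
class CSTEstimate:
    """Relative codon selection times with per-gene translation parameters.

    ``cst`` is rescaled so the maximum defined value is 1; codons never
    observed in the expected-frequency denominator are NaN and listed in
    ``missing``. ``R`` (initiation rate), ``e`` (elongation rate,
    codons/time), and ``d`` (ribosomes/codon) are per-gene relative
    values.
    """

    codons: tuple[str, ...]
    cst: np.ndarray
    gene_ids: list[str]
    R: np.ndarray
    e: np.ndarray
    d: np.ndarray
    iterations: int
    converged: bool
    missing: tuple[str, ...] = ()
    se: np.ndarray | None = None
    se_n: np.ndarray | None = None

    def as_series(self) -> pd.Series:
        return pd.Series(self.cst, index=list(self.codons), name="cst")


def _prepare(counts: CodonCountMatrix):
    fp_tot = counts.footprint.sum(axis=1)
    mr_tot = counts.mrna.sum(axis=1)
    keep = (fp_tot > 0) & (mr_tot > 0)
    if not keep.all():
        dropped = [g for g, k in zip(counts.gene_ids, keep) if not k]
        warn_data(f"excluding {len(dropped)} genes with all-zero counts")
    if not keep.any():
        raise ValueError("no gene has nonzero footprint and mRNA counts")
    idx = np.flatnonzero(keep)
    sub = counts.subset(idx)
    if counts.composition is not None:
        D = counts.composition[idx]
    else:
        D = sub.mrna / sub.mrna.sum(axis=1, keepdims=True) * sub.lengths[:, None]
    return sub, D


def estimate_cst(
    counts: CodonCountMatrix,
    initial_R: np.ndarray | dict[str, float] | None = None,
    iterations: int = 10,
    tol: float = 1e-8,
) -> CSTEstimate:
    """Iteratively estimate relative CSTs and per-gene initiation rates.

    Per iteration: observed A-site codon frequencies f_i are compared
    with expected frequencies F_i (mRNA-Seq codon counts weighted by
    current initiation rates R_j); CST_i = f_i / F_i; per-gene
    elongation rates e_j and ribosome densities d_j then update
    R_j = d_j * e_j. Runs ``iterations`` times (default 10) with early
    stop when the maximum relative CST change drops below ``tol``.
    """
    sub, D = _prepare(counts)
    g = len(sub.gene_ids)
    if initial_R is None:
        R = np.ones(g)
    elif isinstance(initial_R, dict):
        R = np.array([initial_R[gid] for gid in sub.gene_ids], float)
    else:
        R = np.asarray(initial_R, float)
        if R.shape != (g,):
            # caller may have passed values for the pre-filter gene list
            full = np.asarray(initial_R, float)
            if full.shape == (len(counts.gene_ids),):
                keep = [counts.gene_ids.index(gid) for gid in sub.gene_ids]
                R = full[keep]
            else:
                raise ValueError("initial_R has wrong length")
    if (R <= 0).any():
        raise ValueError("initial_R must be positive")

    f = sub.footprint.sum(axis=0)
    f = f / f.sum()
    cst = np.full(len(sub.codons), np.nan)
    converged = False
    it_done = 0
    for it in range(1, iterations + 1):
        weighted = (R[:, None] * sub.mrna).sum(axis=0)
        F = weighted / weighted.sum()
        new = np.full_like(cst, np.nan)
        defined = F > 0
        new[defined] = f[defined] / F[defined]
        # elongation rate: codons per unit time, from codon composition
        # and CSTs; codons with undefined CST are dropped from both sums
        use = defined & np.isfinite(new)
        denom = D[:, use] @ new[use]
        numer = D[:, use].sum(axis=1)
        e = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), np.nan)
        d = sub.footprint.sum(axis=1) / sub.mrna.sum(axis=1)
        R = d * e
        R = R / R.mean()
        prev, cst = cst, new
        it_done = it
        both = np.isfinite(prev) & np.isfinite(cst) & (np.abs(prev) > 0)
        if both.any():
            delta = np.max(np.abs(cst[both] - prev[both]) / np.abs(prev[both]))
            if delta < tol:
                converged = True
                break

    missing = tuple(
        c for c, v in zip(sub.codons, cst) if not np.isfinite(v)
    )
    if missing:
        warn_data(f"CST undefined for {len(missing)} codons: {missing[:5]}...")
    positive = np.isfinite(cst) & (cst > 0)
    if positive.any():
        scaled = cst / cst[positive].max()
    else:
        # pathologically sparse input: nothing to rescale against
        warn_data("no codon has a positive CST estimate; returning unscaled")
        scaled = cst
    return CSTEstimate(
        codons=sub.codons,
        cst=scaled,
        gene_ids=sub.gene_ids,
        R=R,
        e=e,
        d=d,
        iterations=it_done,
        converged=converged,
        missing=missing,
    )


def bootstrap_cst(
    counts: CodonCountMatrix,
    replicates: int = 1000,
    seed: int | None = None,
    iterations: int = 10,
    tol: float = 1e-8,
) -> CSTEstimate:
    """Gene-bootstrap standard errors for the CST estimates.

    Genes are resampled with replacement ``replicates`` times and the
    estimator re-run. Each replicate's CST vector is normalized to unit
    geometric mean (over its defined codons) before taking per-codon
    standard deviations; the SDs are then mapped onto the max = 1 scale
    of the point estimate. Codons undefined in a replicate contribute no
    value there; ``se_n`` records how many replicates informed each SE.
    """
    if len(counts.gene_ids) < 2:
        raise ValueError("bootstrap requires >= 2 genes")
    point = estimate_cst(counts, iterations=iterations, tol=tol)
    rng = np.random.default_rng(seed)
    g = len(counts.gene_ids)
    k = len(counts.codons)
    reps = np.full((replicates, k), np.nan)
    for b in range(replicates):
        idx = rng.integers(0, g, size=g)
        try:
            est = estimate_cst(counts.subset(idx), iterations=iterations, tol=tol)
        except ValueError:
            continue
        v = est.cst.copy()
        ok = np.isfinite(v) & (v > 0)
        if not ok.any():
            continue
        geo = math.exp(float(np.mean(np.log(v[ok]))))
        v[~ok] = np.nan
        reps[b] = v / geo
    se_n = np.sum(np.isfinite(reps), axis=0)
    with np.errstate(invalid="ignore"):
        sd_geo = np.nanstd(reps, axis=0, ddof=1)
    # the point estimate is on a max=1 scale; its unit-geometric-mean
    # version differs by the constant factor geomean/max
    ok = np.isfinite(point.cst) & (point.cst > 0)
    geo_point = math.exp(float(np.mean(np.log(point.cst[ok]))))
    point.se = sd_geo * geo_point
    point.se_n = se_n
    return point


def _read_codons(placement: FootprintPlacement, genes: GeneSet):
    """Codons fully covered by an in-frame usable 28-nt read (9 codons)."""
    gene = genes[placement.gene_id]
    first = placement.start // 3
    n = placement.length // 3
    return gene.codons[first : first + n]


def position_rscu_profile(
    placements,
    mrna_placements,
    genes: GeneSet,
    rscu_table: RSCUTable,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Ratio of geometric-mean RSCU' (footprint / mRNA reads) per read codon slot.

    For every usable in-frame read, the codons at read slots 1..9 (nt
    1-3, ..., 25-27; slot 6 is the A site) contribute their RSCU'.
    Positions in single-codon families are excluded, as in CAI. The
    per-slot ratio of geometric means is returned with bootstrap (over
    reads) standard errors. A flat profile (~1 everywhere) means A-site
    codon composition is not depleted of preferred codons relative to
    the read background.
    """

    def usable(pls):
        out = []
        for pl in pls:
            if (
                pl.length == READ_LENGTH
                and pl.n_ambiguous == 0
                and pl.gene_id in genes
                and pl.start >= 0
                and pl.start + pl.length <= 3 * len(genes[pl.gene_id])
                and (pl.start + ASITE_OFFSET_NT) % 3 == 0
            ):
                out.append(pl)
        return out

    n_slots = READ_LENGTH // 3

    def log_matrix(pls) -> np.ndarray:
        """reads x slots matrix of log RSCU' (NaN where uninformative)."""
        m = np.full((len(pls), n_slots), np.nan)
        for r, pl in enumerate(pls):
            for s, codon in enumerate(_read_codons(pl, genes)):
                prime = rscu_table.rscu_prime.get(codon)
                aa = rscu_table.table.aa_of(codon)
                if prime is None or prime <= 0:
                    continue
                if len(rscu_table.table.families[aa]) < 2:
                    continue
                m[r, s] = math.log(prime)
        return m

    fp = log_matrix(usable(placements))
    mr = log_matrix(usable(mrna_placements))
    if fp.size == 0 or mr.size == 0:
        raise ValueError("no usable reads in one of the datasets")

    def ratios(fp_m, mr_m):
        with np.errstate(invalid="ignore"):
            return np.exp(np.nanmean(fp_m, axis=0) - np.nanmean(mr_m, axis=0))

    point = ratios(fp, mr)
    rng = np.random.default_rng(seed)
    boots = np.empty((bootstrap_reps, n_slots))
    for b in range(bootstrap_reps):
        fi = rng.integers(0, fp.shape[0], fp.shape[0])
        mi = rng.integers(0, mr.shape[0], mr.shape[0])
        boots[b] = ratios(fp[fi], mr[mi])
    se = np.nanstd(boots, axis=0, ddof=1)
    return pd.DataFrame(
        {
            "read_codon_slot": np.arange(1, n_slots + 1),
            "ratio": point,
            "se": se,
            "is_a_site": np.arange(n_slots) == ASITE_OFFSET_NT // 3,
        }
    )


def asite_preference_ratio(
    counts: CodonCountMatrix, rscu_table: RSCUTable
) -> tuple[float, float, int]:
    """Preferred/unpreferred codon ratio at the A site, mRNA-corrected.

    Within each gene, footprint and mRNA-Seq counts are collapsed to
    preferred vs unpreferred codons (multi-codon families only) and the
    per-gene odds ratios are combined by the Mantel-Haenszel procedure.
    Returns (common ratio, two-tail chi-square P, strata skipped for an
    empty margin). A ratio of 1 means preferred codons dwell at the A
    site no longer and no shorter than unpreferred codons.
    """
    pref_mask = np.array(
        [rscu_table.is_preferred(c) for c in counts.codons]
    )
    multi_mask = np.array(
        [
            len(rscu_table.table.family_of(c)) >= 2 and c in rscu_table.rscu
            for c in counts.codons
        ]
    )
    unpref_mask = multi_mask & ~pref_mask
    pref_mask = multi_mask & pref_mask
    strata = []
    skipped = 0
    for j in range(len(counts.gene_ids)):
        a = counts.footprint[j, pref_mask].sum()
        b = counts.footprint[j, unpref_mask].sum()
        c = counts.mrna[j, pref_mask].sum()
        d = counts.mrna[j, unpref_mask].sum()
        t = np.array([[a, b], [c, d]])
        if min(a + b, c + d, a + c, b + d) == 0:
            skipped += 1
            continue
        strata.append(t)
    if not strata:
        raise ValueError("no informative gene stratum")
    ratio, p = mantel_haenszel(strata)
    return ratio, p, skipped
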