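"""Tests of codon/amino-acid usage against tRNA pools.

Three candidate rules relate the relative usage p_i of synonymous codons
to the relative concentrations q_i of their cognate isoaccepting tRNAs:

* proportional rule: p_i = q_i (the efficiency optimum when available
  ternary complexes are scarce: every codon then sees the same local
  cognate-tRNA concentration, and expected selection time is minimal);
* square rule: p_i proportional to q_i**2 (the optimum for tRNA pools
  adapting to a fixed codon usage without shortage);
* truncation rule: exclusive use of the codon whose cognate tRNA is
  most abundant (the optimum for codon usage adapting to fixed tRNA
  pools without shortage).

Observed usage is compared to each rule's prediction by Euclidian or
Manhattan distance; significance comes from a Monte-Carlo null that
draws usage vectors flat on each family's simplex, in either direction
(random codon usage against the fixed prediction, or the fixed observed
usage against predictions from random tRNA fractions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from codonbalance.genetic_code import UsageVector, warn_data

__all__ = [
    "RULES",
    "predict_usage",
    "expected_selection_time",
    "optimal_usage_numeric",
    "NullTestResult",
    "null_distance_test",
    "rule_likelihood",
    "trna_availability_correlation",
    "synonymous_correlation_sign_test",
]

RULES = ("proportional", "square", "truncation")


def _predict_array(q: np.ndarray, rule: str) -> np.ndarray:
    """Rule prediction for fraction array(s) q; vectorized over leading axes."""
    if rule == "proportional":
        return q.copy()
    if rule == "square":
        sq = q**2
        return sq / sq.sum(axis=-1, keepdims=True)
    if rule == "truncation":
        out = np.zeros_like(q)
        # argmax returns the first (lexicographically smallest index) on ties
        idx = np.argmax(q, axis=-1)
        np.put_along_axis(out, np.expand_dims(idx, -1), 1.0, axis=-1)
        return out
    raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")


def predict_usage(q: UsageVector, rule: str) -> UsageVector:
    """Predicted codon usage for one synonymous family under a rule.

    Items are processed in sorted key order, so a truncation tie between
    equally abundant tRNAs resolves to the lexicographically first item
    (a warning flags the tie).
    """
    keys = sorted(q.values)
    arr = np.array([q[k] for k in keys], float)
    if rule == "truncation" and (arr == arr.max()).sum() > 1:
        warn_data(f"truncation tie among {keys}; lexicographic tie-break")
    pred = _predict_array(arr, rule)
    return UsageVector(dict(zip(keys, pred.tolist())), scope=q.scope)


def expected_selection_time(p: UsageVector, q: UsageVector) -> float:
    """Expected codon selection time sum_i p_i^2 / q_i, in units of b/a.

    Under shortage the local concentration of tRNA i scales as q_i/p_i,
    so codon i is selected in time proportional to p_i/q_i and the
    usage-weighted mean is sum p_i^2/q_i, minimized at p = q with value 1.
    A codon used (p_i > 0) without any cognate tRNA (q_i = 0) takes
    infinite time.
    """
    if set(p.values) != set(q.values):
        raise ValueError("p and q cover different item sets")
    t = 0.0
    for k, pk in p.items():
        if pk == 0.0:
            continue
        qk = q[k]
        if qk == 0.0:
            warn_data(f"item {k!r} used with zero tRNA fraction: infinite time")
            return math.inf
        t += pk * pk / qk
    return t


def optimal_usage_numeric(q: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Numerically minimize sum p_i^2/q_i over the probability simplex.

    Independent check (sequential quadratic programming from the uniform
    start) of the analytic optimum p = q.
    """
    q = np.asarray(q, float)
    k = q.size
    res = optimize.minimize(
        lambda p: float(np.sum(p**2 / q)),
        x0=np.full(k, 1.0 / k),
        jac=lambda p: 2.0 * p / q,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0}],
        options={"ftol": tol, "maxiter": 500},
    )
    if not res.success:
        raise RuntimeError(f"simplex minimization failed: {res.message}")
    return res.x


def _simplex_sample(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """n draws flat on the (k-1)-simplex (normalized iid exponentials)."""
    e = rng.standard_exponential((n, k))
    return e / e.sum(axis=1, keepdims=True)


def _distances(samples: np.ndarray, target: np.ndarray, metric: str) -> np.ndarray:
    diff = samples - target
    if metric == "euclidian":
        return np.sqrt(np.sum(diff**2, axis=-1))
    if metric == "manhattan":
        return np.sum(np.abs(diff), axis=-1)
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class NullTestResult:
    """Aggregate Monte-Carlo null test over synonymous families.

    ``statistic`` is the sum over families of the distance between the
    observed usage and the rule's prediction; ``p_value`` the fraction
    of null replicates whose statistic is *smaller* than observed (small
    p means the observation is closer to the rule than chance).
    """

    statistic: float
    p_value: float
    replicates: int
    direction: str
    samples: np.ndarray
    per_family: dict[str, tuple[float, float]]
    seed: int | None = None


def null_distance_test(
    observed: dict[str, UsageVector],
    q: dict[str, UsageVector],
    rule: str = "proportional",
    metric: str = "euclidian",
    replicates: int = 1_000_000,
    seed: int | None = None,
    direction: str = "codon",
) -> NullTestResult:
    """Is observed usage closer to a rule's prediction than chance?

    direction="codon": null replicates draw each family's codon usage
    flat on its simplex and measure their distance to the prediction
    computed from the observed tRNA fractions. direction="trna": the
    observed usage is fixed and tRNA fractions are drawn flat on the
    simplex, predictions recomputed per draw. The test statistic sums
    the per-family distances; per-family distances and p-values are also
    reported.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if set(observed) != set(q):
        raise ValueError("observed and q cover different families")
    rng = np.random.default_rng(seed)
    total_obs = 0.0
    total_null = np.zeros(replicates)
    per_family: dict[str, tuple[float, float]] = {}
    for fam in sorted(observed):
        keys = sorted(observed[fam].values)
        if set(q[fam].values) != set(keys):
            raise ValueError(f"family {fam}: observed/q item mismatch")
        obs = np.array([observed[fam][k] for k in keys])
        qv = np.array([q[fam][k] for k in keys])
        k = len(keys)
        if direction == "codon":
            pred = _predict_array(qv, rule)
            d_obs = float(_distances(obs, pred, metric))
            d_null = _distances(_simplex_sample(rng, replicates, k), pred, metric)
        elif direction == "trna":
            pred = _predict_array(qv, rule)
            d_obs = float(_distances(obs, pred, metric))
            rand_pred = _predict_array(_simplex_sample(rng, replicates, k), rule)
            d_null = _distances(rand_pred, obs, metric)
        else:
            raise ValueError("direction must be 'codon' or 'trna'")
        total_obs += d_obs
        total_null += d_null
        per_family[fam] = (d_obs, float(np.mean(d_null < d_obs)))
    p = float(np.mean(total_null < total_obs))
    return NullTestResult(
        statistic=total_obs,
        p_value=p,
        replicates=replicates,
        direction=direction,
        samples=total_null,
        per_family=per_family,
        seed=seed,
    )


def rule_likelihood(
    observed_counts: dict[str, dict[str, float]],
    q: dict[str, UsageVector],
    rule_a: str = "proportional",
    rule_b: str = "square",
    effective_total: float | None = 10_000.0,
) -> float:
    """log10 likelihood ratio of rule_a over rule_b given observed counts.

    Counts (possibly real-valued, e.g. expression-weighted) are modelled
    as multinomial within each family under each rule's predicted
    frequencies; family log-likelihoods add. A rule that assigns zero
    frequency to an observed codon (the truncation rule does, for every
    non-modal codon) has likelihood zero, giving a ratio of +/- inf.

    ``effective_total`` rescales the counts to a fixed overall total
    (preserving proportions) so that the magnitude of the ratio does not
    depend on arbitrary count units; pass None to use raw counts.
    """
    total = sum(sum(d.values()) for d in observed_counts.values())
    if total <= 0:
        raise ValueError("observed counts are all zero")
    scale = 1.0 if effective_total is None else effective_total / total

    def loglik(rule: str) -> float:
        ll = 0.0
        for fam in sorted(observed_counts):
            keys = sorted(observed_counts[fam])
            x = np.array([observed_counts[fam][k] for k in keys], float) * scale
            qv = np.array([q[fam][k] for k in keys], float)
            pred = _predict_array(qv, rule)
            used = x > 0
            if np.any(pred[used] == 0):
                return -math.inf
            # real-valued multinomial log-likelihood via log-gamma
            n = x.sum()
            ll += math.lgamma(n + 1.0) - float(
                np.sum([math.lgamma(v + 1.0) for v in x])
            )
            ll += float(np.sum(x[used] * np.log(pred[used])))
        return ll

    la, lb = loglik(rule_a), loglik(rule_b)
    if la == -math.inf and lb == -math.inf:
        raise ValueError("both rules have zero likelihood")
    if lb == -math.inf:
        return math.inf
    if la == -math.inf:
        return -math.inf
    return (la - lb) / math.log(10.0)


def trna_availability_correlation(
    aa_freq: dict[str, float],
    trna_copies: dict[str, float],
    mean_cst: dict[str, float],
    permutations: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Correlation of per-amino-acid tRNA availability with mean CST.

    Availability of an amino acid = (its fraction of all tRNA gene
    copies) / (its frequency in the transcriptome). Under shortage,
    amino acids with scarcer cognate tRNA should be selected more
    slowly, so availability and mean CST should correlate negatively.
    Returns (Pearson r, one-tail permutation P for negative correlation)
    with P = (1 + #{permuted r <= observed r}) / (1 + permutations).
    """
    aas = sorted(set(aa_freq) & set(trna_copies) & set(mean_cst))
    zero = [a for a in aas if aa_freq[a] == 0]
    if zero:
        warn_data(f"amino acids with zero frequency excluded: {zero}")
        aas = [a for a in aas if a not in zero]
    total_copies = sum(trna_copies[a] for a in aas)
    avail = np.array([trna_copies[a] / total_copies / aa_freq[a] for a in aas])
    cst = np.array([mean_cst[a] for a in aas])
    if np.ptp(cst) == 0 or np.ptp(avail) == 0:
        raise ValueError("correlation undefined: zero variance")
    r = float(stats.pearsonr(avail, cst).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        rp = float(stats.pearsonr(avail, rng.permutation(cst)).statistic)
        if rp <= r:
            hits += 1
    p = (1 + hits) / (1 + permutations)
    return r, p


def synonymous_correlation_sign_test(per_aa_signs: dict[str, float]) -> float:
    """One-tail sign test for an excess of negative per-amino-acid correlations.

    Input maps each multi-codon amino acid to the sign (or value) of its
    within-family usage/CST correlation; zeros are excluded with a
    warning. Returns P(X >= observed negatives | n, 1/2).
    """
    signs = dict(per_aa_signs)
    zeros = [a for a, s in signs.items() if s == 0]
    if zeros:
        warn_data(f"zero-valued correlations excluded from sign test: {zeros}")
        for a in zeros:
            del signs[a]
    n = len(signs)
    if n == 0:
        raise ValueError("no nonzero correlations to test")
    negatives = sum(1 for s in signs.values() if s < 0)
    return float(stats.binom.sf(negatives - 1, n, 0.5))
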