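"""Resampling inference: permutation tests, Monte-Carlo Hardy-Weinberg
exact tests, Mann-Whitney U, FDR control and a bootstrapped two-sample
Kolmogorov-Smirnov test.

All resampling p-values use +1 smoothing, ``p = (count + 1) / (B + 1)``,
so p is never exactly zero and is bit-reproducible given (seed, B).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

_EPS = 1e-12


# -- permutation test -----------------------------------------------------

@dataclass
class PermutationResult:
    statistic: str
    observed: float
    n_permutations: int
    p: float
    adjusted_p: float | None = None
    seed: int | None = None


def permute_diff(
    values_a, values_b, B: int = 10_000, seed: int | None = None,
    exact: bool = False,
) -> PermutationResult:
    """Two-sided permutation test for a difference in group means.

    Group labels are permuted jointly B times; ``p = (#{|d*| >= |d|} + 1)
    / (B + 1)``.  With all values identical every permuted difference ties
    the observed one and p = 1.  With ``exact=True`` all C(n, n_a)
    assignments are enumerated instead and p is the exact tail fraction
    (no smoothing; small n only).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n_a, n = a.size, pooled.size
    if exact:
        from itertools import combinations
        from math import comb as _comb

        if _comb(n, n_a) > 200_000:
            raise ValueError("exact enumeration is limited to small samples")
        count = total = 0
        for idx in combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            d = pooled[mask].mean() - pooled[~mask].mean()
            count += abs(d) >= abs(obs) - _EPS
            total += 1
        return PermutationResult(
            statistic="mean_difference", observed=float(obs),
            n_permutations=total, p=count / total, seed=None,
        )
    # mean difference depends only on which entries land in group a
    perms = rng.permuted(np.tile(pooled, (B, 1)), axis=1)
    mean_a = perms[:, :n_a].mean(axis=1)
    mean_b = perms[:, n_a:].mean(axis=1)
    diffs = mean_a - mean_b
    count = int((np.abs(diffs) >= abs(obs) - _EPS).sum())
    return PermutationResult(
        statistic="mean_difference", observed=float(obs),
        n_permutations=B, p=(count + 1) / (B + 1), seed=seed,
    )


def permute_stat(
    items_a, items_b, stat_fn, B: int = 10_000, seed: int | None = None,
    statistic: str = "stat_difference",
) -> PermutationResult:
    """Permutation test for an arbitrary two-group statistic.

    ``stat_fn(group_a, group_b)`` receives two sequences of items (e.g.
    sample indices) and returns a scalar; items are permuted between the
    groups, preserving group sizes.  Used for statistics that must be
    recomputed per permutation (gene diversity, allelic richness, theta),
    so within-individual dependence is preserved.
    """
    items_a = list(items_a)
    items_b = list(items_b)
    if not items_a or not items_b:
        raise ValueError("both groups must be non-empty")
    obs = float(stat_fn(items_a, items_b))
    pooled = items_a + items_b
    n_a = len(items_a)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        perm = rng.permutation(len(pooled))
        ga = [pooled[i] for i in perm[:n_a]]
        gb = [pooled[i] for i in perm[n_a:]]
        if abs(stat_fn(ga, gb)) >= abs(obs) - _EPS:
            count += 1
    return PermutationResult(
        statistic=statistic, observed=obs,
        n_permutations=B, p=(count + 1) / (B + 1), seed=seed,
    )


# -- Hardy-Weinberg exact test (Monte Carlo) ------------------------------

def _log_levene(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Log conditional probability of a genotype configuration given the
    allele counts (Levene 1949): P = n! n_A! n_B! 2^n_AB /
    (n_AA! n_AB! n_BB! (2n)!)."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    return (
        lgamma(n + 1) + lgamma(n_a + 1) + lgamma(n_b + 1) + n_ab * log(2)
        - lgamma(n_aa + 1) - lgamma(n_ab + 1) - lgamma(n_bb + 1)
        - lgamma(2 * n + 1)
    )


def hwe_exact_mc(
    counts: tuple[int, int, int], B: int = 1000, seed: int | None = None,
    criterion: str = "prob",
) -> float:
    """Monte-Carlo exact test for Hardy-Weinberg deviation at one biallelic
    locus.

    ``counts`` are genotype counts (n_AA, n_Aa, n_aa).  The 2n observed
    gene copies are shuffled into diploids B times; with the default
    ``criterion="prob"`` a resample is at least as extreme when its Levene
    conditional probability does not exceed the observed one
    (exact-test convention).  ``criterion="het"`` instead uses distance of
    the heterozygote count from its conditional expectation.
    Monomorphic loci return p = 1.
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    n = n_aa + n_ab + n_bb
    if n < 2:
        raise ValueError("need at least two individuals")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    copies = np.zeros((B, 2 * n), dtype=np.int8)
    copies[:, :n_a] = 1
    copies = rng.permuted(copies, axis=1)
    het_star = (copies[:, ::2] != copies[:, 1::2]).sum(axis=1)
    if criterion == "prob":
        # n_AB determines the configuration given fixed allele counts
        h_values = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
        logp = np.array(
            [_log_levene((n_a - h) // 2, h, (n_b - h) // 2) for h in h_values]
        )
        lookup = dict(zip(h_values.tolist(), logp.tolist()))
        obs_lp = lookup[n_ab]
        star_lp = np.array([lookup[h] for h in het_star.tolist()])
        count = int((star_lp <= obs_lp + _EPS).sum())
    elif criterion == "het":
        e_het = n_a * n_b / (2 * n - 1)
        count = int((np.abs(het_star - e_het) >= abs(n_ab - e_het) - _EPS).sum())
    else:
        raise ValueError("criterion must be 'prob' or 'het'")
    return (count + 1) / (B + 1)


def hwe_screen(
    genotype_counts, B: int = 1000, seed: int | None = None,
    alpha: float = 0.05, fdr: str = "storey",
):
    """HWE test over many loci with multiplicity control.

    ``genotype_counts`` is an iterable of (n_AA, n_Aa, n_aa).  Returns
    (p values, q values, boolean flags marking loci with q < alpha).
    """
    rng = np.random.default_rng(seed)
    p = np.array(
        [
            hwe_exact_mc(c, B=B, seed=int(rng.integers(2**31)))
            for c in genotype_counts
        ]
    )
    q = storey_q(p) if fdr == "storey" else bh_fdr(p)
    return p, q, q < alpha


# -- Mann-Whitney ---------------------------------------------------------

def mann_whitney(values_a, values_b) -> tuple[float, float]:
    """Mann-Whitney U with midranks for ties; two-sided.

    Returns (W, p) where W is the U statistic of the first group, i.e. the
    rank-sum of group a minus n_a(n_a+1)/2, matching the W reported by R's
    ``wilcox.test``.  p is exact (enumeration) for n_a + n_b <= 12 without
    ties, otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


# -- FDR ------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_pi0(p_values, lambdas=(0.5,)) -> float:
    """Estimate the null proportion pi0 from the tail of the p-value
    distribution: ``#{p > lambda} / (m (1 - lambda))``, capped at 1.

    With a single lambda (default 0.5) the plug-in estimate is returned;
    with a grid, per-lambda estimates are smoothed by a cubic polynomial
    evaluated at the largest lambda."""
    p = np.asarray(p_values, dtype=float)
    lam = np.asarray(lambdas, dtype=float)
    m = p.size
    est = np.array([(p > l).sum() / (m * (1 - l)) for l in lam])
    if lam.size == 1:
        pi0 = est[0]
    else:
        coef = np.polyfit(lam, est, deg=min(3, lam.size - 1))
        pi0 = float(np.polyval(coef, lam.max()))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_q(p_values, lambdas=(0.5,), pi0: float | None = None) -> np.ndarray:
    """Storey q-values: ``q_(i) = min_{j>=i} (pi0 * p_(j) * m / j)``.

    ``pi0`` overrides the estimate (``pi0=1`` reduces exactly to
    BH-adjusted p-values).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if pi0 is None:
        pi0 = storey_pi0(p, lambdas)
    return np.minimum(pi0 * bh_fdr(p), 1.0)


# -- bootstrapped Kolmogorov-Smirnov --------------------------------------

@dataclass
class KsBootResult:
    D: float
    p: float
    n_boot: int
    seed: int | None = None
    adjusted_p: float | None = None


def ks_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Classical two-sample sup-distance between empirical CDFs (ties
    allowed; both ECDFs evaluated at the pooled support)."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / a.size
    fb = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(fa - fb).max())


def ks_boot(
    sample_a, sample_b, n_boot: int = 1000, seed: int | None = None
) -> KsBootResult:
    """Bootstrapped two-sample Kolmogorov-Smirnov test.

    The asymptotic KS null distribution is invalid under heavy ties (as in
    folded allele-frequency spectra on a small lattice); instead the null
    distribution of D is built by resampling n_a and n_b values with
    replacement from the pooled sample, and
    ``p = (#{D* >= D} + 1) / (n_boot + 1)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    d_obs = ks_distance(a, b)
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n_a, n = a.size, pooled.size
    count = 0
    for _ in range(n_boot):
        draw = pooled[rng.integers(0, n, size=n)]
        if ks_distance(draw[:n_a], draw[n_a:]) >= d_obs - _EPS:
            count += 1
    return KsBootResult(D=d_obs, p=(count + 1) / (n_boot + 1),
                        n_boot=n_boot, seed=seed)
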