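"""Diversity and differentiation statistics for biallelic SNP matrices.

Implements, from first principles:

* observed heterozygosity per individual and per population;
* Nei gene diversity (expected heterozygosity) with the small-sample
  correction ``Hs = n/(n-1) * (1 - sum(p^2) - Ho/(2n))`` where ``n`` is the
  number of genotyped individuals at the locus, ``p`` the sample allele
  frequencies and ``Ho`` the observed heterozygote fraction;
* rarefied allelic richness ``A_r = sum_i [1 - C(N - N_i, g) / C(N, g)]``
  for a standardized subsample of ``g`` gene copies drawn from ``N``
  genotyped copies with allele counts ``N_i`` (exact hypergeometric
  rarefaction, integer arithmetic);
* private alleles between two populations, with the private allele's
  frequency in its own population;
* the Weir & Cockerham (1984) differentiation estimator theta (F_ST) from
  among-population (a), among-individual (b) and within-individual (c)
  variance components, combined over loci as ``sum(a) / sum(a+b+c)``;
* folded minor-allele-frequency spectra.

Loci are weighted equally in all averages.  Negative theta values are
reported as-is (expected near zero differentiation), never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy.special import gammaln

from museum_popgen.genotypes import MISSING, GenotypeMatrix, population_indices


# -- helpers --------------------------------------------------------------

def _pop_rows(gm: GenotypeMatrix, popmap: pd.DataFrame, population: str) -> np.ndarray:
    groups = population_indices(gm, popmap)
    if population not in groups or len(groups[population]) == 0:
        raise ValueError(f"population {population!r} is empty or unknown")
    return groups[population]


def _locus_counts(gm: GenotypeMatrix, rows: np.ndarray):
    """Per-locus (n genotyped, het count, alt gene copies) over given rows."""
    gt = gm.genotypes[rows]
    called = gt != MISSING
    nn = called.sum(axis=0)
    het = ((gt == 1) & called).sum(axis=0)
    alt = np.where(called, gt, 0).sum(axis=0)
    return nn.astype(np.int64), het.astype(np.int64), alt.astype(np.int64)


# -- observed heterozygosity ----------------------------------------------

def individual_hobs(gm: GenotypeMatrix, sample: str) -> float:
    """Fraction of heterozygous calls among a sample's non-missing calls."""
    i = gm.sample_index(sample)
    gt = gm.genotypes[i]
    called = gt != MISSING
    if not called.any():
        raise ValueError(f"sample {sample!r} has no non-missing calls")
    return float((gt[called] == 1).mean())


def individual_hobs_all(gm: GenotypeMatrix) -> pd.Series:
    """Per-individual observed heterozygosity for every sample with >= 1 call."""
    called = gm.genotypes != MISSING
    n = called.sum(axis=1)
    het = ((gm.genotypes == 1) & called).sum(axis=1)
    with np.errstate(invalid="ignore"):
        vals = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return pd.Series(vals, index=gm.sample_ids, name="H_obs")


# -- gene diversity -------------------------------------------------------

def population_diversity(
    gm: GenotypeMatrix, popmap: pd.DataFrame, population: str
) -> dict:
    """Per-locus and averaged H_obs / H_exp for one population.

    Loci with fewer than two genotyped individuals in the population are
    skipped.  Returns a dict with per-locus arrays (``locus_index``,
    ``h_obs``, ``h_exp``) and equal-weight averages (``mean_h_obs``,
    ``mean_h_exp``).
    """
    rows = _pop_rows(gm, popmap, population)
    nn, het, alt = _locus_counts(gm, rows)
    use = nn >= 2
    n = nn[use].astype(float)
    ho = het[use] / n
    p = alt[use] / (2 * n)
    sum_p2 = p**2 + (1 - p) ** 2
    h_exp = n / (n - 1) * (1 - sum_p2 - ho / (2 * n))
    return {
        "population": population,
        "n_individuals": len(rows),
        "locus_index": np.flatnonzero(use),
        "h_obs": ho,
        "h_exp": h_exp,
        "mean_h_obs": float(ho.mean()) if use.any() else float("nan"),
        "mean_h_exp": float(h_exp.mean()) if use.any() else float("nan"),
    }


# -- rarefied allelic richness --------------------------------------------

def _ar_locus_exact(n_ref: int, n_alt: int, g: int) -> float:
    """Exact per-locus rarefied richness via integer binomials."""
    N = n_ref + n_alt
    total = comb(N, g)
    acc = Fraction(0)
    for ni in (n_ref, n_alt):
        if ni > 0:
            acc += 1 - Fraction(comb(N - ni, g), total)
    return float(acc)


def _ar_mean_float(n_ref: np.ndarray, n_alt: np.ndarray, g: int) -> float:
    """Vectorized float A_r mean over loci (used inside permutation loops)."""
    N = n_ref + n_alt
    use = N >= g
    if not use.any():
        return float("nan")
    N = N[use].astype(float)
    out = np.zeros(use.sum())
    lg_total = gammaln(N + 1) - gammaln(g + 1) - gammaln(N - g + 1)
    for ni in (n_ref[use].astype(float), n_alt[use].astype(float)):
        pos = ni > 0
        M = N[pos] - ni[pos]
        ok = M >= g
        term = np.zeros(pos.sum())
        lg_sub = gammaln(M[ok] + 1) - gammaln(g + 1) - gammaln(M[ok] - g + 1)
        ratio = np.zeros(ok.size)
        ratio[ok] = np.exp(lg_sub - lg_total[pos][ok])
        term = 1.0 - ratio
        out[pos] += term
    return float(out.mean())


def default_rarefaction_size(
    gm: GenotypeMatrix, popmap: pd.DataFrame, populations: list[str] | None = None,
) -> int:
    """Rarefaction size g: smallest number of genotyped gene copies over all
    (population, locus) cells with at least one genotyped individual."""
    groups = population_indices(gm, popmap)
    if populations is not None:
        groups = {k: v for k, v in groups.items() if k in populations}
    mins = []
    for rows in groups.values():
        nn, _, _ = _locus_counts(gm, rows)
        nz = nn[nn > 0]
        if nz.size:
            mins.append(int(nz.min()) * 2)
    if not mins:
        raise ValueError("no genotyped (population, locus) cells")
    return min(mins)


def allelic_richness(
    gm: GenotypeMatrix, popmap: pd.DataFrame, g: int | str | None = None,
    populations: list[str] | None = None,
) -> pd.Series:
    """Per-population rarefied allelic richness (mean over defined loci).

    ``g`` defaults to the smallest genotyped gene-copy count over all
    population x locus cells (rarefaction to the smallest sample).  Loci
    with fewer than ``g`` genotyped copies in a population are skipped for
    that population.  ``g="per-locus"`` rarefies each locus to its own
    smallest per-population copy count instead (loci with an ungenotyped
    population are skipped everywhere in that mode).
    """
    groups = population_indices(gm, popmap)
    if populations is not None:
        groups = {k: groups[k] for k in populations}
    counts = {pop: _locus_counts(gm, rows) for pop, rows in groups.items()}
    if g == "per-locus":
        copies = np.stack([2 * nn for nn, _, _ in counts.values()])
        g_locus = copies.min(axis=0)          # 0 where any pop is ungenotyped
        out = {}
        for pop, (nn, _, alt) in counts.items():
            use = g_locus >= 1
            if not use.any():
                raise ValueError("no locus genotyped in every population")
            vals = [
                _ar_locus_exact(int(2 * nn[j] - alt[j]), int(alt[j]), int(g_locus[j]))
                for j in np.flatnonzero(use)
            ]
            out[pop] = float(np.mean(vals))
        return pd.Series(out, name="A_r(g=per-locus)")
    if g is None:
        g = default_rarefaction_size(gm, popmap, populations=list(groups))
    if g < 1:
        raise ValueError("g must be >= 1")
    out = {}
    for pop, (nn, _, alt) in counts.items():
        N = 2 * nn
        ref = N - alt
        use = N >= g
        if not use.any():
            raise ValueError(f"no locus with >= {g} gene copies in {pop!r}")
        vals = [
            _ar_locus_exact(int(r), int(a), g)
            for r, a in zip(ref[use], alt[use])
        ]
        out[pop] = float(np.mean(vals))
    return pd.Series(out, name=f"A_r(g={g})")


# -- private alleles ------------------------------------------------------

def private_alleles(
    gm: GenotypeMatrix, popmap: pd.DataFrame, pop_a: str, pop_b: str,
    rarefaction_g: int | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Count alleles observed in one population and absent from the other.

    Only loci genotyped (>= 1 non-missing call) in both populations are
    compared.  Returns (count private to a, count private to b, per-locus
    records with the private allele's frequency in its own population).

    With ``rarefaction_g`` set, the rarefied expected private-allele count
    is returned instead (integer counts become expectations): per allele,
    P(present in a subsample of g copies from A) x P(absent in g copies
    from B), summed over loci — the standardized comparison for unequal
    sample sizes.  Loci with fewer than g copies in either population are
    skipped in that mode.
    """
    rows_a = _pop_rows(gm, popmap, pop_a)
    rows_b = _pop_rows(gm, popmap, pop_b)
    nn_a, _, alt_a = _locus_counts(gm, rows_a)
    nn_b, _, alt_b = _locus_counts(gm, rows_b)
    both = (nn_a > 0) & (nn_b > 0)
    if rarefaction_g is not None:
        both &= (2 * nn_a >= rarefaction_g) & (2 * nn_b >= rarefaction_g)
    if not both.any():
        raise ValueError("no loci genotyped in both populations")
    records = []
    for j in np.flatnonzero(both):
        Na, Nb = 2 * nn_a[j], 2 * nn_b[j]
        counts = {
            "ref": (Na - alt_a[j], Nb - alt_b[j]),
            "alt": (alt_a[j], alt_b[j]),
        }
        for allele, (ca, cb) in counts.items():
            if rarefaction_g is None:
                if ca >= 1 and cb == 0:
                    records.append(
                        {"locus_index": j, "allele": allele, "private_to": pop_a,
                         "frequency": ca / Na, "weight": 1.0}
                    )
                elif cb >= 1 and ca == 0:
                    records.append(
                        {"locus_index": j, "allele": allele, "private_to": pop_b,
                         "frequency": cb / Nb, "weight": 1.0}
                    )
            else:
                g = rarefaction_g
                p_in_a = 1 - comb(Na - ca, g) / comb(Na, g)
                p_out_b = comb(Nb - cb, g) / comb(Nb, g)
                p_in_b = 1 - comb(Nb - cb, g) / comb(Nb, g)
                p_out_a = comb(Na - ca, g) / comb(Na, g)
                if ca and (w := p_in_a * p_out_b) > 0:
                    records.append(
                        {"locus_index": j, "allele": allele, "private_to": pop_a,
                         "frequency": ca / Na, "weight": w}
                    )
                if cb and (w := p_in_b * p_out_a) > 0:
                    records.append(
                        {"locus_index": j, "allele": allele, "private_to": pop_b,
                         "frequency": cb / Nb, "weight": w}
                    )
    df = pd.DataFrame(
        records, columns=["locus_index", "allele", "private_to", "frequency", "weight"]
    )
    n_a = float(df.loc[df["private_to"] == pop_a, "weight"].sum()) if len(df) else 0.0
    n_b = float(df.loc[df["private_to"] == pop_b, "weight"].sum()) if len(df) else 0.0
    if rarefaction_g is None:
        n_a, n_b = int(n_a), int(n_b)
    return n_a, n_b, df


# -- Weir-Cockerham theta -------------------------------------------------

@dataclass
class PairwiseFst:
    """Weir-Cockerham theta for one population pair with per-locus variance
    components; ``theta = sum(a) / sum(a + b + c)`` over loci with a
    defined denominator."""

    pop_a: str
    pop_b: str
    theta: float
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    locus_index: np.ndarray
    permutation_p: float | None = None
    adjusted_p: float | None = None


def wc_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
):
    """Per-locus WC84 variance components (a, b, c) for two populations.

    ``n`` = genotyped individuals, ``p`` = alt-allele frequency, ``h`` =
    observed heterozygote fraction; all arrays per locus.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


def wc_theta_from_rows(
    gm: GenotypeMatrix, rows_a: np.ndarray, rows_b: np.ndarray
) -> float:
    """Multi-locus theta for two explicit sample-row sets (permutation core)."""
    nn_a, het_a, alt_a = _locus_counts(gm, rows_a)
    nn_b, het_b, alt_b = _locus_counts(gm, rows_b)
    use = (nn_a >= 2) & (nn_b >= 2)
    if not use.any():
        raise ValueError("no locus with >= 2 genotyped individuals in both groups")
    n1, n2 = nn_a[use].astype(float), nn_b[use].astype(float)
    a, b, c = wc_components(
        n1, alt_a[use] / (2 * n1), het_a[use] / n1,
        n2, alt_b[use] / (2 * n2), het_b[use] / n2,
    )
    denom = a + b + c
    ok = denom != 0
    if not ok.any():
        return float("nan")
    return float(a[ok].sum() / denom[ok].sum())


def wc_theta(
    gm: GenotypeMatrix, popmap: pd.DataFrame, pop_a: str, pop_b: str
) -> PairwiseFst:
    """Weir-Cockerham theta between two populations.

    Loci require >= 2 genotyped individuals in each population; loci with
    zero total variance (a + b + c = 0, e.g. monomorphic and fully
    homozygous) are excluded from the ratio.
    """
    rows_a = _pop_rows(gm, popmap, pop_a)
    rows_b = _pop_rows(gm, popmap, pop_b)
    nn_a, het_a, alt_a = _locus_counts(gm, rows_a)
    nn_b, het_b, alt_b = _locus_counts(gm, rows_b)
    use = (nn_a >= 2) & (nn_b >= 2)
    if not use.any():
        raise ValueError("no locus with >= 2 genotyped individuals per population")
    n1, n2 = nn_a[use].astype(float), nn_b[use].astype(float)
    a, b, c = wc_components(
        n1, alt_a[use] / (2 * n1), het_a[use] / n1,
        n2, alt_b[use] / (2 * n2), het_b[use] / n2,
    )
    denom = a + b + c
    ok = denom != 0
    theta = float(a[ok].sum() / denom[ok].sum()) if ok.any() else float("nan")
    return PairwiseFst(
        pop_a=pop_a, pop_b=pop_b, theta=theta,
        a=a, b=b, c=c, locus_index=np.flatnonzero(use),
    )


# -- minor allele frequencies ---------------------------------------------

@dataclass
class MafDistribution:
    """Folded per-locus minor allele frequencies for one population."""

    population: str
    maf: np.ndarray
    locus_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.maf = np.asarray(self.maf, dtype=float)
        if self.maf.size and (self.maf.min() < 0 or self.maf.max() > 0.5 + 1e-12):
            raise ValueError("minor allele frequencies must lie in [0, 0.5]")


def maf_spectrum(
    gm: GenotypeMatrix, popmap: pd.DataFrame, population: str
) -> MafDistribution:
    """Per-locus alt-allele frequency among non-missing calls, folded to
    [0, 0.5]; loci with zero genotyped individuals are omitted."""
    rows = _pop_rows(gm, popmap, population)
    nn, _, alt = _locus_counts(gm, rows)
    use = nn > 0
    p = alt[use] / (2 * nn[use])
    return MafDistribution(
        population=population,
        maf=np.minimum(p, 1 - p),
        locus_index=np.flatnonzero(use),
    )


# -- summary table --------------------------------------------------------

@dataclass
class DiversityTable:
    """Per-population n / H_obs / H_exp / A_r summary (the temporal-analysis
    headline table) plus the per-individual H_obs vector."""

    table: pd.DataFrame
    g: int
    individual_hobs: pd.Series


def diversity_table(
    gm: GenotypeMatrix, popmap: pd.DataFrame,
    populations: list[str] | None = None, g: int | None = None,
) -> DiversityTable:
    groups = population_indices(gm, popmap)
    pops = populations if populations is not None else sorted(groups)
    if g is None:
        g = default_rarefaction_size(gm, popmap, populations=pops)
    ar = allelic_richness(gm, popmap, g=g, populations=pops)
    rows = []
    for pop in pops:
        d = population_diversity(gm, popmap, pop)
        rows.append(
            {"population": pop, "n": d["n_individuals"],
             "H_obs": d["mean_h_obs"], "H_exp": d["mean_h_exp"],
             "A_r": ar[pop]}
        )
    return DiversityTable(
        table=pd.DataFrame(rows).set_index("population"),
        g=g,
        individual_hobs=individual_hobs_all(gm),
    )
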