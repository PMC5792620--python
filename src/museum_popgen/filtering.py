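"""Post-calling SNP and sample filters for capture data from degraded DNA.

The cascade keeps only high-quality, informative biallelic SNPs.  Stages
run in a fixed, documented order:

1. drop sites with QUAL below ``min_qual``;
2. drop indels;
3. keep biallelic SNPs only;
4. set individual calls with DP below ``min_genotype_depth`` to missing;
5. drop sites whose missing fraction exceeds ``max_site_missing_fraction``;
6. drop sites with minor allele count (gene copies over all non-missing
   diploid calls) below ``min_minor_allele_count``;
7. drop sites with QUAL below ``qual_depth_ratio`` x site total DP (high
   depth inflates QUAL, so a low QUAL/DP ratio flags artefacts);
8. drop putative paralogs: sites whose mean per-genotyped-sample depth
   exceeds the across-site mean by more than ``paralog_sd_multiplier``
   standard deviations.

Sample filtering (missing fraction above ``max_sample_missing_fraction``)
runs once, after the site cascade.  A separate within-population
missingness filter supports population-level analyses on sparse temporal
matrices.  Every stage is accounted for in a :class:`FilterReport` whose
per-stage counts telescope exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from museum_popgen.genotypes import MISSING, GenotypeMatrix, population_indices


@dataclass
class FilterConfig:
    """Thresholds for the site/sample filter cascade (defaults tuned for
    hyRAD-style museum data)."""

    min_qual: float = 30.0
    biallelic_only: bool = True
    min_minor_allele_count: int = 6
    max_site_missing_fraction: float = 0.5
    min_genotype_depth: int = 6
    qual_depth_ratio: float = 0.25
    paralog_sd_multiplier: float = 3.0
    max_sample_missing_fraction: float = 0.8
    max_within_pop_missing_fraction: float = 0.7
    # "all": a SNP must satisfy the within-population missingness bound in
    # every population; "any": in at least one.
    within_pop_mode: str = "all"
    # QUAL-vs-depth uses the site total DP ("total") or the mean per-call
    # DP ("mean").
    qual_depth_statistic: str = "total"

    def __post_init__(self) -> None:
        for name in (
            "max_site_missing_fraction",
            "qual_depth_ratio",
            "max_sample_missing_fraction",
            "max_within_pop_missing_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_minor_allele_count < 0 or self.min_genotype_depth < 0:
            raise ValueError("counts must be >= 0")
        if self.within_pop_mode not in ("all", "any"):
            raise ValueError("within_pop_mode must be 'all' or 'any'")


@dataclass
class FilterReport:
    """Per-stage accounting of a filter pass.

    ``stages`` entries are ``{"stage", "sites_in", "sites_removed"}`` (plus
    ``calls_masked`` for the depth-masking stage); counts telescope so that
    ``sites_in - sites_removed`` equals the next stage's ``sites_in``.
    """

    stages: list[dict] = field(default_factory=list)
    samples_removed: list[str] = field(default_factory=list)
    completeness: float = float("nan")
    mean_site_depth: float = float("nan")
    mean_snps_per_sample: float = float("nan")

    def add_stage(self, name: str, sites_in: int, sites_removed: int, **extra) -> None:
        self.stages.append(
            {"stage": name, "sites_in": sites_in, "sites_removed": sites_removed, **extra}
        )

    def finalize(self, gm: GenotypeMatrix) -> None:
        self.completeness = gm.completeness
        self.mean_site_depth = gm.mean_site_depth
        called = ~gm.missing_mask
        self.mean_snps_per_sample = (
            float(called.sum(axis=1).mean()) if gm.n_samples else float("nan")
        )

    @property
    def sites_out(self) -> int:
        if not self.stages:
            return 0
        last = self.stages[-1]
        return last["sites_in"] - last["sites_removed"]

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "samples_removed": self.samples_removed,
            "completeness": self.completeness,
            "mean_site_depth": self.mean_site_depth,
            "mean_snps_per_sample": self.mean_snps_per_sample,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def pretty(self) -> str:
        lines = ["stage                        in  removed"]
        for s in self.stages:
            lines.append(f"{s['stage']:<26}{s['sites_in']:>6}{s['sites_removed']:>9}")
        lines.append(f"sites retained: {self.sites_out}")
        if self.samples_removed:
            lines.append(f"samples removed: {', '.join(self.samples_removed)}")
        lines.append(f"matrix completeness: {self.completeness:.3f}")
        lines.append(f"mean site depth: {self.mean_site_depth:.2f}")
        return "\n".join(lines)


def _allele_counts(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (ref, alt) gene-copy counts over non-missing diploid calls."""
    called = ~gm.missing_mask
    gt = np.where(called, gm.genotypes, 0)
    alt = gt.sum(axis=0)
    ref = 2 * called.sum(axis=0) - alt
    return ref.astype(np.int64), alt.astype(np.int64)


def filter_sites(gm: GenotypeMatrix, cfg: FilterConfig) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the eight-stage site cascade; returns the filtered matrix and report."""
    report = FilterReport()
    out = gm.copy()

    # 1. site quality
    n_in = out.n_loci
    qual = out.loci["qual"].to_numpy(dtype=float)
    keep = ~(qual < cfg.min_qual)  # NaN QUAL passes; depth-ratio stage judges it
    report.add_stage("qual", n_in, int((~keep).sum()))
    out = out.take_sites(np.flatnonzero(keep))

    # 2. indels
    n_in = out.n_loci
    keep = ~out.is_indel
    report.add_stage("indels", n_in, int((~keep).sum()))
    out = out.take_sites(np.flatnonzero(keep))

    # 3. biallelic SNPs only
    n_in = out.n_loci
    if cfg.biallelic_only:
        keep = out.n_alt_alleles == 1
    else:
        keep = np.ones(n_in, dtype=bool)
    report.add_stage("biallelic", n_in, int((~keep).sum()))
    out = out.take_sites(np.flatnonzero(keep))

    # 4. per-genotype depth masking (no site is removed here)
    n_in = out.n_loci
    low = (~out.missing_mask) & (out.depths < cfg.min_genotype_depth)
    out.genotypes[low] = MISSING
    out.depths[low] = 0
    report.add_stage("genotype_depth_mask", n_in, 0, calls_masked=int(low.sum()))

    # 5. site missingness
    n_in = out.n_loci
    miss_frac = out.missing_mask.mean(axis=0) if out.n_samples else np.zeros(n_in)
    keep = miss_frac <= cfg.max_site_missing_fraction
    report.add_stage("site_missingness", n_in, int((~keep).sum()))
    out = out.take_sites(np.flatnonzero(keep))

    # 6. minor allele count (gene copies over all non-missing calls)
    n_in = out.n_loci
    ref, alt = _allele_counts(out)
    mac = np.minimum(ref, alt)
    keep = mac >= cfg.min_minor_allele_count
    report.add_stage("minor_allele_count", n_in, int((~keep).sum()))
    out = out.take_sites(np.flatnonzero(keep))

    # 7. QUAL vs depth ratio
    n_in = out.n_loci
    if cfg.qual_depth_statistic == "total":
        site_dp = out.depths.sum(axis=0).astype(float)
    else:
        called = ~out.missing_mask
        with np.errstate(invalid="ignore"):
            site_dp = np.where(
                called.any(axis=0),
                out.depths.sum(axis=0) / np.maximum(called.sum(axis=0), 1),
                0.0,
            )
    qual = out.loci["qual"].to_numpy(dtype=float)
    keep = ~(qual < cfg.qual_depth_ratio * site_dp)
    report.add_stage("qual_depth_ratio", n_in, int((~keep).sum()))
    out = out.take_sites(np.flatnonzero(keep))

    # 8. paralog proxy: outlying mean per-genotyped-sample depth.
    # The mean+k*SD cut is iterated to convergence so the cascade is
    # idempotent (a single cut would leave a truncated distribution whose
    # own mean+k*SD can flag further sites on a re-run).
    n_in = out.n_loci
    if n_in > 1 and math.isfinite(cfg.paralog_sd_multiplier):
        called = ~out.missing_mask
        n_called = np.maximum(called.sum(axis=0), 1)
        site_mean = out.depths.sum(axis=0) / n_called
        keep = np.ones(n_in, dtype=bool)
        while keep.sum() > 1:
            vals = site_mean[keep]
            cut = vals.mean() + cfg.paralog_sd_multiplier * vals.std(ddof=1)
            new_keep = keep & (site_mean <= cut)
            if new_keep.sum() == keep.sum():
                break
            keep = new_keep
    else:
        keep = np.ones(n_in, dtype=bool)
    report.add_stage("paralog_depth", n_in, int((~keep).sum()))
    out = out.take_sites(np.flatnonzero(keep))

    report.finalize(out)
    return out, report


def filter_samples(gm: GenotypeMatrix, cfg: FilterConfig) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop samples whose missing fraction over retained sites exceeds the
    ``max_sample_missing_fraction`` threshold (single pass)."""
    report = FilterReport()
    if gm.n_loci == 0:
        keep = np.ones(gm.n_samples, dtype=bool)
    else:
        miss = gm.missing_mask.mean(axis=1)
        keep = miss <= cfg.max_sample_missing_fraction
    report.samples_removed = [s for s, k in zip(gm.sample_ids, keep) if not k]
    out = gm.take_samples(np.flatnonzero(keep))
    report.add_stage("sample_missingness", gm.n_loci, 0,
                     samples_in=gm.n_samples, samples_removed=len(report.samples_removed))
    report.finalize(out)
    return out, report


def filter_within_population(
    gm: GenotypeMatrix, popmap: pd.DataFrame, cfg: FilterConfig
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop SNPs too sparse within analysis populations.

    A SNP is retained iff its missing fraction is <= the threshold (strict
    inequality drops) within every population (``within_pop_mode="all"``,
    default) or within at least one (``"any"``).  Only samples assigned to
    a population in ``popmap`` are considered.
    """
    groups = population_indices(gm, popmap)
    assigned = {s for idx in groups.values() for s in (gm.sample_ids[i] for i in idx)}
    unassigned = [s for s in gm.sample_ids if s not in assigned]
    if unassigned:
        raise ValueError(f"samples without population assignment: {unassigned}")
    if not groups:
        raise ValueError("no populations in popmap")

    fracs = np.stack(
        [gm.missing_mask[idx].mean(axis=0) for idx in groups.values()]
    )  # (n_pops, n_loci)
    ok = fracs <= cfg.max_within_pop_missing_fraction
    keep = ok.all(axis=0) if cfg.within_pop_mode == "all" else ok.any(axis=0)

    report = FilterReport()
    report.add_stage("within_population_missingness", gm.n_loci, int((~keep).sum()))
    out = gm.take_sites(np.flatnonzero(keep))
    report.finalize(out)
    return out, report
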