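"""End-to-end temporal analysis: filter cascade, HWE screen, diversity
statistics with permutation inference, private alleles, F_ST, the
historical-versus-contemporary individual-heterozygosity comparison, and
decline-scenario testing — deterministic given the configured seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from museum_popgen.decline import (
    ScenarioSpec,
    default_scenario_grid,
    evaluate_scenarios,
    scenarios_from_yaml,
)
from museum_popgen.diversity import (
    _ar_mean_float,
    _locus_counts,
    default_rarefaction_size,
    diversity_table,
    individual_hobs_all,
    maf_spectrum,
    private_alleles,
    wc_theta,
    wc_theta_from_rows,
)
from museum_popgen.filtering import (
    FilterConfig,
    filter_samples,
    filter_sites,
    filter_within_population,
)
from museum_popgen.genotypes import (
    MISSING,
    GenotypeMatrix,
    population_indices,
    read_popmap,
    read_vcf,
)
from museum_popgen.resampling import (
    bh_fdr,
    hwe_exact_mc,
    mann_whitney,
    permute_diff,
    permute_stat,
    storey_q,
)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    ``vcf`` / ``popmap`` may be paths or in-memory objects.  All sources
    of randomness derive from ``seed``; the seed and a hash of the
    configuration are recorded in the report.
    """

    vcf: object = None
    popmap: object = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    min_samples_per_population: int = 4
    min_year_interval: int = 10
    split_year: int = 1955       # historical/contemporary boundary
    hwe_small_n: int = 7         # HWE tested only where n exceeds this
    hwe_B: int = 1000
    hwe_alpha: float = 0.05
    perm_B: int = 10_000
    n_boot: int = 1000
    fdr: str = "bh"              # pairwise tests; HWE always uses q-values
    alpha: float = 0.05
    seed: int = 0
    scenarios: list[ScenarioSpec] | str | None = None
    decline_early: str | None = None
    decline_late: str | None = None
    resample_to_n_late: bool = True
    private_pairs: list[tuple[str, str]] | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.min_samples_per_population < 1:
            raise ValueError("min_samples_per_population must be >= 1")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        for k in ("vcf", "popmap"):
            v = d.get(k)
            d[k] = str(v) if isinstance(v, (str, Path)) else "<in-memory>"
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        filters = FilterConfig(**raw.pop("filters", {}))
        return cls(filters=filters, **raw)


def define_populations(
    popmap: pd.DataFrame,
    min_samples: int = 4,
    min_year_interval: int = 10,
) -> tuple[pd.DataFrame, list[str]]:
    """Group samples into analysis populations.

    Samples belong to the same population when collected at the same
    location within less than ``min_year_interval`` years (greedy
    clustering of sorted collection years).  Pre-existing non-empty
    ``population`` labels are respected.  Returns the popmap with the
    ``population`` column filled and the list of labels meeting the
    minimum size; undersized groups keep their label (they still enter
    individual-level analyses) but are excluded from the returned list.
    """
    pm = popmap.copy()
    needs_label = pm["population"].isna() | (pm["population"] == "")
    for location, sub in pm[needs_label].groupby("location"):
        years = np.sort(sub["year"].unique())
        cluster_start, labels = None, {}
        for y in years:
            if cluster_start is None or y - cluster_start >= min_year_interval:
                cluster_start = y
            labels[y] = cluster_start
        reps = {}
        for y, start in labels.items():
            reps.setdefault(start, []).append(y)
        rep_year = {start: int(np.median(ys)) for start, ys in reps.items()}
        mask = needs_label & (pm["location"] == location)
        pm.loc[mask, "population"] = [
            f"{location} {rep_year[labels[y]]}" for y in pm.loc[mask, "year"]
        ]
    sizes = pm.groupby("population").size()
    analysis = sorted(sizes[sizes >= min_samples].index)
    if not analysis:
        raise ValueError("no population meets the minimum sample size")
    return pm, analysis


def _significance_letters(
    populations: list[str], pairs: pd.DataFrame, alpha: float
) -> dict[str, str]:
    """Letter groupings from connected components of the graph whose edges
    join pairs that are NOT significantly different."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(populations)
    for _, row in pairs.iterrows():
        if row["adjusted_p"] >= alpha:
            g.add_edge(row["pop_a"], row["pop_b"])
    letters = {}
    comps = sorted(nx.connected_components(g), key=lambda c: populations.index(sorted(c)[0]))
    for i, comp in enumerate(comps):
        for pop in comp:
            letters[pop] = chr(ord("a") + i)
    return letters


def _mean_hexp_stat(gm: GenotypeMatrix):
    def stat(rows_a, rows_b):
        vals = []
        for rows in (np.asarray(rows_a), np.asarray(rows_b)):
            nn, het, alt = _locus_counts(gm, rows)
            use = nn >= 2
            n = nn[use].astype(float)
            ho = het[use] / n
            p = alt[use] / (2 * n)
            hs = n / (n - 1) * (1 - p**2 - (1 - p) ** 2 - ho / (2 * n))
            vals.append(hs.mean())
        return vals[0] - vals[1]

    return stat


def _mean_ar_stat(gm: GenotypeMatrix, g: int):
    def stat(rows_a, rows_b):
        vals = []
        for rows in (np.asarray(rows_a), np.asarray(rows_b)):
            nn, _, alt = _locus_counts(gm, rows)
            vals.append(_ar_mean_float(2 * nn - alt, alt, g))
        return vals[0] - vals[1]

    return stat


def _mean_hobs_of(gm: GenotypeMatrix, rows: np.ndarray) -> np.ndarray:
    hobs = individual_hobs_all(gm)
    return hobs.iloc[rows].to_numpy()


def run_all(cfg: RunConfig) -> dict:
    """Execute the full temporal analysis; returns the run report dict.

    Any stage failure raises with the stage name attached so partial
    diagnosis is possible.
    """
    rng = np.random.default_rng(cfg.seed)
    from importlib.metadata import version

    report: dict = {
        "provenance": {
            "package_version": version("museum-popgen"),
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
        }
    }
    stage = "load"
    try:
        gm = cfg.vcf if isinstance(cfg.vcf, GenotypeMatrix) else read_vcf(cfg.vcf)
        popmap = (
            cfg.popmap if isinstance(cfg.popmap, pd.DataFrame)
            else read_popmap(cfg.popmap)
        )

        stage = "site_filters"
        gm, site_report = filter_sites(gm, cfg.filters)
        report["filter_report"] = site_report.to_dict()

        stage = "sample_filter"
        gm, sample_report = filter_samples(gm, cfg.filters)
        report["sample_filter"] = sample_report.to_dict()
        report["n_snps_full_matrix"] = gm.n_loci
        report["n_samples_full_matrix"] = gm.n_samples
        report["matrix_completeness"] = gm.completeness
        report["mean_site_depth"] = gm.mean_site_depth

        stage = "define_populations"
        popmap = popmap[popmap["sample_id"].isin(gm.sample_ids)].reset_index(drop=True)
        popmap, analysis_pops = define_populations(
            popmap, cfg.min_samples_per_population, cfg.min_year_interval
        )
        report["populations"] = {
            "analysis": analysis_pops,
            "sizes": popmap.groupby("population").size().to_dict(),
        }

        stage = "individual_hobs"
        hobs = individual_hobs_all(gm).dropna()
        year_of = dict(zip(popmap["sample_id"], popmap["year"]))
        hist = [s for s in hobs.index if year_of.get(s, cfg.split_year) < cfg.split_year]
        cont = [s for s in hobs.index if s in year_of and year_of[s] >= cfg.split_year]
        report["individual_hobs"] = hobs.round(6).to_dict()
        if hist and cont:
            w, p = mann_whitney(hobs[hist], hobs[cont])
            report["mann_whitney"] = {
                "W": w, "p": p, "n_historical": len(hist), "n_contemporary": len(cont),
            }
        else:
            report["mann_whitney"] = None

        stage = "hwe_screen"
        groups = population_indices(gm, popmap)
        screened = [
            p for p in analysis_pops if len(groups.get(p, [])) > cfg.hwe_small_n
        ]
        drop = np.zeros(gm.n_loci, dtype=bool)
        hwe_info = {"populations": screened, "B": cfg.hwe_B, "per_population": {}}
        for pop in screened:
            rows = groups[pop]
            gt = gm.genotypes[rows]
            called = gt != MISSING
            counts = np.stack(
                [
                    ((gt == 0) & called).sum(axis=0),
                    ((gt == 1) & called).sum(axis=0),
                    ((gt == 2) & called).sum(axis=0),
                ],
                axis=1,
            )
            testable = counts.sum(axis=1) >= 2
            p_vals = np.ones(gm.n_loci)
            for j in np.flatnonzero(testable):
                p_vals[j] = hwe_exact_mc(
                    tuple(counts[j]), B=cfg.hwe_B, seed=int(rng.integers(2**31))
                )
            q = storey_q(p_vals[testable])
            flag = np.zeros(gm.n_loci, dtype=bool)
            flag[np.flatnonzero(testable)] = q < cfg.hwe_alpha
            drop |= flag
            hwe_info["per_population"][pop] = {
                "n_tested": int(testable.sum()),
                "n_flagged": int(flag.sum()),
            }
        hwe_info["n_loci_dropped"] = int(drop.sum())
        report["hwe"] = hwe_info
        gm = gm.take_sites(np.flatnonzero(~drop))

        stage = "population_matrix"
        analysis_map = popmap[popmap["population"].isin(analysis_pops)]
        keep_rows = [
            i for i, s in enumerate(gm.sample_ids)
            if s in set(analysis_map["sample_id"])
        ]
        pop_gm = gm.take_samples(np.array(keep_rows, dtype=int))
        pop_gm, wp_report = filter_within_population(pop_gm, analysis_map, cfg.filters)
        report["within_pop_filter"] = wp_report.to_dict()
        report["n_snps_population_matrix"] = pop_gm.n_loci
        report["n_samples_population_matrix"] = pop_gm.n_samples

        stage = "diversity"
        g = default_rarefaction_size(pop_gm, analysis_map, populations=analysis_pops)
        div = diversity_table(pop_gm, analysis_map, populations=analysis_pops, g=g)
        report["rarefaction_g"] = g

        stage = "pairwise_tests"
        groups_pop = population_indices(pop_gm, analysis_map)
        pairs = [
            (a, b)
            for i, a in enumerate(analysis_pops)
            for b in analysis_pops[i + 1 :]
        ]
        test_rows = []
        hexp_stat = _mean_hexp_stat(pop_gm)
        ar_stat = _mean_ar_stat(pop_gm, g)
        for a, b in pairs:
            ra, rb = groups_pop[a], groups_pop[b]
            res_hobs = permute_diff(
                _mean_hobs_of(pop_gm, ra), _mean_hobs_of(pop_gm, rb),
                B=cfg.perm_B, seed=int(rng.integers(2**31)),
            )
            test_rows.append(
                {"statistic": "H_obs", "pop_a": a, "pop_b": b,
                 "observed": res_hobs.observed, "p": res_hobs.p}
            )
            for name, fn in (("H_exp", hexp_stat), ("A_r", ar_stat)):
                res = permute_stat(
                    list(ra), list(rb), fn, B=cfg.perm_B,
                    seed=int(rng.integers(2**31)), statistic=name,
                )
                test_rows.append(
                    {"statistic": name, "pop_a": a, "pop_b": b,
                     "observed": res.observed, "p": res.p}
                )
        tests = pd.DataFrame(test_rows)
        tests["adjusted_p"] = np.nan
        for name in ("H_obs", "H_exp", "A_r"):
            sel = tests["statistic"] == name
            adj = bh_fdr(tests.loc[sel, "p"].to_numpy())
            tests.loc[sel, "adjusted_p"] = (
                adj if cfg.fdr == "bh" else storey_q(tests.loc[sel, "p"].to_numpy())
            )
        report["pairwise_tests"] = tests.to_dict(orient="records")

        letters = {
            name: _significance_letters(
                analysis_pops, tests[tests["statistic"] == name], cfg.alpha
            )
            for name in ("H_obs", "H_exp", "A_r")
        }
        table = div.table.copy()
        for name in ("H_obs", "H_exp", "A_r"):
            table[f"{name}_group"] = [letters[name][p] for p in table.index]
        report["diversity_table"] = table.reset_index().to_dict(orient="records")

        stage = "private_alleles"
        year_of_pop = (
            analysis_map.groupby("population")["year"].median().to_dict()
        )
        loc_of_pop = (
            analysis_map.groupby("population")["location"].first().to_dict()
        )
        if cfg.private_pairs is not None:
            ppairs = cfg.private_pairs
        else:
            ppairs = []
            for a, b in pairs:
                both_cont = (
                    year_of_pop[a] >= cfg.split_year
                    and year_of_pop[b] >= cfg.split_year
                )
                same_loc_temporal = (
                    loc_of_pop[a] == loc_of_pop[b]
                    and (year_of_pop[a] < cfg.split_year)
                    != (year_of_pop[b] < cfg.split_year)
                )
                if both_cont or same_loc_temporal:
                    ppairs.append((a, b))
        priv_rows = []
        for a, b in ppairs:
            na, nb, detail = private_alleles(pop_gm, analysis_map, a, b)
            priv_rows.append(
                {"pop_a": a, "pop_b": b, "private_a": na, "private_b": nb,
                 "mean_freq_a": float(
                     detail.loc[detail["private_to"] == a, "frequency"].mean()
                 ) if na else float("nan"),
                 "mean_freq_b": float(
                     detail.loc[detail["private_to"] == b, "frequency"].mean()
                 ) if nb else float("nan")}
            )
        report["private_alleles"] = priv_rows

        stage = "fst"
        fst_rows = []
        for a, b in pairs:
            res = wc_theta(pop_gm, analysis_map, a, b)
            perm = permute_stat(
                list(groups_pop[a]), list(groups_pop[b]),
                lambda ra, rb: wc_theta_from_rows(
                    pop_gm, np.asarray(ra), np.asarray(rb)
                ),
                B=cfg.perm_B, seed=int(rng.integers(2**31)), statistic="theta",
            )
            fst_rows.append(
                {"pop_a": a, "pop_b": b, "theta": res.theta, "p": perm.p}
            )
        fst = pd.DataFrame(fst_rows)
        fst["adjusted_p"] = bh_fdr(fst["p"].to_numpy())
        report["fst"] = fst.to_dict(orient="records")

        stage = "decline_scenarios"
        if cfg.decline_early and cfg.decline_late:
            specs = cfg.scenarios
            if specs is None:
                specs = default_scenario_grid()
            elif isinstance(specs, (str, Path)):
                specs = scenarios_from_yaml(specs)
            maf_early = maf_spectrum(pop_gm, analysis_map, cfg.decline_early)
            maf_late = maf_spectrum(pop_gm, analysis_map, cfg.decline_late)
            n_late = len(groups_pop[cfg.decline_late])
            scen = evaluate_scenarios(
                maf_early, maf_late, specs, n_late=n_late,
                n_boot=cfg.n_boot, seed=int(rng.integers(2**31)),
                resample_to_n_late=cfg.resample_to_n_late,
            )
            report["scenarios"] = scen.to_dict(orient="records")
        else:
            report["scenarios"] = None
    except Exception as exc:
        exc.add_note(f"pipeline stage: {stage}")
        raise

    if cfg.out_dir:
        _write_report(report, cfg.out_dir)
    return report


def _write_report(report: dict, out_dir) -> None:
    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    for key in ("diversity_table", "pairwise_tests", "fst", "private_alleles", "scenarios"):
        rows = report.get(key)
        if rows:
            pd.DataFrame(rows).to_csv(out / "tables" / f"{key}.tsv", sep="\t", index=False)
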