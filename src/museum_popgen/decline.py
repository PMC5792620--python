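"""Wright-Fisher population-decline scenarios scored against an observed
temporal change in minor-allele-frequency (MAF) distributions.

A scenario is a decline trajectory from an initial diploid size ``N0`` to a
final size ``Nf`` over ``T`` generations, in one of three families:

* ``linear``:          N_t = round(N0 + (Nf - N0) * t / T)
* ``exp_const_rate``:  N_t = round(N0 * (Nf / N0) ** (t / T))
* ``exp_shape``:       N_t = round(N0 + (Nf - N0) * (e^{s t / T} - 1) /
  (e^s - 1)) with curvature s > 0 (slow-then-fast decline; s < 0 gives
  fast-then-slow)

The early population's observed MAFs are taken as the true initial allele
frequencies; each locus then drifts independently,
``p_t ~ Binomial(2 N_t, p_{t-1}) / (2 N_t)``, with absorption at 0 and 1.
The drifted frequencies are resampled down to the later sample's size
(binomial sampling of 2n gene copies), folded back to MAFs, and compared
with the observed later MAF distribution by the bootstrapped KS test; the
scenario batch is then FDR-adjusted (Benjamini-Hochberg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from museum_popgen.diversity import MafDistribution
from museum_popgen.resampling import bh_fdr, ks_boot

FAMILIES = ("linear", "exp_const_rate", "exp_shape")


@dataclass
class ScenarioSpec:
    """One decline scenario: N0 -> Nf over T generations in a given family."""

    id: str
    N0: int
    Nf: int
    family: str
    T: int = 10
    shape: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.Nf > self.N0:
            raise ValueError("Nf must not exceed N0 (decline scenarios)")
        if self.Nf < 2 or self.T < 1:
            raise ValueError("need Nf >= 2 and T >= 1")
        if self.family == "exp_shape" and not self.shape:
            raise ValueError("exp_shape requires a non-zero shape parameter")


def trajectory(spec: ScenarioSpec) -> np.ndarray:
    """Per-generation diploid sizes N_1..N_T (endpoints hit Nf exactly)."""
    t = np.arange(1, spec.T + 1, dtype=float)
    frac = t / spec.T
    if spec.family == "linear":
        n = spec.N0 + (spec.Nf - spec.N0) * frac
    elif spec.family == "exp_const_rate":
        n = spec.N0 * (spec.Nf / spec.N0) ** frac
    else:
        s = float(spec.shape)
        n = spec.N0 + (spec.Nf - spec.N0) * (np.expm1(s * frac) / np.expm1(s))
    sizes = np.maximum(np.rint(n).astype(np.int64), 2)
    sizes[-1] = max(spec.Nf, 2)
    return sizes


def wright_fisher(
    p0: np.ndarray, sizes: np.ndarray, rng: np.random.Generator,
    keep_path: bool = False,
) -> np.ndarray:
    """Neutral Wright-Fisher drift of independent biallelic loci.

    Each generation the allele frequency is binomially resampled among the
    2 N_t gene copies of that generation.  Returns final frequencies of
    shape ``(n_loci,)``, or the full path ``(n_loci, T + 1)`` including the
    founder generation when ``keep_path``.
    """
    p = np.asarray(p0, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("frequencies must lie in [0, 1]")
    sizes = np.asarray(sizes, dtype=np.int64)
    if (sizes < 1).any():
        raise ValueError("population sizes must be >= 1")
    path = [p.copy()] if keep_path else None
    for n_t in sizes:
        copies = 2 * int(n_t)
        p = rng.binomial(copies, p) / copies
        if keep_path:
            path.append(p.copy())
    return np.stack(path, axis=1) if keep_path else p


def wf_propagate(
    maf0: MafDistribution | np.ndarray, sizes, seed: int | None = None
) -> np.ndarray:
    """Drift an observed MAF distribution through a size trajectory.

    The observed minor-allele frequencies are treated as true initial
    frequencies; the returned per-locus frequencies are folded back to the
    minor-allele convention.
    """
    p0 = maf0.maf if isinstance(maf0, MafDistribution) else np.asarray(maf0, float)
    if (p0 < 0).any() or (p0 > 0.5 + 1e-12).any():
        raise ValueError("initial MAFs must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    p = wright_fisher(p0, sizes, rng)
    return np.minimum(p, 1 - p)


def sample_maf(
    freqs: np.ndarray, n_individuals: int, seed: int | None = None
) -> np.ndarray:
    """Binomial sampling of 2n gene copies per locus, folded to MAF."""
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    rng = np.random.default_rng(seed)
    p = np.asarray(freqs, dtype=float)
    copies = 2 * n_individuals
    f = rng.binomial(copies, p) / copies
    return np.minimum(f, 1 - f)


def evaluate_scenarios(
    maf_early: MafDistribution | np.ndarray,
    maf_late: MafDistribution | np.ndarray,
    scenarios: list[ScenarioSpec],
    n_late: int,
    n_boot: int = 1000,
    seed: int | None = None,
    resample_to_n_late: bool = True,
    bootstrap_start_n: int | None = None,
) -> pd.DataFrame:
    """Score each decline scenario against the observed later MAF
    distribution.

    For each scenario: build the trajectory, drift the early MAFs through
    it (one Wright-Fisher replicate, as a single simulated distribution),
    optionally resample down to the later sample's size, and compare with
    the later observed MAFs by the bootstrapped KS test.  p-values are
    BH-adjusted across the scenario batch.

    The observed early MAFs are taken as the true initial frequencies; if
    ``bootstrap_start_n`` (individuals) is given, starting frequencies are
    instead parametrically re-drawn per scenario as Binomial(2n, maf)/2n,
    propagating the early sample's own uncertainty.
    """
    if not scenarios:
        raise ValueError("scenario list is empty")
    early = maf_early.maf if isinstance(maf_early, MafDistribution) else np.asarray(maf_early, float)
    late = maf_late.maf if isinstance(maf_late, MafDistribution) else np.asarray(maf_late, float)
    rng = np.random.default_rng(seed)
    rows = []
    for spec in scenarios:
        sizes = trajectory(spec)
        start = early
        if bootstrap_start_n is not None:
            start = sample_maf(early, bootstrap_start_n, seed=int(rng.integers(2**31)))
        p_final = wf_propagate(start, sizes, seed=int(rng.integers(2**31)))
        if resample_to_n_late:
            sim = sample_maf(p_final, n_late, seed=int(rng.integers(2**31)))
        else:
            sim = p_final
        ks = ks_boot(sim, late, n_boot=n_boot, seed=int(rng.integers(2**31)))
        rows.append(
            {"id": spec.id, "N0": spec.N0, "Nf": spec.Nf, "family": spec.family,
             "shape": spec.shape, "T": spec.T, "D": ks.D, "p": ks.p}
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = bh_fdr(out["p"].to_numpy())
    return out


def default_scenario_grid(T: int = 10, shape: float = 3.0) -> list[ScenarioSpec]:
    """A 30-scenario grid: 5 initial sizes x 2 final sizes x 3 decline
    families.  A stand-in grid spanning mild to severe bottlenecks; the
    scenario set is fully configurable (YAML) and carries no special
    status."""
    specs = []
    for n0 in (500, 1000, 2000, 5000, 10_000):
        for nf in (10, 50):
            for family in FAMILIES:
                specs.append(
                    ScenarioSpec(
                        id=f"{family}_N0={n0}_Nf={nf}",
                        N0=n0, Nf=nf, family=family, T=T,
                        shape=shape if family == "exp_shape" else None,
                    )
                )
    return specs


def scenarios_from_yaml(path) -> list[ScenarioSpec]:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        ScenarioSpec(
            id=str(d["id"]), N0=int(d["N0"]), Nf=int(d["Nf"]),
            family=d["family"], T=int(d.get("T", 10)),
            shape=d.get("shape"),
        )
        for d in raw
    ]
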