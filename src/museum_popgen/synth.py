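"""Synthetic museum-genomics datasets with known ground truth.

The generator emulates the data a hybridization-capture experiment on
museum specimens yields after variant calling: a sparse genotype matrix
whose missingness is heterogeneous between museum and fresh samples, with
allelic dropout (true heterozygotes miscalled homozygous — low-template
DNA systematically inflates homozygosity), spurious heterozygotes,
overdispersed read depth, and temporal drift between sampling eras.  The
ground truth (per-locus allele-frequency trajectories through a known
population-size history) is retained so parameter-recovery tests can
compare estimates against it.

Genotypes are simulated at the call level (not the read level): dropout
and false-heterozygote events act per genotype, depth is drawn from a
negative binomial per call, and site QUAL is a monotone function of site
total depth with multiplicative noise so that QUAL-versus-depth filters
are exercisable in both directions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from museum_popgen.decline import wright_fisher
from museum_popgen.genotypes import MISSING, GenotypeMatrix, write_popmap, write_vcf


@dataclass
class Era:
    """A sampling era: label, calendar year, and the generation index it
    occupies on the simulated trajectory."""

    label: str
    year: int
    generation: int


@dataclass
class TruthSet:
    """Ground truth behind a synthetic dataset.

    ``trajectories`` has shape (n_loci, T + 1): the true alternate-allele
    frequency of each locus at every generation, founder included.
    """

    loci: list[str]
    eras: list[Era]
    pop_sizes: np.ndarray
    trajectories: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.pop_sizes = np.asarray(self.pop_sizes, dtype=np.int64)
        self.trajectories = np.asarray(self.trajectories, dtype=float)
        if self.trajectories.shape != (len(self.loci), len(self.pop_sizes) + 1):
            raise ValueError("trajectory length must be generations + 1")
        if (self.trajectories < 0).any() or (self.trajectories > 1).any():
            raise ValueError("frequencies must lie in [0, 1]")
        years = [e.year for e in sorted(self.eras, key=lambda e: e.generation)]
        if years != sorted(years):
            raise ValueError("eras must be ordered consistently by year")
        for e in self.eras:
            if not 0 <= e.generation <= len(self.pop_sizes):
                raise ValueError(f"era {e.label!r} outside the simulated span")

    def era(self, label: str) -> Era:
        for e in self.eras:
            if e.label == label:
                return e
        raise KeyError(f"unknown era {label!r}")

    def freqs_at(self, label: str) -> np.ndarray:
        return self.trajectories[:, self.era(label).generation]

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "loci": self.loci,
            "eras": [asdict(e) for e in self.eras],
            "pop_sizes": self.pop_sizes.tolist(),
            "trajectories": self.trajectories.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            loci=d["loci"],
            eras=[Era(**e) for e in d["eras"]],
            pop_sizes=np.array(d["pop_sizes"]),
            trajectories=np.array(d["trajectories"]),
            seed=d["seed"],
        )


@dataclass
class DegradationProfile:
    """Call-level degradation model for museum vs fresh samples.

    Per-sample missing rates are drawn from a normal (clipped to [0, 1])
    with class-specific mean/sd; ``dropout_prob`` is the probability a true
    heterozygote is recorded homozygous (random allele), ``false_het_rate``
    the probability a true homozygote is recorded heterozygous.  Depth is
    negative-binomial with the given mean and dispersion (smaller
    dispersion = more overdispersed); missing calls carry DP 0.  Site QUAL
    is ``0.45 * totalDP`` with multiplicative Gaussian noise (sd 0.25),
    rounded to one decimal and floored at 0.
    """

    museum_missing_mean: float = 0.42
    museum_missing_sd: float = 0.10
    fresh_missing_mean: float = 0.26
    fresh_missing_sd: float = 0.08
    dropout_prob: float = 0.10
    false_het_rate: float = 0.30
    depth_mean: float = 17.0
    depth_dispersion: float = 8.0
    qual_slope: float = 0.45
    qual_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "museum_missing_mean", "fresh_missing_mean",
            "dropout_prob", "false_het_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")

    def missing_params(self, sample_class: str) -> tuple[float, float]:
        if sample_class == "museum":
            return self.museum_missing_mean, self.museum_missing_sd
        if sample_class == "fresh":
            return self.fresh_missing_mean, self.fresh_missing_sd
        raise ValueError(f"unknown sample class {sample_class!r}")


HYRAD_LIKE_PROFILE = DegradationProfile()

# Era year below which a sample counts as museum material.
MUSEUM_YEAR_CUTOFF = 2000


def simulate_truth(
    n_loci: int,
    pop_sizes,
    founder_beta: tuple[float, float] = (0.5, 0.5),
    eras: list[Era] | None = None,
    seed: int | None = None,
) -> TruthSet:
    """Simulate per-locus allele-frequency trajectories under neutral
    Wright-Fisher drift through a diploid size history.

    Founder frequencies are Beta(a, b) draws (the default Jeffreys shape
    puts mass on rare alleles, the regime where capture data are
    informative).  Eras default to a historical era at the founder
    generation and a modern one at the final generation.
    """
    if n_loci < 1:
        raise ValueError("need at least one locus")
    sizes = np.asarray(pop_sizes, dtype=np.int64)
    if (sizes < 1).any():
        raise ValueError("population sizes must be >= 1")
    rng = np.random.default_rng(seed)
    p0 = rng.beta(*founder_beta, size=n_loci)
    traj = wright_fisher(p0, sizes, rng, keep_path=True)
    if eras is None:
        eras = [
            Era("historical", 1940, 0),
            Era("modern", 2005, len(sizes)),
        ]
    loci = [f"locus{j:05d}" for j in range(n_loci)]
    return TruthSet(loci=loci, eras=eras, pop_sizes=sizes,
                    trajectories=traj, seed=seed if seed is not None else -1)


@dataclass
class SampleDesign:
    """Samples to draw for one analysis population."""

    population: str
    era: str
    n: int
    location: str = ""
    year: int | None = None


def sample_genotypes(
    truth: TruthSet, design: list[SampleDesign], seed: int | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw Hardy-Weinberg genotypes at each era's true frequencies.

    Each individual's genotype at each locus is two independent gene
    copies at that era's true alternate-allele frequency.  No missingness
    or depth model is applied (see :func:`degrade`); placeholder DP/QUAL
    are high enough to pass default filters unchanged.  Returns the matrix
    and its population map.
    """
    rng = np.random.default_rng(seed)
    n_loci = len(truth.loci)
    gts, sample_ids, rows, classes = [], [], [], {}
    for d in design:
        freqs = truth.freqs_at(d.era)  # KeyError on unknown era
        year = d.year if d.year is not None else truth.era(d.era).year
        for k in range(d.n):
            sid = f"{d.population.replace(' ', '_')}_{k:02d}"
            sample_ids.append(sid)
            gts.append(rng.binomial(2, freqs).astype(np.int8))
            rows.append(
                {"sample_id": sid, "population": d.population,
                 "location": d.location or d.population, "year": year}
            )
            classes[sid] = "museum" if year < MUSEUM_YEAR_CUTOFF else "fresh"
    genotypes = (
        np.stack(gts) if gts else np.empty((0, n_loci), dtype=np.int8)
    )
    depths = np.full_like(genotypes, 30, dtype=np.int32)
    loci = pd.DataFrame(
        {
            "chrom": truth.loci,
            "pos": np.ones(n_loci, dtype=int),
            "ref": ["A"] * n_loci,
            "alt": ["T"] * n_loci,
            "qual": np.full(n_loci, 100.0),
        }
    )
    gm = GenotypeMatrix(sample_ids, loci, genotypes, depths,
                        sample_meta={"class": classes})
    popmap = pd.DataFrame(rows, columns=["sample_id", "population", "location", "year"])
    return gm, popmap


def degrade(
    gm: GenotypeMatrix, profile: DegradationProfile, seed: int | None = None
) -> GenotypeMatrix:
    """Apply museum-grade degradation to a clean genotype matrix.

    Requires a matrix with no missing calls (degradation composes with
    itself ambiguously otherwise).  Sample classes come from
    ``gm.sample_meta["class"]``; samples without a class are treated as
    fresh.
    """
    if (gm.genotypes == MISSING).any():
        raise ValueError("degrade expects a matrix with no missing calls")
    rng = np.random.default_rng(seed)
    out = gm.copy()
    n, m = out.genotypes.shape
    classes = out.sample_meta.get("class", {})

    # 1. per-sample missingness
    rates = np.empty(n)
    for i, sid in enumerate(out.sample_ids):
        mu, sd = profile.missing_params(classes.get(sid, "fresh"))
        rates[i] = np.clip(rng.normal(mu, sd), 0.0, 1.0)
    miss = rng.random((n, m)) < rates[:, None]

    # 2. allelic dropout on surviving heterozygotes: het -> random homozygote
    het = (out.genotypes == 1) & ~miss
    drop = het & (rng.random((n, m)) < profile.dropout_prob)
    out.genotypes[drop] = rng.choice(
        np.array([0, 2], dtype=np.int8), size=int(drop.sum())
    )

    # 3. spurious heterozygotes on surviving homozygotes
    hom = ((out.genotypes == 0) | (out.genotypes == 2)) & ~miss & ~drop
    flip = hom & (rng.random((n, m)) < profile.false_het_rate)
    out.genotypes[flip] = 1

    out.genotypes[miss] = MISSING

    # 4. depth: negative binomial per called genotype, DP 0 when missing
    k, mu = profile.depth_dispersion, profile.depth_mean
    dp = rng.negative_binomial(k, k / (k + mu), size=(n, m)).astype(np.int32)
    dp = np.maximum(dp, 1)
    dp[miss] = 0
    out.depths = dp

    # 5. QUAL: monotone in site total depth, with noise
    tot = dp.sum(axis=0).astype(float)
    qual = profile.qual_slope * tot * (1.0 + rng.normal(0, profile.qual_noise_sd, m))
    out.loci["qual"] = np.round(np.maximum(qual, 0.0), 1)
    return out


def add_decoys(
    gm: GenotypeMatrix, fraction: float = 0.1, seed: int | None = None
) -> GenotypeMatrix:
    """Append indel and multiallelic decoy records (filter-cascade fodder).

    Half the decoys are 2-bp deletions, half triallelic SNPs, with random
    genotypes and depths matching the matrix's typical values.
    """
    rng = np.random.default_rng(seed)
    n_decoy = int(round(fraction * gm.n_loci))
    if n_decoy == 0:
        return gm.copy()
    n = gm.n_samples
    gts = rng.binomial(2, 0.3, size=(n, n_decoy)).astype(np.int8)
    dp = rng.integers(6, 40, size=(n, n_decoy)).astype(np.int32)
    half = n_decoy // 2
    refs = ["AT"] * half + ["A"] * (n_decoy - half)
    alts = ["A"] * half + ["C,G"] * (n_decoy - half)
    loci = pd.DataFrame(
        {
            "chrom": [f"decoy{j:05d}" for j in range(n_decoy)],
            "pos": np.ones(n_decoy, dtype=int),
            "ref": refs,
            "alt": alts,
            "qual": np.round(rng.uniform(35, 90, n_decoy), 1),
        }
    )
    return GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        loci=pd.concat([gm.loci, loci], ignore_index=True),
        genotypes=np.concatenate([gm.genotypes, gts], axis=1),
        depths=np.concatenate([gm.depths, dp], axis=1),
        sample_meta=dict(gm.sample_meta),
    )


# -- hyrad-like preset ----------------------------------------------------

def hyrad_like_design() -> list[SampleDesign]:
    """Six analysis populations at realistic historical/contemporary sizes
    plus a few undersized historical groups that the minimum-size rule
    must exclude (62 samples: 29 museum, 33 fresh)."""
    return [
        SampleDesign("Finges 1940", era="1940", n=5, location="Finges", year=1939),
        SampleDesign("Finges 1950", era="1950", n=7, location="Finges", year=1949),
        SampleDesign("Sierre 1940", era="1940", n=4, location="Sierre", year=1940),
        SampleDesign("Lower Herens Valley 1940", era="1940", n=4,
                     location="Lower Herens Valley", year=1940),
        SampleDesign("Lower Herens Valley 2005", era="2005", n=15,
                     location="Lower Herens Valley", year=2005),
        SampleDesign("Gampel 2005", era="2005", n=18, location="Gampel", year=2005),
        SampleDesign("Ayent 1940", era="1940", n=3, location="Ayent", year=1941),
        SampleDesign("Sion 1920", era="1920", n=3, location="Sion", year=1920),
        SampleDesign("Leuk 1950", era="1950", n=3, location="Leuk", year=1950),
    ]


def hyrad_like_dataset(
    seed: int | None = None,
    n_loci: int = 2000,
    decoy_fraction: float = 0.1,
    profile: DegradationProfile | None = None,
):
    """Generate a full museum-style dataset: drifting single deme sampled
    in four eras (1920/1940/1950/2005, one generation per year), six
    analysis populations plus undersized groups, degradation applied.

    Returns ``(gm, popmap, truth)``.  The deme declines exponentially from
    N = 3000 to N = 300 over the 86 simulated generations (1919-2005); the
    sampled locations share this single trajectory, i.e. the preset models
    temporal drift but no spatial structure.
    """
    rng = np.random.default_rng(seed)
    generations = 86  # 1919..2005, one generation per year
    t = np.arange(1, generations + 1)
    sizes = np.rint(3000 * (300 / 3000) ** (t / generations)).astype(int)
    eras = [
        Era("1920", 1920, 1),
        Era("1940", 1939, 20),
        Era("1950", 1949, 30),
        Era("2005", 2005, 86),
    ]
    truth = simulate_truth(
        n_loci, sizes, founder_beta=(0.5, 0.5), eras=eras,
        seed=int(rng.integers(2**31)),
    )
    gm, popmap = sample_genotypes(
        truth, hyrad_like_design(), seed=int(rng.integers(2**31))
    )
    gm = degrade(gm, profile or HYRAD_LIKE_PROFILE, seed=int(rng.integers(2**31)))
    gm = add_decoys(gm, fraction=decoy_fraction, seed=int(rng.integers(2**31)))
    return gm, popmap, truth


def write_dataset(
    outdir, gm: GenotypeMatrix, popmap: pd.DataFrame, truth: TruthSet | None = None
) -> None:
    """Write the dataset in the formats the pipeline consumes: VCF 4.2,
    tab-separated population map, and a ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(gm, outdir / "data.vcf")
    write_popmap(popmap, outdir / "popmap.tsv")
    if truth is not None:
        truth.to_json(outdir / "truth.json")
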