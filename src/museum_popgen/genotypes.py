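"""Genotype matrix container and VCF / population-map I/O.

The central object is :class:`GenotypeMatrix`: a samples x loci matrix of
diploid genotype calls (count of non-reference copies, ``-1`` for missing)
with per-call read depth (DP), per-site Phred quality (QUAL) and the locus
table (contig, position, ref, alt).  VCF reading and writing go through
pysam; the matrix round-trips losslessly through an uncompressed VCF 4.2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

MISSING = -1

_LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt", "qual"]


@dataclass
class GenotypeMatrix:
    """Samples x loci diploid genotype calls with DP/QUAL sidecars.

    Parameters
    ----------
    sample_ids :
        Unique sample identifiers, one per matrix row.
    loci :
        DataFrame with columns ``chrom, pos, ref, alt, qual`` (one row per
        site; ``alt`` is a comma-joined string for multiallelic records,
        ``qual`` is Phred-scaled and stored rounded to one decimal).
    genotypes :
        ``int8`` array of shape ``(n_samples, n_loci)``; entries count
        non-reference allele copies (0, 1, 2) or are ``MISSING`` (-1).
    depths :
        ``int32`` array of per-call read depths; missing calls carry DP 0.
    sample_meta :
        Free-form per-sample metadata (e.g. ``{"class": {...}}``).
    """

    sample_ids: list[str]
    loci: pd.DataFrame
    genotypes: np.ndarray
    depths: np.ndarray
    sample_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        n, m = self.genotypes.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match genotype rows")
        if len(self.loci) != m:
            raise ValueError("loci table length does not match genotype columns")
        if self.depths.shape != (n, m):
            raise ValueError("depths shape does not match genotypes")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicated sample ids")
        keys = list(zip(self.loci["chrom"], self.loci["pos"], strict=True))
        if len(set(keys)) != m:
            raise ValueError("duplicated locus keys (chrom, pos)")
        self.loci = self.loci.reset_index(drop=True)

    # -- basic geometry ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    @property
    def completeness(self) -> float:
        """Fraction of non-missing entries in the genotype matrix."""
        if self.genotypes.size == 0:
            return float("nan")
        return float(1.0 - self.missing_mask.mean())

    @property
    def mean_site_depth(self) -> float:
        """Mean DP over non-missing calls."""
        called = ~self.missing_mask
        if not called.any():
            return float("nan")
        return float(self.depths[called].mean())

    @property
    def n_alt_alleles(self) -> np.ndarray:
        """Number of ALT alleles per site (1 = biallelic candidate)."""
        return self.loci["alt"].str.count(",").to_numpy() + 1

    @property
    def is_indel(self) -> np.ndarray:
        """True where REF or any ALT allele is not a single base."""
        ref_len = self.loci["ref"].str.len().to_numpy()
        alt_max = np.array(
            [max(len(a) for a in alts.split(",")) for alts in self.loci["alt"]]
        )
        return (ref_len != 1) | (alt_max != 1)

    # -- subsetting -------------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            loci=self.loci.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[:, index].copy(),
            depths=self.depths[:, index].copy(),
            sample_meta=dict(self.sample_meta),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            loci=self.loci.copy(),
            genotypes=self.genotypes[index].copy(),
            depths=self.depths[index].copy(),
            sample_meta=dict(self.sample_meta),
        )

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            loci=self.loci.copy(),
            genotypes=self.genotypes.copy(),
            depths=self.depths.copy(),
            sample_meta=dict(self.sample_meta),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.loci[_LOCUS_COLUMNS].equals(other.loci[_LOCUS_COLUMNS])
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.depths, other.depths)
        )


# -- VCF ------------------------------------------------------------------

def _gt_tuple(genotype: int, n_alt: int) -> tuple:
    if genotype == MISSING:
        return (None, None)
    if genotype == 0:
        return (0, 0)
    if genotype == 1:
        return (0, 1)
    if genotype == 2:
        return (1, 1)
    raise ValueError(f"cannot encode genotype {genotype}")


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write an uncompressed VCF 4.2 with GT:DP per sample and site QUAL."""
    header = pysam.VariantHeader()
    for chrom in pd.unique(gm.loci["chrom"]):
        header.contigs.add(str(chrom))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for sid in gm.sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(gm.n_loci):
            row = gm.loci.iloc[j]
            alts = tuple(str(row["alt"]).split(","))
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]) - 1 + len(str(row["ref"])),
                alleles=(str(row["ref"]),) + alts,
            )
            rec.qual = float(row["qual"])
            for i, sid in enumerate(gm.sample_ids):
                rec.samples[sid]["GT"] = _gt_tuple(int(gm.genotypes[i, j]), len(alts))
                rec.samples[sid]["DP"] = int(gm.depths[i, j])
            out.write(rec)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load GT/DP/QUAL from a VCF 4.x into a :class:`GenotypeMatrix`.

    Multiallelic and indel records are retained (the filter cascade removes
    them); genotypes at such records count non-reference copies regardless
    of which ALT allele they carry.  A call is missing when any GT allele is
    absent; missing calls get DP 0.
    """
    chroms, poss, refs, alts_, quals = [], [], [], [], []
    gt_cols, dp_cols = [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(set(samples)) != len(samples):
            raise ValueError("duplicated sample ids in VCF header")
        for rec in vcf:
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            refs.append(rec.ref)
            alts_.append(",".join(rec.alts) if rec.alts else ".")
            quals.append(round(float(rec.qual), 1) if rec.qual is not None else float("nan"))
            gts = np.empty(len(samples), dtype=np.int8)
            dps = np.zeros(len(samples), dtype=np.int32)
            for i, sid in enumerate(samples):
                call = rec.samples[sid]
                alleles = call.get("GT")
                if alleles is None or any(a is None for a in alleles):
                    gts[i] = MISSING
                else:
                    gts[i] = sum(1 for a in alleles if a != 0)
                    dp = call.get("DP")
                    dps[i] = int(dp) if dp is not None else 0
            gt_cols.append(gts)
            dp_cols.append(dps)
    loci = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts_, "qual": quals}
    )
    n = len(samples)
    genotypes = (
        np.stack(gt_cols, axis=1) if gt_cols else np.empty((n, 0), dtype=np.int8)
    )
    depths = np.stack(dp_cols, axis=1) if dp_cols else np.empty((n, 0), dtype=np.int32)
    return GenotypeMatrix(samples, loci, genotypes, depths)


# -- population map -------------------------------------------------------

def read_popmap(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated population map.

    Expected columns: ``sample_id, population, location, year``.  The
    ``population`` column may be empty, in which case populations are
    derived from (location, year) by the pipeline's grouping rule.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "location", "year"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"population map lacks columns: {sorted(missing)}")
    if "population" not in df.columns:
        df["population"] = ""
    df["year"] = df["year"].astype(int)
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicated sample ids in population map")
    return df[["sample_id", "population", "location", "year"]]


def write_popmap(popmap: pd.DataFrame, path: str | Path) -> None:
    popmap[["sample_id", "population", "location", "year"]].to_csv(
        path, sep="\t", index=False
    )


def population_indices(gm: GenotypeMatrix, popmap: pd.DataFrame) -> dict[str, np.ndarray]:
    """Map population label -> row indices into ``gm`` (samples present in both)."""
    pop_of = dict(zip(popmap["sample_id"], popmap["population"]))
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(gm.sample_ids):
        if sid in pop_of:
            groups.setdefault(pop_of[sid], []).append(i)
    return {k: np.array(v, dtype=int) for k, v in groups.items()}
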