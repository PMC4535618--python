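"""Pooled-heterozygosity (Hp/ZHp) selective-sweep scan.

The scan follows the pooled-read approach of Rubin et al.: at every
biallelic SNP the reference/alternative allele read depths (AD) of a
breed's animals are summed; the larger sum is the major allele.  SNPs
whose pooled minor-allele frequency is below 0.05 are removed, the genome
is tiled with 150 kb windows overlapping by 50%, and each window's pooled
heterozygosity

    Hp = 2 * sum_maj * sum_min / (sum_maj + sum_min)^2

is computed from the window-summed major/minor read counts, so Hp is 0
for a fully homozygous window and 0.5 when major and minor sums are
equal.  Windows with fewer than 10 retained SNPs are excluded.  Hp is
Z-transformed genome-wide per breed (population standard deviation), and
windows with ZHp strictly below -2 are called as candidate sweeps.

Coordinates: windows are 0-based half-open [s, e); a 1-based SNP position
p lies in a window iff s < p <= e.  Every interior SNP therefore falls in
exactly two consecutive windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import GenomeSpec
from .variant_annotation import GeneModelIndex

__all__ = [
    "PooledCounts",
    "read_breed_map",
    "read_genome_table",
    "pool_breed_counts",
    "pool_all_breeds",
    "maf_filter",
    "make_windows",
    "window_hp",
    "zhp_transform",
    "call_sweeps",
    "per_snp_hp_track",
    "scan",
    "write_window_table",
    "write_sweep_bed",
]

logger = logging.getLogger(__name__)

WINDOW_SIZE = 150_000
WINDOW_STEP = 75_000
MAF_THRESHOLD = 0.05
MIN_SNPS = 10
ZHP_THRESHOLD = -2.0


@dataclass
class PooledCounts:
    """Per-breed pooled allele read counts at each retained SNP.

    ``table`` columns: chrom, pos (1-based), ref, alt, major_allele,
    minor_allele, major_count, minor_count.
    """

    breed: str
    table: pd.DataFrame
    n_multiallelic_skipped: int = 0

    def __len__(self) -> int:
        return len(self.table)


def read_breed_map(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "breed"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "breed"])
    return df


def read_genome_table(path: str, snp_density: float = 1 / 500) -> GenomeSpec:
    df = pd.read_csv(path, sep="\t")
    return GenomeSpec(
        chromosomes=tuple((str(c), int(l)) for c, l in zip(df["chrom"], df["length"])),
        snp_density=snp_density,
    )


def _vcf_pooled_ad(vcf_path: str, sample_sets: dict[str, list[str]]):
    """Single pass over a GT:AD VCF summing ref/alt AD per breed.

    Yields nothing; returns (records DataFrame, per-breed (ref_sum, alt_sum)
    arrays, n_multiallelic).  Sites where a sample lacks AD raise a
    ValueError naming the sample and site.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path, gts012=True)
    samples = list(vcf.samples)
    idx = {
        breed: np.array([samples.index(s) for s in ss])
        for breed, ss in sample_sets.items()
    }
    for breed, ss in sample_sets.items():
        missing = set(ss) - set(samples)
        if missing:
            raise ValueError(f"samples {sorted(missing)} of breed {breed} not in VCF")
    chroms, poss, refs, alts = [], [], [], []
    sums = {breed: [] for breed in sample_sets}
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_multi += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"missing AD field at {v.CHROM}:{v.POS}")
        ad = np.asarray(ad)
        ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes missing as negative
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        for breed, rows in idx.items():
            sub = ad[rows]
            sums[breed].append((int(sub[:, 0].sum()), int(sub[:, 1].sum())))
    records = pd.DataFrame(
        {"chrom": chroms, "pos": np.array(poss, dtype=np.int64), "ref": refs, "alt": alts}
    )
    pooled = {breed: np.array(v, dtype=np.int64).reshape(-1, 2) for breed, v in sums.items()}
    return records, pooled, n_multi


def _to_pooled(breed: str, records: pd.DataFrame, sums: np.ndarray, n_multi: int) -> PooledCounts:
    ref_sum, alt_sum = sums[:, 0], sums[:, 1]
    total = ref_sum + alt_sum
    keep = total > 0
    # major = larger pooled sum; tie -> reference allele is major
    alt_is_major = alt_sum > ref_sum
    table = pd.DataFrame(
        {
            "chrom": records["chrom"].to_numpy()[keep],
            "pos": records["pos"].to_numpy()[keep],
            "ref": records["ref"].to_numpy()[keep],
            "alt": records["alt"].to_numpy()[keep],
            "major_allele": np.where(alt_is_major, records["alt"], records["ref"])[keep],
            "minor_allele": np.where(alt_is_major, records["ref"], records["alt"])[keep],
            "major_count": np.maximum(ref_sum, alt_sum)[keep],
            "minor_count": np.minimum(ref_sum, alt_sum)[keep],
        }
    )
    return PooledCounts(breed=breed, table=table, n_multiallelic_skipped=n_multi)


def pool_breed_counts(vcf_path: str, breed_map: pd.DataFrame, breed: str) -> PooledCounts:
    """Sum ref/alt allele depths over one breed's samples at every biallelic
    SNP; drops sites with zero pooled reads; skips multi-allelic records."""
    samples = breed_map.loc[breed_map["breed"] == breed, "sample"].tolist()
    if not samples:
        raise ValueError(f"breed {breed!r} has no samples in the breed map")
    records, pooled, n_multi = _vcf_pooled_ad(vcf_path, {breed: samples})
    return _to_pooled(breed, records, pooled[breed], n_multi)


def pool_all_breeds(vcf_path: str, breed_map: pd.DataFrame) -> dict[str, PooledCounts]:
    """One VCF pass pooling every breed in the map."""
    sample_sets = {
        b: g["sample"].tolist() for b, g in breed_map.groupby("breed", sort=False)
    }
    records, pooled, n_multi = _vcf_pooled_ad(vcf_path, sample_sets)
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    return {b: _to_pooled(b, records, pooled[b], n_multi) for b in sample_sets}


def maf_filter(pooled: PooledCounts, threshold: float = MAF_THRESHOLD) -> PooledCounts:
    """Retain SNPs with pooled minor-allele frequency >= threshold.

    The rule removes MAF < threshold (strictly below), so a SNP at exactly
    the threshold survives.  Filtering is per breed: the same SNP may
    survive in one breed's pool and not another's.
    """
    if not 0 < threshold <= 0.5:
        raise ValueError("threshold must be in (0, 0.5]")
    t = pooled.table
    total = t["major_count"] + t["minor_count"]
    maf = t["minor_count"] / total
    return PooledCounts(
        breed=pooled.breed,
        table=t.loc[maf >= threshold].reset_index(drop=True),
        n_multiallelic_skipped=pooled.n_multiallelic_skipped,
    )


def make_windows(
    genome: GenomeSpec, size: int = WINDOW_SIZE, step: int | None = None
) -> pd.DataFrame:
    """Tile each chromosome with fixed-size windows advancing by ``step``
    (default size/2, i.e. 50% overlap).

    Windows are 0-based half-open, start at 0, and are emitted while
    start + size <= chromosome length — no partial trailing windows, so a
    chromosome shorter than ``size`` contributes none.  ``index`` is a
    genome-wide ordinal (bin number).
    """
    if size <= 0:
        raise ValueError("size must be positive")
    step = size // 2 if step is None else step
    if step <= 0:
        raise ValueError("step must be positive")
    rows = []
    for chrom, length in genome.chromosomes:
        start = 0
        while start + size <= length:
            rows.append((chrom, start, start + size))
            start += step
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["index"] = np.arange(len(df))
    return df


def window_hp(
    pooled: PooledCounts, windows: pd.DataFrame, min_snps: int = MIN_SNPS
) -> pd.DataFrame:
    """Window-summed pooled counts and Hp for one breed.

    A SNP at 1-based position p belongs to window [s, e) iff s < p <= e.
    Windows with fewer than ``min_snps`` retained SNPs are flagged
    ``excluded`` and get no Hp.  Returns the window table with breed,
    n_snps, sum_maj, sum_min, hp, excluded columns (zhp left unset).
    """
    t = pooled.table
    out = windows.copy()
    n_snps = np.zeros(len(out), dtype=np.int64)
    sum_maj = np.zeros(len(out), dtype=np.int64)
    sum_min = np.zeros(len(out), dtype=np.int64)
    for chrom, wsub in out.groupby("chrom", sort=False):
        snps = t.loc[t["chrom"] == chrom]
        pos = snps["pos"].to_numpy()
        cmaj = np.concatenate([[0], np.cumsum(snps["major_count"].to_numpy())])
        cmin = np.concatenate([[0], np.cumsum(snps["minor_count"].to_numpy())])
        # s < p <= e  ->  indices in (searchsorted(pos, s, 'right'), searchsorted(pos, e, 'right')]
        lo = np.searchsorted(pos, wsub["start"].to_numpy(), side="right")
        hi = np.searchsorted(pos, wsub["end"].to_numpy(), side="right")
        n_snps[wsub.index] = hi - lo
        sum_maj[wsub.index] = cmaj[hi] - cmaj[lo]
        sum_min[wsub.index] = cmin[hi] - cmin[lo]
    out["breed"] = pooled.breed
    out["n_snps"] = n_snps
    out["sum_maj"] = sum_maj
    out["sum_min"] = sum_min
    excluded = n_snps < min_snps
    total = (sum_maj + sum_min).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        hp = 2.0 * sum_maj * sum_min / total**2
    out["hp"] = np.where(excluded, np.nan, hp)
    out["excluded"] = excluded
    out["zhp"] = np.nan
    return out


def zhp_transform(stats: pd.DataFrame) -> pd.DataFrame:
    """Z-transform Hp genome-wide over a breed's retained windows.

    zhp = (hp - mean) / sd with the population (divisor-n) standard
    deviation, so retained windows have mean 0 and sd 1 exactly.  Raises on
    fewer than two retained windows or zero spread.
    """
    out = stats.copy()
    retained = ~out["excluded"]
    hp = out.loc[retained, "hp"].to_numpy()
    if len(hp) < 2:
        raise ValueError("ZHp needs >=2 retained windows")
    mean, sd = float(np.mean(hp)), float(np.std(hp))
    if sd == 0:
        raise ValueError("ZHp undefined: all retained windows have identical Hp")
    out.loc[retained, "zhp"] = (hp - mean) / sd
    return out


def call_sweeps(
    stats: pd.DataFrame,
    threshold: float = ZHP_THRESHOLD,
    gene_models: GeneModelIndex | None = None,
) -> pd.DataFrame:
    """Windows with ZHp strictly below the threshold, most extreme first.

    With gene models supplied, each call lists the names of genes whose
    transcript span intersects the window (either strand).
    """
    calls = stats.loc[stats["zhp"] < threshold].sort_values("zhp", kind="mergesort")
    calls = calls.reset_index(drop=True)
    calls["threshold"] = threshold
    if gene_models is not None:
        genes = []
        for row in calls.itertuples(index=False):
            hits = gene_models.overlapping_interval(row.chrom, row.start + 1, row.end)
            genes.append(",".join(sorted({tx.gene for tx in hits})))
        calls["genes"] = genes
    return calls


def per_snp_hp_track(
    pooled: PooledCounts, region: tuple[str, int, int]
) -> pd.DataFrame:
    """Per-SNP heterozygosity track over a region (chrom, start, end).

    hp_snp = 2*maj*min/(maj+min)^2 from that SNP's own pooled counts: 0 for
    a fixed site, 0.5 for equal major/minor read counts.  Region bounds use
    the same convention as windows (start < pos <= end).
    """
    chrom, start, end = region
    t = pooled.table
    sub = t.loc[(t["chrom"] == chrom) & (t["pos"] > start) & (t["pos"] <= end)]
    total = (sub["major_count"] + sub["minor_count"]).to_numpy(dtype=float)
    hp = 2.0 * sub["major_count"].to_numpy() * sub["minor_count"].to_numpy() / total**2
    return pd.DataFrame(
        {"chrom": chrom, "pos": sub["pos"].to_numpy(), "hp_snp": hp}
    )


def scan(
    vcf_path: str,
    breed_map: pd.DataFrame,
    genome: GenomeSpec,
    window_size: int = WINDOW_SIZE,
    step: int | None = None,
    maf_threshold: float = MAF_THRESHOLD,
    min_snps: int = MIN_SNPS,
    zhp_threshold: float = ZHP_THRESHOLD,
    gene_models: GeneModelIndex | None = None,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Full per-breed scan: pool -> MAF filter -> windows -> Hp -> ZHp -> calls.

    Returns ({breed: window stats}, {breed: sweep calls}).
    """
    windows = make_windows(genome, window_size, step)
    pooled = pool_all_breeds(vcf_path, breed_map)
    stats, calls = {}, {}
    for breed, pc in pooled.items():
        filtered = maf_filter(pc, maf_threshold)
        st = window_hp(filtered, windows, min_snps)
        st = zhp_transform(st)
        stats[breed] = st
        calls[breed] = call_sweeps(st, zhp_threshold, gene_models)
        logger.info(
            "%s: %d/%d SNPs past MAF filter, %d/%d windows retained, %d sweep calls",
            breed,
            len(filtered),
            len(pc),
            int((~st["excluded"]).sum()),
            len(st),
            len(calls[breed]),
        )
    return stats, calls


def write_window_table(stats: pd.DataFrame, path: str, params: str = "") -> None:
    with open(path, "w") as fh:
        if params:
            fh.write(f"# {params}\n")
        stats.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def write_sweep_bed(calls: pd.DataFrame, path: str) -> None:
    """Sweep calls as BED: score column holds round(-100 * zhp)."""
    cols = [calls["chrom"], calls["start"], calls["end"], calls["index"], calls["zhp"]]
    genes = calls["genes"] if "genes" in calls.columns else None
    with open(path, "w") as fh:
        for i, (chrom, start, end, ordinal, zhp) in enumerate(zip(*cols)):
            name = (genes.iloc[i] if genes is not None else "") or f"win{ordinal}"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{round(-100 * zhp)}\n")
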