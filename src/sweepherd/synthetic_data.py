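"""Synthetic multi-breed resequencing cohorts.

Everything downstream of read mapping and SNP calling in a multi-breed
resequencing study can be exercised on a cohort generated here: per-breed
allele frequencies drawn around an ancestral frequency under the
Balding–Nichols model, Hardy–Weinberg phased genotypes, per-individual
sequencing read counts with Poisson depth and a per-read base-error rate,
selective-sweep intervals in which chosen breeds are driven to near
fixation, gene models with coding structure for functional annotation, a
SIFT score table, a known-sites list (dbSNP stand-in) and SNP-chip
genotypes with a known error rate.

The default cohort mirrors a five-breed pig resequencing design: 55
animals (10 wild-boar-like + 10/6/14/15 in four domesticated-breed
analogues) at ~12x mean depth.  Breed differentiation parameters are
fixture choices in the 0.05–0.25 range, not estimates of any real
population.

All randomness flows from one master seed through named substreams, so
each stage is independently reproducible and outputs are byte-identical
for identical seeds and specs.

Coordinate conventions: SNP and GFF3 positions are 1-based; the truth
sweep BED is 0-based half-open.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_annotation import Transcript, GeneModelIndex, _in_intervals

__all__ = [
    "GenomeSpec",
    "BreedModel",
    "SweepSpec",
    "ChipSpec",
    "default_breeds",
    "simulate_frequencies",
    "apply_sweeps",
    "simulate_genotypes",
    "simulate_read_counts",
    "sample_names",
    "make_reference",
    "make_gene_models",
    "assign_alleles",
    "make_sift_table",
    "choose_known_sites",
    "make_chip_genotypes",
    "write_cohort",
    "CohortFiles",
]

_BASES = np.array(["A", "C", "G", "T"])
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_STOP_CODONS = ("TAA", "TAG", "TGA")

# named substreams hanging off the master seed
_STREAMS = (
    "genome",
    "genes",
    "frequencies",
    "alleles",
    "genotypes",
    "reads",
    "chip",
    "sift",
    "known",
)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named stage of the simulation."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS.index(stream),))
    )


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names/lengths and the expected SNP density (SNPs per bp)."""

    chromosomes: tuple[tuple[str, int], ...]
    snp_density: float = 1 / 500

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome needs >=1 chromosome")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for _, l in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be positive")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for c, l in self.chromosomes:
            if c == chrom:
                return l
        raise KeyError(chrom)


@dataclass(frozen=True)
class BreedModel:
    """One breed: differentiation (Fst), cohort size, and sequencing model."""

    name: str
    fst: float
    n_individuals: int
    mean_depth: float = 12.0
    base_error: float = 0.001

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 1:
            raise ValueError(f"{self.name}: fst must be in [0,1)")
        if self.n_individuals < 1:
            raise ValueError(f"{self.name}: need >=1 individual")
        if self.mean_depth <= 0:
            raise ValueError(f"{self.name}: mean_depth must be positive")
        if not 0 <= self.base_error < 0.5:
            raise ValueError(f"{self.name}: base_error must be in [0,0.5)")


@dataclass(frozen=True)
class SweepSpec:
    """A selective-sweep interval: minor alleles pushed to residual_maf."""

    chromosome: str
    start: int
    end: int
    breeds: tuple[str, ...]
    residual_maf: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("need 0 <= start < end")
        if not 0 <= self.residual_maf < 0.05:
            raise ValueError("residual_maf must be in [0, 0.05)")
        if not self.breeds:
            raise ValueError("sweep must name >=1 breed")


@dataclass(frozen=True)
class ChipSpec:
    """SNP-chip design: probe count, genotype error and missingness rates."""

    n_probes: int
    genotype_error: float = 0.01
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >=1")
        if not (0 <= self.genotype_error < 1 and 0 <= self.missing_rate < 1):
            raise ValueError("rates must be in [0,1)")


def default_breeds() -> list[BreedModel]:
    """The five-breed, 55-animal default cohort (~12x depth).

    Sizes follow the 10/10/6/14/15 split of the design being emulated; Fst
    values are fixture choices, the wild-boar analogue being the most
    differentiated.
    """
    return [
        BreedModel("KWB", fst=0.25, n_individuals=10),
        BreedModel("KNP", fst=0.15, n_individuals=10),
        BreedModel("DUR", fst=0.12, n_individuals=6),
        BreedModel("LAN", fst=0.08, n_individuals=14),
        BreedModel("YOR", fst=0.08, n_individuals=15),
    ]


def sample_names(breeds: Sequence[BreedModel]) -> list[str]:
    return [f"{b.name}_{i + 1}" for b in breeds for i in range(b.n_individuals)]


def sample_breed_labels(breeds: Sequence[BreedModel]) -> list[str]:
    return [b.name for b in breeds for _ in range(b.n_individuals)]


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def simulate_frequencies(
    genome: GenomeSpec, breeds: Sequence[BreedModel], seed: int
) -> pd.DataFrame:
    """Draw SNP positions and per-breed alt-allele frequencies.

    Ancestral frequencies are Uniform(0.05, 0.95) (avoiding a monomorphic
    bulk); each breed's frequency is Balding–Nichols around the ancestral
    value: Beta(p(1-F)/F, (1-p)(1-F)/F), degenerating to p exactly at F=0.

    Returns one row per SNP: chrom, pos (1-based, strictly increasing per
    chromosome), p_anc, and one p_<breed> column per breed.
    """
    if not genome.chromosomes:
        raise ValueError("empty genome")
    if not breeds:
        raise ValueError("no breeds supplied")
    rng = _rng(seed, "frequencies")
    chroms, positions = [], []
    for name, length in genome.chromosomes:
        n = int(rng.poisson(length * genome.snp_density))
        n = min(n, length)
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1
        chroms.extend([name] * n)
        positions.append(pos)
    pos_all = np.concatenate(positions) if positions else np.array([], dtype=int)
    n_snps = len(pos_all)
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    table = pd.DataFrame({"chrom": chroms, "pos": pos_all.astype(np.int64), "p_anc": p_anc})
    for b in breeds:
        if b.fst == 0:
            table[f"p_{b.name}"] = p_anc
        else:
            scale = (1 - b.fst) / b.fst
            table[f"p_{b.name}"] = rng.beta(p_anc * scale, (1 - p_anc) * scale)
    return table


def apply_sweeps(
    freq_table: pd.DataFrame, sweeps: Sequence[SweepSpec], genome: GenomeSpec
) -> pd.DataFrame:
    """Impose sweep intervals: inside each interval the affected breeds'
    minor allele is pushed to residual_maf (major allele = the currently
    more frequent allele at that SNP in that breed).  Positions are matched
    on the 0-based half-open [start, end) interval."""
    out = freq_table.copy()
    for sw in sweeps:
        if sw.chromosome not in genome.names:
            raise ValueError(f"sweep on unknown chromosome {sw.chromosome!r}")
        if sw.end > genome.length(sw.chromosome):
            raise ValueError(
                f"sweep [{sw.start},{sw.end}) off the end of {sw.chromosome}"
            )
        in_iv = (
            (out["chrom"] == sw.chromosome)
            & (out["pos"] - 1 >= sw.start)
            & (out["pos"] - 1 < sw.end)
        )
        for breed in sw.breeds:
            col = f"p_{breed}"
            if col not in out.columns:
                raise ValueError(f"sweep names unknown breed {breed!r}")
            p = out.loc[in_iv, col]
            out.loc[in_iv, col] = np.where(p > 0.5, 1 - sw.residual_maf, sw.residual_maf)
    return out


# ---------------------------------------------------------------------------
# genotypes and reads
# ---------------------------------------------------------------------------


def simulate_genotypes(
    freq_table: pd.DataFrame, breeds: Sequence[BreedModel], seed: int
) -> np.ndarray:
    """Phased Hardy–Weinberg haplotypes.

    Returns an int8 matrix of shape (2 * total individuals, n_SNPs); rows
    2k and 2k+1 are the two haplotypes of individual k, individuals ordered
    breed by breed.  Each haplotype allele is an independent
    Bernoulli(breed frequency) draw.
    """
    rng = _rng(seed, "genotypes")
    n_snps = len(freq_table)
    blocks = []
    for b in breeds:
        p = freq_table[f"p_{b.name}"].to_numpy()
        blocks.append(
            (rng.random((2 * b.n_individuals, n_snps)) < p).astype(np.int8)
        )
    return np.vstack(blocks)


def dosage_matrix(haplotypes: np.ndarray) -> np.ndarray:
    """(n_individuals, n_SNPs) alt-allele dosage from a phased matrix."""
    return haplotypes[0::2] + haplotypes[1::2]


def simulate_read_counts(
    haplotypes: np.ndarray, breeds: Sequence[BreedModel], seed: int
) -> np.ndarray:
    """Per-individual (ref_reads, alt_reads) at every SNP.

    Depth at each individual-site is Poisson(breed mean_depth); each read
    samples one of the individual's two haplotypes uniformly and reports
    that allele flipped with probability base_error.  Returns an int32
    array of shape (n_individuals, n_SNPs, 2).
    """
    rng = _rng(seed, "reads")
    dose = dosage_matrix(haplotypes)
    n_ind, n_snps = dose.shape
    depth = np.empty((n_ind, n_snps), dtype=np.int64)
    err = np.empty((n_ind, 1))
    row = 0
    for b in breeds:
        depth[row : row + b.n_individuals] = rng.poisson(
            b.mean_depth, size=(b.n_individuals, n_snps)
        )
        err[row : row + b.n_individuals] = b.base_error
        row += b.n_individuals
    # P(read reports alt) given dosage d: e + (d/2)(1-2e)
    p_alt = err + (dose / 2.0) * (1 - 2 * err)
    alt = rng.binomial(depth, p_alt)
    out = np.empty((n_ind, n_snps, 2), dtype=np.int32)
    out[..., 0] = depth - alt
    out[..., 1] = alt
    return out


# ---------------------------------------------------------------------------
# reference sequence and gene models
# ---------------------------------------------------------------------------


def make_reference(genome: GenomeSpec, seed: int) -> dict[str, np.ndarray]:
    """Random reference sequence per chromosome as a mutable '<U1' array."""
    rng = _rng(seed, "genome")
    return {
        name: _BASES[rng.integers(0, 4, size=length)]
        for name, length in genome.chromosomes
    }


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) random sense codons + a stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(_BASES[rng.integers(0, 4, size=3)])
        if c not in _STOP_CODONS:  # internal ATG (Met) is fine
            codons.append(c)
    codons.append(_STOP_CODONS[rng.integers(0, 3)])
    return "".join(codons)


_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_RC[b] for b in reversed(s))


def make_gene_models(
    genome: GenomeSpec,
    reference: dict[str, np.ndarray],
    seed: int,
    mean_gap: int = 15_000,
    coding_fraction: float = 0.8,
) -> list[Transcript]:
    """Place non-overlapping transcripts along each chromosome and patch the
    reference so every coding transcript carries a valid ORF (ATG start, no
    internal stop, terminal stop) and canonical GT/AG splice dinucleotides.

    Transcripts have 2–5 exons; coding ones get a 5' and 3' UTR inside the
    terminal exons.  All intervals returned are 1-based inclusive.
    """
    rng = _rng(seed, "genes")
    transcripts: list[Transcript] = []
    gidx = 0
    for chrom, length in genome.chromosomes:
        cursor = int(rng.integers(mean_gap // 3, mean_gap))
        while True:
            n_exons = int(rng.integers(2, 6))
            exon_lens = rng.integers(150, 400, size=n_exons)
            intron_lens = rng.integers(500, 3000, size=n_exons - 1)
            span = int(exon_lens.sum() + intron_lens.sum())
            if cursor + span + 1 >= length:
                break
            start = cursor + 1  # 1-based
            exons = []
            p = start
            for i in range(n_exons):
                exons.append((p, p + int(exon_lens[i]) - 1))
                p += int(exon_lens[i])
                if i < n_exons - 1:
                    p += int(intron_lens[i])
            strand = "+" if rng.random() < 0.5 else "-"
            coding = rng.random() < coding_fraction
            gidx += 1
            gene = f"GENE{gidx:04d}"
            tid = f"TX{gidx:04d}"
            if coding:
                tx = _build_coding_transcript(gene, tid, chrom, strand, exons, rng)
                _patch_orf(reference[chrom], tx, rng)
            else:
                tx = Transcript(gene, tid, chrom, strand, tuple(exons))
            _patch_splice_sites(reference[chrom], tx)
            transcripts.append(tx)
            cursor = exons[-1][1] + int(rng.integers(mean_gap // 2, 2 * mean_gap))
    return transcripts


def _build_coding_transcript(gene, tid, chrom, strand, exons, rng) -> Transcript:
    total = sum(e - s + 1 for s, e in exons)
    u5 = int(rng.integers(30, 90))
    u3 = int(rng.integers(30, 90))
    cds_len = total - u5 - u3
    u3 += cds_len % 3  # make CDS a codon multiple
    cds_len = total - u5 - u3
    # walk exons in transcript orientation, splitting into UTR5 | CDS | UTR3
    order = exons if strand == "+" else exons[::-1]
    utr5, cds, utr3 = [], [], []
    offset = 0  # transcript-space offset of current exon start
    for s, e in order:
        elen = e - s + 1
        for t0, t1, bucket in (
            (0, u5, utr5),
            (u5, u5 + cds_len, cds),
            (u5 + cds_len, total, utr3),
        ):
            lo = max(t0, offset)
            hi = min(t1, offset + elen)
            if lo < hi:
                if strand == "+":
                    bucket.append((s + lo - offset, s + hi - 1 - offset))
                else:
                    bucket.append((e - (hi - 1 - offset), e - (lo - offset)))
        offset += elen
    return Transcript(
        gene,
        tid,
        chrom,
        strand,
        tuple(exons),
        cds=tuple(sorted(cds)),
        utr5=tuple(sorted(utr5)),
        utr3=tuple(sorted(utr3)),
    )


def _patch_orf(seq: np.ndarray, tx: Transcript, rng: np.random.Generator) -> None:
    coding_pos = tx.coding_positions()
    orf = _random_orf(rng, len(coding_pos) // 3)
    if tx.strand == "-":
        # coding_pos is in translation order (descending); write complement
        for p, b in zip(coding_pos, orf):
            seq[p - 1] = _RC[b]
    else:
        for p, b in zip(coding_pos, orf):
            seq[p - 1] = b


def _patch_splice_sites(seq: np.ndarray, tx: Transcript) -> None:
    for istart, iend in tx.introns():
        if iend - istart + 1 < 4:
            continue
        if tx.strand == "+":
            seq[istart - 1], seq[istart] = "G", "T"
            seq[iend - 2], seq[iend - 1] = "A", "G"
        else:
            seq[iend - 2], seq[iend - 1] = "A", "C"  # revcomp of GT
            seq[istart - 1], seq[istart] = "C", "T"  # revcomp of AG


def assign_alleles(
    freq_table: pd.DataFrame,
    reference: dict[str, np.ndarray],
    seed: int,
    ti_fraction: float = 2 / 3,
) -> pd.DataFrame:
    """Attach ref/alt bases to each SNP.

    The ref allele is the reference-genome base; the alt allele is the
    transition partner with probability ti_fraction (default 2/3, i.e. a
    2:1 Ti:Tv mutation mix) and otherwise one of the two transversion
    partners, uniformly.
    """
    rng = _rng(seed, "alleles")
    out = freq_table.copy()
    refs = np.empty(len(out), dtype="<U1")
    for chrom, sub in out.groupby("chrom", sort=False):
        refs[sub.index] = reference[chrom][sub["pos"].to_numpy() - 1]
    is_ti = rng.random(len(out)) < ti_fraction
    pick = rng.integers(0, 2, size=len(out))
    alts = np.empty(len(out), dtype="<U1")
    for i, r in enumerate(refs):
        if is_ti[i]:
            alts[i] = _TRANSITION_PARTNER[r]
        else:
            tv = [b for b in "ACGT" if b != r and b != _TRANSITION_PARTNER[r]]
            alts[i] = tv[pick[i]]
    out["ref"] = refs
    out["alt"] = alts
    return out


# ---------------------------------------------------------------------------
# auxiliary tables: SIFT, known sites, chip
# ---------------------------------------------------------------------------


def make_sift_table(
    freq_table: pd.DataFrame,
    gene_models: GeneModelIndex,
    seed: int,
    coverage: float = 0.8,
) -> pd.DataFrame:
    """SIFT scores (Uniform(0,1), 3 decimals) for a random subset of coding
    SNPs; columns transcript, chrom, pos, alt, score."""
    rng = _rng(seed, "sift")
    rows = []
    for row in freq_table.itertuples(index=False):
        for tx in gene_models.overlapping(row.chrom, int(row.pos)):
            if tx.coding and _in_intervals(int(row.pos), tx.cds):
                rows.append((tx.transcript_id, row.chrom, int(row.pos), row.alt))
                break
    keep = rng.random(len(rows)) < coverage
    scores = np.round(rng.uniform(0, 1, size=len(rows)), 3)
    table = pd.DataFrame(rows, columns=["transcript", "chrom", "pos", "alt"])
    table["score"] = scores
    return table.loc[keep].reset_index(drop=True)


def choose_known_sites(
    freq_table: pd.DataFrame, fraction: float, seed: int
) -> pd.DataFrame:
    """Random subset of SNP positions standing in for a dbSNP build; the
    complement of ``fraction`` is the expected novel fraction on re-ingest."""
    rng = _rng(seed, "known")
    keep = rng.random(len(freq_table)) < fraction
    return freq_table.loc[keep, ["chrom", "pos"]].reset_index(drop=True)


def make_chip_genotypes(
    freq_table: pd.DataFrame,
    haplotypes: np.ndarray,
    breeds: Sequence[BreedModel],
    chip: ChipSpec,
    seed: int,
) -> pd.DataFrame:
    """Chip genotypes for every animal at ``n_probes`` probes drawn
    uniformly from the simulated SNPs.

    Genotype errors flip a call to a uniformly chosen *different* genotype
    with probability genotype_error; missing calls are '.' alleles.
    Returns long-format columns: animal, chrom, pos, allele1, allele2.
    """
    if chip.n_probes > len(freq_table):
        raise ValueError("n_probes exceeds the number of simulated SNPs")
    rng = _rng(seed, "chip")
    probe_idx = np.sort(rng.choice(len(freq_table), size=chip.n_probes, replace=False))
    probes = freq_table.iloc[probe_idx]
    dose = dosage_matrix(haplotypes)[:, probe_idx]  # (n_ind, n_probes)
    err = rng.random(dose.shape) < chip.genotype_error
    shift = rng.integers(1, 3, size=dose.shape)
    observed = np.where(err, (dose + shift) % 3, dose)
    missing = rng.random(dose.shape) < chip.missing_rate
    names = sample_names(breeds)
    ref = probes["ref"].to_numpy()
    alt = probes["alt"].to_numpy()
    a1 = np.where(observed >= 1, alt, ref)
    a2 = np.where(observed == 2, alt, ref)
    rec = {
        "animal": np.repeat(names, chip.n_probes),
        "chrom": np.tile(probes["chrom"].to_numpy(), len(names)),
        "pos": np.tile(probes["pos"].to_numpy(), len(names)),
        "allele1": np.where(missing, ".", a1).ravel(),
        "allele2": np.where(missing, ".", a2).ravel(),
    }
    return pd.DataFrame(rec)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


@dataclass
class CohortFiles:
    """Paths of a written cohort plus the in-memory truth behind it."""

    outdir: str
    vcf: str
    breed_map: str
    genome_table: str
    reference_fasta: str
    gene_models: str
    sift_table: str
    known_sites: str
    chip_table: str | None
    truth_sweeps: str
    truth_frequencies: str
    truth_chip: str | None
    manifest: str
    # in-memory truth
    genome: GenomeSpec = None
    breeds: list[BreedModel] = field(default_factory=list)
    freq_table: pd.DataFrame = None
    haplotypes: np.ndarray = None
    samples: list[str] = field(default_factory=list)
    sample_breeds: list[str] = field(default_factory=list)
    transcripts: list[Transcript] = field(default_factory=list)
    read_counts: np.ndarray = None


def _write_fasta(path: str, reference: dict[str, np.ndarray], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, arr in reference.items():
            fh.write(f">{name}\n")
            s = "".join(arr.tolist())
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def _write_vcf(
    path: str,
    freq_table: pd.DataFrame,
    haplotypes: np.ndarray,
    read_counts: np.ndarray,
    samples: Sequence[str],
    genome: GenomeSpec,
) -> None:
    n_ind = len(samples)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepherd-synthetic\n")
        for name, length in genome.chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        chroms = freq_table["chrom"].to_numpy()
        poss = freq_table["pos"].to_numpy()
        refs = freq_table["ref"].to_numpy()
        alts = freq_table["alt"].to_numpy()
        h1 = haplotypes[0::2]
        h2 = haplotypes[1::2]
        for j in range(len(freq_table)):
            cells = [
                f"{h1[i, j]}|{h2[i, j]}:{read_counts[i, j, 0]},{read_counts[i, j, 1]}"
                for i in range(n_ind)
            ]
            fh.write(
                f"{chroms[j]}\t{poss[j]}\t.\t{refs[j]}\t{alts[j]}\t.\tPASS\t.\tGT:AD\t"
                + "\t".join(cells)
                + "\n"
            )


def _write_gff3(path: str, transcripts: Sequence[Transcript]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in transcripts:
            attrs_gene = f"ID=g_{tx.gene};Name={tx.gene}"
            fh.write(
                f"{tx.chrom}\tsweepherd\tgene\t{tx.start}\t{tx.end}\t.\t{tx.strand}\t.\t{attrs_gene}\n"
            )
            fh.write(
                f"{tx.chrom}\tsweepherd\tmRNA\t{tx.start}\t{tx.end}\t.\t{tx.strand}\t.\t"
                f"ID={tx.transcript_id};Parent=g_{tx.gene};gene={tx.gene}\n"
            )
            for ftype, ivs in (
                ("exon", tx.exons),
                ("CDS", tx.cds),
                ("five_prime_UTR", tx.utr5),
                ("three_prime_UTR", tx.utr3),
            ):
                phase_needed = ftype == "CDS"
                if phase_needed:
                    # compute phase walking CDS in transcript orientation
                    order = ivs if tx.strand == "+" else ivs[::-1]
                    phases = {}
                    acc = 0
                    for s, e in order:
                        phases[(s, e)] = (3 - acc % 3) % 3
                        acc += e - s + 1
                for s, e in ivs:
                    phase = str(phases[(s, e)]) if phase_needed else "."
                    fh.write(
                        f"{tx.chrom}\tsweepherd\t{ftype}\t{s}\t{e}\t.\t{tx.strand}\t{phase}\t"
                        f"Parent={tx.transcript_id}\n"
                    )


def write_cohort(
    outdir: str,
    genome: GenomeSpec,
    breeds: Sequence[BreedModel] | None = None,
    sweeps: Sequence[SweepSpec] = (),
    chip: ChipSpec | None = None,
    seed: int = 0,
    known_fraction: float = 0.745,
    sift_coverage: float = 0.8,
    ti_fraction: float = 2 / 3,
) -> CohortFiles:
    """Simulate a full cohort and write every downstream input to ``outdir``.

    Files written: cohort VCF (GT:AD), sample->breed TSV, chromosome-length
    TSV, reference FASTA, GFF3 gene models, SIFT TSV, known-sites TSV,
    optional chip TSV, and a truth/ directory (sweep BED, true frequency
    table, chip error rates, manifest).  Identical arguments produce
    byte-identical files.
    """
    breeds = list(breeds) if breeds is not None else default_breeds()
    os.makedirs(outdir, exist_ok=True)
    truth_dir = os.path.join(outdir, "truth")
    os.makedirs(truth_dir, exist_ok=True)

    reference = make_reference(genome, seed)
    transcripts = make_gene_models(genome, reference, seed)
    index = GeneModelIndex(transcripts)
    freq = simulate_frequencies(genome, breeds, seed)
    freq = apply_sweeps(freq, sweeps, genome)
    freq = assign_alleles(freq, reference, seed, ti_fraction=ti_fraction)
    haps = simulate_genotypes(freq, breeds, seed)
    reads = simulate_read_counts(haps, breeds, seed)
    samples = sample_names(breeds)
    labels = sample_breed_labels(breeds)

    paths = {
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "breed_map": os.path.join(outdir, "breeds.tsv"),
        "genome_table": os.path.join(outdir, "genome.tsv"),
        "reference_fasta": os.path.join(outdir, "reference.fa"),
        "gene_models": os.path.join(outdir, "genes.gff3"),
        "sift_table": os.path.join(outdir, "sift.tsv"),
        "known_sites": os.path.join(outdir, "known_sites.tsv"),
        "chip_table": os.path.join(outdir, "chip.tsv") if chip else None,
        "truth_sweeps": os.path.join(truth_dir, "sweeps.bed"),
        "truth_frequencies": os.path.join(truth_dir, "frequencies.tsv"),
        "truth_chip": os.path.join(truth_dir, "chip.json") if chip else None,
        "manifest": os.path.join(truth_dir, "manifest.json"),
    }

    _write_vcf(paths["vcf"], freq, haps, reads, samples, genome)
    pd.DataFrame({"sample": samples, "breed": labels}).to_csv(
        paths["breed_map"], sep="\t", index=False
    )
    pd.DataFrame(genome.chromosomes, columns=["chrom", "length"]).to_csv(
        paths["genome_table"], sep="\t", index=False
    )
    _write_fasta(paths["reference_fasta"], reference)
    _write_gff3(paths["gene_models"], transcripts)
    make_sift_table(freq, index, seed, coverage=sift_coverage).to_csv(
        paths["sift_table"], sep="\t", index=False
    )
    choose_known_sites(freq, known_fraction, seed).to_csv(
        paths["known_sites"], sep="\t", index=False
    )
    chip_df = None
    if chip:
        chip_df = make_chip_genotypes(freq, haps, breeds, chip, seed)
        chip_df.to_csv(paths["chip_table"], sep="\t", index=False)
        with open(paths["truth_chip"], "w") as fh:
            json.dump(
                {"genotype_error": chip.genotype_error, "missing_rate": chip.missing_rate},
                fh,
                indent=1,
            )

    with open(paths["truth_sweeps"], "w") as fh:
        for sw in sweeps:
            fh.write(
                f"{sw.chromosome}\t{sw.start}\t{sw.end}\t{','.join(sw.breeds)}\t"
                f"{sw.residual_maf:g}\n"
            )
    freq.to_csv(paths["truth_frequencies"], sep="\t", index=False, float_format="%.6f")
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {
                "seed": int(seed),
                "genome": {"chromosomes": list(genome.chromosomes), "snp_density": genome.snp_density},
                "breeds": [asdict(b) for b in breeds],
                "sweeps": [asdict(s) for s in sweeps],
                "chip": asdict(chip) if chip else None,
                "known_fraction": known_fraction,
                "sift_coverage": sift_coverage,
                "ti_fraction": ti_fraction,
                "n_snps": int(len(freq)),
                "files": {k: v for k, v in paths.items() if v},
            },
            fh,
            indent=1,
        )

    return CohortFiles(
        outdir=outdir,
        **paths,
        genome=genome,
        breeds=breeds,
        freq_table=freq,
        haplotypes=haps,
        samples=samples,
        sample_breeds=labels,
        transcripts=transcripts,
        read_counts=reads,
    )
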