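"""Functional annotation of SNPs against canonical gene models.

Every biallelic SNP is assigned exactly one of 12 functional categories
(splice_site_acceptor, splice_site_donor, start_lost, stop_gained, stop_lost,
non_synonymous_coding, synonymous_coding, utr_5, utr_3, non_coding_exon,
intron, intergenic), resolved most-severe-first when a site is covered by
more than one annotation context.  Coding effects are computed by
substituting the alternate base into the affected codon on the coding
strand of the transcript, so minus-strand genes are handled by reverse
complementing both the codon and the alternate allele.

The module also provides the SNP-level QC statistics that accompany such an
annotation in resequencing studies: the transition/transversion ratio,
novelty against a known-sites list (a dbSNP stand-in), SIFT
damaging/tolerant classification of non-synonymous SNPs, breed-specific
nsSNP extraction, and a per-breed category summary table.

One canonical transcript per gene is assumed; the gene-model file is taken
as already reduced to canonical transcripts.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

__all__ = [
    "CATEGORIES",
    "Transcript",
    "GeneModelIndex",
    "TiTvSummary",
    "load_gene_models",
    "classify_variant",
    "annotate_variants",
    "titv",
    "novelty",
    "sift_classify",
    "breed_presence",
    "breed_specific_nssnps",
    "category_summary",
    "write_annotated_vcf",
]

#: The 12 SNP categories, in decreasing severity.  The order IS the
#: precedence used when a variant is covered by several contexts.
CATEGORIES = (
    "splice_site_acceptor",
    "splice_site_donor",
    "start_lost",
    "stop_gained",
    "stop_lost",
    "non_synonymous_coding",
    "synonymous_coding",
    "utr_5",
    "utr_3",
    "non_coding_exon",
    "intron",
    "intergenic",
)

_PRECEDENCE = {cat: i for i, cat in enumerate(CATEGORIES)}

#: coding categories -> coarse functional class
_FUNCTIONAL_CLASS = {
    "non_synonymous_coding": "missense",
    "stop_gained": "nonsense",
    "synonymous_coding": "silent",
}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class Transcript:
    """One canonical transcript; intervals are 1-based inclusive, genomic order."""

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for name in ("exons", "cds", "utr5", "utr3"):
            ivs = getattr(self, name)
            if any(s > e for s, e in ivs):
                raise ValueError(f"{self.transcript_id}: malformed {name} interval")
            if list(ivs) != sorted(ivs):
                raise ValueError(f"{self.transcript_id}: {name} not sorted")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript without exons")
        if self.coding and self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} not a multiple of 3"
            )

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] - self.exons[i][1] > 1
        ]

    def coding_positions(self) -> np.ndarray:
        """Genomic positions of the CDS in translation (5'->3' coding) order."""
        pos = np.concatenate(
            [np.arange(s, e + 1, dtype=np.int64) for s, e in self.cds]
        )
        return pos[::-1] if self.strand == "-" else pos


class GeneModelIndex:
    """Interval index over transcripts for fast per-position lookup."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts = list(transcripts)
        self._trees: dict[str, IntervalTree] = {}
        for tx in self.transcripts:
            tree = self._trees.setdefault(tx.chrom, IntervalTree())
            # IntervalTree is half-open; transcript span is 1-based inclusive
            tree.addi(tx.start, tx.end + 1, tx)
        self._coding_pos_cache: dict[str, np.ndarray] = {}

    def overlapping(self, chrom: str, pos: int) -> list[Transcript]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree[pos]]

    def overlapping_interval(self, chrom: str, start: int, end: int) -> list[Transcript]:
        """Transcripts intersecting [start, end] (1-based inclusive)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree[start : end + 1]]

    def coding_positions(self, tx: Transcript) -> np.ndarray:
        arr = self._coding_pos_cache.get(tx.transcript_id)
        if arr is None:
            arr = tx.coding_positions()
            self._coding_pos_cache[tx.transcript_id] = arr
        return arr


def load_gene_models(gff_path: str) -> GeneModelIndex:
    """Read canonical gene models from a GFF3 file (gene/mRNA|transcript/
    exon/CDS/five_prime_UTR/three_prime_UTR features)."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    transcripts = []
    for tx in db.features_of_type(("mRNA", "transcript")):
        gene_name = tx.attributes.get("gene", tx.attributes.get("Parent", [tx.id]))[0]

        def ivs(ftype: str) -> tuple[tuple[int, int], ...]:
            return tuple(
                sorted((f.start, f.end) for f in db.children(tx, featuretype=ftype))
            )

        transcripts.append(
            Transcript(
                gene=gene_name,
                transcript_id=tx.id,
                chrom=tx.seqid,
                strand=tx.strand,
                exons=ivs("exon"),
                cds=ivs("CDS"),
                utr5=ivs("five_prime_UTR"),
                utr3=ivs("three_prime_UTR"),
            )
        )
    return GeneModelIndex(transcripts)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _ref_base(reference, chrom: str, pos: int) -> str:
    """1-based base lookup working for pyfaidx.Fasta or a plain dict of str."""
    seq = reference[chrom]
    return str(seq[pos - 1]).upper()


def _in_intervals(pos: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def _splice_category(tx: Transcript, pos: int) -> str | None:
    for istart, iend in tx.introns():
        if iend - istart + 1 < 2:
            continue
        left = (istart, min(istart + 1, iend))
        right = (max(iend - 1, istart), iend)
        donor, acceptor = (left, right) if tx.strand == "+" else (right, left)
        if donor[0] <= pos <= donor[1]:
            return "splice_site_donor"
        if acceptor[0] <= pos <= acceptor[1]:
            return "splice_site_acceptor"
    return None


def _coding_effect(
    tx: Transcript, pos: int, ref: str, alt: str, reference, index: GeneModelIndex | None
) -> str:
    coding_pos = index.coding_positions(tx) if index is not None else tx.coding_positions()
    hits = np.flatnonzero(coding_pos == pos)
    if hits.size == 0:  # pragma: no cover - guarded by caller
        raise ValueError(f"position {pos} not in CDS of {tx.transcript_id}")
    idx = int(hits[0])
    codon_idx = idx // 3
    codon_genomic = coding_pos[codon_idx * 3 : codon_idx * 3 + 3]
    if codon_genomic.size < 3:
        raise ValueError(f"{tx.transcript_id}: incomplete terminal codon")
    bases = [_ref_base(reference, tx.chrom, int(p)) for p in codon_genomic]
    if tx.strand == "-":
        bases = [_COMPLEMENT[b] for b in bases]
        ref_c, alt_c = _COMPLEMENT[ref], _COMPLEMENT[alt]
    else:
        ref_c, alt_c = ref, alt
    within = idx - codon_idx * 3
    if bases[within] != ref_c:
        raise ValueError(
            f"reference mismatch at {tx.chrom}:{pos}: VCF ref {ref} vs genome "
            f"{bases[within] if tx.strand == '+' else _COMPLEMENT[bases[within]]}"
        )
    ref_codon = "".join(bases)
    alt_codon = ref_codon[:within] + alt_c + ref_codon[within + 1 :]
    if codon_idx == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return "start_lost"
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref != "*" and aa_alt == "*":
        return "stop_gained"
    if aa_ref == "*" and aa_alt != "*":
        return "stop_lost"
    return "synonymous_coding" if aa_ref == aa_alt else "non_synonymous_coding"


def _transcript_category(
    tx: Transcript, pos: int, ref: str, alt: str, reference, index: GeneModelIndex | None
) -> tuple[str, Transcript | None]:
    splice = _splice_category(tx, pos)
    if splice is not None:
        return splice, tx
    if _in_intervals(pos, tx.exons):
        if tx.coding:
            if _in_intervals(pos, tx.cds):
                return _coding_effect(tx, pos, ref, alt, reference, index), tx
            if _in_intervals(pos, tx.utr5):
                return "utr_5", tx
            if _in_intervals(pos, tx.utr3):
                return "utr_3", tx
            return "non_coding_exon", tx
        return "non_coding_exon", tx
    return "intron", tx


def classify_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene_models: GeneModelIndex,
    reference,
) -> dict:
    """Assign a single functional category to one biallelic SNP.

    Returns a dict with ``category``, ``functional_class`` and the ``gene`` /
    ``transcript`` that determined the call (None for intergenic).  Raises
    ``ValueError`` when the stated ref allele disagrees with the reference
    sequence.
    """
    genome_base = _ref_base(reference, chrom, pos)
    if genome_base != ref.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: VCF ref {ref}, genome {genome_base}"
        )
    best: tuple[str, Transcript | None] = ("intergenic", None)
    for tx in gene_models.overlapping(chrom, pos):
        cat, src = _transcript_category(tx, pos, ref.upper(), alt.upper(), reference, gene_models)
        if _PRECEDENCE[cat] < _PRECEDENCE[best[0]]:
            best = (cat, src)
    cat, tx = best
    return {
        "category": cat,
        "functional_class": _FUNCTIONAL_CLASS.get(cat, "none"),
        "gene": tx.gene if tx is not None else None,
        "transcript": tx.transcript_id if tx is not None else None,
    }


def annotate_variants(
    variants: pd.DataFrame, gene_models: GeneModelIndex, reference
) -> pd.DataFrame:
    """Classify a table of SNPs (columns chrom, pos, ref, alt).

    Returns a copy with category / functional_class / gene / transcript
    columns appended; order is preserved.
    """
    records = [
        classify_variant(row.chrom, int(row.pos), row.ref, row.alt, gene_models, reference)
        for row in variants.itertuples(index=False)
    ]
    out = variants.reset_index(drop=True).copy()
    extra = pd.DataFrame.from_records(records)
    for col in ("category", "functional_class", "gene", "transcript"):
        out[col] = extra[col]
    return out


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TiTvSummary:
    transitions: int
    transversions: int

    @property
    def ratio(self) -> float | None:
        """Ti/Tv ratio; None (undefined) when no transversions were seen."""
        if self.transversions == 0:
            return None
        return self.transitions / self.transversions


def is_transition(ref: str, alt: str) -> bool:
    return (ref.upper(), alt.upper()) in _TRANSITIONS


def titv(variants: pd.DataFrame, mask: np.ndarray | None = None) -> TiTvSummary:
    """Transition/transversion tally over biallelic SNPs (columns ref, alt).

    ``mask`` optionally restricts the tally, e.g. to sites segregating in one
    breed."""
    ref = variants["ref"].str.upper().to_numpy()
    alt = variants["alt"].str.upper().to_numpy()
    ti = np.array([(r, a) in _TRANSITIONS for r, a in zip(ref, alt)])
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        ti, total = ti[mask], int(mask.sum())
    else:
        total = len(ti)
    n_ti = int(ti.sum())
    return TiTvSummary(transitions=n_ti, transversions=total - n_ti)


def novelty(
    variants: pd.DataFrame,
    known_sites: Iterable,
    allele_aware: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Flag variants absent from a known-sites list and report the novel fraction.

    ``known_sites`` holds (chrom, pos) tuples, or (chrom, pos, ref, alt) when
    ``allele_aware``.  Position-only matching is the default, mirroring how
    dbSNP-build comparisons were done before allele-aware matching was common.
    """
    known = set(map(tuple, known_sites))
    if allele_aware:
        keys = zip(variants["chrom"], variants["pos"], variants["ref"], variants["alt"])
    else:
        keys = zip(variants["chrom"], variants["pos"])
    flags = np.array([k not in known for k in keys], dtype=bool)
    out = variants.copy()
    out["novel"] = flags
    fraction = float(flags.mean()) if len(out) else 0.0
    return out, fraction


def sift_classify(
    nssnps: pd.DataFrame, sift_table: pd.DataFrame, threshold: float = 0.05
) -> pd.DataFrame:
    """Attach damaging/tolerant/unscored SIFT classes to nsSNPs.

    ``sift_table`` columns: chrom, pos, alt, score.  A score <= threshold
    (default 0.05) is damaging, above it tolerant; nsSNPs without a score
    are unscored.
    """
    scores = sift_table["score"].to_numpy(dtype=float)
    if ((scores < 0) | (scores > 1)).any():
        bad = sift_table.loc[(scores < 0) | (scores > 1)].iloc[0]
        raise ValueError(f"SIFT score outside [0,1] at {bad['chrom']}:{bad['pos']}")
    lookup = {
        (c, int(p), a): float(s)
        for c, p, a, s in zip(
            sift_table["chrom"], sift_table["pos"], sift_table["alt"], scores
        )
    }
    out = nssnps.copy()
    got = [lookup.get((c, int(p), a)) for c, p, a in zip(out["chrom"], out["pos"], out["alt"])]
    out["sift_score"] = [math.nan if s is None else s for s in got]
    out["sift_class"] = [
        "unscored" if s is None else ("damaging" if s <= threshold else "tolerant")
        for s in got
    ]
    return out


def breed_presence(
    dosages: np.ndarray, sample_breeds: Sequence[str], breed_order: Sequence[str]
) -> np.ndarray:
    """Boolean (n_breeds, n_sites) matrix: alt allele seen in >=1 individual.

    ``dosages`` is (n_samples, n_sites) with values 0/1/2 and -1 for missing.
    """
    sample_breeds = np.asarray(sample_breeds)
    out = np.zeros((len(breed_order), dosages.shape[1]), dtype=bool)
    for i, breed in enumerate(breed_order):
        rows = dosages[sample_breeds == breed]
        out[i] = (rows > 0).any(axis=0)
    return out


def breed_specific_nssnps(
    annotated: pd.DataFrame,
    presence: np.ndarray,
    breed_order: Sequence[str],
) -> dict[str, pd.DataFrame]:
    """Per-breed lists of nsSNPs whose alt allele occurs in exactly one breed.

    ``presence`` rows follow ``breed_order`` and columns follow the row order
    of ``annotated``.
    """
    ns_mask = (annotated["category"] == "non_synonymous_coding").to_numpy()
    n_breeds_with = presence.sum(axis=0)
    out: dict[str, pd.DataFrame] = {}
    for i, breed in enumerate(breed_order):
        keep = ns_mask & presence[i] & (n_breeds_with == 1)
        out[breed] = annotated.loc[keep].reset_index(drop=True)
    return out


def category_summary(
    annotated: pd.DataFrame,
    presence: np.ndarray | None = None,
    breed_order: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-breed and total SNP counts per category, plus functional-class and
    Ti/Tv rows — the shape of a cohort annotation summary table."""

    def column(mask: np.ndarray | None) -> dict[str, object]:
        sub = annotated if mask is None else annotated.loc[mask]
        cat_counts = Counter(sub["category"])
        tt = titv(sub) if len(sub) else TiTvSummary(0, 0)
        col: dict[str, object] = {"SNP": len(sub)}
        col["Transition"] = tt.transitions
        col["Transversion"] = tt.transversions
        for cat in CATEGORIES:
            col[cat] = cat_counts.get(cat, 0)
        col["missense"] = cat_counts.get("non_synonymous_coding", 0)
        col["nonsense"] = cat_counts.get("stop_gained", 0)
        col["silent"] = cat_counts.get("synonymous_coding", 0)
        return col

    data = {"Total": column(None)}
    for i, breed in enumerate(breed_order):
        data[breed] = column(presence[i])
    return pd.DataFrame(data)


def write_annotated_vcf(in_vcf: str, annotated: pd.DataFrame, out_path: str) -> None:
    """Copy a VCF adding CAT / SIFTCLS / NOVEL INFO tags from an annotation table."""
    ann = annotated.set_index(["chrom", "pos"])
    header_extra = (
        '##INFO=<ID=CAT,Number=1,Type=String,Description="Functional category">\n'
        '##INFO=<ID=SIFTCLS,Number=1,Type=String,Description="SIFT class">\n'
        '##INFO=<ID=NOVEL,Number=0,Type=Flag,Description="Absent from known sites">\n'
    )
    with open(in_vcf) as fin, open(out_path, "w") as fout:
        for line in fin:
            if line.startswith("##"):
                fout.write(line)
                continue
            if line.startswith("#CHROM"):
                fout.write(header_extra)
                fout.write(line)
                continue
            fields = line.rstrip("\n").split("\t")
            key = (fields[0], int(fields[1]))
            if key in ann.index:
                row = ann.loc[key]
                tags = [f"CAT={row['category']}"]
                if "sift_class" in row and isinstance(row.get("sift_class"), str):
                    tags.append(f"SIFTCLS={row['sift_class']}")
                if bool(row.get("novel", False)):
                    tags.append("NOVEL")
                fields[7] = ";".join(tags) if fields[7] in (".", "") else fields[7] + ";" + ";".join(tags)
            fout.write("\t".join(fields) + "\n")
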