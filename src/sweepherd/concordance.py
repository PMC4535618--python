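"""Chip-vs-sequencing genotype concordance.

Validates sequencing-derived genotypes against SNP-array calls: for each
animal, the concordance rate is the number of probes whose unordered
chip allele pair equals the sequencing genotype at that position, divided
by the TOTAL number of probes — probes with a missing chip call, a
missing sequencing call, or (optionally) no VCF record count in the
denominator but never in the numerator.

Chip alleles are assumed oriented to the reference strand (the chip's
reference allele equals the reference-genome base).  A harmonisation
helper fixes probes reported on the opposite strand, erroring on
strand-ambiguous A/T and C/G probes unless they are dropped.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["read_chip_table", "harmonize_chip_alleles", "concordance"]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", ".": "."}


def read_chip_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"animal", "chrom", "pos", "allele1", "allele2"}
    if not required <= set(df.columns):
        raise ValueError(f"chip table must have columns {sorted(required)}")
    return df


def harmonize_chip_alleles(
    chip: pd.DataFrame, sites: pd.DataFrame, drop_ambiguous: bool = False
) -> pd.DataFrame:
    """Orient chip allele pairs to the VCF ref/alt alleles.

    Probes whose alleles are not a subset of {ref, alt} are complemented;
    strand-ambiguous probes (A/T or C/G ref-alt pairs) cannot be resolved
    and raise, or are set to missing when ``drop_ambiguous``.
    """
    site_alleles = {
        (c, int(p)): {r.upper(), a.upper()}
        for c, p, r, a in zip(sites["chrom"], sites["pos"], sites["ref"], sites["alt"])
    }
    out = chip.copy()
    a1 = out["allele1"].str.upper().to_numpy().copy()
    a2 = out["allele2"].str.upper().to_numpy().copy()
    for i, (c, p) in enumerate(zip(out["chrom"], out["pos"])):
        alleles = site_alleles.get((c, int(p)))
        if alleles is None or a1[i] == ".":
            continue
        probe = {a1[i], a2[i]}
        if probe <= alleles:
            continue
        flipped = {_COMPLEMENT[a] for a in probe}
        ambiguous = {frozenset({"A", "T"}), frozenset({"C", "G"})}
        if frozenset(alleles) in ambiguous:
            if drop_ambiguous:
                a1[i] = a2[i] = "."
                continue
            raise ValueError(
                f"strand-ambiguous probe at {c}:{p} with alleles {sorted(alleles)}"
            )
        if flipped <= alleles:
            a1[i] = _COMPLEMENT[a1[i]]
            a2[i] = _COMPLEMENT[a2[i]]
        elif drop_ambiguous:
            a1[i] = a2[i] = "."
        else:
            raise ValueError(
                f"probe alleles {sorted(probe)} at {c}:{p} match neither strand of "
                f"{sorted(alleles)}"
            )
    out["allele1"] = a1
    out["allele2"] = a2
    return out


def concordance(
    chip: pd.DataFrame,
    seq_genotypes: Mapping[str, Mapping[tuple[str, int], tuple[str, str] | None]],
    animal_map: Mapping[str, str] | None = None,
    absent_as_homref: bool = True,
    reference=None,
) -> pd.DataFrame:
    """Per-animal concordance between chip and sequencing genotypes.

    ``seq_genotypes`` maps sequencing sample -> {(chrom, pos): unordered
    allele pair or None for a missing call}; ``animal_map`` translates chip
    animal ids to sequencing sample ids (identity by default).  A probe is
    concordant iff its unordered allele pair equals the sequencing pair.
    Probes absent from the VCF are, with ``absent_as_homref`` and a
    reference sequence supplied, compared against a homozygous-reference
    call (the variant-only-VCF convention); otherwise they stay in the
    denominator only.  Returns animal / n_probes / n_concordant / rate.
    """
    animal_map = animal_map or {}
    rows = []
    for animal, sub in chip.groupby("animal", sort=False):
        sample = animal_map.get(animal, animal)
        if sample not in seq_genotypes:
            raise ValueError(f"animal {animal!r} (sample {sample!r}) not in sequencing data")
        calls = seq_genotypes[sample]
        n_probes = len(sub)
        n_conc = 0
        for c, p, a1, a2 in zip(sub["chrom"], sub["pos"], sub["allele1"], sub["allele2"]):
            if a1 == "." or a2 == ".":
                continue  # missing chip call: denominator only
            key = (c, int(p))
            if key in calls:
                pair = calls[key]
                if pair is not None and frozenset((a1.upper(), a2.upper())) == frozenset(
                    a.upper() for a in pair
                ):
                    n_conc += 1
            elif absent_as_homref and reference is not None:
                ref_base = str(reference[c][int(p) - 1]).upper()
                if a1.upper() == ref_base and a2.upper() == ref_base:
                    n_conc += 1
        rows.append((animal, n_probes, n_conc, n_conc / n_probes if n_probes else 0.0))
    return pd.DataFrame(rows, columns=["animal", "n_probes", "n_concordant", "rate"])


def seq_genotypes_from_vcf(vcf_path: str) -> dict[str, dict[tuple[str, int], tuple[str, str] | None]]:
    """Sequencing genotypes as unordered allele pairs per sample per site."""
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    out: dict[str, dict[tuple[str, int], tuple[str, str] | None]] = {
        s: {} for s in samples
    }
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        key = (v.CHROM, v.POS)
        alleles = (v.REF, v.ALT[0])
        for s, g in zip(samples, v.genotypes):
            a1, a2 = g[0], g[1]
            out[s][key] = None if a1 < 0 or a2 < 0 else (alleles[a1], alleles[a2])
    return out
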