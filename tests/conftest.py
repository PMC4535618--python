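import numpy as np
import pytest

from sweepherd import synthetic_data as sd

ALL_BREEDS = ("KWB", "KNP", "DUR", "LAN", "YOR")

#: 5 x 4 Mb study genome, one SNP per ~500 bp, with three 300 kb sweeps
#: shared by the whole cohort (residual MAF 0.01) and a 5,000-probe chip
#: with 1% genotype error.
STUDY_SEED = 7
STUDY_SWEEPS = [
    sd.SweepSpec("chr1", 1_000_000, 1_300_000, ALL_BREEDS, residual_maf=0.01),
    sd.SweepSpec("chr3", 2_500_000, 2_800_000, ALL_BREEDS, residual_maf=0.01),
    sd.SweepSpec("chr5", 500_000, 800_000, ALL_BREEDS, residual_maf=0.01),
]


def study_genome() -> sd.GenomeSpec:
    return sd.GenomeSpec(
        tuple((f"chr{i + 1}", 4_000_000) for i in range(5)), snp_density=1 / 500
    )


@pytest.fixture(scope="session")
def study_cohort(tmp_path_factory):
    """The full-scale synthetic cohort shared across the deeper tests."""
    outdir = tmp_path_factory.mktemp("study_cohort")
    return sd.write_cohort(
        str(outdir),
        study_genome(),
        sweeps=STUDY_SWEEPS,
        chip=sd.ChipSpec(n_probes=5_000, genotype_error=0.01, missing_rate=0.0),
        seed=STUDY_SEED,
    )


@pytest.fixture(scope="session")
def study_scan(study_cohort):
    from sweepherd import sweep_scan as ss

    breed_map = ss.read_breed_map(study_cohort.breed_map)
    return ss.scan(study_cohort.vcf, breed_map, study_cohort.genome)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A ~1 Mb cohort for fast end-to-end checks."""
    outdir = tmp_path_factory.mktemp("small_cohort")
    genome = sd.GenomeSpec((("chr1", 500_000), ("chr2", 400_000)))
    return sd.write_cohort(
        str(outdir),
        genome,
        sweeps=[sd.SweepSpec("chr1", 100_000, 250_000, ALL_BREEDS)],
        chip=sd.ChipSpec(n_probes=200, genotype_error=0.02, missing_rate=0.05),
        seed=3,
    )


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def translation_oracle_category(tx, pos, ref, alt, reference):
    """Brute-force effect call: translate the whole reference CDS and the
    whole mutated CDS and diff the proteins (independent of the per-codon
    classifier path)."""
    from Bio.Seq import Seq

    coding = tx.coding_positions()  # genomic positions in translation order
    idx = int(np.flatnonzero(coding == pos)[0])

    def base(p):
        return str(reference[tx.chrom][int(p) - 1]).upper()

    seq = [base(p) for p in coding]
    if tx.strand == "-":
        seq = [_COMP[b] for b in seq]
        ref_c, alt_c = _COMP[ref], _COMP[alt]
    else:
        ref_c, alt_c = ref, alt
    assert seq[idx] == ref_c, "oracle fixture inconsistent with reference"
    mut = list(seq)
    mut[idx] = alt_c
    if idx < 3 and "".join(seq[:3]) == "ATG" and "".join(mut[:3]) != "ATG":
        return "start_lost"
    ref_prot = str(Seq("".join(seq)).translate())
    alt_prot = str(Seq("".join(mut)).translate())
    if ref_prot == alt_prot:
        return "synonymous_coding"
    i = next(k for k, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b)
    if alt_prot[i] == "*":
        return "stop_gained"
    if ref_prot[i] == "*":
        return "stop_lost"
    return "non_synonymous_coding"


def write_mini_vcf(path, records, samples):
    """Tiny GT:AD VCF for hand-built pooling examples.

    ``records``: (chrom, pos, ref, alt, [(gt, (ad_ref, ad_alt)), ...]).
    """
    chroms = {}
    for chrom, pos, *_ in records:
        chroms[chrom] = max(chroms.get(chrom, 0), pos + 1000)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, l in chroms.items():
            fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, cells in records:
            body = "\t".join(f"{gt}:{ad[0]},{ad[1]}" for gt, ad in cells)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD\t{body}\n")
    return str(path)
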