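# Methods

This note documents the models, conventions and design choices behind
sweepherd: what each stage computes, the knobs that matter, what the
synthetic-data generator does and does not emulate, and the numerical
edge cases.

## Pooled-heterozygosity sweep scan

### Statistic

For one breed, the reads supporting the reference and alternative allele
(the VCF `AD` field) are summed over the breed's animals at every
biallelic SNP; the larger pooled sum defines the major allele (ties go to
the reference allele, which keeps the choice deterministic and
reference-stable). Multi-allelic records are skipped and counted. Sites
with zero pooled reads in a breed are dropped for that breed.

A window's pooled heterozygosity is

    Hp = 2 · Σmaj · Σmin / (Σmaj + Σmin)²,

with Σmaj, Σmin the window sums of per-SNP major/minor read counts. The
squared denominator is the Rubin et al. form and is what bounds Hp in
[0, 0.5]: Hp = 0 iff Σmin = 0 (complete homozygosity) and Hp = 0.5 iff
Σmaj = Σmin. The statistic is a read-weighted heterozygosity: deeply
covered SNPs contribute more, which matches the pooled-resequencing
origin of the method.

### Filters, windows, standardization

* **MAF filter** — a SNP is retained for a breed iff its pooled
  minor-read fraction is ≥ 0.05 (the rule removes *strictly below*
  0.05). Filtering is per breed: the same site can survive in one
  breed's pool and not another's. The filter runs before window
  assembly; the order is configurable but MAF-first is the default.
* **Windows** — 150 kb, advancing by 75 kb (50% overlap), 0-based
  half-open, starting at 0 on every chromosome and emitted while
  `start + size ≤ L`; no partial trailing windows, so a chromosome
  shorter than one window size contributes none, and the count on a
  chromosome of length L ≥ size is `floor((L − size)/step) + 1`.
* **SNP membership** — a 1-based SNP position p belongs to window
  [s, e) iff `s < p ≤ e`. Stated once, used everywhere (windows, per-SNP
  tracks, brute-force test oracles). Every interior SNP falls in exactly
  two consecutive windows; this double-counting is intrinsic to
  overlapping-window scans.
* **Exclusion** — windows with fewer than 10 retained SNPs get no Hp.
  "Heterozygous SNPs" for this rule means SNPs still polymorphic in the
  breed's pool after the MAF filter — the only per-breed SNP set in play
  at that stage.
* **ZHp** — `(Hp − mean)/sd` with mean and *population* (divisor-n)
  standard deviation taken genome-wide over the breed's retained
  windows, so retained windows have mean 0 and sd 1 exactly. The scan
  runs over every contig in the genome table; per-chromosome
  standardization is not used. Fewer than two retained windows, or zero
  spread, is an error rather than a silent NaN.
* **Calls** — ZHp strictly below −2 (a window at exactly −2 is not
  called), sorted most-extreme-first, optionally annotated with the
  names of genes whose span intersects the window on either strand.

## Functional annotation

One canonical transcript per gene is assumed; the GFF3 input is taken as
already canonical-reduced. The 12 categories are assigned
most-severe-first:

    splice_site_acceptor > splice_site_donor > start_lost > stop_gained
    > stop_lost > non_synonymous_coding > synonymous_coding > utr_5
    > utr_3 > non_coding_exon > intron > intergenic

mirroring the effect ranking of the snpEff family of annotators; the
precedence also makes the categories a partition (each SNP gets exactly
one), which is what lets category counts sum to the SNP total in the
summary table. Splice sites are the two intronic bases flanking each
exon — donor at the intron's 5′ end and acceptor at its 3′ end *in
transcript orientation*. Coding effects substitute the alternative base
into the affected codon on the coding strand (codons may span introns);
start_lost is any change that destroys the initiator ATG, and
stop-gain/loss compare the translated residue against `*`. The
classifier refuses to annotate a variant whose stated reference allele
disagrees with the reference sequence.

The per-codon path is validated two ways: a metamorphic strand test
(classifying on a minus-strand transcript must equal classifying the
mirrored variant on the plus strand of the reverse-complemented genome)
and an independent brute-force oracle that translates the entire
reference and mutated CDS and diffs the proteins.

Ti/Tv counts A↔G and C↔T as transitions and reports the ratio as
undefined (None) when no transversions were seen, never infinity.
Novelty is by position only by default — the convention of dbSNP-build
comparisons — with an allele-aware mode behind a flag. SIFT scores are
consumed, not computed: ≤ 0.05 damaging, > 0.05 tolerant, absent
unscored; scores outside [0, 1] are rejected. A breed-specific nsSNP is
a non-synonymous SNP whose alternative allele is observed in at least
one animal of exactly one breed.

## Population structure

Similarity is exact genotype identity over pairwise-complete sites
(both calls non-missing); a pair with no comparable site is an error
naming the pair. Distances use Kimura's two-parameter model,
`d = −½·ln((1 − 2P − Q)√(1 − 2Q))`, where for a pair of animals P and Q
are the transition/transversion difference proportions averaged over the
four cross-haplotype comparisons of their phased genotypes — the tree
keeps one tip per animal while still using phased input. How diploid
data collapse to one distance per animal is not canonical; the
4-comparison average is this package's documented choice. Whether a
differing site feeds P or Q is decided by the site's ref/alt base pair.
Saturated pairs (log-domain violations) are an error that names the
offending proportions. An unphased fallback counts het-vs-hom as a 0.5
difference (documented approximation, pairwise-complete denominators).

Neighbour joining is the classic Saitou–Nei agglomeration: join the pair
minimising Q(i,j) = (n−2)d(i,j) − r_i − r_j, ties broken by lowest
(row, column) index for reproducibility; the final three nodes join at a
trifurcation, so the output Newick is an unrooted tree. Negative branch
lengths — possible on non-additive input — are clamped to zero with the
deficit moved to the sibling branch, the standard practical fix. On an
additive matrix the reconstruction is exact; the tests verify recovery
of random 5–12-leaf trees to 1e-9 against a path-length oracle and
against scikit-bio's independent implementation.

## Concordance

A probe is concordant iff its unordered chip allele pair equals the
sequencing genotype at that position; the denominator is always the full
probe count. Missing chip calls, missing sequencing calls and unmatched
probes therefore depress the rate rather than shrinking the denominator.
Probes at positions absent from the VCF can be compared against an
implied homozygous-reference call (`absent_as_homref`, default on, a
reference sequence must be supplied) — the right convention when the VCF
is a cohort-wide variant file in which a site absent for everyone is
reference; turning it off counts such probes in the denominator only,
and both behaviours are kept because chip probes monomorphic in the
sequenced animals are genuinely ambiguous between the two readings.
Chip alleles are expected on the reference strand; a harmonisation
helper complements probes that match the site alleles only after
flipping and errors on strand-ambiguous A/T and C/G probes unless they
are dropped.

## Synthetic cohorts

The generator emulates the downstream-visible structure of a multi-breed
resequencing study; its defaults are the study conditions used
throughout the tests.

* **Cohort** — five breeds, 55 animals (10 wild-boar-like KWB, 10 KNP,
  6 DUR, 14 LAN, 15 YOR), mean depth 12×, per-read base error 1e-3.
  Breed Fst values (0.25, 0.15, 0.12, 0.08, 0.08) are fixture choices in
  a plausible livestock range — the wild-boar analogue most
  differentiated — not estimates of any real population.
* **Frequencies** — ancestral allele frequencies are Uniform(0.05,
  0.95), avoiding a monomorphic bulk; per-breed frequencies are
  Balding–Nichols, Beta(p(1−F)/F, (1−p)(1−F)/F), exactly p at F = 0. A
  Hudson-type ratio-of-averages estimator on two simulated breeds
  returns the nominal Fst (tested at 0.2 ± 0.05).
* **Genotypes and reads** — Hardy–Weinberg phased haplotypes
  (independent Bernoulli draws per haplotype); per-site depth
  Poisson(12); each read samples one haplotype uniformly and reports its
  allele flipped with the base-error probability, so the alt-read
  probability given dosage d is `e + (d/2)(1 − 2e)`. Reads are simulated
  per individual and written as per-sample AD; pooling across a breed is
  deliberately a downstream responsibility, as in real pipelines.
* **Sweeps** — inside a sweep interval the affected breeds' minor allele
  is set to `residual_maf` (default 0.01), the major allele being
  whichever is currently more frequent in that breed. The study fixture
  plants three 300 kb sweeps shared by all five breeds. That sharing is
  a deliberate design choice: a breed with no sweep anywhere has ZHp
  distributed ~N(0, 1) by construction, so ~2–3% of its windows fall
  below −2 as pure standardization tail; only when each breed's own
  genome contains sweep outliers (which inflate the Hp spread and pull
  null windows toward 0) is a high-precision call set possible. The
  sweep scan is a relative-ranking method, and the fixture reflects
  that.
* **Filter interaction** — with residual MAF 0.01, whether a swept SNP
  escapes the 5% pooled-read filter depends on pool size: a lone carrier
  in a 10-animal pool has sample frequency 1/20 = 0.05, exactly at the
  threshold, so such sites are retained about half the time (expected
  fail fraction 0.889); in a 15-animal pool the carrier sits at 1/30 and
  the expected fail fraction is ~0.93. The ≥90% "swept SNPs fail the
  filter" property is therefore asserted on a 15-animal breed and a
  slightly weaker cohort-wide bound on the mixed-size study cohort.
  Swept windows are nonetheless retained (the escaping minority still
  numbers ≥10 SNPs per 150 kb window at 1 SNP per 500 bp) and carry
  Hp ≈ 0.1 against a genome background of ~0.4, which is the signal the
  scan detects.
* **Alleles and annotation inputs** — ref alleles come from a random
  reference sequence; alt alleles are the transition partner with
  probability 2/3 (a 2:1 Ti:Tv mutation mix, recovering a Ti/Tv ratio of
  ~2 downstream). Gene models are non-overlapping, 2–5 exons, one strand
  per transcript, coding with probability 0.8; coding transcripts get
  UTRs in the terminal exons, a patched valid ORF (ATG start, no internal
  stop, terminal stop; codon length enforced) and canonical GT/AG splice
  dinucleotides. The known-sites list covers 74.5% of SNPs by default,
  so ~25.5% re-ingest as novel; SIFT scores are Uniform(0, 1) over 80%
  of coding SNPs; chip probes are drawn uniformly from SNP positions
  with genotype errors flipping to a uniformly chosen *different*
  genotype.
* **Determinism** — all randomness flows from one master seed through
  named substreams (genome, genes, frequencies, alleles, genotypes,
  reads, chip, sift, known), so stages are independently reproducible
  and outputs byte-identical per seed.

What the generator does *not* emulate — and what passing tests therefore
do not demonstrate on real data: linkage disequilibrium and
recombination structure (sites are independent given the frequencies),
demographic history beyond a single-level Balding–Nichols split,
indels, multi-allelic sites, sex-chromosome ploidy, mapping and calling
artifacts (the VCF is taken as already quality-filtered), overlapping or
multi-isoform genes, and chip strand errors (probes are written on the
reference strand; the harmonisation path is exercised by unit fixtures).

## Problem sizes and numerics

The full-scale test cohort is 5 chromosomes × 4 Mb at one SNP per
~500 bp (~40k SNPs, 55 animals, ~260 windows per breed), which keeps the
whole suite under a minute of simulation time while leaving every
statistic in its asymptotic regime; the worked README example uses a
0.9 Mb genome. Window sums use exact integer cumulative sums; Hp needs
no tolerance. ZHp standardization is checked to 1e-9. NJ on additive
matrices is exact to 1e-9; the K2P closed form to 1e-6. Stochastic
recoveries (Fst, concordance, novelty, allele balance) are asserted
within 3 standard errors of their generator truth or at the tolerances
stated in the test docstrings.

## Known limitations

* The scan assumes a biallelic, SNP-only VCF with reliable AD fields;
  depth-weighted Hp means uneven coverage between animals shifts weight
  accordingly.
* Annotation handles one transcript per gene; overlapping genes resolve
  by severity precedence, not by reporting multiple effects.
* The unphased K2P fallback is an approximation; phased input is
  preferred and is what the simulator writes.
* Bayesian admixture-style clustering, haplotype-based sweep statistics
  (iHS/XP-EHH), bootstrap supports and plot rendering are out of scope;
  outputs are TSV/BED/Newick/JSON for downstream tools.
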