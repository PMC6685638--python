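# Methods

This note documents the models implemented in `refbias`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices a maintainer should know
about.

## The measurement model

All analyses are restricted to a panel of known biallelic SNPs, and to
**transversions** only: post-mortem deamination reads as C→T (and G→A on
the opposite strand), so transition sites confound damage with
polymorphism while transversion sites are immune. A site is classified
*supposedly heterozygous* when it is covered by at least `min_depth = 10`
reference- or alternative-carrying reads and the alternative fraction
lies inside the closed band `[0.25, 0.75]`. The prose rule this encodes
("between 25 and 75%") does not state whether the endpoints are
included; the closed band is used, and since counts are rational the
choice only matters at exact quarter fractions. Bases that match neither
panel allele ("other": sequencing error or damage products) are excluded
from both the numerator and denominator of the alternative fraction, so
triallelic noise does not dilute the balance measurement.

Base qualities are used exactly as stored. No rescaling model exists
anywhere in the package, deliberately: rescaling schemes consult the
reference allele and can themselves amplify the bias being measured.

The per-sample summary is the mean of per-site alternative fractions
with its standard error (sample sd / √n). The heterozygosity proxy is
the fraction of sufficiently covered panel sites classified
heterozygous, with a binomial standard error — a *relative* measure, fit
for comparisons between fragment-length strata of the same individual,
not an absolute heterozygosity estimate. Cross-sample bias correlation
is Pearson's r over sites heterozygous in both samples, with the
two-sided p-value from the exact t transform (n−2 df).

## The internal mapper

The mapper exists so that every remapping-based diagnostic and filter is
testable end-to-end, deterministically, without external binaries. It is
a seed-and-extend design:

* **Edit budget.** `maxdiff(L)` is the smallest k such that
  P(X > k) < `miss_frac` for X ~ Poisson(L · `err_rate`), with defaults
  `err_rate = 0.02`, `miss_frac = 0.01` — the same *shape* of
  length-dependent mismatch allowance that short-read aligners use (a
  longer read earns a larger budget in discrete steps: 3 mismatches up
  to 41 bp, 4 up to 63 bp, 5 up to 89 bp at the defaults). No bit-level
  agreement with any specific external aligner is promised; only the
  budget mechanism, which is what drives reference bias, is emulated.
* **Seeding.** For budget e, the read is cut into e+1 non-overlapping
  exact seeds (lengths quantized to {16,14,12,10,8,6,4} so only a few
  k-mer indexes are ever built). By the pigeonhole principle every
  placement within the budget shares at least one exact seed, so hit
  enumeration within the budget is exhaustive — which makes the MAPQ
  model meaningful.
* **Verification.** Each candidate placement is checked twice: an exact
  substitution-only comparison at the seed-implied start, and a banded
  edit-distance alignment (edlib) allowing indels, capped at
  `max_gap_opens = 2` gap openings. Placements whose starts differ by at
  most the budget on the same strand are one physical locus; among a
  locus's representations the one with (lower distance, fewer gap opens)
  wins. Without this canonicalization, a 1-mismatch alignment can be
  re-represented as an equal-cost gapped alignment shifted by one base,
  which would silently corrupt allele lookup at SNPs.
* **MAPQ.** 37 for a unique best hit with no other placement inside the
  budget; 25 for a unique best hit with suboptimal placements present;
  0 for two or more co-optimal placements. The downstream analyses only
  threshold MAPQ, so any monotone uniqueness score works; thresholds
  against real aligner BAMs are *not* transferable exactly.
* **Determinism.** Ties are broken by (chromosome name, start, then
  '+' strand). Identical input always yields identical output.

Sequences are stored reference-forward after mapping (minus-strand reads
are reverse-complemented, qualities reversed), so allele inspection at
SNPs needs no strand logic. When a stored read is remapped (filters,
balance diagnostic) it is first restored to sequencing orientation so
that the strand of the new alignment is comparable to the original.

Mappability masks are unique-k-mer masks (default k = 35): a position is
kept iff its k-mer occurs exactly once in the genome counting both
strands. PCR duplicates are reads sharing (chrom, start, end, strand);
the highest quality-sum read survives. Fragments shorter than 35 bp are
discarded, boundary inclusive (a 35 bp fragment is kept).

## The virtual opposite-allele diagnostic

Every read with MAPQ ≥ 30 carrying ref or alt (BQ ≥ 30) at ≥ 1 panel SNP
is doubled with a copy whose allele at *every* overlapping SNP is
swapped. Swapping all SNPs on multi-SNP reads (rather than only a focal
one) is what preserves exact per-SNP balance in the doubled set. After
remapping, only reads returning to their original locus with MAPQ ≥ 30
count (the `require_original_locus=False` mode reports wanderers
separately). Per-SNP alternative fractions are kept as exact rationals
(`fractions.Fraction`), so membership in the singleton histogram bins
{0}, {1/2}, {1} is decided exactly, never by floating-point comparison.

## The mitigation filters

Both filters are per-read predicates (hence idempotent; their
combination is the intersection of pass sets) and never touch reads that
overlap no panel SNP:

* **Modified reads:** a read carrying the reference allele at ≥ 1 SNP is
  flipped to the alternative at all such SNPs and remapped; it passes iff
  the flipped copy maps to the identical (chrom, start, strand), with no
  indels, and MAPQ ≥ `min_remap_mapq`. This removes exactly those
  reference reads whose alternative twins would have been lost.
* **Modified reference:** the reference is rewritten to carry a seeded
  random third allele (∉ {ref, alt}) at every panel SNP — recorded in a
  substitution table for bit-level reproducibility — and every
  SNP-overlapping read is remapped against it under the same acceptance
  rule. Both alleles are then equidistant from the reference, so
  survival is symmetric by construction.

`min_remap_mapq` defaults to 30, matching the analysis-side MAPQ
threshold; the acceptance rule itself ("same position, no indels") does
not need a separate MAPQ but an ambiguous remap should not count as a
confirmation. Neither filter can restore balance lost *before* or
*during* the first mapping (unmapped alternative reads, reference-biased
contamination); they only prevent the surviving reference reads from
outnumbering further, which is why filtered means approach but need not
reach 0.5.

## Population-genetic statistics

D(W,X;Y,Z) = Σ(pW−pX)(pY−pZ) / Σ(pW+pX−2pWpX)(pY+pZ−2pYpZ), summing
over sites where all four populations are non-missing (complete-case per
statistic). The denominator is the ABBA+BABA normalisation, giving
|D| ≤ 1 with negative values indicating excess sharing of X with Y. One
degenerate case is defined rather than raised: when the denominator sum
is zero but every numerator term also vanishes (e.g. Y and Z identical
haploid columns, where 2·y(1−y) ≡ 0), D is exactly 0 with se 0 and an
undefined Z score; a zero denominator with a nonzero numerator is an
error.

f4(A,B;C,D) is the per-site mean of (pA−pB)(pC−pD). The f4-ratio
estimates an admixture proportion as the ratio of two f4 sums over the
intersection of complete sites; the jackknife resamples the *ratio*
(blocks deleted jointly from numerator and denominator), not the two f4
values separately.

Standard errors use the delete-m_j weighted block jackknife over
contiguous 5 Mbp windows per chromosome (trailing partial windows kept),
with block weights m_j = informative-site counts. With g blocks,
n = Σm_j and h_j = n/m_j:

    θ_J = g·θ̂ − Σ_j (1 − m_j/n)·θ̂₋ⱼ
    var = (1/g) Σ_j (h_j θ̂ − (h_j−1) θ̂₋ⱼ − θ_J)² / (h_j − 1)

which reduces to the standard delete-one jackknife at equal weights
(asserted numerically in the tests). On i.i.d.-site simulations the
jackknife se matches the empirical replicate sd within 20%.

Pseudo-haploid calls draw one ref/alt read per site (uniform with a
seed) or take the majority allele with seeded coin-flip ties. The
diploid caller provided is plumbing: missing below 10 reads, 0.5 inside
the 25–75% band, else the majority homozygote — a threshold rule, not a
genotype-likelihood model, and not suitable for calling novel variants.

## The synthetic-data generator

The generator produces the study conditions for the closed-loop tests:

* **Reference:** i.i.d. bases over a configurable length; repeat
  structure is created by overwriting random target loci with copies of
  a random source segment (length preserved, multimapping loci appear).
* **Individual:** transversion-only SNPs at distinct positions;
  `het_fraction` of sites heterozygous (carrier haplotype random), the
  rest homozygous alternative; truth genotypes returned for recovery
  tests.
* **Fragments:** lengths from a lognormal discretised and truncated at
  ≥ 30 bp, parameterised by its **mode** (σ = 0.25 by default) because
  the mode of the length distribution is the quantity that tracks bias
  strength; a `fixed` length mode exists for exactness tests. Each
  fragment copies one uniformly chosen haplotype, is read on a random
  strand, then damaged: C→T from the 5′ end and G→A from the 3′ end with
  probability p0·exp(−λ·offset) — a minimal exponential terminal model,
  present only to prove the transversion restriction makes the metrics
  damage-robust, not a fitted damage profile. Uniform per-base
  sequencing error follows. Base qualities are constant Phred 40:
  damage is invisible to qualities, as in real data. Contaminant
  fragments (optional fraction) come from a haplotype carrying the
  reference allele at each SNP with probability `ref_bias` (default 1.0,
  the worst case).
* **Admixture tables:** per site, an ancestral frequency U(0.05, 0.95);
  a Mbuti-like frequency adds U(−0.15, 0.15) drift and a
  Neandertal-like frequency adds U(−0.45, 0.45) — the archaic branch
  must be strongly diverged or the denominator f4 carries no signal and
  the ratio is unestimable; two Neandertal samples share the
  Neandertal-like frequency; the target mixes the two at the chosen α;
  the outgroup is fixed at 0; one haploid call per population is drawn
  binomially. Sites are spaced so ≥ 25 jackknife blocks exist.

Everything is byte-deterministic under the seed (independent
`SeedSequence` streams per stage).

What the generator does **not** emulate: UDG library chemistry, realistic
empirical damage profiles, microbial contamination, paired-end overlap
merging artifacts, GC or capture biases, linkage between sites, and real
population history. Passing tests therefore demonstrate the *mechanisms*
(budget-driven allele loss, its length dependence, and the filters'
symmetrisation) at desk scale, not calibrated magnitudes for any real
dataset.

## Study conditions used by the tests and the acceptance script

* Unbiased null: 200 kb repeat-free genome, 500 heterozygous
  transversion SNPs, 20× coverage, length mode 50, no error/damage/
  contamination; expected mean alternative fraction 50% within 2 se.
* Balance by design: 100 kb repeat-free genome, 200 het SNPs, fixed
  50 bp fragments at 15×; every SNP exactly 1/2 after remapping.
* Biased run: 40 kb genome with an 800 bp segment in 3 copies, 6
  SNPs/kb, 60×, length mode 40 (σ 0.4), deamination p0 = 0.5, λ = 0.25,
  error 0.01. The deamination load is roughly constant per read while
  the budget grows with length, so short fragments lose
  alternative-allele reads disproportionately. Length bins for the
  monotonicity check are aligned with the budget steps at 42 and 64 bp
  ([35,42), [42,64), [64,110]; fragments beyond the next step at 90 bp
  are a negligible tail): under a staircase budget the bias is a step
  function of length, and plateau-aligned bins are the
  stratification under which the monotone trend is the model's
  prediction rather than binning noise.
* f4-ratio recovery: 50,000-site admixture tables, α ∈ {0.02, 0.03,
  0.05}, 100 seeded replicates each; α̂ within 3 jackknife se of α in
  ≥ 95 replicates (observed: 100/100, with the empirical sd of α̂
  matching the mean jackknife se).

These sizes keep the full suite and the acceptance script to a few
minutes on a single CPU while leaving the statistical margins wide.

## Known limitations

* MAPQ semantics are package-specific; thresholds tuned on real BAMs do
  not transfer exactly.
* The locus-clustering rule (starts within the edit budget are one
  locus) can in principle merge genuinely distinct placements in a
  tandem repeat with period ≤ the budget; such degenerate repeats are
  outside the generator's regime.
* `alleles_tsv` is a package-defined exchange dialect (chrom, pos, ref,
  alt, optional maf; tab-separated; `#` comments), provided because no
  standard panel exchange format fixes alleles without a full VCF.
* The D-statistic denominator follows the ABBA+BABA normalisation; other
  implementations may normalise differently, so bit-compatibility with
  any specific legacy tool is not guaranteed (sign convention and oracle
  equivalence are pinned by tests instead).
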