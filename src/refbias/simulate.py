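"""Synthetic ancient-DNA data: references, individuals, fragments, tables.

Everything the rest of the package consumes can be generated here,
deterministically under a single seed: a random reference with optional
repeat structure (to create multimapping loci), a diploid individual
genotyped at transversion-only SNPs, degraded short fragments with
terminal deamination / contamination / sequencing error, and admixture
genotype tables with a known mixing proportion for f4-ratio recovery.

What the generator emulates — and what it does not — is documented in
the package methods note; in short, fragment lengths follow a
discretised lognormal parameterised by its mode (the quantity that
correlates with reference-bias strength), deamination is an
exponential-decay terminal C->T / G->A model, and the contaminant
haplotype matches the reference allele at every SNP (the worst case for
reference bias).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import ReferenceGenome, revcomp
from .snp_panel import SNPPanel, SNPRecord

# transversion partners of each reference base
_TRANSVERSION_PARTNERS = {"A": "CT", "C": "AG", "G": "CT", "T": "AG"}
_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    genome_length : bases of the (single-chromosome) reference
    repeat_spec   : [(segment_length, copy_number), ...] — extra copies of
                    a random segment are pasted over random loci to create
                    multimapping regions
    snp_density   : SNPs per kb
    het_fraction  : fraction of SNPs heterozygous (rest homozygous alt)
    coverage      : mean sequencing depth
    length_mode   : mode of the fragment-length distribution (bp)
    length_dist   : 'lognormal' (discretised, sigma=length_sigma,
                    truncated at >= 30 bp) or 'fixed'
    deamination   : (p0, lam) — terminal C->T (5') and G->A (3')
                    probability p0 * exp(-lam * offset)
    contamination : (fraction, ref_bias) — fraction of fragments drawn
                    from a contaminant haplotype carrying the reference
                    allele at each SNP with probability ref_bias
    error_rate    : per-base sequencing error probability
    """

    genome_length: int = 200_000
    repeat_spec: tuple[tuple[int, int], ...] = ()
    snp_density: float = 2.5
    het_fraction: float = 1.0
    coverage: float = 20.0
    length_mode: int = 50
    length_dist: str = "lognormal"
    length_sigma: float = 0.25
    deamination: tuple[float, float] = (0.0, 0.4)
    contamination: tuple[float, float] = (0.0, 1.0)
    error_rate: float = 0.0
    seed: int = 1
    chrom_name: str = "chr1"

    def __post_init__(self):
        for p in (
            self.het_fraction,
            self.deamination[0],
            self.contamination[0],
            self.contamination[1],
            self.error_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.length_dist not in ("lognormal", "fixed"):
            raise ValueError(f"unknown length_dist {self.length_dist!r}")


@dataclass(frozen=True)
class SimulatedRead:
    """A sequenced fragment in sequencing orientation, with its truth."""

    read_id: str
    sequence: str
    base_quals: np.ndarray
    true_chrom: str
    true_start: int  # 0-based on the reference
    true_strand: str
    source: str  # 'hap1' | 'hap2' | 'contaminant'


@dataclass
class DiploidGenotypes:
    """Truth genotypes of the simulated individual at panel sites."""

    chrom: str
    # 0-based position -> (haplotype-1 base, haplotype-2 base)
    alleles: dict[int, tuple[str, str]]

    def is_het(self, pos0: int) -> bool:
        a, b = self.alleles[pos0]
        return a != b


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_reference(config: SimulationConfig) -> ReferenceGenome:
    """Random reference, optionally with duplicated segments.

    Each (length, copies) entry of ``repeat_spec`` picks a random source
    segment and overwrites copies-1 random target loci with it, so total
    genome length is preserved while multimapping loci appear.
    """
    if config.genome_length < 1000:
        raise ValueError("genome_length must be >= 1 kb")
    rng = _rng(config, 0)
    bases = rng.integers(0, 4, size=config.genome_length)
    seq = np.frombuffer(b"ACGT", dtype="S1")[bases]
    for seg_len, copies in config.repeat_spec:
        if seg_len > config.genome_length:
            raise ValueError("repeat segment longer than the genome")
        src = int(rng.integers(0, config.genome_length - seg_len + 1))
        segment = seq[src : src + seg_len].copy()
        for _ in range(copies - 1):
            dst = int(rng.integers(0, config.genome_length - seg_len + 1))
            seq[dst : dst + seg_len] = segment
    return ReferenceGenome({config.chrom_name: b"".join(seq).decode()})


def simulate_individual(
    reference: ReferenceGenome, config: SimulationConfig
) -> tuple[DiploidGenotypes, SNPPanel]:
    """Place transversion-only SNPs and assign diploid genotypes.

    ``het_fraction`` of the sites are heterozygous (one haplotype
    reference, one alternative, carrier chosen at random); the remainder
    are homozygous alternative.  The truth genotypes are returned for
    recovery tests alongside the panel.
    """
    chrom = config.chrom_name
    seq = reference[chrom]
    L = len(seq)
    n_snps = round(config.snp_density * L / 1000.0)
    margin = 1
    n_positions = L - 2 * margin
    if n_snps > n_positions:
        raise ValueError("snp_density too high for this genome")
    rng = _rng(config, 1)
    positions = np.sort(
        rng.choice(np.arange(margin, L - margin), size=n_snps, replace=False)
    )
    n_het = round(config.het_fraction * n_snps)
    het_flags = np.zeros(n_snps, dtype=bool)
    het_flags[rng.choice(n_snps, size=n_het, replace=False)] = True

    records = []
    alleles: dict[int, tuple[str, str]] = {}
    for i, pos0 in enumerate(positions):
        ref_base = seq[pos0]
        partners = _TRANSVERSION_PARTNERS[ref_base]
        alt_base = partners[rng.integers(2)]
        records.append(
            SNPRecord(chrom, int(pos0) + 1, ref_base, alt_base, maf=0.5)
        )
        if het_flags[i]:
            if rng.integers(2):
                alleles[int(pos0)] = (ref_base, alt_base)
            else:
                alleles[int(pos0)] = (alt_base, ref_base)
        else:
            alleles[int(pos0)] = (alt_base, alt_base)
    return DiploidGenotypes(chrom=chrom, alleles=alleles), SNPPanel(records)


def _haplotype_sequences(
    reference: ReferenceGenome, genotypes: DiploidGenotypes
) -> tuple[str, str]:
    seq = reference[genotypes.chrom]
    h1 = list(seq)
    h2 = list(seq)
    for pos0, (a, b) in genotypes.alleles.items():
        h1[pos0] = a
        h2[pos0] = b
    return "".join(h1), "".join(h2)


def _sample_lengths(
    config: SimulationConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    if config.length_dist == "fixed":
        return np.full(n, config.length_mode, dtype=np.int64)
    sigma = config.length_sigma
    mu = math.log(config.length_mode) + sigma * sigma  # lognormal mode
    lengths = np.rint(np.exp(rng.normal(mu, sigma, size=n))).astype(np.int64)
    return np.clip(lengths, 30, None)


def simulate_fragments(
    reference: ReferenceGenome,
    genotypes: DiploidGenotypes,
    config: SimulationConfig,
) -> list[SimulatedRead]:
    """Draw degraded fragments from the individual's two haplotypes.

    Each fragment copies one uniformly chosen haplotype (or, with the
    configured probability, the reference-biased contaminant), is read on
    a random strand, and then damaged: terminal deamination C->T from the
    5' end and G->A from the 3' end with probability p0*exp(-lam*offset),
    plus uniform per-base sequencing error.  Base qualities are constant
    Phred 40 — damage is invisible to qualities, as in real data.
    """
    chrom = genotypes.chrom
    h1, h2 = _haplotype_sequences(reference, genotypes)
    contaminant = reference[chrom]  # carries the reference allele everywhere
    c_frac, c_ref_bias = config.contamination
    if c_frac > 0 and c_ref_bias < 1.0:
        # contaminant drawn per-site: keep ref allele with prob ref_bias
        rng_c = _rng(config, 5)
        chars = list(contaminant)
        for pos0, (a, b) in genotypes.alleles.items():
            if rng_c.random() >= c_ref_bias:
                alt = a if a != contaminant[pos0] else b
                chars[pos0] = alt
        contaminant = "".join(chars)

    L = len(contaminant)
    rng = _rng(config, 2)
    mean_len = (
        config.length_mode
        if config.length_dist == "fixed"
        else config.length_mode * math.exp(1.5 * config.length_sigma**2)
    )
    n_frags = int(round(config.coverage * L / mean_len))
    lengths = _sample_lengths(config, n_frags, rng)
    np.clip(lengths, None, L, out=lengths)
    starts = (rng.random(n_frags) * (L - lengths + 1)).astype(np.int64)
    strands = rng.integers(0, 2, size=n_frags)  # 0 = '+', 1 = '-'
    sources = rng.random(n_frags)
    hap_choice = rng.integers(0, 2, size=n_frags)

    p0, lam = config.deamination
    reads = []
    for i in range(n_frags):
        ln = int(lengths[i])
        start = int(starts[i])
        if sources[i] < c_frac:
            template, source = contaminant, "contaminant"
        elif hap_choice[i] == 0:
            template, source = h1, "hap1"
        else:
            template, source = h2, "hap2"
        frag = template[start : start + ln]
        strand = "+" if strands[i] == 0 else "-"
        if strand == "-":
            frag = revcomp(frag)
        chars = list(frag)
        if p0 > 0:
            for j in range(ln):
                if chars[j] == "C" and rng.random() < p0 * math.exp(-lam * j):
                    chars[j] = "T"
            for j in range(ln):
                off3 = ln - 1 - j
                if chars[j] == "G" and rng.random() < p0 * math.exp(-lam * off3):
                    chars[j] = "A"
        if config.error_rate > 0:
            err_mask = rng.random(ln) < config.error_rate
            for j in np.nonzero(err_mask)[0]:
                current = chars[j]
                options = _BASES.replace(current, "")
                chars[j] = options[rng.integers(3)]
        reads.append(
            SimulatedRead(
                read_id=f"frag{i:07d}",
                sequence="".join(chars),
                base_quals=np.full(ln, 40, dtype=np.int64),
                true_chrom=chrom,
                true_start=start,
                true_strand=strand,
                source=source,
            )
        )
    return reads


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ReferenceGenome, DiploidGenotypes, SNPPanel, list[SimulatedRead]]:
    """Reference + individual + fragments in one call."""
    reference = simulate_reference(config)
    genotypes, panel = simulate_individual(reference, config)
    reads = simulate_fragments(reference, genotypes, config)
    return reference, genotypes, panel, reads


def write_fastq(reads: Sequence[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = "".join(chr(q + 33) for q in r.base_quals)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{quals}\n")


def write_truth_tsv(
    genotypes: DiploidGenotypes, panel: SNPPanel, path
) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\thap1\thap2\n")
        for r in panel:
            a, b = genotypes.alleles[r.pos0]
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref_allele}\t{r.alt_allele}\t{a}\t{b}\n")


def simulate_admixture_table(
    n_sites: int,
    alpha: float,
    drift: float = 0.15,
    seed: int = 0,
    nea_drift: float = 0.45,
    min_blocks: int = 25,
    block_size: int = 5_000_000,
):
    """Genotype table with a known admixture proportion.

    Per site: an ancestral frequency is drawn Uniform(0.05, 0.95); a
    'Mbuti'-like and a 'Neandertal'-like frequency add independent
    bounded drift noise (Uniform(-drift, drift) resp.
    Uniform(-nea_drift, nea_drift), clipped to [0, 1] — the archaic
    branch is far more diverged, which is what gives the denominator f4
    its signal); two Neandertal samples share the Neandertal-like
    frequency; the target's frequency is alpha * p_Nea +
    (1 - alpha) * p_Mbuti; the outgroup is fixed 0.  One haploid call per
    population is drawn binomially.  Site positions are spaced so at
    least ``min_blocks`` jackknife blocks exist at the default block
    size.
    """
    from .popgen import GenotypeTable

    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.05, 0.95, size=n_sites)
    p_mbuti = np.clip(anc + rng.uniform(-drift, drift, size=n_sites), 0.0, 1.0)
    p_nea = np.clip(
        anc + rng.uniform(-nea_drift, nea_drift, size=n_sites), 0.0, 1.0
    )
    p_target = alpha * p_nea + (1.0 - alpha) * p_mbuti
    spacing = max(1, math.ceil(min_blocks * block_size / n_sites))
    pos = spacing * (np.arange(n_sites, dtype=np.int64) + 1)
    frame = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos,
            "Target": (rng.random(n_sites) < p_target).astype(float),
            "Mbuti": (rng.random(n_sites) < p_mbuti).astype(float),
            "Nea1": (rng.random(n_sites) < p_nea).astype(float),
            "Nea2": (rng.random(n_sites) < p_nea).astype(float),
            "Outgroup": np.zeros(n_sites),
        }
    )
    return GenotypeTable(frame)
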