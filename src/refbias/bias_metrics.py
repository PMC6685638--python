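"""Allelic-balance metrics at known heterozygous SNPs.

At a true heterozygote the sequenced fragments should carry the two
alleles in a 50/50 ratio on average; a deficit of alternative-allele
reads after mapping quantifies reference bias.  This module builds
pileups restricted to a SNP panel, classifies supposedly heterozygous
sites (>= 10 reads, 25-75% alternative), and summarises the alternative
allele fraction overall, per fragment-length bin, and between samples.

Base qualities are used exactly as stored: no rescaling model exists in
this package, because rescaling schemes consult the reference allele and
can themselves amplify reference bias.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import pearsonr

from .mapper import ReadAlignment
from .snp_panel import SNPPanel, SNPRecord

DEFAULT_MIN_DEPTH = 10
DEFAULT_HET_BAND = (0.25, 0.75)


@dataclass(frozen=True)
class PileupObservation:
    read_id: str
    allele_class: str  # 'ref' | 'alt' | 'other'
    base_qual: int
    mapq: int
    fragment_length: int
    read_group: Optional[str] = None


@dataclass
class PileupSite:
    snp: SNPRecord
    observations: list[PileupObservation]

    @property
    def n_ref(self) -> int:
        return sum(1 for o in self.observations if o.allele_class == "ref")

    @property
    def n_alt(self) -> int:
        return sum(1 for o in self.observations if o.allele_class == "alt")

    @property
    def n_other(self) -> int:
        return sum(1 for o in self.observations if o.allele_class == "other")


@dataclass(frozen=True)
class BiasSummary:
    """Mean alternative-allele fraction over heterozygous sites."""

    mean_alt_fraction: float
    se: float
    n_sites: int


def pileup(
    alignments: Sequence[ReadAlignment],
    panel: SNPPanel,
    min_mapq: int,
    min_baseq: int,
    read_group: Optional[str] = None,
) -> list[PileupSite]:
    """Collect per-SNP read observations from filtered alignments.

    A read contributes one observation at each overlapping panel SNP if
    its MAPQ passes ``min_mapq`` and the base covering the SNP has quality
    >= ``min_baseq``; a deletion spanning the SNP contributes nothing.
    ``read_group`` restricts to a single library.  Alignments must be
    coordinate-sorted (the order duplicate removal emits).
    """
    last = None
    for a in alignments:
        key = (a.chrom, a.start)
        if last is not None and key < last:
            raise ValueError("alignments must be coordinate-sorted")
        last = key

    sites: dict[tuple[str, int], PileupSite] = {
        (r.chrom, r.pos): PileupSite(r, []) for r in panel
    }
    for a in alignments:
        if a.is_duplicate or a.mapq < min_mapq:
            continue
        if read_group is not None and a.read_group != read_group:
            continue
        for snp in panel.overlapping(a.chrom, a.start, a.ref_end):
            off = a.read_offset_at(snp.pos0)
            if off is None:  # deletion spans the SNP
                continue
            if a.base_quals[off] < min_baseq:
                continue
            base = a.sequence[off]
            if base == snp.ref_allele:
                klass = "ref"
            elif base == snp.alt_allele:
                klass = "alt"
            else:
                klass = "other"
            sites[(snp.chrom, snp.pos)].observations.append(
                PileupObservation(
                    read_id=a.read_id,
                    allele_class=klass,
                    base_qual=int(a.base_quals[off]),
                    mapq=a.mapq,
                    fragment_length=a.length,
                    read_group=a.read_group,
                )
            )
    return [sites[(r.chrom, r.pos)] for r in panel]


def classify_heterozygous(
    site: PileupSite,
    min_depth: int = DEFAULT_MIN_DEPTH,
    band: tuple[float, float] = DEFAULT_HET_BAND,
) -> bool:
    """Supposedly-heterozygous call: >= min_depth ref+alt reads with an
    alternative fraction inside the closed band."""
    n = site.n_ref + site.n_alt
    if n < min_depth:
        return False
    frac = site.n_alt / n
    return band[0] <= frac <= band[1]


def alt_fraction(site: PileupSite) -> float:
    """alt / (ref + alt); 'other' bases enter neither numerator nor
    denominator so triallelic noise cannot dilute the balance."""
    n = site.n_ref + site.n_alt
    if n == 0:
        raise ValueError(
            f"no ref/alt observations at {site.snp.chrom}:{site.snp.pos}"
        )
    return site.n_alt / n


def bias_summary(sites: Sequence[PileupSite]) -> BiasSummary:
    """Mean and standard error of per-site alternative fractions."""
    if len(sites) < 2:
        raise ValueError("bias_summary requires >= 2 heterozygous sites")
    fracs = np.array([alt_fraction(s) for s in sites])
    mean = float(fracs.mean())
    se = float(fracs.std(ddof=1) / math.sqrt(len(fracs)))
    return BiasSummary(mean_alt_fraction=mean, se=se, n_sites=len(fracs))


def _restrict_site(site: PileupSite, lo: int, hi: int, closed_right: bool) -> PileupSite:
    obs = [
        o
        for o in site.observations
        if lo <= o.fragment_length < hi
        or (closed_right and o.fragment_length == hi)
    ]
    return PileupSite(site.snp, obs)


def stratify_by_fragment_length(
    sites: Sequence[PileupSite],
    bin_edges: Sequence[int],
    min_depth: int = DEFAULT_MIN_DEPTH,
    band: tuple[float, float] = DEFAULT_HET_BAND,
) -> list[tuple[tuple[int, int], BiasSummary]]:
    """Alternative fraction per fragment-length bin.

    Bins are [e0,e1), [e1,e2), ..., with the last bin closed on the
    right.  The >= min_depth heterozygosity rule is re-applied within
    each bin, so only sites still classifiable from bin-restricted reads
    contribute.  Empty bins are reported with n_sites 0.
    """
    if len(bin_edges) < 2:
        raise ValueError("need at least two bin edges")
    out = []
    n_bins = len(bin_edges) - 1
    for i in range(n_bins):
        lo, hi = bin_edges[i], bin_edges[i + 1]
        closed_right = i == n_bins - 1
        restricted = [_restrict_site(s, lo, hi, closed_right) for s in sites]
        het = [s for s in restricted if classify_heterozygous(s, min_depth, band)]
        if len(het) >= 2:
            summary = bias_summary(het)
        elif len(het) == 1:
            summary = BiasSummary(alt_fraction(het[0]), float("nan"), 1)
        else:
            summary = BiasSummary(float("nan"), float("nan"), 0)
        out.append(((lo, hi), summary))
    return out


def heterozygosity_proxy(
    sites: Sequence[PileupSite],
    min_depth: int = DEFAULT_MIN_DEPTH,
    band: tuple[float, float] = DEFAULT_HET_BAND,
) -> tuple[float, float]:
    """Fraction of sufficiently covered panel sites classified heterozygous.

    A relative (not absolute) heterozygosity measure: (# het sites) /
    (# sites with ref+alt depth >= min_depth), with a binomial standard
    error.
    """
    eligible = [s for s in sites if s.n_ref + s.n_alt >= min_depth]
    if not eligible:
        raise ValueError("no sites with sufficient coverage")
    n = len(eligible)
    k = sum(1 for s in eligible if classify_heterozygous(s, min_depth, band))
    p = k / n
    se = math.sqrt(p * (1 - p) / n)
    return p, se


def fragment_length_mode(alignments: Sequence[ReadAlignment]) -> int:
    """Most frequent fragment length; ties broken toward the smaller."""
    if not alignments:
        raise ValueError("no alignments")
    counts = Counter(a.length for a in alignments)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def bias_correlation(
    sites_a: Sequence[PileupSite],
    sites_b: Sequence[PileupSite],
    min_depth: int = DEFAULT_MIN_DEPTH,
    band: tuple[float, float] = DEFAULT_HET_BAND,
) -> tuple[float, float, int]:
    """Pearson correlation of per-site alt fractions between two samples.

    Only sites classified heterozygous in BOTH samples enter; returns
    (r, two-sided p-value from the exact t transform, n shared sites).
    """
    het_a = {
        (s.snp.chrom, s.snp.pos): alt_fraction(s)
        for s in sites_a
        if classify_heterozygous(s, min_depth, band)
    }
    shared = []
    for s in sites_b:
        key = (s.snp.chrom, s.snp.pos)
        if key in het_a and classify_heterozygous(s, min_depth, band):
            shared.append((het_a[key], alt_fraction(s)))
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared heterozygous sites, got {len(shared)}"
        )
    xs, ys = zip(*shared)
    r, p = pearsonr(xs, ys)
    return float(r), float(p), len(shared)
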