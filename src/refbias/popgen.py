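"""Pseudo-haploid sampling, D / f4 statistics and the weighted block jackknife.

The four-population D statistic is computed in its allele-frequency form

    D = sum_i (pW - pX)(pY - pZ) / sum_i (pW + pX - 2 pW pX)(pY + pZ - 2 pY pZ)

summing over sites where all four populations are non-missing.  The
denominator is the classic ABBA+BABA normalisation, so |D| <= 1 and the
sign convention reads: negative D indicates excess allele sharing of X
with Y (W being the outgroup-side population).  f4(A,B;C,D) is the plain
per-site mean of (pA - pB)(pC - pD), and the f4-ratio estimates an
admixture proportion as the ratio of two f4 statistics over the shared
complete-site set, with the jackknife applied to the ratio itself.

Standard errors use the delete-m_j weighted block jackknife over
contiguous genomic blocks (default 5 Mbp), with block weights equal to
informative-site counts.  With g blocks of weights m_j, n = sum m_j and
h_j = n / m_j:

    theta_J = g * theta_hat - sum_j (1 - m_j / n) * theta_minus_j
    var = (1/g) * sum_j (h_j * theta_hat - (h_j - 1) * theta_minus_j - theta_J)^2
                        / (h_j - 1)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bias_metrics import PileupSite
from .snp_panel import SNPPanel

DEFAULT_BLOCK_SIZE = 5_000_000

_META_COLS = ("chrom", "pos")


class GenotypeTable:
    """Per-site alternative-allele frequencies for several populations.

    Wraps a DataFrame with columns ``chrom``, ``pos`` (1-based) plus one
    float column per population: haploid calls are 0/1, diploid calls
    {0, 0.5, 1}, frequencies anywhere in [0, 1]; NaN is missing.  Rows
    must be sorted by (chrom, pos) with no duplicates.
    """

    def __init__(self, frame: pd.DataFrame):
        if list(frame.columns[:2]) != list(_META_COLS):
            raise ValueError("first two columns must be 'chrom' and 'pos'")
        pops = list(frame.columns[2:])
        if len(set(pops)) != len(pops):
            raise ValueError("population names must be unique")
        key = list(zip(frame["chrom"], frame["pos"]))
        if key != sorted(key):
            raise ValueError("sites must be sorted by (chrom, pos)")
        if len(set(key)) != len(key):
            raise ValueError("duplicate (chrom, pos) rows")
        vals = frame[pops].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
                raise ValueError("allele frequencies must lie in [0, 1]")
        self.frame = frame.reset_index(drop=True)

    @property
    def populations(self) -> list[str]:
        return list(self.frame.columns[2:])

    @property
    def n_sites(self) -> int:
        return len(self.frame)

    def freqs(self, pop: str) -> np.ndarray:
        return self.frame[pop].to_numpy(dtype=float)

    def restrict(self, mask: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(self.frame.loc[np.asarray(mask, bool)].reset_index(drop=True))

    def block_ids(self, block_size: int = DEFAULT_BLOCK_SIZE) -> np.ndarray:
        """Contiguous block index per site: ``block_size`` windows per
        chromosome starting at position 1; trailing partial windows are
        kept as blocks."""
        chroms = self.frame["chrom"].to_numpy()
        pos = self.frame["pos"].to_numpy(dtype=np.int64)
        window = (pos - 1) // block_size
        ids = np.zeros(len(pos), dtype=np.int64)
        next_id = 0
        mapping: dict[tuple, int] = {}
        for i, key in enumerate(zip(chroms, window)):
            if key not in mapping:
                mapping[key] = next_id
                next_id += 1
            ids[i] = mapping[key]
        return ids

    @classmethod
    def from_tsv(cls, path) -> "GenotypeTable":
        frame = pd.read_csv(path, sep="\t", comment="#")
        frame.columns = [c.lstrip("#") for c in frame.columns]
        return cls(frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_eigenstrat(cls, geno_path, snp_path, ind_path) -> "GenotypeTable":
        """Read an EIGENSTRAT trio.

        ``.geno`` digits count copies of the first ``.snp`` allele (taken
        as the reference allele; 9 = missing); individuals sharing an
        ``.ind`` population label are averaged into one frequency column.
        """
        from .snp_panel import read_panel

        panel = read_panel(snp_path, "eigenstrat_snp")
        inds = []
        with open(ind_path) as fh:
            for line in fh:
                fields = line.split()
                if fields:
                    inds.append((fields[0], fields[-1]))
        pops: dict[str, list[int]] = {}
        for idx, (_ind_id, pop) in enumerate(inds):
            pops.setdefault(pop, []).append(idx)
        rows = []
        with open(geno_path) as fh:
            geno_lines = [line.strip() for line in fh if line.strip()]
        if len(geno_lines) != len(panel):
            raise ValueError(
                f".geno has {len(geno_lines)} rows but .snp has {len(panel)}"
            )
        for rec, line in zip(panel, geno_lines):
            if len(line) != len(inds):
                raise ValueError(
                    f"{rec.chrom}:{rec.pos}: geno row width {len(line)} != "
                    f"{len(inds)} individuals"
                )
            row = {"chrom": rec.chrom, "pos": rec.pos}
            for pop, idxs in pops.items():
                vals = []
                for i in idxs:
                    g = line[i]
                    if g == "9":
                        continue
                    vals.append((2 - int(g)) / 2.0)  # alt-allele frequency
                row[pop] = float(np.mean(vals)) if vals else np.nan
            rows.append(row)
        frame = pd.DataFrame(rows)
        frame = frame.sort_values(["chrom", "pos"]).reset_index(drop=True)
        return cls(frame)


@dataclass(frozen=True)
class DStatResult:
    d: float
    se: float
    z: Optional[float]
    n_sites: int
    n_blocks: int


@dataclass(frozen=True)
class F4Result:
    f4: float
    se: float
    n_sites: int
    n_blocks: int


@dataclass(frozen=True)
class F4RatioResult:
    alpha: float
    se: float
    n_sites: int
    n_blocks: int


def weighted_block_jackknife(
    theta_hat: float,
    theta_minus: Sequence[float],
    weights: Sequence[float],
) -> float:
    """Delete-m_j weighted block jackknife standard error."""
    theta_minus = np.asarray(theta_minus, dtype=float)
    weights = np.asarray(weights, dtype=float)
    g = len(weights)
    if g < 2:
        raise ValueError("need >= 2 jackknife blocks")
    if np.any(weights <= 0):
        raise ValueError("block weights must be positive")
    n = weights.sum()
    if np.any(weights >= n):
        raise ValueError("degenerate jackknife: a single block carries all weight")
    if np.all(theta_minus == theta_hat):
        return 0.0
    h = n / weights
    theta_j = g * theta_hat - np.sum((1.0 - weights / n) * theta_minus)
    terms = (h * theta_hat - (h - 1.0) * theta_minus - theta_j) ** 2 / (h - 1.0)
    var = terms.sum() / g
    return float(math.sqrt(max(var, 0.0)))


def _block_sums(values: np.ndarray, blocks: np.ndarray, n_blocks: int) -> np.ndarray:
    return np.bincount(blocks, weights=values, minlength=n_blocks)


def d_statistic(
    table: GenotypeTable,
    w: str,
    x: str,
    y: str,
    z: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> DStatResult:
    """Four-population D with weighted block jackknife standard error.

    A site enters the sums when all four populations are non-missing; a
    site is *informative* when its ABBA+BABA denominator term is nonzero.
    When the denominator sum is zero but every numerator term vanishes as
    well (e.g. D(W, X; Y, Y) with haploid Y), D is exactly 0 with se 0
    and an undefined Z.
    """
    pw, px, py, pz = (table.freqs(p) for p in (w, x, y, z))
    complete = ~(np.isnan(pw) | np.isnan(px) | np.isnan(py) | np.isnan(pz))
    if not complete.any():
        raise ValueError("no sites with all four populations non-missing")
    pw, px, py, pz = pw[complete], px[complete], py[complete], pz[complete]
    num = (pw - px) * (py - pz)
    den = (pw + px - 2 * pw * px) * (py + pz - 2 * py * pz)
    informative = den != 0
    n_sites = int(informative.sum())

    blocks_all = table.block_ids(block_size)[complete]
    # renumber to consecutive ids over complete sites
    _uniq, blocks = np.unique(blocks_all, return_inverse=True)
    n_blocks = int(blocks.max()) + 1 if len(blocks) else 0

    num_sum = float(num.sum())
    den_sum = float(den.sum())
    if den_sum == 0.0:
        if num_sum == 0.0 and np.all(num == 0.0):
            return DStatResult(d=0.0, se=0.0, z=None, n_sites=n_sites, n_blocks=n_blocks)
        raise ValueError("no informative sites: D denominator is zero")

    d = num_sum / den_sum
    if n_blocks < 2:
        return DStatResult(d=d, se=float("nan"), z=None, n_sites=n_sites, n_blocks=n_blocks)
    num_b = _block_sums(num, blocks, n_blocks)
    den_b = _block_sums(den, blocks, n_blocks)
    weights = _block_sums(informative.astype(float), blocks, n_blocks)
    keep = weights > 0
    if keep.sum() < 2:
        return DStatResult(d=d, se=float("nan"), z=None, n_sites=n_sites, n_blocks=n_blocks)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_minus = (num_sum - num_b[keep]) / (den_sum - den_b[keep])
    se = weighted_block_jackknife(d, theta_minus, weights[keep])
    zscore = d / se if se > 0 else None
    return DStatResult(d=d, se=se, z=zscore, n_sites=n_sites, n_blocks=int(keep.sum()))


def f4_statistic(
    table: GenotypeTable,
    a: str,
    b: str,
    c: str,
    d: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> F4Result:
    """f4(A,B;C,D): mean of (pA-pB)(pC-pD) over complete sites."""
    pa, pb, pc, pd_ = (table.freqs(p) for p in (a, b, c, d))
    complete = ~(np.isnan(pa) | np.isnan(pb) | np.isnan(pc) | np.isnan(pd_))
    if not complete.any():
        raise ValueError("no sites with all four populations non-missing")
    terms = ((pa - pb) * (pc - pd_))[complete]
    n = len(terms)
    f4 = float(terms.mean())

    blocks_all = table.block_ids(block_size)[complete]
    _uniq, blocks = np.unique(blocks_all, return_inverse=True)
    n_blocks = int(blocks.max()) + 1
    if n_blocks < 2:
        return F4Result(f4=f4, se=float("nan"), n_sites=n, n_blocks=n_blocks)
    sums = _block_sums(terms, blocks, n_blocks)
    weights = np.bincount(blocks, minlength=n_blocks).astype(float)
    total = terms.sum()
    theta_minus = (total - sums) / (n - weights)
    se = weighted_block_jackknife(f4, theta_minus, weights)
    return F4Result(f4=f4, se=se, n_sites=n, n_blocks=n_blocks)


def f4_ratio(
    table: GenotypeTable,
    numerator: tuple[str, str, str, str],
    denominator: tuple[str, str, str, str],
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> F4RatioResult:
    """Admixture proportion as a ratio of two f4 statistics.

    Both f4 sums run over the intersection of sites complete for every
    population involved; the jackknife deletes each block from numerator
    and denominator jointly and resamples the ratio itself.
    """
    pops = sorted(set(numerator) | set(denominator))
    freqs = {p: table.freqs(p) for p in pops}
    complete = np.ones(table.n_sites, dtype=bool)
    for p in pops:
        complete &= ~np.isnan(freqs[p])
    if not complete.any():
        raise ValueError("no sites complete for all populations")

    def terms(quad):
        pa, pb, pc, pd_ = (freqs[p][complete] for p in quad)
        return (pa - pb) * (pc - pd_)

    num = terms(numerator)
    den = terms(denominator)
    num_sum, den_sum = float(num.sum()), float(den.sum())
    if den_sum == 0.0:
        raise ValueError("denominator f4 is zero")
    alpha = num_sum / den_sum

    blocks_all = table.block_ids(block_size)[complete]
    _uniq, blocks = np.unique(blocks_all, return_inverse=True)
    n_blocks = int(blocks.max()) + 1
    n = len(num)
    if n_blocks < 2:
        return F4RatioResult(alpha=alpha, se=float("nan"), n_sites=n, n_blocks=n_blocks)
    num_b = _block_sums(num, blocks, n_blocks)
    den_b = _block_sums(den, blocks, n_blocks)
    weights = np.bincount(blocks, minlength=n_blocks).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_minus = (num_sum - num_b) / (den_sum - den_b)
    if not np.all(np.isfinite(theta_minus)):
        raise ValueError("a delete-one block zeroes the denominator f4")
    se = weighted_block_jackknife(alpha, theta_minus, weights)
    return F4RatioResult(alpha=alpha, se=se, n_sites=n, n_blocks=n_blocks)


def stratified_d(
    table: GenotypeTable,
    w: str,
    x: str,
    y: str,
    z: str,
    panel: SNPPanel,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> dict[str, Optional[DStatResult]]:
    """One D statistic per reference-ancestry stratum.

    ``panel`` must carry ancestry labels (see ``annotate_ancestry``);
    jackknife blocks are re-derived within each stratum.  Strata with no
    informative site are reported as None.
    """
    ancestry = {(r.chrom, r.pos): r.ancestry for r in panel}
    labels = sorted({a for a in ancestry.values() if a is not None})
    if not labels:
        raise ValueError("panel has no ancestry annotation")
    site_labels = np.array(
        [
            ancestry.get((c, p)) or "Uncertain"
            for c, p in zip(table.frame["chrom"], table.frame["pos"])
        ]
    )
    out: dict[str, Optional[DStatResult]] = {}
    for label in labels:
        mask = site_labels == label
        if not mask.any():
            out[label] = None
            continue
        try:
            out[label] = d_statistic(table.restrict(mask), w, x, y, z, block_size)
        except ValueError:
            out[label] = None
    return out


# ---------------------------------------------------------------------------
# Genotype calling from pileups

def pseudo_haploid_sample(
    pileups: Sequence[PileupSite],
    min_mapq: int = 30,
    min_baseq: int = 30,
    mode: str = "random",
    seed: int = 0,
) -> pd.Series:
    """One allele per site: the pseudo-haploid genotypes of an individual.

    ``random`` draws one ref/alt observation uniformly; ``majority``
    takes the modal allele with seeded coin-flip ties.  Sites without a
    qualifying ref/alt observation are missing (NaN).  Returns a Series
    of 0/1/NaN indexed by (chrom, pos).
    """
    if mode not in ("random", "majority"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    index = []
    calls = []
    for site in pileups:
        obs = [
            o
            for o in site.observations
            if o.allele_class in ("ref", "alt")
            and o.mapq >= min_mapq
            and o.base_qual >= min_baseq
        ]
        index.append((site.snp.chrom, site.snp.pos))
        if not obs:
            calls.append(np.nan)
            continue
        if mode == "random":
            pick = obs[rng.integers(len(obs))]
            calls.append(1.0 if pick.allele_class == "alt" else 0.0)
        else:
            n_alt = sum(1 for o in obs if o.allele_class == "alt")
            n_ref = len(obs) - n_alt
            if n_alt > n_ref:
                calls.append(1.0)
            elif n_ref > n_alt:
                calls.append(0.0)
            else:
                calls.append(float(rng.integers(2)))
    return pd.Series(
        calls, index=pd.MultiIndex.from_tuples(index, names=["chrom", "pos"])
    )


def naive_diploid_call(
    site: PileupSite,
    min_depth: int = 10,
    band: tuple[float, float] = (0.25, 0.75),
) -> float:
    """Plumbing-grade diploid call from raw allele counts.

    Missing (NaN) below ``min_depth``; 0.5 when the alternative fraction
    falls inside the band; otherwise the majority homozygote.  This is a
    deliberately simple threshold caller, not a genotype-likelihood model.
    """
    n_ref, n_alt = site.n_ref, site.n_alt
    total = n_ref + n_alt
    if total < min_depth:
        return float("nan")
    frac = n_alt / total
    if band[0] <= frac <= band[1]:
        return 0.5
    return 1.0 if frac > 0.5 else 0.0


def genotype_table_from_columns(
    columns: dict[str, pd.Series]
) -> GenotypeTable:
    """Assemble per-population call Series (indexed by (chrom, pos)) into
    a GenotypeTable on the union of their sites."""
    frame = pd.DataFrame(columns)
    frame = frame.sort_index()
    frame.index.names = ["chrom", "pos"]
    frame = frame.reset_index()
    return GenotypeTable(frame)
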