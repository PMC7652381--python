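"""Diversity and differentiation statistics: per-site nucleotide diversity
(theta-pi), Watterson's theta, Tajima's D, Weir-Cockerham and Hudson FST,
sliding windows, and genotype-dosage LD decay.

Missing-data conventions: theta-pi and theta-w use pairwise deletion with
each site's own number of called allele copies; Tajima's D uses
complete-case sites only, since the classical variance constants assume a
fixed sample size.  LD uses composite genotype-dosage r^2 (squared Pearson
correlation of dosages), which needs no phase; for highly selfing, mostly
homozygous data it converges to the haplotype r^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix

__all__ = [
    "theta_pi",
    "theta_w",
    "tajimas_d",
    "fst",
    "sliding_windows",
    "ld_decay",
    "LDDecay",
]


def _subset(gm: GenotypeMatrix, samples):
    if samples is None:
        return gm.genotypes
    if isinstance(samples, str):
        return gm.genotypes[gm.sample_indices(samples)]
    return gm.genotypes[np.asarray(samples)]


def _pi_site_sum(g: np.ndarray) -> float:
    """Sum over sites of unbiased per-site heterozygosity
    2 d (n_s - d) / (n_s (n_s - 1)) with pairwise deletion."""
    called = g != MISSING
    ns = 2 * called.sum(axis=0)
    d = np.where(called, g, 0).sum(axis=0)
    ok = ns >= 2
    ns, d = ns[ok], d[ok]
    return float((2.0 * d * (ns - d) / (ns * (ns - 1.0))).sum())


def theta_pi(gm: GenotypeMatrix, samples=None, span_bp: float | None = None) -> float:
    """Average pairwise difference per site over ``span_bp``.

    ``samples`` may be a population label, an index array, or None (all).
    ``span_bp`` defaults to the number of sites in ``gm`` (per-variant
    diversity); pass the surveyed length for per-bp diversity.
    """
    if span_bp is None:
        span_bp = gm.n_sites
    if span_bp <= 0:
        raise ValueError("span_bp must be positive")
    return _pi_site_sum(_subset(gm, samples)) / span_bp


@lru_cache(maxsize=None)
def _harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def theta_w(gm: GenotypeMatrix, samples=None, span_bp: float | None = None) -> float:
    """Watterson's estimator S / (a1 * span); sites with missing calls use
    their own called copy number in a1."""
    if span_bp is None:
        span_bp = gm.n_sites
    if span_bp <= 0:
        raise ValueError("span_bp must be positive")
    g = _subset(gm, samples)
    called = g != MISSING
    ns = 2 * called.sum(axis=0)
    d = np.where(called, g, 0).sum(axis=0)
    seg = (d > 0) & (d < ns)
    total = 0.0
    for n_s in ns[seg]:
        if n_s < 2:
            raise ValueError("theta_w needs >= 2 allele copies per site")
        total += 1.0 / _harmonic(int(n_s))
    return total / span_bp


# Tajima (1989) variance constants for haploid sample size n
def _tajima_constants(n: int):
    a1 = _harmonic(n)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(gm: GenotypeMatrix, samples=None) -> float:
    """Tajima's D over complete-case sites; NaN when no site segregates."""
    g = _subset(gm, samples)
    complete = (g != MISSING).all(axis=0)
    g = g[:, complete]
    n = 2 * g.shape[0]
    if n < 4:
        raise ValueError("Tajima's D needs >= 2 diploids")
    d = g.sum(axis=0)
    seg = (d > 0) & (d < n)
    S = int(seg.sum())
    if S == 0:
        return math.nan
    dseg = d[seg].astype(float)
    pi_sum = float((2.0 * dseg * (n - dseg) / (n * (n - 1.0))).sum())
    a1, e1, e2 = _tajima_constants(n)
    return (pi_sum - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1.0))


def _wc_components(g1: np.ndarray, g2: np.ndarray):
    """Weir-Cockerham (1984) per-site variance components a, b, c for two
    populations of diploids, genotype-level (with heterozygosity term)."""
    r = 2.0
    comps = []
    for g in (g1, g2):
        called = g != MISSING
        n_i = called.sum(axis=0).astype(float)  # diploids with data
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(called, g, 0).sum(axis=0) / (2.0 * n_i)
            h_i = np.where(called, g == 1, False).sum(axis=0) / n_i
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    ok = (n1 > 0) & (n2 > 0)
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    # monomorphic-across-both sites contribute nothing
    poly = ok & (pbar > 0) & (pbar < 1) & (nbar > 1)
    for arr in (a, b, c):
        arr[~poly] = 0.0
    return a, b, c, poly


def _hudson_components(g1: np.ndarray, g2: np.ndarray):
    """Hudson FST numerator/denominator per site (Bhatia et al. form)."""
    comps = []
    for g in (g1, g2):
        called = g != MISSING
        nh = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, g, 0).sum(axis=0) / nh
        comps.append((nh, p))
    (n1, p1), (n2, p2) = comps
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1.0)
            - p2 * (1 - p2) / (n2 - 1.0)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    poly = ok & (den > 0)
    num[~poly] = 0.0
    den[~poly] = 0.0
    return num, den, poly


def fst(
    gm: GenotypeMatrix,
    pop1: str,
    pop2: str,
    estimator: str = "weir_cockerham",
    site_mask=None,
) -> float:
    """Global FST between two populations (ratio of sums across sites).

    ``weir_cockerham`` uses the variance-component estimator
    (sum a / sum (a+b+c)); ``hudson`` the sample-size-corrected
    heterozygosity form.  Negative values are reported as-is.  NaN when no
    site is polymorphic across the pair.
    """
    g1 = gm.genotypes[gm.sample_indices(pop1)]
    g2 = gm.genotypes[gm.sample_indices(pop2)]
    if site_mask is not None:
        g1, g2 = g1[:, site_mask], g2[:, site_mask]
    if estimator == "weir_cockerham":
        a, b, c, poly = _wc_components(g1, g2)
        den = (a + b + c).sum()
        return float(a.sum() / den) if poly.any() and den != 0 else math.nan
    if estimator == "hudson":
        num, den, poly = _hudson_components(g1, g2)
        return float(num.sum() / den.sum()) if poly.any() else math.nan
    raise ValueError(f"unknown FST estimator {estimator!r}")


def _window_starts(length: int, size: int, step: int) -> np.ndarray:
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    if length <= 0:
        return np.array([], dtype=int)
    n = max(1, math.ceil((length - size) / step) + 1) if length > size else 1
    return np.arange(n) * step


def sliding_windows(
    gm: GenotypeMatrix,
    size_bp: int = 100_000,
    step_bp: int = 40_000,
    pop1: str | None = None,
    pop2: str | None = None,
    estimator: str = "weir_cockerham",
    contig_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window diversity/differentiation table over 0-based half-open
    windows starting at 0, step, 2*step, ... on each contig.

    Columns: chrom, start, end, n_sites, and per population theta_pi /
    theta_w / tajima_d, plus fst and log2_pi_ratio (pop1 over pop2) when
    two populations are given.  Contig length defaults to the last site's
    position (pass ``contig_lengths`` for full-length tiling).
    """
    pops = gm.populations
    if pop1 is None and len(pops) >= 1:
        pop1 = pops[0]
    if pop2 is None and len(pops) >= 2:
        pop2 = pops[1]
    rows = []
    for contig in dict.fromkeys(gm.chrom):
        on = gm.chrom == contig
        pos0 = gm.pos[on] - 1  # 0-based
        length = (
            contig_lengths[contig]
            if contig_lengths is not None
            else int(pos0.max()) + 1
        )
        sub = gm.take_sites(np.nonzero(on)[0])
        for start in _window_starts(length, size_bp, step_bp):
            end = start + size_bp
            inw = (pos0 >= start) & (pos0 < end)
            wgm = sub.take_sites(np.nonzero(inw)[0])
            row = {
                "chrom": contig,
                "start": int(start),
                "end": int(end),
                "n_sites": wgm.n_sites,
            }
            pis = {}
            for pop in ([pop1] if pop2 is None else [pop1, pop2]):
                if pop is None:
                    continue
                pis[pop] = theta_pi(wgm, pop, size_bp) if wgm.n_sites else 0.0
                row[f"theta_pi_{pop}"] = pis[pop]
                row[f"theta_w_{pop}"] = (
                    theta_w(wgm, pop, size_bp) if wgm.n_sites else 0.0
                )
                row[f"tajima_d_{pop}"] = (
                    tajimas_d(wgm, pop) if wgm.n_sites else math.nan
                )
            if pop1 is not None and pop2 is not None:
                row["fst"] = (
                    fst(wgm, pop1, pop2, estimator) if wgm.n_sites else math.nan
                )
                p1, p2 = pis[pop1], pis[pop2]
                row["log2_pi_ratio"] = (
                    math.log2(p1 / p2) if p1 > 0 and p2 > 0 else math.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class LDDecay:
    """Mean genotype r^2 by physical-distance bin."""

    bin_edges: np.ndarray  # length n_bins + 1, bp
    mean_r2: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dist_low": self.bin_edges[:-1],
                "dist_high": self.bin_edges[1:],
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs,
            }
        )


def ld_decay(
    gm: GenotypeMatrix,
    samples=None,
    min_maf: float = 0.05,
    max_dist_bp: int = 100_000,
    window_avg_bp: int = 20_000,
) -> LDDecay:
    """Composite genotype-dosage r^2 for all intra-contig site pairs within
    ``max_dist_bp``, averaged in ``window_avg_bp`` distance bins.

    Sites are pre-filtered to pooled MAF >= ``min_maf`` over the chosen
    samples; missing dosages are dropped pairwise and pairs with < 4
    co-observed samples or zero variance are skipped.
    """
    g = _subset(gm, samples).astype(float)
    g[g == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g, axis=0) / 2.0
    maf_ok = np.minimum(p, 1 - p) >= min_maf
    edges = np.arange(0, max_dist_bp + window_avg_bp, window_avg_bp)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for contig in dict.fromkeys(gm.chrom):
        idx = np.nonzero((gm.chrom == contig) & maf_ok)[0]
        pos = gm.pos[idx]
        for ii in range(len(idx)):
            for jj in range(ii + 1, len(idx)):
                dist = pos[jj] - pos[ii]
                if dist > max_dist_bp:
                    break
                x, y = g[:, idx[ii]], g[:, idx[jj]]
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 4:
                    continue
                xv, yv = x[ok], y[ok]
                vx, vy = xv.var(), yv.var()
                if vx == 0 or vy == 0:
                    continue
                r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / math.sqrt(vx * vy)
                b = min(int(dist // window_avg_bp), len(sums) - 1)
                sums[b] += r * r
                counts[b] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecay(edges, mean, counts)
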