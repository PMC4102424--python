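"""Population-genetic statistics for interruption alleles.

Heterozygosity (H = 2pq), the fixation index F_ST = (H_T - H_S)/H_T on
unweighted population means, binned heterozygosity distributions, a pooled
two-sample bootstrap Kolmogorov-Smirnov test (the bootstrap handles the
heavy ties of binned allele-frequency data), and haplotype r^2 linkage
disequilibrium with max-R^2 partner selection inside a 1-Mb window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LD_WINDOW_BP = 500_000  # each side of the focal indel (1 Mb total window)
PERFECT_LD_TOL = 1e-12


def heterozygosity(p: float) -> float:
    """Expected heterozygosity 2p(1-p) of a biallelic locus."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {p}")
    return 2.0 * p * (1.0 - p)


@dataclass(frozen=True)
class FstResult:
    h_s: float
    h_t: float
    fst: float | None  # None when H_T == 0 (monomorphic everywhere)


def fst(frequencies) -> FstResult:
    """F_ST over k >= 2 populations from variant allele frequencies.

    H_S is the unweighted mean of the within-population heterozygosities
    2 p_i q_i; the total-population frequency P is the unweighted mean of
    the p_i; H_T = 2PQ; F_ST = (H_T - H_S)/H_T, undefined (None) at H_T = 0.
    """
    p = np.asarray(list(frequencies), dtype=float)
    if p.size < 2:
        raise ValueError("F_ST needs at least two populations")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must be in [0, 1]")
    h_s = float(np.mean(2.0 * p * (1.0 - p)))
    P = float(np.mean(p))
    Q = float(np.mean(1.0 - p))
    h_t = 2.0 * P * Q
    if h_t == 0.0:
        return FstResult(h_s=h_s, h_t=h_t, fst=None)
    # H_T - H_S = 2 Var(p); the variance form avoids the cancellation the
    # direct difference suffers near fixation
    var_p = float(np.mean((p - P) ** 2))
    value = min(var_p / (P * Q), 1.0)
    return FstResult(h_s=h_s, h_t=h_t, fst=value)


HET_BIN_WIDTH = 0.02
HET_RANGE = (0.0, 0.5)


def het_distribution(
    het_values, bin_width: float = HET_BIN_WIDTH, het_range=HET_RANGE
) -> tuple[np.ndarray, np.ndarray]:
    """Relative frequencies of heterozygosity values in left-closed bins of
    width 0.02 spanning [0, 0.5] (last bin closed).  Returns (bin_edges,
    frequencies); frequencies sum to 1."""
    h = np.asarray(list(het_values), dtype=float)
    if h.size == 0:
        raise ValueError("empty heterozygosity sample")
    lo, hi = het_range
    if np.any(h < lo) or np.any(h > hi):
        raise ValueError(f"heterozygosity outside [{lo}, {hi}] is impossible "
                         "for a biallelic 2pq value")
    n_bins = int(round((hi - lo) / bin_width))
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(h, bins=edges)
    return edges, counts / h.size


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic D = sup |ECDF_a - ECDF_b| (tie-safe)."""
    grid = np.concatenate([a, b])
    grid.sort(kind="mergesort")
    fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
    fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def ks_boot(
    sample_a,
    sample_b,
    iterations: int = 10_000,
    rng_seed: int | None = None,
) -> dict:
    """Two-sample bootstrap Kolmogorov-Smirnov test.

    The null distribution of D is generated by resampling, with
    replacement, samples of the original sizes from the pooled data; the
    p-value is the fraction of bootstrap statistics >= the observed D.
    Ties are handled naturally (the reason bootstrap is preferred over the
    asymptotic test for binned data).
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    d_obs = _ks_statistic(a, b)
    pooled = np.concatenate([a, b])
    values, counts = np.unique(pooled, return_counts=True)
    probs = counts / pooled.size
    rng = np.random.default_rng(rng_seed)
    # multinomial draws over the pooled support are equivalent to index
    # resampling and allow fully vectorised ECDFs
    boot_a = rng.multinomial(a.size, probs, size=iterations).cumsum(axis=1) / a.size
    boot_b = rng.multinomial(b.size, probs, size=iterations).cumsum(axis=1) / b.size
    d_null = np.max(np.abs(boot_a - boot_b), axis=1)
    # add-one Monte Carlo p-value: never exactly zero, mildly conservative
    n_ge = int(np.sum(d_null >= d_obs - 1e-12))
    p = (1 + n_ge) / (iterations + 1)
    return {"D": d_obs, "p": p, "iterations": iterations}


def ld_r2(hap_a, hap_b) -> float | None:
    """Squared haplotype correlation r^2 between two biallelic variants.

    ``hap_a`` and ``hap_b`` are equal-length 0/1 vectors of phased
    haplotype states.  Returns None when either vector is monomorphic
    (r^2 undefined).
    """
    a = np.asarray(list(hap_a), dtype=float)
    b = np.asarray(list(hap_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("haplotype vectors must have equal length")
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return None
    p_ab = float(np.mean(a * b))
    num = (p_ab - p_a * p_b) ** 2
    den = p_a * (1 - p_a) * p_b * (1 - p_b)
    return float(num / den)


@dataclass(frozen=True)
class LdPartner:
    snp_id: str
    position: int
    r2: float
    perfect: bool


def max_ld_partner(
    indel_position: int,
    indel_haplotypes,
    snps,
    window_bp: int = LD_WINDOW_BP,
) -> LdPartner | None:
    """Best-LD SNP partner of an interruption-causing indel.

    ``snps`` is an iterable of (snp_id, position, haplotype vector).  Only
    SNPs within ``window_bp`` of the indel on each side are considered.
    Ties on r^2 are broken by distance to the indel, then by coordinate.
    Returns None when the window holds no usable (polymorphic) SNP.
    """
    best: tuple[float, int, int, str] | None = None
    for snp_id, pos, haps in snps:
        if abs(pos - indel_position) > window_bp:
            continue
        r2 = ld_r2(indel_haplotypes, haps)
        if r2 is None:
            continue
        key = (-r2, abs(pos - indel_position), pos, snp_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    r2 = -best[0]
    return LdPartner(
        snp_id=best[3],
        position=best[2],
        r2=r2,
        perfect=r2 >= 1.0 - PERFECT_LD_TOL,
    )
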