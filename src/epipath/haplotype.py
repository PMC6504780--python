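"""EM haplotype-frequency estimation, D' linkage disequilibrium, and
per-haplotype case/control association tests over 2-4 SNP windows.

The EM runs over unphased multilocus genotypes: the E-step assigns each
haplotype pair compatible with an individual's genotype a posterior
proportional to the product of current frequencies (doubled for
heterozygous pairs), the M-step re-estimates frequencies from expected
counts.  Initialization is uniform, so the fit is deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from math import log, sqrt

import numpy as np
from scipy.special import erfc
from scipy.stats import chi2 as chi2_dist

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "HaplotypeTable",
    "HaplotypeAssocResult",
    "UndefinedLDError",
    "em_haplotype_frequencies",
    "dprime",
    "haplotype_case_control_test",
    "chisq_p",
    "sliding_windows",
]

_EM_TOL = 1e-8
_EM_MAX_ITER = 1000


class UndefinedLDError(ValueError):
    """LD requested for a monomorphic SNP."""


@dataclass
class HaplotypeTable:
    """EM-estimated haplotype frequencies for one SNP window and stratum."""

    window_snps: list[str]
    haplotypes: list[str]           # allele strings, one char per SNP
    frequencies: np.ndarray
    loglik: float
    n_iterations: int
    n_chromosomes: int
    loglik_path: list[float]

    def freq(self, haplotype: str) -> float:
        try:
            return float(self.frequencies[self.haplotypes.index(haplotype)])
        except ValueError:
            return 0.0


@dataclass
class HaplotypeAssocResult:
    """Per-haplotype 2x2 case/control test (haplotype vs all others)."""

    haplotype: str
    freq_cases: float
    freq_controls: float
    chi2: float
    df: int
    p: float
    defined: bool = True


def _stratum_mask(matrix: GenotypeMatrix, stratum: str) -> np.ndarray:
    if stratum == "all":
        return matrix.phenotype != MISSING
    if stratum == "cases":
        return matrix.case_mask
    if stratum == "controls":
        return matrix.control_mask
    raise ValueError(f"unknown stratum {stratum!r}")


def em_haplotype_frequencies(matrix: GenotypeMatrix, window_snps: list[str],
                             stratum: str = "all",
                             tol: float = _EM_TOL,
                             max_iter: int = _EM_MAX_ITER) -> HaplotypeTable:
    """EM haplotype frequencies for a 2-4 SNP window in one stratum.

    Samples with any missing genotype in the window are excluded.
    Convergence: max absolute frequency change < ``tol``.
    """
    k = len(window_snps)
    if not 2 <= k <= 4:
        raise ValueError("window size must be 2, 3, or 4 SNPs")
    idx = [matrix.snp_index(s) for s in window_snps]
    sub = matrix.genotypes[_stratum_mask(matrix, stratum)][:, idx]
    complete = (sub != MISSING).all(axis=1)
    sub = sub[complete]
    if sub.shape[0] == 0:
        raise ValueError("no complete-data samples in stratum")

    H = 2 ** k
    # haplotype h: bit i set -> allele a1 at window SNP i
    hap_bits = [tuple((h >> i) & 1 for i in range(k)) for h in range(H)]

    geno_tuples, counts = np.unique(sub, axis=0, return_counts=True)
    compat: list[list[tuple[int, int, float]]] = []
    for g in geno_tuples:
        pairs = []
        for h1, h2 in combinations_with_replacement(range(H), 2):
            if all(hap_bits[h1][i] + hap_bits[h2][i] == g[i] for i in range(k)):
                pairs.append((h1, h2, 1.0 if h1 == h2 else 2.0))
        compat.append(pairs)

    n = int(counts.sum())
    freqs = np.full(H, 1.0 / H)
    loglik_path: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new = np.zeros(H)
        ll = 0.0
        for pairs, cnt in zip(compat, counts):
            w = np.array([mult * freqs[h1] * freqs[h2] for h1, h2, mult in pairs])
            tot = w.sum()
            if tot <= 0:
                continue
            ll += cnt * log(tot)
            w *= cnt / tot
            for (h1, h2, _), wi in zip(pairs, w):
                new[h1] += wi
                new[h2] += wi
        new /= 2.0 * n
        loglik_path.append(ll)
        if np.abs(new - freqs).max() < tol:
            freqs = new
            break
        freqs = new

    # final log-likelihood at the converged frequencies
    ll = 0.0
    for pairs, cnt in zip(compat, counts):
        tot = sum(mult * freqs[h1] * freqs[h2] for h1, h2, mult in pairs)
        if tot > 0:
            ll += cnt * log(tot)
    loglik_path.append(ll)

    variants = [matrix.variants[j] for j in idx]
    hap_strings = [
        "".join(variants[i].allele_a1 if bits[i] else variants[i].allele_a2
                for i in range(k))
        for bits in hap_bits
    ]
    return HaplotypeTable(
        window_snps=list(window_snps), haplotypes=hap_strings,
        frequencies=freqs, loglik=ll, n_iterations=n_iter,
        n_chromosomes=2 * n, loglik_path=loglik_path,
    )


def dprime(matrix: GenotypeMatrix, snp_a: str, snp_b: str,
           stratum: str = "all") -> float:
    """|D'| between two SNPs from EM two-SNP haplotype frequencies."""
    table = em_haplotype_frequencies(matrix, [snp_a, snp_b], stratum)
    f = table.frequencies
    # bit 0 = snp_a, bit 1 = snp_b (a1 alleles)
    p_a = float(f[1] + f[3])
    p_b = float(f[2] + f[3])
    if not (0.0 < p_a < 1.0) or not (0.0 < p_b < 1.0):
        raise UndefinedLDError(f"{snp_a} or {snp_b} monomorphic in stratum")
    d = float(f[3]) - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    if d_max == 0:
        return 0.0
    return float(min(1.0, abs(d / d_max)))


def haplotype_case_control_test(table_cases: HaplotypeTable,
                                table_controls: HaplotypeTable,
                                n_cases: int, n_controls: int,
                                min_overall_freq: float = 0.01
                                ) -> list[HaplotypeAssocResult]:
    """Haplotype-vs-others 2x2 tests from stratum frequency tables.

    Expected counts per haplotype h: ``2*n_cases*F_A`` vs the remainder in
    cases, likewise in controls; Pearson chi-square with df=1.  Haplotypes
    with overall (case+control weighted) frequency below
    ``min_overall_freq`` are skipped.  A zero margin flags the result
    undefined (chi2/p = nan).
    """
    if table_cases.window_snps != table_controls.window_snps:
        raise ValueError("case and control tables cover different windows")
    n_ca_chr = 2.0 * n_cases
    n_co_chr = 2.0 * n_controls
    haps = list(dict.fromkeys(table_cases.haplotypes + table_controls.haplotypes))
    out: list[HaplotypeAssocResult] = []
    for h in haps:
        fa = table_cases.freq(h)
        fu = table_controls.freq(h)
        overall = (n_ca_chr * fa + n_co_chr * fu) / (n_ca_chr + n_co_chr)
        if overall < min_overall_freq:
            continue
        a = n_ca_chr * fa
        b = n_ca_chr * (1.0 - fa)
        c = n_co_chr * fu
        d = n_co_chr * (1.0 - fu)
        n_tot = a + b + c + d
        margins = (a + b) * (c + d) * (a + c) * (b + d)
        if margins <= 0:
            out.append(HaplotypeAssocResult(h, fa, fu, float("nan"), 1,
                                            float("nan"), defined=False))
            continue
        chi2 = n_tot * (a * d - b * c) ** 2 / margins
        out.append(HaplotypeAssocResult(h, fa, fu, float(chi2), 1,
                                        chisq_p(float(chi2), 1)))
    return out


def chisq_p(chi2: float, df: int) -> float:
    """Upper-tail chi-square probability; closed form via erfc for df=1."""
    if chi2 < 0:
        raise ValueError("chi2 must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    if df == 1:
        return float(erfc(sqrt(chi2 / 2.0)))
    return float(chi2_dist.sf(chi2, df))


def sliding_windows(snp_ids: list[str], sizes=(2, 3, 4)) -> list[list[str]]:
    """All contiguous windows of each requested size, in positional order."""
    if len(snp_ids) < 2:
        raise ValueError("need at least 2 SNPs")
    out: list[list[str]] = []
    for size in sorted(set(sizes)):
        if not 2 <= size <= 4:
            raise ValueError("window sizes must be in {2, 3, 4}")
        for start in range(len(snp_ids) - size + 1):
            out.append(list(snp_ids[start:start + size]))
    return out
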