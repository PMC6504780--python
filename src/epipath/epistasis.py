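"""Pairwise SNP-SNP interaction tests for case/control panels.

Two statistics are provided:

* a fast allele-based screen comparing the SNP1-SNP2 allelic odds ratio
  between cases (R) and controls (S),
  ``z = (ln R - ln S) / sqrt(var_lnR + var_lnS)``, with Woolf variances
  computed from 2x2 allele-pair tables; and
* a refinement fit, logistic regression of case status on the two allele
  dosages and their product, reporting a Wald test for the interaction
  coefficient.

Double heterozygotes are ambiguous for allele pairing; the cross-product
convention used here splits each individual's contribution as
``cell[j][k] = 0.5 * c_j(g1) * c_k(g2)`` with ``c_1(g) = g`` and
``c_0(g) = 2 - g``, which is deterministic, phase-free, and exact for all
unambiguous genotypes.  Each complete-data sample contributes total mass 2
to its group's table.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from math import log, sqrt

import numpy as np
from scipy.stats import norm

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "ScanConfig",
    "InteractionStat",
    "LogisticFit",
    "ScanResult",
    "UndefinedStatisticError",
    "allele_pair_table",
    "fast_epistasis_z",
    "dosage_logistic_interaction",
    "pairwise_scan",
    "n_pairs",
    "bonferroni_threshold",
]

logger = logging.getLogger(__name__)


class UndefinedStatisticError(ValueError):
    """Contingency table empty/degenerate; statistic undefined."""


@dataclass(frozen=True)
class ScanConfig:
    """Screening and refinement parameters for the pairwise scan."""

    p_screen: float = 1e-8
    alpha: float = 0.05
    continuity_correction: float = 0.5
    min_maf: float = 0.05
    min_group_n: int = 10
    min_distance_bp: int = 0  # within-chromosome pairs closer than this are skipped

    def __post_init__(self) -> None:
        if not 0.0 < self.p_screen < 1.0:
            raise ValueError(f"p_screen must be in (0, 1), got {self.p_screen}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class InteractionStat:
    """One SNP pair's interaction test result."""

    snp1_id: str
    snp2_id: str
    z: float
    p_z: float
    beta_int: float = float("nan")
    p_dosage: float = float("nan")
    n_used: int = 0


@dataclass
class LogisticFit:
    """Dosage-logistic interaction fit (coefficient order: 1, g1, g2, g1*g2)."""

    beta: np.ndarray
    se: np.ndarray
    p_interaction: float
    converged: bool
    n_used: int
    loglik_path: list[float]

    @property
    def beta_int(self) -> float:
        return float(self.beta[3])

    @property
    def se_int(self) -> float:
        return float(self.se[3])


@dataclass
class ScanResult:
    interactions: list[InteractionStat]
    n_tests_planned: int
    n_skipped: int


# ---------------------------------------------------------------------------
# Allele-based screen
# ---------------------------------------------------------------------------

def allele_pair_table(g1: np.ndarray, g2: np.ndarray,
                      mask: np.ndarray | None = None) -> np.ndarray:
    """2x2 allele-pair table for one phenotype group.

    Index 0 is allele a2, index 1 is allele a1 for both SNPs, so
    ``table[1, 1]`` is the a1-a1 cell.
    """
    g1 = np.asarray(g1, dtype=np.int64)
    g2 = np.asarray(g2, dtype=np.int64)
    if g1.shape != g2.shape:
        raise ValueError("g1 and g2 must have the same length")
    if mask is not None:
        g1, g2 = g1[mask], g2[mask]
    ok = (g1 != MISSING) & (g2 != MISSING)
    if not ok.any():
        raise UndefinedStatisticError("no complete-data samples in group")
    a1, a2 = g1[ok].astype(float), g2[ok].astype(float)
    c1_1, c0_1 = a1, 2.0 - a1
    c1_2, c0_2 = a2, 2.0 - a2
    table = 0.5 * np.array([
        [np.dot(c0_1, c0_2), np.dot(c0_1, c1_2)],
        [np.dot(c1_1, c0_2), np.dot(c1_1, c1_2)],
    ])
    return table


def _corrected(table: np.ndarray, cc: float) -> np.ndarray:
    if (table == 0).any():
        return table + cc
    return table


def fast_epistasis_z(table_cases: np.ndarray, table_controls: np.ndarray,
                     cc: float = 0.5) -> tuple[float, float]:
    """Z statistic for the difference of log odds ratios between groups.

    ``cc`` is added to every cell of a table that contains a zero cell
    (Haldane-Anscombe).  Returns ``(z, p)`` with a two-sided normal P.

    The variance of each group's ln OR is half the Woolf reciprocal-cell
    sum: the smoothed table carries total mass ``2n`` but encodes only
    ``n`` independent individuals, and under Hardy-Weinberg proportions
    the delta method gives exactly half the naive Woolf variance for any
    allele frequencies.  The naive sum would deflate |z| by sqrt(2) and
    make the screen badly conservative.
    """
    tc = np.asarray(table_cases, dtype=float)
    tk = np.asarray(table_controls, dtype=float)
    for t in (tc, tk):
        if t.shape != (2, 2) or (t < 0).any():
            raise ValueError("tables must be nonnegative 2x2")
        if t.sum() == 0:
            raise UndefinedStatisticError("all-zero contingency table")
    tc = _corrected(tc, cc)
    tk = _corrected(tk, cc)
    ln_r = log(tc[0, 0]) + log(tc[1, 1]) - log(tc[0, 1]) - log(tc[1, 0])
    ln_s = log(tk[0, 0]) + log(tk[1, 1]) - log(tk[0, 1]) - log(tk[1, 0])
    var = 0.5 * float((1.0 / tc).sum() + (1.0 / tk).sum())
    z = (ln_r - ln_s) / sqrt(var)
    p = 2.0 * float(norm.sf(abs(z)))
    return z, p


# ---------------------------------------------------------------------------
# Dosage-logistic refinement
# ---------------------------------------------------------------------------

def _logistic_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # numerically stable: -log(1 + exp(-eta)) for y=1, -log(1 + exp(eta)) for y=0
    return float(-(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y)).sum())


def dosage_logistic_interaction(g1: np.ndarray, g2: np.ndarray,
                                phenotype: np.ndarray,
                                max_iter: int = 100, tol: float = 1e-8,
                                min_group_n: int = 10) -> LogisticFit:
    """Fit ``logit P(case) = b0 + b1*g1 + b2*g2 + b3*g1*g2`` by IRLS.

    Newton steps with step-halving (log-likelihood never decreases).
    Non-convergence within ``max_iter`` iterations, or quasi-separation,
    yields a flagged result with a missing P-value rather than an exception.
    """
    g1 = np.asarray(g1, dtype=np.int64)
    g2 = np.asarray(g2, dtype=np.int64)
    ph = np.asarray(phenotype, dtype=np.int64)
    ok = (g1 != MISSING) & (g2 != MISSING) & (ph != MISSING)
    g1f, g2f, y = g1[ok].astype(float), g2[ok].astype(float), ph[ok].astype(float)
    n = int(ok.sum())
    if (y == 1).sum() < min_group_n or (y == 0).sum() < min_group_n:
        raise ValueError(
            f"need >= {min_group_n} complete-data samples per phenotype group"
        )
    X = np.column_stack([np.ones(n), g1f, g2f, g1f * g2f])
    beta = np.zeros(4)
    ll = _logistic_loglik(X, y, beta)
    path = [ll]
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        if np.abs(grad).max() < tol:
            converged = True
            break
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # step halving keeps the log-likelihood monotone
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _logistic_loglik(X, y, cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        beta = cand
        ll = ll_new
        path.append(ll)
    # Fisher information at the optimum for Wald SEs
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    separated = bool(np.abs(beta).max() > 30.0)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(4, np.nan)
        separated = True
    if converged and not separated and np.isfinite(se[3]) and se[3] > 0:
        wald = beta[3] / se[3]
        p_int = 2.0 * float(norm.sf(abs(wald)))
        flag = True
    else:
        p_int = float("nan")
        flag = False
    return LogisticFit(beta=beta, se=se, p_interaction=p_int, converged=flag,
                       n_used=n, loglik_path=path)


# ---------------------------------------------------------------------------
# Whole-panel scan
# ---------------------------------------------------------------------------

def _group_pair_cells(G: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, ...]:
    """All-pairs 2x2 cells for one phenotype group, as four m x m matrices
    (n00, n01, n10, n11) indexed (a2, a1) per :func:`allele_pair_table`."""
    sub = G[mask].astype(np.float64)
    missing = sub < 0
    A = np.where(missing, 0.0, sub)          # c_1 contributions
    B = np.where(missing, 0.0, 2.0 - sub)    # c_0 contributions
    n11 = 0.5 * (A.T @ A)
    n10 = 0.5 * (A.T @ B)
    n01 = 0.5 * (B.T @ A)
    n00 = 0.5 * (B.T @ B)
    return n00, n01, n10, n11


def pairwise_scan(matrix: GenotypeMatrix, config: ScanConfig = ScanConfig()) -> ScanResult:
    """Screen all unordered SNP pairs with the allele-based Z test and
    refine pairs below ``config.p_screen`` with the dosage-logistic fit.

    Results are sorted ascending by screen P, ties broken by SNP ids.
    """
    m = matrix.n_variants
    if m < 2:
        raise ValueError("need at least 2 SNPs to scan")
    cc = config.continuity_correction
    cells_ca = _group_pair_cells(matrix.genotypes, matrix.case_mask)
    cells_co = _group_pair_cells(matrix.genotypes, matrix.control_mask)

    def corrected(cells):
        c00, c01, c10, c11 = cells
        anyzero = (c00 == 0) | (c01 == 0) | (c10 == 0) | (c11 == 0)
        add = np.where(anyzero, cc, 0.0)
        return c00 + add, c01 + add, c10 + add, c11 + add

    with np.errstate(divide="ignore", invalid="ignore"):
        ca = corrected(cells_ca)
        co = corrected(cells_co)
        ln_r = np.log(ca[0]) + np.log(ca[3]) - np.log(ca[1]) - np.log(ca[2])
        ln_s = np.log(co[0]) + np.log(co[3]) - np.log(co[1]) - np.log(co[2])
        var = 0.5 * (sum(1.0 / c for c in ca) + sum(1.0 / c for c in co))
        zmat = (ln_r - ln_s) / np.sqrt(var)

    total_ca = sum(cells_ca).astype(float)
    total_co = sum(cells_co).astype(float)
    defined = (total_ca > 0) & (total_co > 0) & np.isfinite(zmat)

    iu, ju = np.triu_indices(m, k=1)
    if config.min_distance_bp > 0:
        chroms = np.array([v.chrom for v in matrix.variants])
        pos = np.array([v.pos_bp for v in matrix.variants])
        near = (chroms[iu] == chroms[ju]) & (
            np.abs(pos[iu] - pos[ju]) < config.min_distance_bp
        )
        defined_u = defined[iu, ju] & ~near
    else:
        defined_u = defined[iu, ju]

    n_planned = n_pairs(m)
    n_skipped = int(n_planned - defined_u.sum())
    if n_skipped:
        logger.info("pairwise_scan: skipped %d undefined/excluded pairs", n_skipped)

    zi = zmat[iu, ju][defined_u]
    pz = 2.0 * norm.sf(np.abs(zi))
    ii, jj = iu[defined_u], ju[defined_u]
    snp_ids = [v.snp_id for v in matrix.variants]

    # complete-data sample counts per pair (each sample contributes mass 2)
    n_used_pair = ((total_ca[ii, jj] + total_co[ii, jj]) / 2.0).astype(int)

    order = sorted(
        range(len(zi)),
        key=lambda k: (pz[k], snp_ids[ii[k]], snp_ids[jj[k]]),
    )
    results: list[InteractionStat] = []
    for k in order:
        stat = InteractionStat(
            snp1_id=snp_ids[ii[k]], snp2_id=snp_ids[jj[k]],
            z=float(zi[k]), p_z=float(pz[k]), n_used=int(n_used_pair[k]),
        )
        if stat.p_z < config.p_screen:
            try:
                fit = dosage_logistic_interaction(
                    matrix.genotypes[:, ii[k]], matrix.genotypes[:, jj[k]],
                    matrix.phenotype, min_group_n=config.min_group_n,
                )
                stat.beta_int = fit.beta_int
                stat.p_dosage = fit.p_interaction
            except ValueError:
                pass
        results.append(stat)
    logger.info(
        "pairwise_scan: %d SNPs, %d tests planned, %d computed",
        m, n_planned, len(results),
    )
    return ScanResult(interactions=results, n_tests_planned=n_planned,
                      n_skipped=n_skipped)


def n_pairs(m: int) -> int:
    """Exact number of unordered pairs m(m-1)/2."""
    if m < 2:
        raise ValueError(f"need m >= 2, got {m}")
    return m * (m - 1) // 2


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
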