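"""Gene-set (pathway) association testing for case/control panels.

Two methods are provided:

* a permutation-based enrichment test on genotypes: per-SNP allelic
  chi-square statistics are collapsed to per-gene maxima (SNPs mapped to
  genes within a +/- flank window), genes are ranked, and each set's
  weighted Kolmogorov-Smirnov enrichment score is compared with its
  distribution under phenotype-label permutations (genotypes untouched,
  preserving LD) to yield NES, empirical P, FDR, and FWER; and
* a precomputed-P method: per-gene scores (-log10 P) are compared between
  set members and the genome-wide background with a z statistic and
  Benjamini-Hochberg FDR across sets.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .genotype_io import MISSING, FormatError, GenotypeMatrix
from .locus_mapping import GeneAnnotation

__all__ = [
    "GeneSet",
    "GeneStat",
    "PathwayResult",
    "GsaSnpResult",
    "UndefinedESError",
    "snp_assoc_chi2",
    "gene_level_stats",
    "enrichment_score",
    "gsea_permutation_test",
    "filter_gene_sets",
    "gsa_snp_pathway",
    "bh_fdr",
    "read_gmt",
    "write_gmt",
]

logger = logging.getLogger(__name__)


class UndefinedESError(ValueError):
    """Enrichment score requested for a set with no ranked member."""


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    member_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_genes:
            raise ValueError(f"{self.set_id}: empty gene set")
        if len(set(self.member_genes)) != len(self.member_genes):
            raise ValueError(f"{self.set_id}: duplicate member genes")


@dataclass(frozen=True)
class GeneStat:
    gene_id: str
    stat: float
    n_snps: int


@dataclass
class PathwayResult:
    set_id: str
    es: float
    nes: float
    empirical_p: float
    fdr: float
    fwer: float
    n_members: int = 0


@dataclass
class GsaSnpResult:
    set_id: str
    z: float
    p: float
    bh_fdr: float
    n_members: int = 0


# ---------------------------------------------------------------------------
# Per-SNP and per-gene statistics
# ---------------------------------------------------------------------------

def _chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins <= 0:
        return 0.0
    return float(n * (a * d - b * c) ** 2 / margins)


def snp_assoc_chi2(genotypes: np.ndarray, phenotype: np.ndarray) -> float:
    """1-df allelic chi-square from the 2x2 allele-count x phenotype table.

    Zero cells trigger a 0.5 continuity correction on every cell;
    monomorphic SNPs return 0.
    """
    g = np.asarray(genotypes, dtype=np.int64)
    ph = np.asarray(phenotype, dtype=np.int64)
    case = (ph == 1) & (g != MISSING)
    ctrl = (ph == 0) & (g != MISSING)
    if not case.any() or not ctrl.any():
        raise ValueError("both phenotype groups must be non-empty")
    a = float(g[case].sum())          # a1 alleles in cases
    b = 2.0 * case.sum() - a
    c = float(g[ctrl].sum())
    d = 2.0 * ctrl.sum() - c
    if (a + c) == 0 or (b + d) == 0:  # monomorphic
        return 0.0
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return _chi2_2x2(a, b, c, d)


def snp_trend_chi2(genotypes: np.ndarray, phenotype: np.ndarray) -> float:
    """Cochran-Armitage trend chi-square (1 df) with additive scores."""
    g = np.asarray(genotypes, dtype=np.float64)
    ph = np.asarray(phenotype, dtype=np.int64)
    ok = (g != MISSING) & (ph != MISSING)
    g, y = g[ok], (ph[ok] == 1).astype(float)
    n = g.size
    if y.sum() == 0 or y.sum() == n:
        raise ValueError("both phenotype groups must be non-empty")
    gbar, ybar = g.mean(), y.mean()
    sxx = ((g - gbar) ** 2).sum()
    syy = ((y - ybar) ** 2).sum()
    if sxx == 0 or syy == 0:
        return 0.0
    sxy = ((g - gbar) * (y - ybar)).sum()
    return float(n * sxy ** 2 / (sxx * syy))


def _allelic_chi2_many(A: np.ndarray, Mn: np.ndarray, case: np.ndarray,
                       ctrl: np.ndarray) -> np.ndarray:
    """Vectorized allelic chi-square for every SNP column.

    ``A``: a1 dosages with missing zeroed; ``Mn``: non-missing indicator;
    ``case``/``ctrl``: float sample-indicator vectors.
    """
    a = case @ A
    c = ctrl @ A
    b = 2.0 * (case @ Mn) - a
    d = 2.0 * (ctrl @ Mn) - c
    mono = ((a + c) == 0) | ((b + d) == 0)
    zero = np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0
    corr = np.where(zero, 0.5, 0.0)
    a, b, c, d = a + corr, b + corr, c + corr, d + corr
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / margins
    chi2[mono | (margins <= 0)] = 0.0
    return chi2


def gene_level_stats(matrix: GenotypeMatrix,
                     annotation: list[GeneAnnotation],
                     flank: int = 20000,
                     stat: str = "allelic") -> list[GeneStat]:
    """Per-gene statistic = max allelic chi-square over SNPs within the
    gene's interval widened by ``flank`` bp.  Genes with no SNP are
    omitted.  Output is sorted descending by stat, ties broken by gene id.
    """
    gene_snps = _gene_snp_indices(matrix, annotation, flank)
    chi2 = _snp_stats(matrix, matrix.phenotype, stat)
    out = []
    for gene_id, idx in gene_snps.items():
        out.append(GeneStat(gene_id, float(chi2[idx].max()), len(idx)))
    out.sort(key=lambda g: (-g.stat, g.gene_id))
    return out


def _snp_stats(matrix: GenotypeMatrix, phenotype: np.ndarray, stat: str) -> np.ndarray:
    G = matrix.genotypes.astype(np.float64)
    Mn = (matrix.genotypes != MISSING).astype(np.float64)
    A = np.where(matrix.genotypes == MISSING, 0.0, G)
    case = (phenotype == 1).astype(float)
    ctrl = (phenotype == 0).astype(float)
    if stat == "allelic":
        return _allelic_chi2_many(A, Mn, case, ctrl)
    if stat == "trend":
        return np.array([
            snp_trend_chi2(matrix.genotypes[:, j], phenotype)
            for j in range(matrix.n_variants)
        ])
    raise ValueError(f"unknown per-SNP statistic {stat!r}")


def _gene_snp_indices(matrix: GenotypeMatrix, annotation: list[GeneAnnotation],
                      flank: int) -> dict[str, np.ndarray]:
    chroms = np.array([v.chrom for v in matrix.variants])
    pos = np.array([v.pos_bp for v in matrix.variants], dtype=np.int64)
    out: dict[str, np.ndarray] = {}
    for ann in annotation:
        hit = np.flatnonzero(
            (chroms == ann.chrom)
            & (pos >= ann.start_bp - flank)
            & (pos <= ann.end_bp + flank)
        )
        if hit.size:
            out[ann.gene_id] = hit
    return out


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def enrichment_score(ranked_gene_stats: np.ndarray, member_flags: np.ndarray,
                     weight_p: float = 1.0) -> float:
    """Weighted KS enrichment score over a descending gene ranking.

    Hits increment the running sum by ``stat**weight_p`` normalized by the
    members' total; misses decrement by ``1/(N - N_members)``.  The ES is
    the running-sum value of largest magnitude (signed).
    """
    stats = np.asarray(ranked_gene_stats, dtype=float)
    flags = np.asarray(member_flags, dtype=bool)
    if stats.shape != flags.shape:
        raise ValueError("stats and member flags must align")
    n = stats.size
    n_hit = int(flags.sum())
    if n_hit == 0:
        raise UndefinedESError("no set member present in the ranking")
    w = np.abs(stats) ** weight_p
    total = w[flags].sum()
    steps = np.where(flags, (w / total if total > 0 else 1.0 / n_hit), 0.0)
    if total <= 0:  # all member weights zero: uniform hit increments
        steps = np.where(flags, 1.0 / n_hit, 0.0)
    if n > n_hit:
        steps = steps - np.where(flags, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def _es_per_set(stats_ranked: np.ndarray, flags_ranked: np.ndarray,
                weight_p: float = 1.0) -> np.ndarray:
    """Vectorized ES for several sets: ``flags_ranked`` is n_sets x n_genes."""
    n = stats_ranked.size
    w = np.abs(stats_ranked) ** weight_p
    hit_w = flags_ranked * w
    totals = hit_w.sum(axis=1, keepdims=True)
    n_hits = flags_ranked.sum(axis=1, keepdims=True)
    safe_tot = np.where(totals > 0, totals, 1.0)
    steps = np.where(totals > 0, hit_w / safe_tot,
                     flags_ranked / np.maximum(n_hits, 1))
    n_miss = n - n_hits
    miss_step = np.where(n_miss > 0, 1.0 / np.maximum(n_miss, 1), 0.0)
    steps = steps - (~flags_ranked.astype(bool)) * miss_step
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(running.shape[0]), idx]


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def gsea_permutation_test(matrix: GenotypeMatrix,
                          annotation: list[GeneAnnotation],
                          gene_sets: list[GeneSet],
                          n_perm: int = 1000,
                          seed: int | None = None,
                          flank: int = 20000,
                          weight_p: float = 1.0,
                          stat: str = "allelic") -> list[PathwayResult]:
    """Phenotype-permutation enrichment test over gene sets.

    Permutes case/control labels only (genotypes untouched, preserving
    LD).  Per set: NES = ES / mean positive permuted ES; empirical P =
    ``(1 + #{perm ES >= observed}) / (n_perm + 1)``; FDR = ratio of the
    pooled-permutation NES exceedance fraction to the observed NES
    exceedance fraction, capped at 1; FWER = fraction of permutation
    rounds whose maximum NES reaches the observed NES.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    rng = np.random.default_rng(seed)
    gene_snps = _gene_snp_indices(matrix, annotation, flank)
    gene_ids = sorted(gene_snps)  # lexicographic: deterministic tie order
    if not gene_ids:
        raise ValueError("no gene covered by any SNP")
    n_genes = len(gene_ids)
    flat = np.concatenate([gene_snps[g] for g in gene_ids])
    ptr = np.cumsum([0] + [gene_snps[g].size for g in gene_ids])[:-1]

    covered = set(gene_ids)
    sets_kept = [s for s in gene_sets
                 if any(g in covered for g in s.member_genes)]
    if not sets_kept:
        raise UndefinedESError("no gene set has a covered member")
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    S = np.zeros((len(sets_kept), n_genes), dtype=bool)
    for si, s in enumerate(sets_kept):
        for g in s.member_genes:
            if g in gene_pos:
                S[si, gene_pos[g]] = True

    G = matrix.genotypes
    Mn = (G != MISSING).astype(np.float64)
    A = np.where(G == MISSING, 0.0, G.astype(np.float64))
    labeled = matrix.phenotype != MISSING
    labels = matrix.phenotype[labeled]

    def round_es(phenotype: np.ndarray) -> np.ndarray:
        if stat == "allelic":
            case = (phenotype == 1).astype(float)
            ctrl = (phenotype == 0).astype(float)
            chi2 = _allelic_chi2_many(A, Mn, case, ctrl)
        else:
            chi2 = _snp_stats(matrix, phenotype, stat)
        gstats = np.maximum.reduceat(chi2[flat], ptr)
        order = np.argsort(-gstats, kind="stable")  # stable: gene-id tiebreak
        return _es_per_set(gstats[order], S[:, order], weight_p)

    es_obs = round_es(matrix.phenotype)

    es_perm = np.empty((n_perm, len(sets_kept)))
    perm_pheno = matrix.phenotype.copy()
    for r in range(n_perm):
        perm_pheno[labeled] = rng.permutation(labels)
        es_perm[r] = round_es(perm_pheno)

    pos = es_perm > 0
    mean_pos = np.where(pos.sum(axis=0) > 0,
                        np.sum(es_perm * pos, axis=0) / np.maximum(pos.sum(axis=0), 1),
                        np.nan)
    with np.errstate(invalid="ignore"):
        nes_obs = np.where(np.isfinite(mean_pos) & (mean_pos > 0),
                           es_obs / mean_pos, 0.0)
        nes_perm = np.where(np.isfinite(mean_pos) & (mean_pos > 0),
                            es_perm / mean_pos, 0.0)

    emp_p = (1.0 + (es_perm >= es_obs).sum(axis=0)) / (n_perm + 1.0)

    pool = nes_perm.ravel()
    n_pool = pool.size
    max_per_round = nes_perm.max(axis=1)
    results = []
    for si, s in enumerate(sets_kept):
        nes_star = nes_obs[si]
        frac_perm = (pool >= nes_star).sum() / n_pool
        frac_obs = (nes_obs >= nes_star).sum() / nes_obs.size
        fdr = min(1.0, frac_perm / frac_obs) if frac_obs > 0 else 1.0
        fwer = float((max_per_round >= nes_star).mean())
        results.append(PathwayResult(
            set_id=s.set_id, es=float(es_obs[si]), nes=float(nes_star),
            empirical_p=float(emp_p[si]), fdr=float(fdr), fwer=fwer,
            n_members=int(S[si].sum()),
        ))
    results.sort(key=lambda r: (-r.nes, r.set_id))
    return results


# ---------------------------------------------------------------------------
# Set filtering and precomputed-P method
# ---------------------------------------------------------------------------

def filter_gene_sets(gene_sets: list[GeneSet], covered_genes,
                     min_size: int = 5, max_size: int = 200) -> list[GeneSet]:
    """Intersect memberships with the covered-gene universe and drop sets
    outside [min_size, max_size] after intersection."""
    covered = set(covered_genes)
    out = []
    for s in gene_sets:
        members = tuple(g for g in s.member_genes if g in covered)
        if min_size <= len(members) <= max_size:
            out.append(GeneSet(s.set_id, s.description, members))
    return out


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted P-values (monotonized)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def gsa_snp_pathway(gene_pvalues: dict[str, float],
                    gene_sets: list[GeneSet]) -> list[GsaSnpResult]:
    """Z test of mean member gene score against the genome-wide background.

    Gene score = -log10(P).  Per set:
    ``z = (mean_member - mean_all) / (sd_all / sqrt(set_size))`` with a
    two-sided normal P, then BH-FDR across sets.  Sets with no scored
    gene are omitted with a warning.
    """
    genes = sorted(gene_pvalues)
    scores = np.array([-np.log10(gene_pvalues[g]) for g in genes])
    if not np.isfinite(scores).all():
        raise ValueError("gene P-values must be in (0, 1]")
    mean_all = scores.mean()
    sd_all = scores.std(ddof=1)
    if sd_all == 0:
        sd_all = np.inf  # all scores equal -> z = 0 everywhere
    lookup = dict(zip(genes, scores))
    rows = []
    for s in gene_sets:
        member_scores = [lookup[g] for g in s.member_genes if g in lookup]
        if not member_scores:
            logger.warning("gsa_snp_pathway: set %s has no scored gene; omitted",
                           s.set_id)
            continue
        k = len(member_scores)
        z = (float(np.mean(member_scores)) - mean_all) / (sd_all / np.sqrt(k))
        p = 2.0 * float(norm.sf(abs(z)))
        rows.append((s.set_id, z, p, k))
    if not rows:
        return []
    fdrs = bh_fdr(np.array([r[2] for r in rows]))
    out = [GsaSnpResult(set_id=r[0], z=r[1], p=r[2], bh_fdr=float(f), n_members=r[3])
           for r, f in zip(rows, fdrs)]
    out.sort(key=lambda r: (r.p, r.set_id))
    return out


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[GeneSet]:
    """Read a tab-separated gene-set file (set id, description, genes...).

    Duplicate genes within a set are deduplicated; empty sets are rejected.
    """
    out: list[GeneSet] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{ln}: GMT lines need set id, description, and "
                    "at least one gene"
                )
            genes = tuple(dict.fromkeys(g for g in parts[2:] if g))
            if not genes:
                raise FormatError(f"{path}:{ln}: gene set {parts[0]!r} is empty")
            out.append(GeneSet(parts[0], parts[1], genes))
    return out


def write_gmt(gene_sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in gene_sets:
            fh.write("\t".join([s.set_id, s.description, *s.member_genes]) + "\n")
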