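"""Synthetic case/control cohort generators.

Every generator is bit-reproducible from its spec and seed.  The
case/control ascertainment design mirrors the analysis model: disease
status is drawn from a logistic penetrance on allele dosages, and
individuals are rejection-sampled until the case and control quotas are
filled.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, VariantRecord
from .locus_mapping import GeneAnnotation
from .pathway import GeneSet

__all__ = [
    "CohortSpec",
    "EpistasisSpec",
    "LDBlockSpec",
    "PathwaySignalSpec",
    "simulate_null_cohort",
    "simulate_epistatic_cohort",
    "simulate_ld_block",
    "simulate_pathway_cohort",
]

_MAX_DRAWS = 10 ** 7


@dataclass(frozen=True)
class CohortSpec:
    """Cohort dimensions; defaults mirror a 493-case / 537-control design."""

    n_cases: int = 493
    n_controls: int = 537
    m_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0.01 <= low <= high <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class EpistasisSpec:
    """Planted logistic interaction between two panel SNPs (logit scale)."""

    snp1_index: int
    snp2_index: int
    b0: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    b3: float = 0.0

    def __post_init__(self) -> None:
        if self.snp1_index == self.snp2_index:
            raise ValueError("focal SNP indices must be distinct")


@dataclass(frozen=True)
class LDBlockSpec:
    """Haplotype-frequency model for a 2-4 SNP block.

    ``case_shift`` is added to ``shift_haplotype``'s case-stratum
    frequency, with the other haplotypes renormalized proportionally.
    """

    haplotype_freqs: dict[str, float] = field(
        default_factory=lambda: {"AC": 0.6, "GT": 0.4})
    case_shift: float = 0.0
    shift_haplotype: str | None = None

    def __post_init__(self) -> None:
        freqs = self.haplotype_freqs
        if not freqs:
            raise ValueError("need at least one haplotype")
        lengths = {len(h) for h in freqs}
        if len(lengths) != 1:
            raise ValueError("haplotype strings must have equal length")
        k = lengths.pop()
        if not 2 <= k <= 4:
            raise ValueError("block width must be 2-4 SNPs")
        if abs(sum(freqs.values()) - 1.0) > 1e-9 or min(freqs.values()) < 0:
            raise ValueError("haplotype frequencies must form a distribution")
        if self.case_shift != 0.0:
            target = self.shift_haplotype or next(iter(sorted(freqs)))
            if target not in freqs:
                raise ValueError(f"shift haplotype {target!r} not in distribution")
            if freqs[target] + self.case_shift < 0 or freqs[target] + self.case_shift > 1:
                raise ValueError("case_shift produces an invalid frequency")

    @property
    def n_snps_in_block(self) -> int:
        return len(next(iter(self.haplotype_freqs)))


@dataclass(frozen=True)
class PathwaySignalSpec:
    """Marginal-effect signal planted in one gene set's SNPs."""

    n_genes: int = 200
    snps_per_gene: tuple[int, int] = (2, 4)
    enriched_set_id: str = "planted"
    enriched_set_size: int = 19
    n_random_sets: int = 19
    effect_logit: float = 0.0

    def __post_init__(self) -> None:
        if not 5 <= self.enriched_set_size <= 200:
            raise ValueError("enriched set size must be within [5, 200]")
        if self.enriched_set_size > self.n_genes:
            raise ValueError("enriched set larger than the gene panel")


def _variant_panel(mafs: np.ndarray, chrom: str = "1",
                   spacing: int = 10_000,
                   positions: np.ndarray | None = None) -> list[VariantRecord]:
    m = mafs.size
    if positions is None:
        positions = spacing * (1 + np.arange(m))
    return [
        VariantRecord(f"snp{j + 1:05d}", chrom, int(positions[j]), "A", "G",
                      float(min(mafs[j], 1 - mafs[j])))
        for j in range(m)
    ]


def _apply_missingness(G: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    if rate > 0:
        G[rng.random(G.shape) < rate] = MISSING


def _finalize(variants, genotypes, phenotype, prefix="S") -> GenotypeMatrix:
    samples = [f"{prefix}{i + 1:05d}" for i in range(genotypes.shape[0])]
    return GenotypeMatrix(variants, samples, genotypes, phenotype)


def simulate_null_cohort(spec: CohortSpec) -> GenotypeMatrix:
    """Cohort with genotypes independent of phenotype.

    Per-SNP MAF uniform in ``maf_range``; genotypes Binomial(2, maf); the
    first ``n_cases`` samples are cases.
    """
    rng = np.random.default_rng(spec.seed)
    mafs = rng.uniform(*spec.maf_range, size=spec.m_snps)
    n = spec.n_cases + spec.n_controls
    G = rng.binomial(2, mafs, size=(n, spec.m_snps)).astype(np.int8)
    _apply_missingness(G, spec.missing_rate, rng)
    phenotype = np.zeros(n, dtype=np.int8)
    phenotype[: spec.n_cases] = 1
    return _finalize(_variant_panel(mafs), G, phenotype)


def _ascertain(draw_genotypes, penetrance, spec: CohortSpec,
               rng: np.random.Generator,
               chunk: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample genotype rows until case/control quotas are met."""
    cases, controls = [], []
    drawn = 0
    while len(cases) < spec.n_cases or len(controls) < spec.n_controls:
        if drawn >= _MAX_DRAWS:
            raise RuntimeError(
                f"ascertainment failed to fill quotas within {_MAX_DRAWS} draws"
            )
        G = draw_genotypes(chunk, rng)
        p = penetrance(G)
        y = rng.random(chunk) < p
        drawn += chunk
        for row, is_case in zip(G, y):
            if is_case and len(cases) < spec.n_cases:
                cases.append(row)
            elif not is_case and len(controls) < spec.n_controls:
                controls.append(row)
    G = np.vstack([np.array(cases), np.array(controls)]).astype(np.int8)
    phenotype = np.zeros(spec.n_cases + spec.n_controls, dtype=np.int8)
    phenotype[: spec.n_cases] = 1
    return G, phenotype


def simulate_epistatic_cohort(spec: CohortSpec,
                              effect: EpistasisSpec) -> GenotypeMatrix:
    """Cohort with a planted pairwise interaction.

    Case probability is ``expit(b0 + b1*g1 + b2*g2 + b3*g1*g2)`` on the two
    focal SNPs; background SNPs are independent of phenotype.
    """
    if not (0 <= effect.snp1_index < spec.m_snps
            and 0 <= effect.snp2_index < spec.m_snps):
        raise ValueError("focal SNP indices outside the panel")
    rng = np.random.default_rng(spec.seed)
    mafs = rng.uniform(*spec.maf_range, size=spec.m_snps)

    def draw(k, r):
        return r.binomial(2, mafs, size=(k, spec.m_snps))

    def penetrance(G):
        g1 = G[:, effect.snp1_index].astype(float)
        g2 = G[:, effect.snp2_index].astype(float)
        eta = effect.b0 + effect.b1 * g1 + effect.b2 * g2 + effect.b3 * g1 * g2
        return 1.0 / (1.0 + np.exp(-eta))

    G, phenotype = _ascertain(draw, penetrance, spec, rng)
    _apply_missingness(G, spec.missing_rate, rng)
    return _finalize(_variant_panel(mafs), G, phenotype)


def simulate_ld_block(spec: LDBlockSpec, n_cases: int, n_controls: int,
                      seed: int = 0) -> GenotypeMatrix:
    """Cohort of one LD block: two haplotypes per individual drawn from the
    stratum-specific haplotype distribution; genotypes are unphased sums."""
    rng = np.random.default_rng(seed)
    haps = sorted(spec.haplotype_freqs)
    base = np.array([spec.haplotype_freqs[h] for h in haps])
    case_freqs = base.copy()
    if spec.case_shift != 0.0:
        target = spec.shift_haplotype or haps[0]
        ti = haps.index(target)
        shifted = base[ti] + spec.case_shift
        rest = 1.0 - base[ti]
        case_freqs = base * ((1.0 - shifted) / rest if rest > 0 else 0.0)
        case_freqs[ti] = shifted
    k = spec.n_snps_in_block

    # per-SNP allele labels: a1 = rarer character under the base distribution
    alleles = []
    for i in range(k):
        chars = sorted({h[i] for h in haps})
        if len(chars) > 2:
            raise ValueError(f"more than two alleles at block position {i}")
        if len(chars) == 1:
            alleles.append((("N" if chars[0] != "N" else "M"), chars[0]))
            continue
        f0 = sum(spec.haplotype_freqs[h] for h in haps if h[i] == chars[0])
        a1, a2 = (chars[0], chars[1]) if f0 <= 0.5 else (chars[1], chars[0])
        alleles.append((a1, a2))
    hap_dosage = np.array(
        [[1 if h[i] == alleles[i][0] else 0 for i in range(k)] for h in haps]
    )

    def draw_stratum(n, freqs):
        pick = rng.choice(len(haps), size=(n, 2), p=freqs)
        return (hap_dosage[pick[:, 0]] + hap_dosage[pick[:, 1]]).astype(np.int8)

    G = np.vstack([draw_stratum(n_cases, case_freqs),
                   draw_stratum(n_controls, base)])
    phenotype = np.zeros(n_cases + n_controls, dtype=np.int8)
    phenotype[:n_cases] = 1
    variants = []
    for i in range(k):
        col = G[:, i]
        maf = float(col.sum()) / (2 * col.size)
        variants.append(VariantRecord(f"blk{i + 1:02d}", "1", 1000 * (i + 1),
                                      alleles[i][0], alleles[i][1],
                                      min(maf, 1 - maf)))
    return _finalize(variants, G, phenotype)


def simulate_pathway_cohort(
    spec: PathwaySignalSpec, cohort: CohortSpec
) -> tuple[GenotypeMatrix, list[GeneAnnotation], list[GeneSet]]:
    """Cohort plus annotation and gene sets with one signal-bearing set.

    Genes are tiled on a synthetic chromosome with non-overlapping bodies;
    each gene carries ``snps_per_gene`` SNPs inside its body.  SNPs of the
    enriched set's member genes add ``effect_logit`` per a1 allele to the
    disease logit.  Gene sets are the enriched set plus size-matched random
    sets.
    """
    rng = np.random.default_rng(cohort.seed)
    gene_span, gene_body = 50_000, 30_000
    lo, hi = spec.snps_per_gene
    snp_counts = rng.integers(lo, hi + 1, size=spec.n_genes)
    gene_ids = [f"G{j + 1:04d}" for j in range(spec.n_genes)]
    annotation, positions = [], []
    for j in range(spec.n_genes):
        start = j * gene_span + 1
        end = start + gene_body - 1
        annotation.append(GeneAnnotation(gene_ids[j], "1", start, end))
        offs = np.sort(rng.choice(gene_body - 2, size=snp_counts[j], replace=False))
        positions.extend(start + 1 + offs)
    positions = np.array(positions, dtype=np.int64)
    m = positions.size
    mafs = rng.uniform(*cohort.maf_range, size=m)
    variants = _variant_panel(mafs, chrom="1", positions=positions)

    member_idx = rng.choice(spec.n_genes, size=spec.enriched_set_size, replace=False)
    member_set = {gene_ids[j] for j in member_idx}
    snp_gene = np.repeat(np.arange(spec.n_genes), snp_counts)
    signal_snps = np.flatnonzero(
        np.isin(snp_gene, member_idx) & (spec.effect_logit != 0.0))
    beta = np.zeros(m)
    beta[signal_snps] = spec.effect_logit
    # keep overall prevalence near 1/2 under the planted effects
    b0 = -float(beta @ (2 * mafs))

    def draw(kk, r):
        return r.binomial(2, mafs, size=(kk, m))

    def penetrance(G):
        eta = b0 + G.astype(float) @ beta
        return 1.0 / (1.0 + np.exp(-eta))

    local = CohortSpec(cohort.n_cases, cohort.n_controls, m,
                       cohort.maf_range, cohort.missing_rate, cohort.seed)
    G, phenotype = _ascertain(draw, penetrance, local, rng)
    _apply_missingness(G, cohort.missing_rate, rng)
    matrix = _finalize(variants, G, phenotype)

    gene_sets = [GeneSet(spec.enriched_set_id, "planted signal set",
                         tuple(sorted(member_set)))]
    for r in range(spec.n_random_sets):
        members = rng.choice(spec.n_genes, size=spec.enriched_set_size,
                             replace=False)
        gene_sets.append(GeneSet(f"random{r + 1:03d}", "size-matched random set",
                                 tuple(sorted(gene_ids[j] for j in members))))
    return matrix, annotation, gene_sets
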