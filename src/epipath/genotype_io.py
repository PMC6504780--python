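"""Genotype I/O, variant metadata, and quality-control filtering.

Supports PLINK 1.x text (ped/map) and binary (bed/bim/fam) formats.
Genotypes are stored as an ``n_samples x n_variants`` int8 matrix of
minor-allele (a1) dosages in {0, 1, 2}; missing genotypes are coded
:data:`MISSING` (-1).  The minor allele is determined empirically from
the data at read time; a tie (allele frequency exactly 0.5) keeps the
file's a1 designation where the format provides one, otherwise the
lexicographically smaller allele label.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MISSING",
    "VariantRecord",
    "GenotypeMatrix",
    "QCThresholds",
    "FormatError",
    "UndefinedMAFError",
    "read_plink_text",
    "write_plink_text",
    "read_plink_binary",
    "write_plink_binary",
    "compute_maf",
    "hwe_exact_p",
    "qc_filter",
    "normalize_minor_alleles",
]

logger = logging.getLogger(__name__)

MISSING: int = -1

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = 0x01
# 2-bit code (LSB-first within each byte) -> a1 dosage
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class FormatError(ValueError):
    """Malformed genotype/annotation file."""


class UndefinedMAFError(ValueError):
    """MAF requested for an all-missing genotype column."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant; ``allele_a1`` is the (empirical) minor allele."""

    snp_id: str
    chrom: str
    pos_bp: int
    allele_a1: str
    allele_a2: str
    maf: float

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"{self.snp_id}: pos_bp must be >= 1")
        if self.allele_a1 == self.allele_a2:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf {self.maf} outside [0, 0.5]")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with a binary phenotype.

    ``phenotype`` uses 1 for cases, 0 for controls, -1 for missing.
    """

    variants: list[VariantRecord]
    samples: list[str]
    genotypes: np.ndarray
    phenotype: np.ndarray
    _snp_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        n, m = self.genotypes.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError("genotype matrix shape does not match metadata")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, missing}")
        self._snp_index = {v.snp_id: j for j, v in enumerate(self.variants)}

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._snp_index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not present in matrix") from None

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotype == 1

    @property
    def control_mask(self) -> np.ndarray:
        return self.phenotype == 0

    def subset_variants(self, indices: np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(
            variants=[self.variants[j] for j in indices],
            samples=list(self.samples),
            genotypes=self.genotypes[:, indices].copy(),
            phenotype=self.phenotype.copy(),
        )


@dataclass(frozen=True)
class QCThresholds:
    """Per-SNP filter thresholds: drop if MAF < ``maf_min``, HWE exact
    P < ``hwe_p_min``, or missing fraction > ``max_missing_per_snp``."""

    maf_min: float = 0.05
    hwe_p_min: float = 0.001
    max_missing_per_snp: float = 0.05

    def __post_init__(self) -> None:
        for name in ("maf_min", "hwe_p_min", "max_missing_per_snp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# MAF / HWE
# ---------------------------------------------------------------------------

def compute_maf(genotype_column: np.ndarray) -> float:
    """Minor allele frequency min(f, 1-f) over non-missing genotypes."""
    col = np.asarray(genotype_column)
    col = col[col != MISSING]
    if col.size == 0:
        raise UndefinedMAFError("all genotypes missing")
    f = float(col.sum()) / (2.0 * col.size)
    return min(f, 1.0 - f)


def _hwe_het_distribution(n_rare: int, n_genotypes: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of heterozygote counts given the rare-allele
    count ``n_rare`` among ``n_genotypes`` diploid samples.

    Returns (het_counts, probabilities); probabilities sum to 1.
    """
    if n_genotypes < 1:
        raise ValueError("need at least one genotype")
    # het count shares the parity of the rare allele count
    h_min = n_rare % 2
    h_max = min(n_rare, 2 * n_genotypes - n_rare)
    hets = np.arange(h_min, h_max + 1, 2)
    # unnormalized log-probabilities via the hypergeometric-style closed form
    from scipy.special import gammaln

    n_common = 2 * n_genotypes - n_rare
    logp = (
        gammaln(n_genotypes + 1)
        - gammaln((n_rare - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((n_common - hets) / 2 + 1)
        + hets * np.log(2.0)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return hets, p


def hwe_exact_p(genotype_column: np.ndarray) -> float:
    """Exact two-sided Hardy-Weinberg P-value.

    Sums the probabilities of all heterozygote counts whose conditional
    probability (given the allele counts) does not exceed that of the
    observed count.
    """
    col = np.asarray(genotype_column)
    col = col[col != MISSING]
    if col.size == 0:
        raise UndefinedMAFError("all genotypes missing")
    n_het = int((col == 1).sum())
    n_hom_a1 = int((col == 2).sum())
    n_hom_a2 = int((col == 0).sum())
    n = n_het + n_hom_a1 + n_hom_a2
    n_rare = min(2 * n_hom_a1 + n_het, 2 * n_hom_a2 + n_het)
    if n_rare == 0:
        return 1.0
    hets, probs = _hwe_het_distribution(n_rare, n)
    p_obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(matrix: GenotypeMatrix, thresholds: QCThresholds,
              hwe_stratum: str = "all") -> GenotypeMatrix:
    """Drop SNPs failing MAF, HWE, or missingness thresholds.

    ``hwe_stratum`` selects the samples the HWE test runs on: ``"all"``
    (default) or ``"controls"``.  Survivor order is preserved.  Per-filter
    drop counts are logged at INFO.
    """
    if hwe_stratum not in ("all", "controls"):
        raise ValueError(f"hwe_stratum must be 'all' or 'controls', got {hwe_stratum!r}")
    hwe_rows = (np.ones(matrix.n_samples, dtype=bool) if hwe_stratum == "all"
                else matrix.control_mask)
    logger.info("qc_filter: HWE computed on %s samples", hwe_stratum)
    n_drop_maf = n_drop_hwe = n_drop_miss = 0
    keep: list[int] = []
    for j in range(matrix.n_variants):
        col = matrix.genotypes[:, j]
        miss_frac = float((col == MISSING).mean())
        if miss_frac >= 1.0:
            n_drop_miss += 1
            continue
        if miss_frac > thresholds.max_missing_per_snp:
            n_drop_miss += 1
            continue
        if compute_maf(col) < thresholds.maf_min:
            n_drop_maf += 1
            continue
        if thresholds.hwe_p_min > 0:
            hwe_col = col[hwe_rows]
            if (hwe_col != MISSING).any() and hwe_exact_p(hwe_col) < thresholds.hwe_p_min:
                n_drop_hwe += 1
                continue
        keep.append(j)
    logger.info(
        "qc_filter: kept %d/%d SNPs (dropped %d MAF, %d HWE, %d missingness)",
        len(keep), matrix.n_variants, n_drop_maf, n_drop_hwe, n_drop_miss,
    )
    if not keep:
        logger.warning("qc_filter removed every SNP")
    return matrix.subset_variants(np.array(keep, dtype=int))


# ---------------------------------------------------------------------------
# Allele coding helpers
# ---------------------------------------------------------------------------

def _code_from_allele_counts(raw_alleles: list[tuple[str, str]],
                             a1_hint: str | None = None) -> tuple[str, str, np.ndarray]:
    """Determine (a1, a2) and dosage codes from per-sample allele pairs.

    ``"0"`` marks a missing allele. ``a1_hint`` (e.g. the bim a1 column) wins
    ties at frequency exactly 0.5.
    """
    counts: dict[str, int] = {}
    for x, y in raw_alleles:
        for a in (x, y):
            if a != "0":
                counts[a] = counts.get(a, 0) + 1
    alleles = sorted(counts)  # lexicographic fallback for ties
    if len(alleles) > 2:
        raise FormatError(f"more than two alleles observed: {alleles}")
    if not alleles:
        a1, a2 = (a1_hint or "A"), "0"
        codes = np.full(len(raw_alleles), MISSING, dtype=np.int8)
        return a1, a2, codes
    if len(alleles) == 1:
        # monomorphic: the observed allele has frequency 1 -> it is a2
        a2 = alleles[0]
        a1 = a1_hint if (a1_hint and a1_hint != a2) else ("N" if a2 != "N" else "M")
        codes = np.array(
            [MISSING if x == "0" else 0 for x, _ in raw_alleles], dtype=np.int8
        )
        return a1, a2, codes
    c0, c1 = counts[alleles[0]], counts[alleles[1]]
    if c0 < c1:
        a1, a2 = alleles[0], alleles[1]
    elif c1 < c0:
        a1, a2 = alleles[1], alleles[0]
    else:  # exact tie
        if a1_hint in alleles:
            a1 = a1_hint
            a2 = alleles[0] if a1 == alleles[1] else alleles[1]
        else:
            a1, a2 = alleles[0], alleles[1]
    codes = np.empty(len(raw_alleles), dtype=np.int8)
    for i, (x, y) in enumerate(raw_alleles):
        if x == "0" or y == "0":
            codes[i] = MISSING
        else:
            codes[i] = (x == a1) + (y == a1)
    return a1, a2, codes


def _parse_phenotype(token: str) -> int:
    if token == "2":
        return 1
    if token == "1":
        return 0
    return MISSING


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read a whitespace-delimited PLINK ped/map pair.

    Genotypes are coded as counts of the empirical minor allele; ``0 0``
    allele pairs become missing. Phenotype is ped column 6 (2=case,
    1=control, anything else missing).
    """
    map_rows: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    m = len(map_rows)

    samples: list[str] = []
    phenos: list[int] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields for {m} SNPs, "
                    f"got {len(parts)}"
                )
            samples.append(parts[1])
            phenos.append(_parse_phenotype(parts[5]))
            allele_rows.append(parts[6:])

    n = len(samples)
    genotypes = np.empty((n, m), dtype=np.int8)
    variants: list[VariantRecord] = []
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        pairs = [(row[2 * j], row[2 * j + 1]) for row in allele_rows]
        a1, a2, codes = _code_from_allele_counts(pairs)
        genotypes[:, j] = codes
        nonmiss = codes[codes != MISSING]
        maf = float(nonmiss.sum()) / (2 * nonmiss.size) if nonmiss.size else 0.0
        variants.append(VariantRecord(snp_id, chrom, pos, a1, a2, min(maf, 1 - maf)))
    return GenotypeMatrix(variants, samples, genotypes, np.array(phenos, dtype=np.int8))


def write_plink_text(matrix: GenotypeMatrix, ped_path, map_path) -> None:
    with open(map_path, "w") as fh:
        for v in matrix.variants:
            fh.write(f"{v.chrom}\t{v.snp_id}\t0\t{v.pos_bp}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(matrix.samples):
            ph = {1: "2", 0: "1"}.get(int(matrix.phenotype[i]), "0")
            fields = [f"F{i}", sid, "0", "0", "0", ph]
            for j, v in enumerate(matrix.variants):
                g = int(matrix.genotypes[i, j])
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 2:
                    fields += [v.allele_a1, v.allele_a1]
                elif g == 1:
                    fields += [v.allele_a1, v.allele_a2]
                else:
                    fields += [v.allele_a2, v.allele_a2]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK binary
# ---------------------------------------------------------------------------

def read_plink_binary(bed_path, bim_path, fam_path) -> GenotypeMatrix:
    """Read a PLINK 1.x SNP-major bed/bim/fam trio."""
    variants_raw: list[tuple[str, str, int, str, str]] = []
    with open(bim_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise FormatError(f"{bim_path}:{ln}: expected 6 columns")
            chrom, snp_id, _cm, pos, a1, a2 = parts
            variants_raw.append((chrom, snp_id, int(pos), a1, a2))
    samples: list[str] = []
    phenos: list[int] = []
    with open(fam_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise FormatError(f"{fam_path}:{ln}: expected 6 columns")
            samples.append(parts[1])
            phenos.append(_parse_phenotype(parts[5]))

    n, m = len(samples), len(variants_raw)
    with open(bed_path, "rb") as fh:
        header = fh.read(3)
        if len(header) < 3 or header[:2] != _BED_MAGIC:
            raise FormatError(f"{bed_path}: not a PLINK bed file (bad magic bytes)")
        if header[2] != _BED_SNP_MAJOR:
            raise FormatError(
                f"{bed_path}: unsupported mode byte 0x{header[2]:02x} "
                "(only SNP-major 0x01 is supported)"
            )
        payload = np.frombuffer(fh.read(), dtype=np.uint8)
    bps = (n + 3) // 4
    if payload.size != m * bps:
        raise FormatError(
            f"{bed_path}: payload of {payload.size} bytes does not match "
            f"{m} SNPs x {bps} bytes"
        )
    data = payload.reshape(m, bps)
    # expand 2-bit fields, LSB first
    codes2 = np.empty((m, bps * 4), dtype=np.uint8)
    for k in range(4):
        codes2[:, k::4] = (data >> (2 * k)) & 0b11
    raw = _BED_DECODE[codes2[:, :n]].T  # n x m, a1 dosage per bim designation

    genotypes = np.empty((n, m), dtype=np.int8)
    variants: list[VariantRecord] = []
    for j, (chrom, snp_id, pos, a1, a2) in enumerate(variants_raw):
        col = raw[:, j].copy()
        nonmiss = col[col != MISSING]
        f = float(nonmiss.sum()) / (2 * nonmiss.size) if nonmiss.size else 0.0
        if f > 0.5:  # bim a1 is actually the major allele here: flip
            a1, a2 = a2, a1
            col[col != MISSING] = 2 - col[col != MISSING]
            f = 1.0 - f
        genotypes[:, j] = col
        variants.append(VariantRecord(snp_id, chrom, pos, a1, a2, f))
    return GenotypeMatrix(variants, samples, genotypes, np.array(phenos, dtype=np.int8))


def write_plink_binary(matrix: GenotypeMatrix, bed_path, bim_path, fam_path) -> None:
    with open(bim_path, "w") as fh:
        for v in matrix.variants:
            fh.write(f"{v.chrom}\t{v.snp_id}\t0\t{v.pos_bp}\t{v.allele_a1}\t{v.allele_a2}\n")
    with open(fam_path, "w") as fh:
        for i, sid in enumerate(matrix.samples):
            ph = {1: "2", 0: "1"}.get(int(matrix.phenotype[i]), "0")
            fh.write(f"F{i} {sid} 0 0 0 {ph}\n")
    n, m = matrix.n_samples, matrix.n_variants
    bps = (n + 3) // 4
    out = np.zeros((m, bps), dtype=np.uint8)
    enc = np.zeros((m, bps * 4), dtype=np.uint8)
    G = matrix.genotypes.T  # m x n
    for code, bits in _BED_ENCODE.items():
        enc[:, :n][G == code] = bits
    for k in range(4):
        out |= enc[:, k::4] << (2 * k)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
        fh.write(out.tobytes())


def normalize_minor_alleles(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Flip coding at any SNP whose designated a1 is not the empirical minor
    allele, so that text/binary round trips are exact."""
    G = matrix.genotypes.copy()
    variants = []
    for j, v in enumerate(matrix.variants):
        col = G[:, j]
        nonmiss = col != MISSING
        if not nonmiss.any():
            variants.append(v)
            continue
        f = float(col[nonmiss].sum()) / (2 * int(nonmiss.sum()))
        if f > 0.5 or (f == 0.5 and v.allele_a2 < v.allele_a1):
            col[nonmiss] = 2 - col[nonmiss]
            variants.append(replace(v, allele_a1=v.allele_a2, allele_a2=v.allele_a1,
                                    maf=min(f, 1 - f)))
        else:
            variants.append(replace(v, maf=f))
    return GenotypeMatrix(variants, list(matrix.samples), G, matrix.phenotype.copy())
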