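"""Map interaction SNPs to genes/regions and isolate supported
locus-locus interaction clusters.

A "locus" is any annotated interval: a named gene or a cytoband-style
region supplied as an ordinary annotation record, so intergenic clusters
can be retained when a region annotation covers them.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .epistasis import InteractionStat
from .genotype_io import FormatError, VariantRecord

__all__ = [
    "GeneAnnotation",
    "LocusPair",
    "read_bed4",
    "map_snp_to_loci",
    "apply_exclusion_criteria",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """Annotated interval, 1-based inclusive coordinates after BED conversion.

    ``flank_bp`` widens the interval on both sides when mapping (0 for
    strict containment; 20000 for pathway-style mapping).
    """

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    flank_bp: int = 0

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.gene_id}: start_bp > end_bp")
        if self.flank_bp < 0:
            raise ValueError(f"{self.gene_id}: flank_bp must be >= 0")

    def contains(self, chrom: str, pos_bp: int) -> bool:
        return (
            chrom == self.chrom
            and self.start_bp - self.flank_bp <= pos_bp <= self.end_bp + self.flank_bp
        )


@dataclass
class LocusPair:
    """A locus-locus interaction cluster with its supporting SNP pairs."""

    locus1_id: str
    locus2_id: str
    supporting_interactions: list[InteractionStat]
    distinct_snps1: int
    distinct_snps2: int
    best_p: float


def read_bed4(path, flank_bp: int = 0) -> list[GeneAnnotation]:
    """Read BED4 (chrom, start, end, id; 0-based half-open) annotation,
    converting to 1-based inclusive coordinates."""
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: BED4 needs 4 columns")
            chrom, start, end, gene_id = parts[0], int(parts[1]), int(parts[2]), parts[3]
            out.append(GeneAnnotation(gene_id, chrom, start + 1, end, flank_bp))
    out.sort(key=lambda a: (a.chrom, a.start_bp))
    return out


def map_snp_to_loci(snp: VariantRecord,
                    annotation: list[GeneAnnotation]) -> list[str]:
    """All locus ids whose flanked interval contains the SNP position."""
    return [a.gene_id for a in annotation if a.contains(snp.chrom, snp.pos_bp)]


def apply_exclusion_criteria(
    interactions: list[InteractionStat],
    variants: dict[str, VariantRecord],
    annotation: list[GeneAnnotation],
    min_support: int = 2,
) -> list[LocusPair]:
    """Reduce screened SNP-SNP interactions to supported locus pairs.

    Interactions where either SNP maps to no locus are dropped.  Survivors
    are grouped by unordered locus pair; pairs with fewer than
    ``min_support`` interactions, or with fewer than 2 distinct SNPs on
    either side, are dropped.  Output is sorted by best (smallest) screen P.

    Within each retained pair, locus1 is the side the supporting
    interactions' SNP1 mapped to (majority orientation; lexicographic
    order breaks an even split).
    """
    # groups[frozenset]: list of (interaction, locus_of_snp1, locus_of_snp2)
    groups: dict[frozenset, list[tuple[InteractionStat, str, str]]] = defaultdict(list)
    for it in interactions:
        v1 = variants.get(it.snp1_id)
        v2 = variants.get(it.snp2_id)
        if v1 is None or v2 is None:
            raise KeyError(f"no variant record for {it.snp1_id}/{it.snp2_id}")
        loci1 = map_snp_to_loci(v1, annotation)
        loci2 = map_snp_to_loci(v2, annotation)
        if not loci1 or not loci2:  # criterion: both SNPs must be in loci
            continue
        for l1 in loci1:
            for l2 in loci2:
                if l1 == l2:
                    continue
                groups[frozenset((l1, l2))].append((it, l1, l2))

    pairs: list[LocusPair] = []
    for key, members in groups.items():
        if len(members) < min_support:
            continue
        la, lb = sorted(key)
        # orientation: which locus did SNP1 map to, in the majority of members
        n_a_first = sum(1 for _, l1, _ in members if l1 == la)
        if 2 * n_a_first >= len(members):
            locus1, locus2 = la, lb
        else:
            locus1, locus2 = lb, la
        snps1 = {it.snp1_id if l1 == locus1 else it.snp2_id for it, l1, _ in members}
        snps2 = {it.snp2_id if l1 == locus1 else it.snp1_id for it, l1, _ in members}
        if len(snps1) < 2 or len(snps2) < 2:  # single-SNP side: insufficient
            continue
        stats = [it for it, _, _ in members]
        pairs.append(
            LocusPair(
                locus1_id=locus1,
                locus2_id=locus2,
                supporting_interactions=stats,
                distinct_snps1=len(snps1),
                distinct_snps2=len(snps2),
                best_p=min(it.p_z for it in stats),
            )
        )
    pairs.sort(key=lambda p: (p.best_p, p.locus1_id, p.locus2_id))
    return pairs
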