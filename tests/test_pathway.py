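import numpy as np
import pytest

from epipath import data_path
from epipath.locus_mapping import GeneAnnotation
from epipath.pathway import (
    GeneSet,
    UndefinedESError,
    bh_fdr,
    enrichment_score,
    filter_gene_sets,
    gene_level_stats,
    gsa_snp_pathway,
    gsea_permutation_test,
    read_gmt,
    snp_assoc_chi2,
    write_gmt,
)
from epipath.genotype_io import FormatError
from epipath.simulate import CohortSpec, PathwaySignalSpec, simulate_pathway_cohort

from conftest import make_matrix


# ---------------------------------------------------------------------------
# snp_assoc_chi2
# ---------------------------------------------------------------------------

def test_equal_allele_frequencies_give_zero():
    g = np.array([1] * 40, dtype=np.int8)
    ph = np.array([1] * 20 + [0] * 20, dtype=np.int8)
    assert snp_assoc_chi2(g, ph) == pytest.approx(0.0, abs=1e-12)


def test_chi2_matches_textbook_2x2():
    # allele counts: cases (60, 40), controls (40, 60)
    g = np.array([2] * 10 + [1] * 40 + [0] * 0 + [1] * 40 + [0] * 10,
                 dtype=np.int8)
    ph = np.array([1] * 50 + [0] * 50, dtype=np.int8)
    # cases: 10 hom + 40 het -> 60 a1 of 100; controls: 40 het -> 40 of 100
    a, b, c, d = 60.0, 40.0, 40.0, 60.0
    n = a + b + c + d
    expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    assert snp_assoc_chi2(g, ph) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(8.0)


def test_monomorphic_snp_is_zero():
    g = np.zeros(40, dtype=np.int8)
    ph = np.array([1] * 20 + [0] * 20, dtype=np.int8)
    assert snp_assoc_chi2(g, ph) == 0.0


def test_null_chi2_distribution_calibrated(rng):
    stats = []
    ph = np.array([1] * 250 + [0] * 250, dtype=np.int8)
    for _ in range(600):
        g = rng.binomial(2, 0.3, 500).astype(np.int8)
        stats.append(snp_assoc_chi2(g, ph))
    stats = np.array(stats)
    # chi2(1): mean 1, P(>3.841) = 0.05
    assert abs(stats.mean() - 1.0) < 0.2
    frac = (stats > 3.841).mean()
    assert abs(frac - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / stats.size)


# ---------------------------------------------------------------------------
# gene_level_stats
# ---------------------------------------------------------------------------

def _toy_annotated_matrix(rng):
    G = rng.binomial(2, 0.3, size=(100, 6)).astype(np.int8)
    ph = np.array([1] * 50 + [0] * 50)
    positions = [1000, 2000, 3000, 10_000, 11_000, 20_000]
    m = make_matrix(G, ph, positions=positions)
    ann = [
        GeneAnnotation("GA", "1", 500, 3500),
        GeneAnnotation("GB", "1", 9500, 12_000),
        GeneAnnotation("GC", "1", 19_500, 20_500),
        GeneAnnotation("GD", "1", 50_000, 51_000),  # no SNPs
    ]
    return m, ann


def test_single_snp_gene_stat(rng):
    m, ann = _toy_annotated_matrix(rng)
    stats = {g.gene_id: g for g in gene_level_stats(m, ann, flank=0)}
    assert stats["GC"].n_snps == 1
    assert stats["GC"].stat == pytest.approx(
        snp_assoc_chi2(m.genotypes[:, 5], m.phenotype))
    assert "GD" not in stats


def test_shared_snp_counts_for_overlapping_genes(rng):
    m, _ = _toy_annotated_matrix(rng)
    ann = [GeneAnnotation("G1", "1", 500, 2500), GeneAnnotation("G2", "1", 1500, 3500)]
    stats = {g.gene_id: g for g in gene_level_stats(m, ann, flank=0)}
    assert stats["G1"].n_snps == 2  # pos 1000, 2000
    assert stats["G2"].n_snps == 2  # pos 2000, 3000


def test_gene_stats_match_brute_force(rng):
    m, ann = _toy_annotated_matrix(rng)
    stats = {g.gene_id: g for g in gene_level_stats(m, ann, flank=500)}
    for a in ann:
        member = [j for j, v in enumerate(m.variants)
                  if a.start_bp - 500 <= v.pos_bp <= a.end_bp + 500]
        if not member:
            assert a.gene_id not in stats
            continue
        expected = max(snp_assoc_chi2(m.genotypes[:, j], m.phenotype)
                       for j in member)
        assert stats[a.gene_id].stat == pytest.approx(expected)


# ---------------------------------------------------------------------------
# enrichment_score
# ---------------------------------------------------------------------------

def _brute_force_es(stats, flags, weight_p=1.0):
    stats = np.asarray(stats, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    n = stats.size
    total = (np.abs(stats[flags]) ** weight_p).sum()
    n_miss = n - flags.sum()
    run, best = 0.0, 0.0
    for s, f in zip(stats, flags):
        if f:
            run += (abs(s) ** weight_p) / total if total > 0 else 1.0 / flags.sum()
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


def test_es_all_members_degenerate():
    stats = np.array([5.0, 3.0, 1.0])
    flags = np.array([True, True, True])
    es = enrichment_score(stats, flags)
    assert es == pytest.approx(_brute_force_es(stats, flags))
    assert es == pytest.approx(1.0)  # running sum reaches the full mass


def test_es_members_at_top_is_maximal():
    stats = np.array([9.0, 7.0, 5.0, 2.0, 1.0, 0.5])
    flags = np.array([True, True, False, False, False, False])
    es = enrichment_score(stats, flags)
    assert es == pytest.approx(1.0)  # sum of member increments before any miss
    assert es >= _brute_force_es(stats, np.array([False, True, True, False, False, False]))


def test_es_equals_brute_force_walk(rng):
    for _ in range(100):
        n = int(rng.integers(10, 60))
        stats = np.sort(rng.gamma(1.5, 2.0, n))[::-1]
        flags = np.zeros(n, dtype=bool)
        flags[rng.choice(n, size=int(rng.integers(1, max(2, n // 3))),
                         replace=False)] = True
        assert enrichment_score(stats, flags) == pytest.approx(
            _brute_force_es(stats, flags), abs=1e-12)


def test_es_no_member_errors():
    with pytest.raises(UndefinedESError):
        enrichment_score(np.array([1.0, 2.0]), np.array([False, False]))


# ---------------------------------------------------------------------------
# gsea_permutation_test
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def null_pathway_cohort():
    spec = PathwaySignalSpec(n_genes=120, snps_per_gene=(1, 3),
                             enriched_set_size=10, n_random_sets=19,
                             effect_logit=0.0)
    return simulate_pathway_cohort(spec, CohortSpec(150, 150, 0, seed=71))


def test_gsea_null_empirical_p_calibrated(null_pathway_cohort):
    matrix, annotation, sets = null_pathway_cohort
    res = gsea_permutation_test(matrix, annotation, sets, n_perm=200, seed=3,
                                flank=0)
    ps = np.array([r.empirical_p for r in res])
    assert ps.min() >= 1 / 201
    # ~uniform: mean near 0.5, not all tiny
    assert 0.25 < ps.mean() < 0.75


def test_gsea_reproducible_given_seed(null_pathway_cohort):
    matrix, annotation, sets = null_pathway_cohort
    r1 = gsea_permutation_test(matrix, annotation, sets, n_perm=120, seed=9, flank=0)
    r2 = gsea_permutation_test(matrix, annotation, sets, n_perm=120, seed=9, flank=0)
    for a, b in zip(r1, r2):
        assert (a.set_id, a.es, a.nes, a.empirical_p, a.fdr, a.fwer) == \
               (b.set_id, b.es, b.nes, b.empirical_p, b.fdr, b.fwer)


def test_gsea_planted_set_wins():
    spec = PathwaySignalSpec(n_genes=100, snps_per_gene=(2, 3),
                             enriched_set_size=12, n_random_sets=15,
                             effect_logit=0.5)
    matrix, annotation, sets = simulate_pathway_cohort(
        spec, CohortSpec(300, 300, 0, seed=41))
    res = gsea_permutation_test(matrix, annotation, sets, n_perm=200, seed=5,
                                flank=0)
    assert res[0].set_id == "planted"
    assert res[0].empirical_p < 0.05
    assert res[0].fwer < 0.1


def test_gsea_empirical_p_floor(null_pathway_cohort):
    matrix, annotation, sets = null_pathway_cohort
    res = gsea_permutation_test(matrix, annotation, sets, n_perm=100, seed=3,
                                flank=0)
    for r in res:
        assert r.empirical_p >= 1 / 101
        assert 0.0 <= r.fdr <= 1.0
        assert 0.0 <= r.fwer <= 1.0


def test_gsea_rejects_small_n_perm(null_pathway_cohort):
    matrix, annotation, sets = null_pathway_cohort
    with pytest.raises(ValueError):
        gsea_permutation_test(matrix, annotation, sets, n_perm=50, seed=1)


# ---------------------------------------------------------------------------
# filter_gene_sets
# ---------------------------------------------------------------------------

def _set(set_id, n):
    return GeneSet(set_id, "d", tuple(f"g{i}" for i in range(n)))


def test_small_and_large_sets_dropped():
    universe = {f"g{i}" for i in range(300)}
    sets = [_set("too_small", 4), _set("ok", 5), _set("too_big", 201),
            _set("big_ok", 200)]
    kept = {s.set_id for s in filter_gene_sets(sets, universe)}
    assert kept == {"ok", "big_ok"}


def test_intersection_applied_before_size_check():
    universe = {"g0", "g1", "g2", "g3"}
    sets = [_set("s", 10)]  # 10 members but only 4 covered
    assert filter_gene_sets(sets, universe, min_size=5) == []
    assert len(filter_gene_sets(sets, universe, min_size=4)[0].member_genes) == 4


def test_packaged_tob1_set_survives_size_filter():
    sets = read_gmt(data_path("tob1_pathway.gmt"))
    assert len(sets) == 1
    assert len(sets[0].member_genes) == 19
    kept = filter_gene_sets(sets, set(sets[0].member_genes))
    assert len(kept) == 1
    assert len(kept[0].member_genes) == 19


# ---------------------------------------------------------------------------
# gsa_snp_pathway
# ---------------------------------------------------------------------------

def test_equal_scores_give_zero_z():
    gene_p = {f"g{i}": 0.1 for i in range(50)}
    sets = [_set("s1", 10), _set("s2", 5)]
    res = gsa_snp_pathway(gene_p, sets)
    for r in res:
        assert r.z == 0.0
        assert r.p == pytest.approx(1.0)


def test_top_scoring_set_has_largest_z(rng):
    ps = rng.uniform(0.001, 1.0, 60)
    gene_p = {f"g{i}": float(p) for i, p in enumerate(ps)}
    order = np.argsort(ps)  # smallest P = highest score
    top_set = GeneSet("top", "d", tuple(f"g{i}" for i in order[:8]))
    rand_sets = [GeneSet(f"r{k}", "d",
                         tuple(f"g{i}" for i in rng.choice(60, 8, replace=False)))
                 for k in range(5)]
    res = gsa_snp_pathway(gene_p, [top_set] + rand_sets)
    assert res[0].set_id == "top"
    assert res[0].z == max(r.z for r in res)


def test_bh_fdr_hand_computation():
    got = bh_fdr(np.array([0.01, 0.02, 0.04, 0.8]))
    assert np.allclose(got, [0.04, 0.04, 0.04 * 4 / 3, 0.8])


def test_unscored_set_omitted():
    gene_p = {"g1": 0.2, "g2": 0.4, "g3": 0.6}
    sets = [GeneSet("scored", "d", ("g1", "g2")),
            GeneSet("unscored", "d", ("zz1", "zz2"))]
    res = gsa_snp_pathway(gene_p, sets)
    assert [r.set_id for r in res] == ["scored"]


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def test_read_gmt_basic(tmp_path):
    p = tmp_path / "x.gmt"
    p.write_text("tob1Pathway\tRole of Tob in T-cell activation\tTOB1\tTOB2\n")
    sets = read_gmt(p)
    assert sets[0].member_genes == ("TOB1", "TOB2")


def test_read_gmt_dedupes(tmp_path):
    p = tmp_path / "x.gmt"
    p.write_text("s\td\tA\tB\tA\n")
    assert read_gmt(p)[0].member_genes == ("A", "B")


def test_read_gmt_rejects_empty_set(tmp_path):
    p = tmp_path / "x.gmt"
    p.write_text("s\td\n")
    with pytest.raises(FormatError, match=":1"):
        read_gmt(p)


def test_gmt_round_trip(tmp_path):
    sets = read_gmt(data_path("tob1_pathway.gmt"))
    out = tmp_path / "rt.gmt"
    write_gmt(sets, out)
    assert read_gmt(out) == sets
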