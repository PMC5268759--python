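import numpy as np
import pytest

from germdecon.genotypes import MISSING
from germdecon.popgen import (
    PopgenError,
    amova,
    diversity_stats,
    pca_genotypes,
    select_k_bic,
)
from germdecon.synthetic_data import SimulationConfig, simulate_collection

from conftest import make_gm


def amova_oracle(gm, grouping):
    """Direct-definition AMOVA oracle: expand every accession into explicit
    binary allele copies and take nested sums of squares, then solve the
    expected-mean-square equations."""
    ids = gm.accession_ids
    groups = sorted(set(grouping.values()))
    ss_a = ss_b = ss_w = 0.0
    for m in range(gm.n_snps):
        copies = {}  # accession -> list of 0/1
        for i, a in enumerate(ids):
            d = gm.dosage[i, m]
            if d == MISSING:
                continue
            p = int(gm.ploidy[i])
            copies[a] = [1] * int(d) + [0] * (p - int(d))
        allv = [x for v in copies.values() for x in v]
        if len(allv) <= 1:
            continue
        gmean = np.mean(allv)
        for g in groups:
            gv = [x for a, v in copies.items() if grouping[a] == g for x in v]
            if not gv:
                continue
            gm_mean = np.mean(gv)
            ss_a += len(gv) * (gm_mean - gmean) ** 2
            for a, v in copies.items():
                if grouping[a] != g:
                    continue
                am = np.mean(v)
                ss_b += len(v) * (am - gm_mean) ** 2
                ss_w += sum((x - am) ** 2 for x in v)
    # coefficients from the full design
    pl = {a: int(p) for a, p in zip(ids, gm.ploidy)}
    I, g = len(ids), len(groups)
    n = sum(pl.values())
    n_i = {grp: sum(pl[a] for a in ids if grouping[a] == grp) for grp in groups}
    s2 = sum(sum(pl[a] ** 2 for a in ids if grouping[a] == grp) / n_i[grp]
             for grp in groups)
    df_a, df_b, df_w = g - 1, I - g, sum(p - 1 for p in pl.values())
    coef_a = (n - s2) / df_b
    coef_b = (s2 - sum(p ** 2 for p in pl.values()) / n) / df_a
    coef_c = (n - sum(v ** 2 for v in n_i.values()) / n) / df_a
    ms_a, ms_b, ms_w = ss_a / df_a, ss_b / df_b, ss_w / df_w
    var_w = ms_w
    var_b = (ms_b - var_w) / coef_a
    var_a = (ms_a - var_w - coef_b * var_b) / coef_c
    return (ss_a, ss_b, ss_w), (var_a, var_b, var_w)


class TestPCA:
    def test_variance_percentages_well_formed(self, structured_diploid):
        gm, _ = structured_diploid
        pca = pca_genotypes(gm)
        assert np.all(np.diff(pca.pct_variance) <= 1e-9)
        assert pca.pct_variance.sum() <= 100 + 1e-9

    def test_two_divergent_subpops_separate_on_pc1(self):
        cfg = SimulationConfig(seed=71, n_snps=1000, n_subpops=2, fst=0.4,
                               n_genotypes_per_subpop=10, default_ploidy=2)
        gm, truth = simulate_collection(cfg)
        pca = pca_genotypes(gm)
        labels = np.array([truth.genotype_subpop[truth.clone_map[a]]
                           for a in pca.ids])
        pc1 = pca.scores[:, 0]
        assert max(pc1[labels == 0]) < min(pc1[labels == 1]) or \
            max(pc1[labels == 1]) < min(pc1[labels == 0])

    def test_all_missing_column_rejected(self):
        gm = make_gm([[1, MISSING], [0, MISSING]], ploidy=2)
        with pytest.raises(PopgenError):
            pca_genotypes(gm)

    def test_constant_column_contributes_nothing(self):
        gm = make_gm([[1, 0], [0, 0], [2, 0], [1, 0]], ploidy=2)
        pca = pca_genotypes(gm)
        assert pca.pct_variance[0] == pytest.approx(100.0)


class TestKSelection:
    def test_three_planted_subpopulations_recovered(self):
        cfg = SimulationConfig(seed=81, n_snps=1000, n_subpops=3, fst=0.3,
                               n_genotypes_per_subpop=20, default_ploidy=4)
        gm, truth = simulate_collection(cfg)
        ks = select_k_bic(pca_genotypes(gm), range(2, 11), seed=0)
        assert ks.chosen_k == 3

    def test_homogeneous_population_chooses_smallest_k(self):
        rng = np.random.default_rng(0)
        dosage = rng.binomial(2, 0.5, size=(40, 300)).astype(np.int16)
        gm = make_gm(dosage, ploidy=2)
        ks = select_k_bic(pca_genotypes(gm), range(2, 8), seed=0)
        # no structure: BIC has no interior optimum worth 2+ clusters
        assert ks.chosen_k == 2 or ks.bic[2] <= min(ks.bic.values()) + 2 * np.log(40)

    def test_same_seed_same_assignments(self, structured_diploid):
        gm, _ = structured_diploid
        pca = pca_genotypes(gm)
        a = select_k_bic(pca, range(2, 6), seed=4)
        b = select_k_bic(pca, range(2, 6), seed=4)
        assert a.assignments == b.assignments and a.chosen_k == b.chosen_k

    def test_bad_k_range(self, structured_diploid):
        gm, _ = structured_diploid
        pca = pca_genotypes(gm)
        with pytest.raises(PopgenError):
            select_k_bic(pca, [])
        with pytest.raises(PopgenError):
            select_k_bic(pca, [1000])


class TestAmova:
    def test_identical_homozygotes_no_variance(self):
        gm = make_gm(np.zeros((6, 20), dtype=np.int16), ploidy=2)
        t = amova(gm, {a: ("X" if i < 3 else "Y")
                       for i, a in enumerate(gm.accession_ids)}, n_perm=0)
        assert t.among_groups.ss == 0 and t.within_genotypes.ss == 0

    def test_opposite_homozygote_groups_fully_among(self):
        dosage = np.vstack([np.zeros((3, 20)), np.full((3, 20), 2)]).astype(np.int16)
        gm = make_gm(dosage, ploidy=2)
        t = amova(gm, {a: ("X" if i < 3 else "Y")
                       for i, a in enumerate(gm.accession_ids)}, n_perm=0)
        assert t.among_groups.var_pct == pytest.approx(100.0)
        assert t.fst == pytest.approx(1.0)

    def test_matches_direct_definition_oracle(self):
        rng = np.random.default_rng(2)
        dosage = rng.integers(0, 5, size=(6, 30)).astype(np.int16)
        dosage[rng.random(dosage.shape) < 0.1] = MISSING
        gm = make_gm(dosage, ploidy=4)
        grouping = {a: ("X" if i % 2 else "Y")
                    for i, a in enumerate(gm.accession_ids)}
        t = amova(gm, grouping, n_perm=0)
        (ss_a, ss_b, ss_w), (va, vb, vw) = amova_oracle(gm, grouping)
        assert t.among_groups.ss == pytest.approx(ss_a, abs=1e-9)
        assert t.among_genotypes.ss == pytest.approx(ss_b, abs=1e-9)
        assert t.within_genotypes.ss == pytest.approx(ss_w, abs=1e-9)
        # raw (pre-truncation) components solve the same equations
        for got, want in [(t.among_groups.var, va), (t.among_genotypes.var, vb),
                          (t.within_genotypes.var, vw)]:
            assert got == pytest.approx(max(want, 0.0), abs=1e-9)

    def test_var_pct_sums_to_100(self, structured_diploid):
        gm, truth = structured_diploid
        grouping = {a: str(truth.genotype_subpop[truth.clone_map[a]])
                    for a in gm.accession_ids}
        t = amova(gm, grouping, n_perm=0)
        total = (t.among_groups.var_pct + t.among_genotypes.var_pct
                 + t.within_genotypes.var_pct)
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_structure_detected_by_permutation(self, structured_diploid):
        gm, truth = structured_diploid
        grouping = {a: str(truth.genotype_subpop[truth.clone_map[a]])
                    for a in gm.accession_ids}
        t = amova(gm, grouping, n_perm=99, seed=0)
        assert t.among_groups.p_value <= 0.05
        assert t.fst > 0.2

    def test_permutation_p_uniform_without_structure(self):
        """Among-group permutation p-values on structureless data follow
        the uniform distribution (Kolmogorov check over replicates)."""
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(400):
            dosage = rng.binomial(2, rng.uniform(0.2, 0.8, 40),
                                  size=(12, 40)).astype(np.int16)
            gm = make_gm(dosage, ploidy=2)
            grouping = {a: ("X" if i < 6 else "Y")
                        for i, a in enumerate(gm.accession_ids)}
            t = amova(gm, grouping, n_perm=49,
                      seed=int(rng.integers(2 ** 31)), permute_alleles=False)
            pvals.append(t.among_groups.p_value)
        pvals = np.sort(pvals)
        ks = np.max(np.abs(pvals - np.arange(1, 401) / 400))
        # discrete p grid of 50 values adds 1/100 to the achievable D
        assert ks < 0.08

    def test_missing_assignment_rejected(self, structured_diploid):
        gm, _ = structured_diploid
        with pytest.raises(PopgenError):
            amova(gm, {gm.accession_ids[0]: "X"}, n_perm=0)


class TestDiversity:
    def test_closed_form_unbiased_he(self):
        # p = 0.5 with 2 diploid accessions -> n_c = 4, He = (4/3)*0.5
        gm = make_gm([[0], [2]], ploidy=2)
        d = diversity_stats(gm)
        assert d.h_e == pytest.approx(4 / 3 * 0.5)
        assert d.n_e == pytest.approx(2.0)  # two equifrequent alleles
        assert d.h_o == 0.0

    def test_all_het_locus(self):
        gm = make_gm([[1], [1], [1]], ploidy=2)
        assert diversity_stats(gm).h_o == 1.0

    def test_fis_near_zero_under_random_mating(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.1, 0.9, 600)
        dosage = rng.binomial(2, p, size=(60, 600)).astype(np.int16)
        gm = make_gm(dosage, ploidy=2)
        d = diversity_stats(gm)
        assert abs(d.f_is) < 0.05

    def test_fis_negative_under_excess_heterozygosity(self):
        dosage = np.ones((30, 100), dtype=np.int16)  # everyone heterozygous
        gm = make_gm(dosage, ploidy=2)
        assert diversity_stats(gm).f_is < -0.5

    def test_maf_spectrum(self):
        # locus 1: p=0.5 (maf > 0.1); locus 2: monomorphic (maf = 0)
        gm = make_gm([[1, 0], [1, 0]], ploidy=2)
        assert diversity_stats(gm).pct_maf_gt_0p1 == 50.0
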