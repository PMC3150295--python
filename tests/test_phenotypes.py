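"""Causal-site selection, effect scaling and phenotype generation."""
import numpy as np
import pytest

from phenosim import (
    EligibilityError,
    GenotypeMatrix,
    HaplotypeMatrix,
    ModelError,
    PenetranceModel,
    QTNSpec,
    QuantTraitModel,
    ValidationError,
    allele_frequency,
    assign_case_control,
    coding_variance,
    effect_coefficient,
    epistatic_state,
    expected_prevalence,
    find_haploblocks,
    generate_fixture,
    generate_quantitative,
    pair_diploids,
    regression_variance_shares,
    select_qtns,
)


class TestAlleleFrequency:
    @pytest.mark.parametrize(
        "column, expected",
        [([0, 1, 1, 0], 0.5), ([0, 0, 0, 0], 0.0), ([1, 1, 1, 0], 0.75)],
    )
    def test_haplotype_counts(self, column, expected):
        m = HaplotypeMatrix(np.array(column)[:, None], np.array([0.5]))
        assert allele_frequency(m, 0) == expected

    def test_genotype_codes(self):
        g = GenotypeMatrix(np.array([[-1], [0], [1]]), np.array([0.5]))
        assert allele_frequency(g, 0) == pytest.approx(0.5)


class TestSelectQtns:
    def test_forced_single_choice(self):
        # only site 1 is in range: column freqs 0.25, 0.5, 0.75
        alleles = np.array([[0, 0, 1], [0, 1, 1], [0, 1, 1], [1, 0, 0]])
        m = HaplotypeMatrix(alleles, np.array([0.1, 0.2, 0.3]))
        (q,) = select_qtns(m, 1, [0.05], freq_range=(0.4, 0.6), seed=0)
        assert q.site == 1
        assert q.derived_freq == 0.5

    def test_fixed_sites_honored(self):
        m = generate_fixture(40, 10, 0.5, seed=4)
        qtns = select_qtns(m, 2, [0.02, 0.03], fixed_sites=[3, 7], seed=0)
        assert [q.site for q in qtns] == [3, 7]
        assert qtns[0].effect == 0.02
        assert [q.derived_freq for q in qtns] == [
            allele_frequency(m, 3),
            allele_frequency(m, 7),
        ]

    def test_frequency_range_exhaustive(self):
        # exactly 2 of 20 sites fall in [0.4, 0.6]; every seed must pick them
        p = np.full(20, 0.05)
        p[[6, 13]] = 0.5
        rng = np.random.default_rng(11)
        alleles = (rng.random((1000, 20)) < p).astype(np.int8)
        m = HaplotypeMatrix(alleles, np.sort(rng.random(20)))
        freqs = alleles.mean(axis=0)
        eligible = set(np.flatnonzero((freqs >= 0.4) & (freqs <= 0.6)).tolist())
        assert eligible == {6, 13}  # oracle: exhaustive eligibility scan
        for seed in range(1000):
            qtns = select_qtns(m, 2, [0.01, 0.01], freq_range=(0.4, 0.6), seed=seed)
            assert {q.site for q in qtns} == eligible

    def test_no_eligible_site_raises(self):
        m = generate_fixture(1000, 5, 0.05, seed=0)
        with pytest.raises(EligibilityError, match="frequency range"):
            select_qtns(m, 1, [0.05], freq_range=(0.45, 0.55), seed=0)

    def test_monomorphic_fixed_site_rejected(self):
        m = HaplotypeMatrix(np.array([[0, 1], [0, 0]]), np.array([0.1, 0.2]))
        with pytest.raises(EligibilityError, match="monomorphic"):
            select_qtns(m, 1, [0.05], fixed_sites=[0], seed=0)

    def test_haploblock_constraint_pair_shares_block(self):
        # columns 0,1 mutually compatible; 2,3 identical; 1-2 show all four
        # gametes, so the blocks are [0..1] and [2..3]
        alleles = np.column_stack(
            [
                [0, 0, 0, 0, 1, 1, 1, 1],
                [0, 0, 0, 1, 1, 1, 1, 1],
                [1, 1, 0, 0, 0, 1, 0, 1],
                [1, 1, 0, 0, 0, 1, 0, 1],
            ]
        )
        m = HaplotypeMatrix(alleles, np.linspace(0.1, 0.4, 4))
        blocks = find_haploblocks(m)
        assert [(b.start_site, b.end_site) for b in blocks] == [(0, 1), (2, 3)]
        seen = set()
        for seed in range(50):
            a, b = (
                q.site
                for q in select_qtns(
                    m, 2, [0.01, 0.01], require_common_haploblock=True, seed=seed
                )
            )
            assert any(a in blk and b in blk for blk in blocks)
            seen.add((a, b))
        assert seen == {(0, 1), (2, 3)}  # both eligible pairs reachable

    def test_haploblock_constraint_impossible_raises(self):
        # independent common sites on many chromosomes: every block is a
        # singleton, so no block holds two eligible sites
        m = generate_fixture(30, 40, 0.5, seed=9)
        with pytest.raises(EligibilityError, match="haploblock"):
            select_qtns(m, 2, [0.01, 0.01], require_common_haploblock=True, seed=0)


class TestEffectCoefficient:
    def test_zero_effect_zero_coefficient(self):
        assert effect_coefficient(0.0, 0.3, 0.1, 0.21) == 0.0

    def test_haploid_and_diploid_values(self):
        # beta = sqrt(pi / (v (1 - h^2)))
        assert effect_coefficient(0.05, 0.5, 0.1, 0.25) == pytest.approx(0.4714, abs=1e-4)
        assert effect_coefficient(0.05, 0.5, 0.1, 0.5) == pytest.approx(0.3333, abs=1e-4)

    def test_unit_heritability_rejected(self):
        with pytest.raises(ModelError):
            effect_coefficient(0.5, 0.5, 1.0, 0.25)

    def test_coding_variances(self):
        assert coding_variance(0.5, "haploid") == 0.25
        assert coding_variance(0.5, "diploid") == 0.5
        assert coding_variance(0.5, "diploid", dominance=True) == 0.25

    def test_empirical_variance_share(self):
        # oracle: simulate 1e5 haploids at two pi=0.05 QTNs; each QTN's
        # share of phenotypic variance must recover its pi
        m = generate_fixture(100_000, 2, 0.5, seed=21)
        qtns = select_qtns(m, 2, [0.05, 0.05], fixed_sites=[0, 1], seed=0)
        y = generate_quantitative(m, QuantTraitModel(qtns), seed=21)
        _, shares = regression_variance_shares(y.values, m.alleles.astype(float))
        np.testing.assert_allclose(shares, 0.05, atol=0.01)


class TestEpistaticState:
    @pytest.mark.parametrize(
        "g1, g2, ploidy, expected",
        [
            (0, 0, "diploid", 1),  # double heterozygote carries both derived alleles
            (1, -1, "diploid", 0),
            (-1, -1, "diploid", 0),
            (1, 1, "haploid", 1),
            (1, 0, "haploid", 0),
        ],
    )
    def test_states(self, g1, g2, ploidy, expected):
        assert epistatic_state(g1, g2, ploidy) == expected

    def test_vectorized(self):
        out = epistatic_state([1, 1, 0], [1, 0, 1], "haploid")
        np.testing.assert_array_equal(out, [1, 0, 0])


class TestGenerateQuantitative:
    def test_zero_qtns_pure_noise(self):
        m = generate_fixture(20_000, 3, 0.5, seed=5)
        y = generate_quantitative(m, QuantTraitModel([]), seed=5)
        assert y.values.var() == pytest.approx(1.0, abs=0.05)

    def test_ancestral_individuals_get_pure_noise(self):
        m = generate_fixture(500, 4, 0.3, seed=6)
        qtns = select_qtns(m, 2, [0.04, 0.04], fixed_sites=[0, 1], seed=0)
        noise = generate_quantitative(m, QuantTraitModel([]), seed=6).values
        y = generate_quantitative(m, QuantTraitModel(qtns), seed=6).values
        ancestral = (m.alleles[:, [0, 1]] == 0).all(axis=1)
        assert ancestral.any()
        np.testing.assert_array_equal(y[ancestral], noise[ancestral])

    def test_heritability_recovery(self):
        m = generate_fixture(20_000, 10, 0.4, seed=8)
        qtns = select_qtns(m, 2, [0.05, 0.05], seed=8)
        y = generate_quantitative(m, QuantTraitModel(qtns), seed=8)
        r2, _ = regression_variance_shares(
            y.values, m.alleles[:, [q.site for q in qtns]].astype(float)
        )
        assert r2 == pytest.approx(0.10, abs=0.01)

    def test_bit_reproducible(self):
        m = generate_fixture(100, 5, 0.4, seed=2)
        qtns = select_qtns(m, 1, [0.05], seed=2)
        a = generate_quantitative(m, QuantTraitModel(qtns), seed=2).values
        b = generate_quantitative(m, QuantTraitModel(qtns), seed=2).values
        np.testing.assert_array_equal(a, b)

    def test_dominance_recoding_equates_het_and_hom_derived(self):
        haps = generate_fixture(2000, 3, 0.5, seed=10)
        g = pair_diploids(haps)
        qtns = [QTNSpec(0, 0.05, allele_frequency(g, 0))]
        model = QuantTraitModel(qtns, dominance=True, ploidy="diploid")
        noise = generate_quantitative(
            g, QuantTraitModel([], ploidy="diploid"), seed=10
        ).values
        y = generate_quantitative(g, model, seed=10).values
        genetic = y - noise
        het = genetic[g.codes[:, 0] == 0]
        hom = genetic[g.codes[:, 0] == 1]
        anc = genetic[g.codes[:, 0] == -1]
        # het and hom-derived carry one identical genetic shift; ancestral none
        assert het.size and hom.size and anc.size
        np.testing.assert_allclose(het, het[0], atol=1e-9)
        np.testing.assert_allclose(hom, het[0], atol=1e-9)
        np.testing.assert_allclose(anc, 0.0, atol=1e-9)
        assert het[0] > 0

    def test_epistatic_monomorphic_raises(self):
        # the derived alleles never co-occur, so the fictive allele is constant 0
        m = HaplotypeMatrix(
            np.array([[1, 0], [1, 0], [0, 1], [0, 1]]), np.array([0.1, 0.2])
        )
        qtns = [QTNSpec(0, 0.01, 0.5), QTNSpec(1, 0.01, 0.5)]
        with pytest.raises(ModelError, match="monomorphic"):
            generate_quantitative(m, QuantTraitModel(qtns, epistatic_effect=0.05), seed=0)

    def test_ploidy_mismatch_rejected(self):
        m = generate_fixture(10, 2, 0.5, seed=0)
        q = [QTNSpec(0, 0.05, allele_frequency(m, 0))]
        with pytest.raises(ModelError):
            generate_quantitative(m, QuantTraitModel(q, ploidy="diploid"), seed=0)


class TestModelInvariants:
    def test_heritability_bound(self):
        q = [QTNSpec(0, 0.6, 0.5), QTNSpec(1, 0.5, 0.5)]
        with pytest.raises(ValidationError, match="heritability"):
            QuantTraitModel(q)

    def test_epistasis_needs_two_qtns(self):
        with pytest.raises(ValidationError):
            QuantTraitModel([QTNSpec(0, 0.05, 0.5)], epistatic_effect=0.05)

    def test_monomorphic_qtn_spec_rejected(self):
        with pytest.raises(ValidationError):
            QTNSpec(0, 0.05, 0.0)

    def test_penetrance_table_shapes(self):
        PenetranceModel((0,), [0.1, 0.9], ploidy="haploid")
        PenetranceModel((0,), [0.1, 0.5, 0.9], ploidy="diploid")
        PenetranceModel((0, 1), np.full((3, 3), 0.2), ploidy="diploid")
        with pytest.raises(ValidationError, match="shape"):
            PenetranceModel((0,), [0.1, 0.9], ploidy="diploid")
        with pytest.raises(ValidationError):
            PenetranceModel((0,), [0.1, 1.5], ploidy="haploid")


class TestCaseControl:
    def test_all_zero_table_no_cases(self):
        m = generate_fixture(200, 2, 0.5, seed=1)
        phen = assign_case_control(m, PenetranceModel((0,), [0, 0], "haploid"), seed=1)
        assert phen.n_cases == 0

    def test_all_one_table_all_cases(self):
        m = generate_fixture(200, 2, 0.5, seed=1)
        phen = assign_case_control(m, PenetranceModel((0,), [1, 1], "haploid"), seed=1)
        assert phen.n_cases == 200

    def test_recessive_prevalence(self):
        # diploid table (0, 0, 1) at f = 0.5 under random pairing: the
        # homozygous-derived fraction is ~0.25
        haps = generate_fixture(80_000, 1, 0.5, seed=13)
        g = pair_diploids(haps)
        model = PenetranceModel((0,), [0, 0, 1], "diploid")
        phen = assign_case_control(g, model, seed=13)
        # oracle: exact expectation from realized genotype frequencies
        counts = np.bincount(g.codes[:, 0] + 1, minlength=3) / g.n_individuals
        expected = expected_prevalence(model, counts)
        assert expected == pytest.approx(0.25, abs=0.01)
        assert phen.n_cases / len(phen) == pytest.approx(expected, abs=0.01)

    def test_reproducible(self):
        m = generate_fixture(500, 1, 0.5, seed=3)
        model = PenetranceModel((0,), [0.2, 0.8], "haploid")
        a = assign_case_control(m, model, seed=3).values
        b = assign_case_control(m, model, seed=3).values
        np.testing.assert_array_equal(a, b)


class TestExpectedPrevalence:
    def test_uniform_penetrance(self):
        model = PenetranceModel((0,), [0.3, 0.3, 0.3], "diploid")
        assert expected_prevalence(model, [0.25, 0.5, 0.25]) == pytest.approx(0.3)

    def test_dot_product(self):
        model = PenetranceModel((0,), [0, 0, 1], "diploid")
        assert expected_prevalence(model, [0.25, 0.5, 0.25]) == pytest.approx(0.25)

    def test_two_locus_product_rule(self):
        model = PenetranceModel((0, 1), [[0, 0], [0, 1]], "haploid")
        # independent loci at f1 = f2 = 0.5
        gf = np.outer([0.5, 0.5], [0.5, 0.5])
        assert expected_prevalence(model, gf) == pytest.approx(0.25)

    def test_frequencies_must_sum_to_one(self):
        model = PenetranceModel((0,), [0, 0, 1], "diploid")
        with pytest.raises(ValidationError, match="sum"):
            expected_prevalence(model, [0.3, 0.3, 0.3])
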