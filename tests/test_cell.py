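"""Genotype→phenotype map: translation, fitness, mutation rate, noise."""

import dataclasses

import numpy as np
import pytest
from Bio.Seq import Seq

import mutatorsim as ms
from mutatorsim import cell as cm


class TestTranslate:
    def test_poly_methionine(self):
        assert cm.translate("ATG" * 27) == "M" * 27

    def test_in_frame_stop_flagged(self):
        gene = "ATG" * 13 + "TAA" + "ATG" * 13
        assert cm.translate(gene) is None

    def test_matches_biopython_table(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            gene = "".join(rng.choice(list("ACGT"), 81))
            expect = str(Seq(gene).translate())
            got = cm.translate(gene)
            if "*" in expect:
                assert got is None
            else:
                assert got == expect

    def test_bad_alphabet(self):
        with pytest.raises(cm.SequenceError):
            cm.translate("ATG" * 26 + "AUG")
        with pytest.raises(cm.SequenceError):
            cm.translate("ATG")

    def test_genome_validation(self):
        with pytest.raises(cm.SequenceError):
            cm.Genome(("ATG" * 27,) * 3)
        with pytest.raises(cm.SequenceError):
            cm.Genome(("ATG" * 27,) * 3 + ("ATG" * 26 + "XYZ",))


class TestBirthRate:
    def test_published_operating_point_arithmetic(self):
        """b0 = 707.445, sigma = 100, C0 = 0.4, total C = 0.76:
        the production penalty is 1 + 100*0.36^2 = 13.96."""
        params = cm.FitnessParams(b0=707.445, sigma=100.0, C0=0.4, G_ref=1.0)
        g1, g23 = 3e-4, 2e-4
        expect = 707.445 * g1 * g23 / 13.96
        assert cm.birth_rate_from(g1, g23, 0.76, params) == pytest.approx(expect)

    def test_optimum_production_has_unit_penalty(self):
        params = cm.FitnessParams(b0=10.0, G_ref=1.0)
        assert cm.birth_rate_from(0.05, 0.05, params.C0, params) == pytest.approx(
            10.0 * 0.05 * 0.05
        )

    def test_no_functional_dimer_no_growth(self):
        params = cm.FitnessParams(G_ref=1.0)
        assert cm.birth_rate_from(0.1, 0.0, 0.4, params) == 0.0

    def test_clamped_to_unit_interval(self):
        params = cm.FitnessParams(b0=1e12, G_ref=1.0)
        assert cm.birth_rate_from(0.1, 0.1, 0.4, params) == 1.0

    def test_sigma_zero_removes_production_penalty(self):
        params = cm.FitnessParams(sigma=1e-300, G_ref=1.0)
        b1 = cm.birth_rate_from(0.01, 0.01, 0.1, params)
        b2 = cm.birth_rate_from(0.01, 0.01, 5.0, params)
        assert b1 == pytest.approx(b2)

    def test_constant_b_overrides_genotype(self):
        params = cm.FitnessParams(G_ref=1.0, constant_b=0.25)
        assert cm.birth_rate_from(0.0, 0.0, 99.0, params) == 0.25


class TestMutationRate:
    def test_reference_concentration_gives_wild_type_rate(self):
        params = cm.FitnessParams(G_ref=0.05)
        assert cm.mutation_rate(0.05, params) == pytest.approx(1e-4)
        assert cm.mutation_rate(0.1, params) == pytest.approx(1e-4)

    def test_no_repair_gives_maximal_rate(self):
        params = cm.FitnessParams(G_ref=0.05, m_max=0.1)
        assert cm.mutation_rate(0.0, params) == pytest.approx(0.1)

    def test_linear_midpoint(self):
        params = cm.FitnessParams(G_ref=0.05)
        assert cm.mutation_rate(0.025, params) == pytest.approx(
            (params.m_min + params.m_max) / 2
        )

    def test_mutator_threshold_is_strict(self, toy_seed):
        cell, params, _ = toy_seed
        for m, expect in ((1e-4, False), (0.02, True), (0.01, False)):
            c = dataclasses.replace(cell, m=m)
            assert cm.is_mutator(c, params) is expect


class TestFluctuations:
    def test_r_zero_is_a_no_op(self, toy_seed):
        cell, params, _env = toy_seed
        p0 = dataclasses.replace(params, r=0.0)
        rng = np.random.default_rng(0)
        c2, events = cm.fluctuate_concentrations(cell, p0, rng)
        assert c2 is cell and events == []

    def test_multiplier_moments(self, toy_seed):
        """Mean multiplier 1 (mean-preserving), s.d. of the relative
        change ~ 0.1, within 3 standard errors over many draws."""
        cell, params, _env = toy_seed
        p1 = dataclasses.replace(params, r=1.0)
        rng = np.random.default_rng(99)
        n = 20_000
        ratios = []
        c = cell
        for _ in range(n // 4):
            c2, events = cm.fluctuate_concentrations(cell, p1, rng)
            ratios.extend(new / old for _g, old, new in events)
        ratios = np.array(ratios)
        se_mean = 0.1 / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 1.0) < 3 * se_mean
        sd = ratios.std()
        se_sd = 0.1 / np.sqrt(2 * len(ratios))
        assert abs(sd - 0.1) < 3 * se_sd

    def test_positivity_floor(self, toy_seed):
        cell, params, _env = toy_seed
        tiny = dataclasses.replace(cell, C=np.full(4, 2e-6))
        p1 = dataclasses.replace(params, r=1.0, fluct_sd=5.0)
        rng = np.random.default_rng(3)
        for _ in range(20):
            c2, _ = cm.fluctuate_concentrations(tiny, p1, rng)
            assert np.all(c2.C >= params.conc_floor)


class TestReplication:
    def test_zero_rate_copies_genome(self, toy_seed):
        cell, params, env = toy_seed
        zero_m = dataclasses.replace(cell, m=0.0)
        rng = np.random.default_rng(0)
        ids = iter(range(10, 20)).__next__
        daughters, events = cm.replicate(zero_m, params, env, rng, ids)
        assert len(daughters) == 2
        assert all(d.genome == cell.genome for d in daughters)
        assert events == []
        assert {d.parent_id for d in daughters} == {cell.lineage_id}

    def test_expected_substitutions_per_daughter(self):
        """Sum of four Poisson(m) draws has mean 4m (Monte-Carlo check)."""
        genome = cm.Genome(("ATG" * 27,) * 4)
        rng = np.random.default_rng(12)
        m = 0.5
        n = 3000
        total = 0
        for _ in range(n):
            _g, touched = cm.mutate_genome(genome, m, rng)
            total += len(touched)
        mean = total / n
        se = np.sqrt(4 * m / n)
        assert abs(mean - 4 * m) < 3 * se

    def test_stop_codon_daughter_is_lethal(self, toy_seed):
        cell, params, env = toy_seed
        gene = cell.genome.genes[0]
        broken = "TAA" + gene[3:]
        genome = cell.genome.with_gene(0, broken)
        d, reason = cm._develop_daughter(cell, genome, [0], env, params, 99)
        assert d is None and "stop" in reason

    def test_destabilised_daughter_is_lethal(self, toy_seed):
        """Raising theta above the protein's own p_nat makes any
        non-synonymous change to that gene lethal."""
        cell, params, env = toy_seed
        strict = dataclasses.replace(params, theta_nat=0.999)
        rng = np.random.default_rng(17)
        saw_lethal = False
        for _ in range(100):
            genome, touched = cm.mutate_genome_counts(
                cell.genome, np.array([1, 0, 0, 0]), rng
            )
            d, reason = cm._develop_daughter(cell, genome, touched, env, strict, 1)
            if d is None and "unstable" in (reason or ""):
                saw_lethal = True
                break
        assert saw_lethal

    def test_synonymous_substitutions_neutral(self, toy_seed):
        """Edits that preserve the protein leave b and m bit-identical."""
        cell, params, env = toy_seed
        rng = np.random.default_rng(21)
        genome = cell.genome
        for gene_idx in range(4):
            gene = genome.genes[gene_idx]
            for _ in range(30):
                codon_i = int(rng.integers(27))
                codon = gene[3 * codon_i : 3 * codon_i + 3]
                aa = cm.CODON_TO_AA[codon]
                syn = [c for c in cm.AA_TO_CODONS[aa] if c != codon]
                if syn:
                    new_codon = syn[int(rng.integers(len(syn)))]
                    gene = gene[: 3 * codon_i] + new_codon + gene[3 * codon_i + 3 :]
            genome = genome.with_gene(gene_idx, gene)
        fresh, reason = cm.develop(genome, cell.C, env, params)
        assert fresh is not None, reason
        assert fresh.b == cell.b
        assert fresh.m == cell.m

    def test_cached_phenotype_equals_fresh_recomputation(self, toy_seed):
        """b and m carried on the cell equal a from-scratch rebuild."""
        cell, params, env = toy_seed
        rng = np.random.default_rng(30)
        c2, _ = cm.fluctuate_concentrations(
            cell, dataclasses.replace(params, r=1.0), rng
        )
        fresh, _ = cm.develop(c2.genome, c2.C, env, params)
        assert c2.b == pytest.approx(fresh.b, rel=1e-9)
        assert c2.m == pytest.approx(fresh.m, rel=1e-9)
        assert cm.birth_rate(c2, params) == pytest.approx(c2.b, rel=1e-12)

    def test_incremental_update_equals_full_rebuild(self, toy_seed):
        """After a real mutation, the row-update path must agree with a
        from-scratch develop()."""
        cell, params, env = toy_seed
        rng = np.random.default_rng(77)
        relaxed = dataclasses.replace(params, theta_nat=0.0)
        for _ in range(10):
            genome, touched = cm.mutate_genome_counts(
                cell.genome, np.array([0, 1, 0, 1]), rng
            )
            d, _ = cm._develop_daughter(cell, genome, touched, env, relaxed, 1)
            if d is None:
                continue
            fresh, reason = cm.develop(genome, cell.C, env, relaxed,
                                       check_viability=False)
            assert fresh is not None, reason
            assert d.b == pytest.approx(fresh.b, rel=1e-9)
            assert d.m == pytest.approx(fresh.m, rel=1e-9)
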