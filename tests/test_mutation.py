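"""Somatic genotype evolution: ISM, signatures, FSM, cnLOH, deletions."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

from sccoalsim import (
    DEL,
    Demography,
    ISMExhaustedError,
    SubstitutionModel,
    add_germline_variants,
    apply_cnloh,
    apply_deletions,
    evolve_fsm_along_tree,
    evolve_genotypes,
    evolve_ism_diploid,
    evolve_signature_mutations,
    expected_segregating_sites,
    fsm_transition_matrix,
    generate_ancestral_genome,
    load_signature_catalogue,
    place_mutations_on_branches,
    signature_channels,
    simulate_coalescent_genealogy,
)
from sccoalsim.mutation import build_rate_matrix


class TestAncestralGenome:
    def test_degenerate_simplex_gives_monomorphic_genome(self, rng):
        g = generate_ancestral_genome(500, [1.0, 0.0, 0.0, 0.0], rng)
        assert np.all(g.maternal == 0)
        assert np.array_equal(g.maternal, g.paternal)

    def test_composition_matches_frequencies(self, rng):
        pi = np.array([0.3, 0.2, 0.2, 0.3])
        l = 100_000
        g = generate_ancestral_genome(l, pi, rng)
        counts = np.bincount(g.maternal, minlength=4)
        for b in range(4):
            se = math.sqrt(pi[b] * (1 - pi[b]) / l)
            assert abs(counts[b] / l - pi[b]) < 3 * se

    def test_invalid_length_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_ancestral_genome(0, [0.25] * 4, rng)

    def test_user_fasta_used_verbatim(self, rng, tmp_path):
        from sccoalsim.mutation import load_ancestral_genome_fasta

        fasta = tmp_path / "anc.fa"
        fasta.write_text(">anc\nACGTACGT\n")
        g = load_ancestral_genome_fasta(fasta)
        assert np.array_equal(g.maternal, [0, 1, 2, 3, 0, 1, 2, 3])
        assert np.array_equal(g.maternal, g.paternal)


class TestGermlineVariants:
    @pytest.mark.parametrize("rate,het_all", [(0.0, False), (1.0, True)])
    def test_degenerate_rates(self, rng, rate, het_all):
        g = generate_ancestral_genome(300, [0.25] * 4, rng)
        model = SubstitutionModel()
        out = add_germline_variants(g, rate, model, rng)
        het = out.maternal != out.paternal
        assert het.all() == het_all
        assert het.any() == het_all

    def test_heterozygous_count_binomial(self, rng):
        l, rate = 100_000, 0.001
        g = generate_ancestral_genome(l, [0.25] * 4, rng)
        out = add_germline_variants(g, rate, SubstitutionModel(), rng)
        n_het = int((out.maternal != out.paternal).sum())
        assert abs(n_het - l * rate) < 3 * math.sqrt(l * rate)

    def test_invalid_rate_rejected(self, rng):
        g = generate_ancestral_genome(10, [0.25] * 4, rng)
        with pytest.raises(ValueError):
            add_germline_variants(g, 1.5, SubstitutionModel(), rng)


class TestMutationPlacement:
    def test_zero_mutations_empty(self, small_tree, rng):
        assert place_mutations_on_branches(small_tree, rng, n_mutations=0) == []

    def test_fixed_count_is_exact(self, small_tree, rng):
        pl = place_mutations_on_branches(small_tree, rng, n_mutations=100)
        assert sum(c for _, c in pl) == 100

    def test_branch_probabilities_proportional_to_length(self, small_tree):
        """Multinomial oracle: placement frequencies track branch lengths."""
        rng = np.random.default_rng(5)
        n = 10_000
        counts = {}
        for _ in range(n):
            for node, c in place_mutations_on_branches(
                small_tree, rng, n_mutations=1
            ):
                counts[node.id] = counts.get(node.id, 0) + c
        branches = [
            b for b in small_tree.preorder() if b.parent is not None
        ]
        lengths = np.array([b.branch_length for b in branches])
        expected = n * lengths / lengths.sum()
        observed = np.array([counts.get(b.id, 0) for b in branches])
        keep = expected > 5
        stat = chisquare(observed[keep], expected[keep] * observed[keep].sum() / expected[keep].sum())
        assert stat.pvalue > 0.001

    def test_negative_count_rejected(self, small_tree, rng):
        with pytest.raises(ValueError):
            place_mutations_on_branches(small_tree, rng, n_mutations=-1)


class TestIsmDiploid:
    def test_segregating_sites_equal_mutations(self, rng, constant_demography):
        tree = simulate_coalescent_genealogy(20, constant_demography, rng)
        genome = generate_ancestral_genome(100, [0.25] * 4, rng)
        pl = place_mutations_on_branches(tree, rng, n_mutations=100)
        res = evolve_ism_diploid(tree, genome, pl, rng)
        anc = genome.maternal[None, :]
        seg = (
            ((res.maternal != anc) & (res.maternal != DEL))
            | ((res.paternal != anc) & (res.paternal != DEL))
        ).any(axis=0)
        assert int(seg.sum()) == 100
        assert len(res.events) == 100

    def test_exhaustion_raises(self, rng, constant_demography):
        tree = simulate_coalescent_genealogy(5, constant_demography, rng)
        genome = generate_ancestral_genome(100, [0.25] * 4, rng)
        pl = place_mutations_on_branches(tree, rng, n_mutations=101)
        with pytest.raises(ISMExhaustedError):
            evolve_ism_diploid(tree, genome, pl, rng)

    def test_tip_branch_mutation_private_to_one_cell(self, rng, constant_demography):
        tree = simulate_coalescent_genealogy(6, constant_demography, rng)
        genome = generate_ancestral_genome(50, [0.25] * 4, rng)
        tip = tree.cell_tips()[2]
        res = evolve_ism_diploid(tree, genome, [(tip, 1)], rng)
        anc = genome.maternal[None, :]
        derived = (res.maternal != anc) | (res.paternal != anc)
        assert derived.sum() == 1
        assert derived[2].sum() == 1

    def test_rate_mode_matches_watterson(self, constant_demography):
        """Analytic oracle: E[S] = mu * 2 * sum 1/i under constant size."""
        rng = np.random.default_rng(17)
        mu, n = 4.0, 10
        totals = []
        for _ in range(3000):
            tree = simulate_coalescent_genealogy(n, constant_demography, rng)
            pl = place_mutations_on_branches(tree, rng, rate=mu)
            totals.append(sum(c for _, c in pl))
        totals = np.array(totals)
        se = totals.std(ddof=1) / math.sqrt(len(totals))
        assert abs(totals.mean() - expected_segregating_sites(n, mu)) < 3 * se

    def test_binary_ism_segregating_sites_despite_ancestral_ones(self, rng):
        """Binary ISM flips 0->1 only, so it must target zero-carrying sites
        even when the ancestor segregates 1s; every mutation stays visible."""
        tree = simulate_coalescent_genealogy(8, Demography.constant(1000), rng)
        genome = generate_ancestral_genome(
            50, [0.6, 0.4], rng, alphabet="binary"
        )
        pl = place_mutations_on_branches(tree, rng, n_mutations=15)
        res = evolve_ism_diploid(tree, genome, pl, rng)
        anc = genome.maternal[None, :]
        seg = ((res.maternal != anc) | (res.paternal != anc)).any(axis=0)
        assert int(seg.sum()) == 15

    def test_fixed_seed_reproducible(self, constant_demography):
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            tree = simulate_coalescent_genealogy(8, constant_demography, rng)
            genome = generate_ancestral_genome(60, [0.25] * 4, rng)
            pl = place_mutations_on_branches(tree, rng, n_mutations=30)
            res = evolve_ism_diploid(tree, genome, pl, rng)
            outs.append((res.maternal.tobytes(), res.paternal.tobytes()))
        assert outs[0] == outs[1]


class TestSignatures:
    def test_catalogue_loads_thirty_signatures(self):
        cat = load_signature_catalogue()
        assert cat.shape == (30, 96)
        assert np.allclose(cat.sum(axis=1), 1.0, atol=1e-6)
        assert list(cat.columns) == signature_channels()

    def test_degenerate_signature_hits_one_channel(self, rng, constant_demography):
        tree = simulate_coalescent_genealogy(5, constant_demography, rng)
        genome = generate_ancestral_genome(5000, [0.25] * 4, rng)
        sig = np.zeros(96)
        target = signature_channels().index("A[C>T]G")
        sig[target] = 1.0
        pl = place_mutations_on_branches(tree, rng, n_mutations=30)
        res = evolve_signature_mutations(tree, genome, sig, pl, rng)
        assert len(res.events) == 30
        assert all(ev.channel == target for ev in res.events)
        # events are C->T in ACG context or G->A in the reverse complement
        for ev in res.events:
            base = int(genome.maternal[ev.site])
            assert (base, ev.to_allele) in ((1, 3), (2, 0))

    def test_channel_frequencies_match_signature(self, constant_demography):
        """Multinomial oracle over a near-uniform-context genome."""
        rng = np.random.default_rng(13)
        tree = simulate_coalescent_genealogy(4, constant_demography, rng)
        genome = generate_ancestral_genome(60_000, [0.25] * 4, rng)
        sig = np.random.default_rng(1).dirichlet(np.full(96, 5.0))
        pl = place_mutations_on_branches(tree, rng, n_mutations=5000)
        res = evolve_signature_mutations(tree, genome, sig, pl, rng)
        observed = np.bincount([ev.channel for ev in res.events], minlength=96)
        keep = sig * 5000 > 5
        stat = chisquare(
            observed[keep],
            sig[keep] * observed[keep].sum() / sig[keep].sum(),
        )
        assert stat.pvalue > 0.001

    def test_no_available_context_errors(self, rng, constant_demography):
        tree = simulate_coalescent_genealogy(4, constant_demography, rng)
        genome = generate_ancestral_genome(200, [1.0, 0.0, 0.0, 0.0], rng)
        sig = np.zeros(96)
        sig[signature_channels().index("C[C>T]C")] = 1.0  # CCC context, all-A genome
        pl = place_mutations_on_branches(tree, rng, n_mutations=1)
        with pytest.raises(ValueError):
            evolve_signature_mutations(tree, genome, sig, pl, rng)


class TestFsm:
    def test_zero_time_identity(self):
        p = fsm_transition_matrix(SubstitutionModel.jc(), 0.0)
        assert np.allclose(p, np.eye(4))

    @pytest.mark.parametrize("t", [0.05, 0.3, 1.2])
    def test_jc_closed_form(self, t):
        p = fsm_transition_matrix(SubstitutionModel.jc(), t)
        diag = 0.25 + 0.75 * math.exp(-4 * t / 3)
        off = 0.25 - 0.25 * math.exp(-4 * t / 3)
        assert np.allclose(np.diag(p), diag)
        assert p[0, 1] == pytest.approx(off)

    def test_rows_sum_to_one_and_detailed_balance(self):
        pi = np.array([0.1, 0.2, 0.3, 0.4])
        r = np.array(
            [
                [0.0, 1.0, 2.0, 0.5],
                [1.0, 0.0, 0.7, 3.0],
                [2.0, 0.7, 0.0, 1.1],
                [0.5, 3.0, 1.1, 0.0],
            ]
        )
        model = SubstitutionModel.gtr(r, pi)
        q = build_rate_matrix(model)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        for i in range(4):
            for j in range(4):
                assert pi[i] * q[i, j] == pytest.approx(pi[j] * q[j, i])
        p = fsm_transition_matrix(model, 0.4)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_mk2_stationary_limit(self):
        p = fsm_transition_matrix(SubstitutionModel.mk2(), 50.0)
        assert np.allclose(p, 0.5, atol=1e-6)

    def test_nonreversible_stationary_frequencies(self):
        rates = np.random.default_rng(3).uniform(0.2, 2.0, (4, 4))
        np.fill_diagonal(rates, 0.0)
        model = SubstitutionModel.nonreversible(rates)
        p = fsm_transition_matrix(model, 100.0)
        for row in p:
            assert np.allclose(row, model.base_freqs, atol=1e-6)

    def test_zero_length_tree_preserves_ancestor(self, rng):
        from sccoalsim.genealogy import CellGenealogy, TreeNode

        root = TreeNode(id=0, time=0.0, label="sMRCA")
        for i in range(2):
            tip = TreeNode(id=i + 1, time=0.0, label="cell", name=f"cell{i + 1}")
            tip.parent = root
            root.children.append(tip)
        tree = CellGenealogy(root)
        genome = generate_ancestral_genome(200, [0.25] * 4, rng)
        res = evolve_fsm_along_tree(tree, genome, SubstitutionModel.jc(), rng)
        assert np.array_equal(res.maternal[0], genome.maternal)

    def test_long_branch_reaches_stationarity(self, rng, constant_demography):
        pi = np.array([0.1, 0.2, 0.3, 0.4])
        model = SubstitutionModel.hky(3.0, pi)
        tree = simulate_coalescent_genealogy(2, Demography.constant(10), rng)
        tree.smrca.time = 10.0  # stretch both tip branches
        l = 100_000
        genome = generate_ancestral_genome(l, pi, rng)
        res = evolve_fsm_along_tree(tree, genome, model, rng)
        freqs = np.bincount(res.maternal[0], minlength=4) / l
        for b in range(4):
            se = math.sqrt(pi[b] * (1 - pi[b]) / l)
            assert abs(freqs[b] - pi[b]) < 3 * se

    def test_gamma_site_rates_overdispersion(self, rng, constant_demography):
        """Rate mixing inflates the variance of per-site change indicators."""
        tree = simulate_coalescent_genealogy(2, Demography.constant(10), rng)
        tree.smrca.time = 0.5
        l = 40_000
        plain = generate_ancestral_genome(l, [0.25] * 4, rng)
        mixed = generate_ancestral_genome(
            l, [0.25] * 4, rng, gamma_site_alpha=0.1
        )
        model = SubstitutionModel.jc()
        res_p = evolve_fsm_along_tree(tree, plain, model, rng)
        res_m = evolve_fsm_along_tree(tree, mixed, model, rng)
        # both-tips-differ probability varies across sites under rate mixing,
        # so the fraction of changed sites is smaller (more sites frozen)
        changed_p = (res_p.maternal[0] != plain.maternal).mean()
        changed_m = (res_m.maternal[0] != mixed.maternal).mean()
        assert changed_m < changed_p


class TestCnlohAndDeletions:
    def _setup(self, rng, l=200):
        tree = simulate_coalescent_genealogy(6, Demography.constant(1000), rng)
        genome = generate_ancestral_genome(l, [0.25] * 4, rng)
        genome = add_germline_variants(
            genome, 1.0, SubstitutionModel(), rng
        )  # everything heterozygous
        return tree, genome

    def test_cnloh_makes_site_homozygous(self, rng):
        tree, genome = self._setup(rng)
        res = apply_cnloh(tree, genome, rng, n_events=50)
        for ev in res.events:
            assert ev.kind == "cnLOH"
            # at descendant tips the site carries one of the two parental alleles twice
        hom_sites = 0
        for ev in res.events:
            carriers = (
                res.maternal[:, ev.site] == res.paternal[:, ev.site]
            )
            if carriers.any():
                hom_sites += 1
        assert hom_sites > 0

    def test_cnloh_copies_either_haplotype_evenly(self):
        rng = np.random.default_rng(6)
        tree, genome = self._setup(rng, l=4000)
        res = apply_cnloh(tree, genome, rng, n_events=2000)
        took_maternal = sum(1 for ev in res.events if ev.haplotype == 1)
        # haplotype choice is uniform: the overwritten copy is maternal or
        # paternal with probability 1/2 each
        assert abs(took_maternal - 1000) < 3 * math.sqrt(2000 * 0.25)

    def test_cnloh_at_homozygous_site_is_silent(self, rng):
        tree = simulate_coalescent_genealogy(4, Demography.constant(1000), rng)
        genome = generate_ancestral_genome(50, [0.25] * 4, rng)  # homozygous
        res = apply_cnloh(tree, genome, rng, n_events=20)
        assert np.array_equal(res.maternal, res.paternal)
        assert np.all(res.maternal == genome.maternal[None, :])

    def test_haploid_ism_no_repeat(self, rng):
        tree, genome = self._setup(rng, l=30)
        res = apply_cnloh(tree, genome, rng, n_events=60)  # exactly 2l slots
        slots = [(ev.site, ev.haplotype) for ev in res.events]
        assert len(slots) == len(set(slots)) == 60
        with pytest.raises(ISMExhaustedError):
            apply_cnloh(tree, genome, rng, n_events=61)

    def test_deletion_marks_descendants(self, rng):
        tree, genome = self._setup(rng)
        res = apply_deletions(tree, genome, rng, n_events=40)
        assert all(ev.to_allele == DEL for ev in res.events)
        assert ((res.maternal == DEL) | (res.paternal == DEL)).any()

    def test_zero_deletions_noop(self, rng):
        tree, genome = self._setup(rng)
        res = apply_deletions(tree, genome, rng, n_events=0)
        assert not (res.maternal == DEL).any()

    def test_both_haplotypes_deleted_possible(self):
        rng = np.random.default_rng(8)
        tree = simulate_coalescent_genealogy(4, Demography.constant(1000), rng)
        genome = generate_ancestral_genome(3, [0.25] * 4, rng)
        res = apply_deletions(tree, genome, rng, n_events=6)  # all slots
        assert ((res.maternal == DEL) & (res.paternal == DEL)).any()


class TestEvolveGenotypes:
    def test_combined_pipeline_event_ordering(self, rng):
        tree = simulate_coalescent_genealogy(6, Demography.constant(1000), rng)
        genome = generate_ancestral_genome(100, [0.25] * 4, rng)
        model = SubstitutionModel(fixed_mutations=20)
        res = evolve_genotypes(tree, genome, model, rng, n_cnloh=5, n_deletions=5)
        kinds = {ev.kind for ev in res.events}
        assert kinds == {"SNV", "cnLOH", "deletion"}
        assert len(res.events) == 30
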