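import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kendalltau as scipy_kendalltau

from pcadea import (
    SyntheticScenario,
    condition_concordance_matrix,
    generate_condition_family,
    generate_planted_frontier,
    influence_panel,
    kendall_tau,
    trait_influence,
    valency,
    valency_panel,
)
from pcadea.rank_stats import _efficiencies

from oracles import kendall_tau_a_brute


def single_efficient_scenario(seed=5, s=8):
    """One planted efficient accession and distinct factors: tie-free thetas."""
    return SyntheticScenario(
        seed=seed, s=s, m=3, n=2,
        planted_efficient=("acc01",),
        inefficiency_factors=tuple(1.3 + 0.15 * i for i in range(s - 1)),
        trait_redundancy=0, noise_sd=0.0, conditions=2,
        perturbation_strengths=(0.0, 0.1),
    )


class TestKendallTau:
    def test_worked_pair_taxonomy(self):
        c = kendall_tau([1, 2, 3], [1, 3, 2], p_method="normal")
        assert c.tau == pytest.approx(1 / 3)
        assert (c.concordant, c.discordant, c.tied) == (2, 1, 0)
        c2 = kendall_tau([1, 1, 2], [1, 2, 3], p_method="normal")
        assert c2.tau == pytest.approx(2 / 3)
        assert (c2.concordant, c2.discordant, c2.tied) == (2, 0, 1)

    def test_perfect_agreement_and_reversal(self, rng):
        e = rng.permutation(10).astype(float)  # tie-free
        assert kendall_tau(e, e, p_method="normal").tau == 1.0
        assert kendall_tau(e, -e, p_method="normal").tau == -1.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=12),
        st.integers(0, 10_000),
    )
    def test_matches_brute_force_with_ties(self, xs, seed):
        rng = np.random.default_rng(seed)
        x = np.array(xs, float)
        y = rng.integers(0, 4, size=len(x)).astype(float)
        c = kendall_tau(x, y, p_method="normal")
        tau_b, cb, db, tb = kendall_tau_a_brute(x, y)
        assert c.tau == pytest.approx(tau_b, abs=1e-12)
        assert (c.concordant, c.discordant, c.tied) == (cb, db, tb)
        assert c.concordant + c.discordant + c.tied == len(x) * (len(x) - 1) // 2

    def test_tau_b_option_agrees_with_scipy(self, rng):
        x = rng.integers(0, 5, 15).astype(float)
        y = rng.integers(0, 5, 15).astype(float)
        ours = kendall_tau(x, y, variant="tau-b", p_method="normal").tau
        ref = scipy_kendalltau(x, y).statistic
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_permutation_p_value_reproducible_and_sane(self, rng):
        x = rng.normal(size=12)
        y = x + rng.normal(scale=0.3, size=12)
        a = kendall_tau(x, y, seed=3, n_permutations=2000)
        b = kendall_tau(x, y, seed=3, n_permutations=2000)
        assert a.p_value == b.p_value
        assert a.p_value < 0.05 and a.significant
        null = kendall_tau(x, rng.normal(size=12), seed=4, n_permutations=500)
        assert 0 < null.p_value <= 1

    def test_input_validation(self):
        with pytest.raises(ValueError, match="length"):
            kendall_tau([1, 2], [1, 2, 3])
        with pytest.raises(ValueError, match="two items"):
            kendall_tau([1.0], [2.0])


class TestTraitInfluence:
    def test_constant_trait_removal_changes_nothing(self):
        inst, _ = generate_planted_frontier(single_efficient_scenario())
        X = np.vstack([inst.X, np.full(inst.n_accessions, 4.2)])
        from pcadea import DEAInstance

        inst2 = DEAInstance(
            inst.accession_ids, X, inst.Y,
            inst.input_trait_names + ("flat",), inst.output_trait_names,
        )
        e_with = _efficiencies(inst2, 0.85, "covariance", 1e-6)
        e_without = _efficiencies(inst2.drop_input_trait("flat"), 0.85, "covariance", 1e-6)
        assert np.allclose(e_with, e_without, atol=1e-9)
        res = trait_influence(inst2, "flat", threshold=0.85, seed=0, n_permutations=200)
        assert res.tau_without == pytest.approx(1.0)

    def test_influential_trait_lowers_tau(self):
        # the second input trait is all that separates C from the frontier:
        # with it, C can only reach 1.5 output units (theta 1.25); without
        # it every accession shares the same input and the frontier moves,
        # reordering the A-C pair, so the with/without tau drops below 1
        from pcadea import DEAInstance

        inst = DEAInstance(
            ("A", "B", "C"),
            X=[[1.2, 1.0, 1.15], [1.0, 3.0, 2.0]],
            Y=[[1.0, 2.0, 1.2]],
            input_trait_names=("x1", "x2"),
            output_trait_names=("y",),
        )
        # by hand: with x2, the x2 row pins A at theta 1 and caps C's
        # reference mix at lambda_A = 0.5, so theta = 1.5/1.2 = 1.25
        e_full = _efficiencies(inst, 1.0, "covariance", 1e-6)
        assert np.allclose(e_full, [1.0, 1.0, 1.25], atol=1e-8)
        # without x2, B (output 2) is affordable for A and C alike
        e_red = _efficiencies(inst.drop_input_trait("x2"), 1.0, "covariance", 1e-6)
        assert np.allclose(e_red, [2.0, 1.0, 2.0 / 1.2], atol=1e-8)
        res = trait_influence(inst, "x2", threshold=1.0, seed=0, n_permutations=200)
        assert res.tau_without < 1.0

    def test_self_consistency_with_independent_reruns(self):
        inst, _ = generate_planted_frontier(single_efficient_scenario(seed=2))
        trait = inst.input_trait_names[0]
        res = trait_influence(inst, trait, threshold=0.9, seed=1, n_permutations=200)
        e_full = _efficiencies(inst, 0.9, "covariance", 1e-6)
        e_red = _efficiencies(inst.drop_input_trait(trait), 0.9, "covariance", 1e-6)
        again = kendall_tau(e_full, e_red, p_method="normal")
        assert res.tau_without == pytest.approx(again.tau, abs=1e-12)

    def test_two_inputs_reduce_to_one(self):
        scenario = SyntheticScenario(
            seed=1, s=6, m=2, n=2, planted_efficient=("acc01", "acc02"),
            inefficiency_factors=(1.5, 1.7, 1.9, 2.1),
            trait_redundancy=0, noise_sd=0.0, conditions=2,
            perturbation_strengths=(0.0, 0.1),
        )
        inst, _ = generate_planted_frontier(scenario)
        res = trait_influence(inst, inst.input_trait_names[0], threshold=0.85,
                              seed=0, n_permutations=100)
        assert -1 <= res.tau_without <= 1

    def test_unknown_trait_and_single_input_rejected(self):
        inst, _ = generate_planted_frontier(single_efficient_scenario())
        with pytest.raises(KeyError):
            trait_influence(inst, "no_such_trait", threshold=0.85)
        single = inst.drop_input_trait(inst.input_trait_names[0])
        single = single.drop_input_trait(single.input_trait_names[0])
        with pytest.raises(ValueError, match="only input"):
            single.drop_input_trait(single.input_trait_names[0])

    def test_panel_orders_by_ascending_tau(self):
        inst, _ = generate_planted_frontier(single_efficient_scenario(seed=3))
        panel = influence_panel(inst, threshold=0.85, seed=0, n_permutations=100)
        assert sorted(r.rank_position for r in panel) == list(range(1, len(panel) + 1))
        by_rank = sorted(panel, key=lambda r: r.rank_position)
        taus = [r.tau_without for r in by_rank]
        assert taus == sorted(taus)


class TestValency:
    def test_identical_conditions_have_zero_valency(self):
        inst, _ = generate_planted_frontier(single_efficient_scenario(seed=4))
        res = valency(inst, inst, inst.input_trait_names[0], threshold=0.85,
                      seed=0, n_permutations=100)
        assert res.phi == 0.0
        assert res.base_tau == res.reduced_tau

    def test_phi_bounds_and_symmetry(self):
        scenario = SyntheticScenario(
            seed=6, s=9, m=4, n=3,
            planted_efficient=tuple(f"acc{i:02d}" for i in range(1, 5)),
            inefficiency_factors=(1.4, 1.6, 1.8, 2.0, 2.2),
            trait_redundancy=1, noise_sd=0.05, conditions=2,
            perturbation_strengths=(0.0, 0.2),
        )
        fam = generate_condition_family(scenario)
        c1, c2 = fam["C1"], fam["C2"]
        for trait in c1.input_trait_names[:2]:
            fwd = valency(c1, c2, trait, threshold=0.85, seed=0, n_permutations=100)
            rev = valency(c2, c1, trait, threshold=0.85, seed=0, n_permutations=100)
            assert 0 <= fwd.phi <= 2
            assert fwd.phi == pytest.approx(rev.phi, abs=1e-12)
            assert fwd.phi == pytest.approx(abs(fwd.base_tau - fwd.reduced_tau), abs=1e-15)

    def test_scrambled_trait_attains_maximal_valency(self):
        scenario = SyntheticScenario(
            seed=11, s=14, m=5, n=4,
            planted_efficient=tuple(f"acc{i:02d}" for i in range(1, 5)),
            inefficiency_factors=tuple(1.4 + 0.1 * i for i in range(10)),
            trait_redundancy=4, noise_sd=0.0, conditions=2,
            perturbation_strengths=(0.0, 0.0), scramble_trait="met1",
        )
        fam = generate_condition_family(scenario)
        panel = valency_panel(fam["C1"], fam["C2"], threshold=1.0, seed=0,
                              n_permutations=100)
        phis = {r.trait: r.phi for r in panel}
        assert panel[0].trait == "met1"
        assert phis["met1"] > 0
        # all other traits are exact duplicates of each other: removing one
        # leaves both conditions' tables informationally unchanged
        assert all(v == pytest.approx(0.0, abs=1e-9) for t, v in phis.items() if t != "met1")

    def test_accession_mismatch_reported(self):
        inst, _ = generate_planted_frontier(single_efficient_scenario())
        from pcadea import DEAInstance

        other = DEAInstance(
            tuple(f"z{i}" for i in range(inst.n_accessions)), inst.X, inst.Y,
            inst.input_trait_names, inst.output_trait_names,
        )
        with pytest.raises(ValueError, match="differ"):
            valency(inst, other, inst.input_trait_names[0], threshold=0.85)


class TestConcordanceMatrix:
    def test_identical_conditions_fully_concordant(self):
        inst, _ = generate_planted_frontier(single_efficient_scenario(seed=7))
        conc = condition_concordance_matrix(
            {"A": inst, "B": inst}, threshold=0.85, seed=0, n_permutations=100
        )
        assert np.allclose(np.diag(conc.tau), 1.0)
        assert conc.tau[0, 1] == pytest.approx(1.0)  # tie-free by construction
        assert conc.fully_efficient_counts == {"A": 1, "B": 1}

    def test_tau_decreases_with_perturbation_strength(self):
        scenario = SyntheticScenario(
            seed=8, s=12, m=4, n=3,
            planted_efficient=tuple(f"acc{i:02d}" for i in range(1, 6)),
            inefficiency_factors=tuple(1.4 + 0.12 * i for i in range(7)),
            trait_redundancy=1, noise_sd=0.03, conditions=3,
            perturbation_strengths=(0.0, 0.08, 0.5),
        )
        fam = generate_condition_family(scenario)
        conc = condition_concordance_matrix(fam, threshold=0.85, seed=0, n_permutations=100)
        i = conc.labels.index("C1")
        mild = conc.tau[i, conc.labels.index("C2")]
        strong = conc.tau[i, conc.labels.index("C3")]
        assert strong < mild

    def test_needs_two_conditions(self):
        inst, _ = generate_planted_frontier(single_efficient_scenario())
        with pytest.raises(ValueError, match="two conditions"):
            condition_concordance_matrix({"A": inst}, threshold=0.85)
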