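"""Birth--death gene-count likelihood and WGD hypothesis scoring."""

import math

import numpy as np
import pandas as pd
import pytest

from paleodup import cornus, synthetic_data as sd, wgd_placement as wp


# -- independent oracles -----------------------------------------------------


def gillespie_bd(rng, n0, lam, mu, t):
    """Event-by-event simulation of the linear birth--death process."""
    n, clock = n0, 0.0
    while n > 0:
        rate = n * (lam + mu)
        if rate == 0:
            break
        clock += rng.exponential(1.0 / rate)
        if clock > t:
            break
        n += 1 if rng.random() < lam / (lam + mu) else -1
    return n


def brute_force_tree_loglik(counts, t_left, t_right, lam, mu, events_q=None, nmax=10):
    """Exhaustive enumeration for a two-leaf tree rooted with one copy.

    P(data) = sum over nothing: root -> leaf transitions are independent
    given the root state (fixed at 1).  ``events_q`` optionally applies a
    retention-q WGD halfway down the left branch.
    """
    def p(i, j, t):
        return wp.bdp_transition_prob(i, j, t, lam, mu)

    def p_left(j):
        if events_q is None:
            return p(1, j, t_left)
        total = 0.0
        for mid in range(nmax + 1):
            pre = p(1, mid, t_left / 2)
            for extra in range(mid + 1):
                w = math.comb(mid, extra) * events_q**extra * (1 - events_q) ** (
                    mid - extra
                )
                total += pre * w * p(mid + extra, j, t_left / 2)
        return total

    return math.log(p_left(counts[0])) + math.log(p(1, counts[1], t_right))


# -- transition probabilities ------------------------------------------------


class TestTransitionProb:
    def test_zero_time_is_identity(self):
        for i in range(4):
            for j in range(4):
                expect = 1.0 if i == j else 0.0
                assert wp.bdp_transition_prob(i, j, 0.0, 0.1, 0.2) == expect

    def test_zero_rates_identity_for_all_t(self):
        assert wp.bdp_transition_prob(3, 3, 50.0, 0.0, 0.0) == 1.0
        assert wp.bdp_transition_prob(3, 2, 50.0, 0.0, 0.0) == 0.0

    def test_rows_sum_to_one(self):
        for i in (1, 2, 5):
            total = sum(
                wp.bdp_transition_prob(i, j, 10.0, 0.01, 0.015) for j in range(400)
            )
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_matches_gillespie_monte_carlo(self):
        # i=1, lambda=mu=0.002, t=1 (per-myr rates over 1 myr) and a longer
        # 80-myr branch; 1e5 replicates, agreement within 3 SE
        rng = np.random.default_rng(7)
        n_rep = 100_000
        for t in (1.0, 80.0):
            draws = np.array(
                [gillespie_bd(rng, 1, 0.002, 0.002, t) for _ in range(n_rep)]
            )
            for j in range(6):
                theo = wp.bdp_transition_prob(1, j, t, 0.002, 0.002)
                emp = (draws == j).mean()
                se = math.sqrt(max(theo * (1 - theo), 1e-12) / n_rep)
                assert abs(emp - theo) <= 3 * se + 1e-6

    def test_unequal_rates_limit_form_continuity(self):
        # lambda ~= mu must approach the lambda == mu limit smoothly
        close = wp.bdp_transition_prob(1, 2, 10.0, 0.01, 0.01 + 1e-13)
        equal = wp.bdp_transition_prob(1, 2, 10.0, 0.01, 0.01)
        assert close == pytest.approx(equal, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wp.bdp_transition_prob(-1, 0, 1.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            wp.bdp_transition_prob(1, 0, -1.0, 0.1, 0.1)


# -- gene count loading ------------------------------------------------------


class TestGeneCounts:
    def test_presence_filter(self):
        counts = pd.DataFrame(
            {
                "CAL": [1, 2, 0],
                "CCO": [0, 1, 1],
                "ACH": [1, 1, 0],
                "DFE": [0, 0, 1],
            },
            index=["f1", "f2", "f3"],
        )
        kept, removed = wp.filter_gene_counts(counts)
        # f1: one Cornus species only -> removed; f2: 2 Cornus + ACH -> kept;
        # f3: 2 Cornus... only CCO -> removed
        assert list(kept.index) == ["f2"] and removed == 2

    def test_filter_matches_brute_force(self):
        rng = np.random.default_rng(0)
        cols = list(cornus.CORNUS_SPECIES) + list(cornus.OUTGROUPS)
        counts = pd.DataFrame(
            rng.integers(0, 3, size=(200, 10)), columns=cols
        )
        kept, removed = wp.filter_gene_counts(counts)
        expect = [
            i
            for i in range(200)
            if (counts.iloc[i][list(cornus.CORNUS_SPECIES)] > 0).sum() >= 2
            and (counts.iloc[i][list(cornus.OUTGROUPS)] > 0).sum() >= 1
        ]
        assert list(kept.index) == expect
        assert removed == 200 - len(expect)

    def test_load_from_membership_tsv(self, tmp_path):
        path = tmp_path / "og.tsv"
        path.write_text(
            "f1\tCALg1,CALg2,ACHg1\n"  # one Cornus species only -> filtered
            "f2\tCALg1,CCOg1,ACHg1\n"
        )
        smap = {"CALg1": "CAL", "CALg2": "CAL", "CCOg1": "CCO", "ACHg1": "ACH"}
        kept, removed = wp.load_gene_counts(str(path), smap)
        assert list(kept.index) == ["f2"] and removed == 1
        assert kept.loc["f2", "CAL"] == 1
        with pytest.raises(KeyError):
            wp.load_gene_counts(str(path), {"CALg1": "CAL"})


# -- pruning likelihood ------------------------------------------------------


class TestFamilyLoglik:
    def test_star_counts_of_one_with_frozen_process(self, species_tree):
        row = pd.Series({lab: 1 for lab in species_tree.leaf_labels})
        assert wp.family_loglik(species_tree, row, 0.0, 0.0, condition="none") == 0.0

    def test_certain_doubling_single_branch(self, species_tree):
        row = {lab: 1 for lab in species_tree.leaf_labels}
        for spp in cornus.CORNUS_SPECIES:
            row[spp] = 2
        ll = wp.family_loglik(
            species_tree,
            pd.Series(row),
            0.0,
            0.0,
            events=((frozenset(cornus.CORNUS_SPECIES), 1.0),),
            condition="none",
        )
        assert ll == pytest.approx(0.0)

    @pytest.mark.parametrize("q", [None, 0.0, 0.4, 1.0])
    def test_two_leaf_tree_matches_enumeration(self, q):
        tree = wp.SpeciesTree("(CAL:30.0,CCO:30.0);", ingroup=("CAL", "CCO"),
                              outgroups=())
        lam, mu = 0.004, 0.003
        events = () if q is None else ((frozenset({"CAL"}), q),)
        for ca in range(3):
            for cb in range(3):
                row = pd.Series({"CAL": ca, "CCO": cb})
                got = wp.family_loglik(
                    tree, row, lam, mu, events=events, condition="none"
                )
                want = brute_force_tree_loglik(
                    (ca, cb), 30.0, 30.0, lam, mu,
                    events_q=None if q is None else q,
                )
                assert got == pytest.approx(want, abs=1e-9)

    def test_truncation_bound_exceeded(self, species_tree):
        row = pd.Series({lab: 1 for lab in species_tree.leaf_labels})
        row["CAL"] = 99
        with pytest.raises(ValueError, match="truncation"):
            wp.family_loglik(species_tree, row, 0.001, 0.001)

    def test_root_event_rejected(self, species_tree):
        row = pd.Series({lab: 1 for lab in species_tree.leaf_labels})
        full = frozenset(species_tree.leaf_labels)
        with pytest.raises(ValueError, match="root"):
            wp.family_loglik(species_tree, row, 0.001, 0.001, events=((full, 0.5),))


class TestObservabilityProb:
    def test_certain_observation_when_nothing_changes(self, species_tree):
        # frozen process keeps the single copy everywhere: filter always passes
        p = wp.observability_prob(species_tree, 0.0, 0.0, (), kmax=10)
        assert p == pytest.approx(1.0)

    def test_matches_simulation(self, species_tree):
        lam = mu = 0.003
        p = wp.observability_prob(species_tree, lam, mu, (), kmax=20)
        counts = sd.simulate_gene_counts(
            cornus.SPECIES_TREE_NEWICK, lam, mu, n_families=40000, seed=9
        )
        _kept, removed = wp.filter_gene_counts(counts)
        emp = 1.0 - removed / 40000
        assert abs(emp - p) < 4 * math.sqrt(p * (1 - p) / 40000) + 1e-3

    def test_conditioning_normalises_the_likelihood(self, species_tree):
        # summed over all observable patterns, conditioned probabilities = 1;
        # spot-check: conditioned logL exceeds unconditioned logL
        row = pd.Series({lab: 1 for lab in species_tree.leaf_labels})
        lam = mu = 0.002
        cond = wp.family_loglik(species_tree, row, lam, mu, condition="filter")
        unc = wp.family_loglik(species_tree, row, lam, mu, condition="none")
        assert cond > unc


# -- hypothesis testing ------------------------------------------------------


class TestHypotheses:
    def test_single_hypothesis_weight_one(self, species_tree):
        counts = sd.simulate_gene_counts(
            cornus.SPECIES_TREE_NEWICK, 0.002, 0.002,
            wgd=[(frozenset(cornus.CORNUS_SPECIES), 0.2)],
            n_families=300, seed=3,
        )
        kept, _ = wp.filter_gene_counts(counts)
        res = wp.test_hypotheses(
            species_tree, kept, hypotheses={"H2": cornus.HYPOTHESES["H2"]}
        )
        assert len(res) == 1 and res[0].akaike_weight == pytest.approx(1.0)

    def test_akaike_weights_sum_to_one(self, species_tree):
        counts = sd.simulate_gene_counts(
            cornus.SPECIES_TREE_NEWICK, 0.002, 0.002,
            wgd=[(frozenset(cornus.CORNUS_SPECIES), 0.2)],
            n_families=400, seed=4,
        )
        kept, _ = wp.filter_gene_counts(counts)
        res = wp.test_hypotheses(
            species_tree, kept,
            hypotheses={k: cornus.HYPOTHESES[k] for k in ("H1", "H2", "H4")},
        )
        assert sum(r.akaike_weight for r in res) == pytest.approx(1.0)

    def test_no_wgd_data_infers_zero_retention(self, species_tree):
        counts = sd.simulate_gene_counts(
            cornus.SPECIES_TREE_NEWICK, 0.002, 0.002, n_families=1500, seed=5
        )
        kept, _ = wp.filter_gene_counts(counts)
        res = wp.test_hypotheses(
            species_tree, kept,
            hypotheses={k: cornus.HYPOTHESES[k] for k in ("H1", "H2")},
        )
        for r in res:
            assert all(q == 0.0 for _c, q in r.events)

    def test_empty_counts_rejected(self, species_tree):
        with pytest.raises(ValueError):
            wp.test_hypotheses(species_tree, pd.DataFrame())


class TestSpeciesTree:
    def test_non_ultrametric_rejected(self):
        with pytest.raises(ValueError, match="ultrametric"):
            wp.SpeciesTree("(A:10,B:20);")

    def test_branch_lookup(self, species_tree):
        idx = species_tree.branch(cornus.BW_GROUP)
        assert species_tree.nodes[idx].clade == frozenset(cornus.BW_GROUP)
        with pytest.raises(KeyError):
            species_tree.branch({"CAL", "CFL"})  # not a clade of the tree
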