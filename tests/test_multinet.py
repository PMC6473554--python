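"""SHD penalty, lambda odds, IEMN/MEMN posteriors and lambda selection."""

import math

import numpy as np
import pytest
from scipy.special import logsumexp

from mdmgroup import (
    GroupStudy,
    PriorPolicy,
    full_powerset_log_normalizer,
    iemn,
    lambda_odds,
    memn_group,
    memn_individual,
    memn_subgroup,
    penalty_log_prior,
    predicted_network,
    select_lambda,
    shd_parent_sets,
)
from mdmgroup.clustering import SubgroupAssignment
from mdmgroup.groups import cs_scores
from mdmgroup.search import ScoreTable, search_network
from mdmgroup.simulate import _preset, simulate_group

from conftest import make_series


def all_in_one(S):
    return SubgroupAssignment(labels=(1,) * S, singleton=(False,) * S)


class TestShdParentSets:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({2, 3}, {2, 3}, 0),
            (set(), {2, 3}, 2),
            ({1, 2}, {2, 4}, 2),
            (0b110, 0b110, 0),
            (0, 0b1100, 2),
        ],
    )
    def test_symmetric_difference(self, a, b, expected):
        assert shd_parent_sets(a, b) == expected
        assert shd_parent_sets(b, a) == expected


class TestLambdaOdds:
    def test_zero(self):
        prob, odds = lambda_odds(0.0)
        assert prob == 0.5 and odds == 1.0

    @pytest.mark.parametrize(
        "lam,odds", [(0.7, math.exp(0.7)), (3.0, math.exp(3.0)), (5.0, math.exp(5.0))]
    )
    def test_odds_is_exp_lambda(self, lam, odds):
        prob, got = lambda_odds(lam)
        assert got == pytest.approx(odds, rel=1e-12)
        assert prob == pytest.approx(got / (1 + got), rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lambda_odds(-0.1)


class TestPenaltyLogPrior:
    def test_lambda_zero_uniform(self):
        masks = [0, 1, 2, 3]
        logs = penalty_log_prior(masks, center=2, lam=0.0)
        np.testing.assert_allclose(logs, -math.log(4))

    def test_closed_form_normalizer_full_powerset(self):
        """n-1 = 3 candidate parents: normaliser equals 3*log(1+e^-lambda)."""
        masks = [m << 1 for m in range(8)]  # all subsets of {1,2,3} for node 0
        lam = 1.0
        raw = -lam * np.array([bin(m ^ 0b10).count("1") for m in masks], float)
        direct = logsumexp(raw)
        assert direct == pytest.approx(full_powerset_log_normalizer(4, lam), abs=1e-12)
        logs = penalty_log_prior(masks, center=0b10, lam=lam)
        np.testing.assert_allclose(logs, raw - direct, atol=1e-12)

    def test_distance_one_gap_is_lambda(self):
        masks = [0, 0b10, 0b100, 0b110]
        lam = 1.7
        logs = penalty_log_prior(masks, center=0b10, lam=lam)
        assert logs[1] - logs[0] == pytest.approx(lam, abs=1e-12)


def _toy_tables(rng, n, S, offset=0.0, max_parents=None):
    """Fabricated per-subject score tables (full parent spaces)."""
    max_parents = n - 1 if max_parents is None else max_parents
    from itertools import combinations

    from mdmgroup.search import set_to_mask

    per_subject = []
    for i in range(S):
        tabs = []
        for r in range(n):
            others = [j for j in range(n) if j != r]
            scores = {}
            for size in range(max_parents + 1):
                for combo in combinations(others, size):
                    scores[set_to_mask(combo)] = float(rng.normal() + offset)
            tabs.append(ScoreTable(f"s{i}", r, n, max_parents, scores))
        per_subject.append(tabs)
    return per_subject


class _TableStudy:
    """Duck-typed study over fabricated tables (no raw data needed)."""

    def __init__(self, per_subject):
        self._tabs = per_subject
        self.S = len(per_subject)
        self.n = per_subject[0][0].n
        self.subjects = [
            type("s", (), {"subject_id": f"s{i}"})() for i in range(self.S)
        ]

    def tables(self, i):
        return self._tabs[i]

    def subset(self, members):
        return _TableStudy([self._tabs[i] for i in members])


def brute_individual_posterior(tabs_i, tabs_others, r, lam):
    """Triple exhaustive summation of the penalised individual posterior."""
    masks = tabs_i[r].masks()
    K = len(masks)
    lognorm = {
        q: logsumexp([-lam * bin(p ^ q).count("1") for p in masks]) for q in masks
    }
    out = np.full(K, -np.inf)
    for a, P in enumerate(masks):
        terms = []
        for Q in masks:
            t = tabs_i[r].scores[P] - lam * bin(P ^ Q).count("1") - lognorm[Q]
            for tabs_k in tabs_others:
                t += logsumexp(
                    [
                        tabs_k[r].scores[Pk] - lam * bin(Pk ^ Q).count("1") - lognorm[Q]
                        for Pk in masks
                    ]
                )
            terms.append(t)
        out[a] = logsumexp(terms)
    return out - logsumexp(out)


def brute_center_posterior(member_tabs, r, lam):
    masks = member_tabs[0][r].masks()
    lognorm = {
        q: logsumexp([-lam * bin(p ^ q).count("1") for p in masks]) for q in masks
    }
    out = []
    for Q in masks:
        t = 0.0
        for tabs in member_tabs:
            t += logsumexp(
                [
                    tabs[r].scores[P] - lam * bin(P ^ Q).count("1") - lognorm[Q]
                    for P in masks
                ]
            )
        out.append(t)
    out = np.array(out)
    return out - logsumexp(out)


class TestMemnOracles:
    @pytest.mark.parametrize("lam", [0.3, 1.0, 5.0])
    @pytest.mark.parametrize("offset", [0.0, -500.0])
    def test_individual_posterior_matches_exhaustive_sum(self, rng, lam, offset):
        """n=3, S_g=2: the penalised individual posterior equals brute-force triple
        summation (log-space tolerance 1e-8), also at LPL-like magnitudes."""
        per_subject = _toy_tables(rng, 3, 2, offset=offset)
        study = _TableStudy(per_subject)
        _, posts = memn_individual(study, all_in_one(2), lam)
        for i in range(2):
            others = [per_subject[k] for k in range(2) if k != i]
            for r in range(3):
                oracle = brute_individual_posterior(
                    per_subject[i], others, r, lam
                )
                np.testing.assert_allclose(
                    posts[i][r].log_posterior, oracle, atol=1e-8
                )

    @pytest.mark.parametrize("lam", [0.5, 2.0])
    def test_center_posteriors_match_exhaustive_sum(self, rng, lam):
        per_subject = _toy_tables(rng, 3, 3)
        study = _TableStudy(per_subject)
        _, posts = memn_subgroup(study, all_in_one(3), lam)
        for r in range(3):
            oracle = brute_center_posterior(per_subject, r, lam)
            np.testing.assert_allclose(posts[0][r].log_posterior, oracle, atol=1e-8)
        _, gposts = memn_group(study, lam)
        for r in range(3):
            oracle = brute_center_posterior(per_subject, r, lam)
            np.testing.assert_allclose(gposts[r].log_posterior, oracle, atol=1e-8)


class TestLambdaLimits:
    def test_lambda_zero_individuals_equal_iemn(self, tiny_study):
        assignment = all_in_one(tiny_study.S)
        res_i = iemn(tiny_study, assignment)
        nets0, _ = memn_individual(tiny_study, assignment, 0.0)
        assert all(a == b for a, b in zip(res_i.individual, nets0))

    def test_huge_lambda_homogenises_subgroup(self, tiny_study, tiny_bundle):
        labels = tiny_bundle.labels
        assignment = SubgroupAssignment(
            labels=labels, singleton=(False,) * len(labels)
        )
        nets, _ = memn_individual(tiny_study, assignment, 1000.0)
        for g in range(1, assignment.G + 1):
            members = assignment.members(g)
            assert len({nets[i].parents for i in members}) == 1

    def test_huge_lambda_group_approaches_summed_score_argmax(self):
        """As lambda grows the group centre tends to the summed-table
        (common-structure) network."""
        spec = _preset(
            3, n=5, T=200, n_groups=1, subjects_per_group=4,
            n_mutations=2, min_shd=1, max_in_degree=2,
        )
        bundle = simulate_group(spec)
        study = GroupStudy.from_bundle(
            bundle, policy=PriorPolicy(delta_grid=(1.0,)), max_parents=2
        )
        cs_net = search_network(cs_scores(study))
        net, _ = memn_group(study, 1000.0)
        assert net.parents == cs_net.parents


class TestSelectionAndPrediction:
    def test_single_value_grid(self, tiny_study):
        lam, report = select_lambda(tiny_study, all_in_one(tiny_study.S), [0.7])
        assert lam == 0.7 and len(report) == 1

    def test_report_covers_grid_and_ties_take_smallest(self, rng):
        per_subject = _toy_tables(rng, 3, 2)
        study = _TableStudy(per_subject)
        lam, report = select_lambda(
            study, all_in_one(2), [0.1, 0.7], criterion="max_group_posterior"
        )
        assert [row["lambda"] for row in report] == [0.1, 0.7]
        best = max(r["criterion"] for r in report)
        winners = [r["lambda"] for r in report if r["criterion"] == best]
        assert lam == min(winners)

    def test_criterion_recomputed_independently(self, rng):
        """Individual-posterior criterion equals a direct recomputation."""
        per_subject = _toy_tables(rng, 3, 2)
        study = _TableStudy(per_subject)
        lam = 0.7
        _, report = select_lambda(
            study, all_in_one(2), [lam], criterion="max_individual_posterior"
        )
        nets, posts = memn_individual(study, all_in_one(2), lam)
        expected = 0.0
        for net, node_posts in zip(nets, posts):
            for r, post in enumerate(node_posts):
                idx = list(post.masks).index(net.parents[r])
                expected += post.log_posterior[idx]
        assert report[0]["criterion"] == pytest.approx(expected, abs=1e-10)

    def test_cross_validation_criterion_runs(self, tiny_study):
        lam, report = select_lambda(
            tiny_study, all_in_one(tiny_study.S), [0.1, 10.0],
            criterion="cross_validation",
        )
        assert lam in (0.1, 10.0)
        assert all(np.isfinite(r["criterion"]) for r in report)

    def test_predicted_network_two_subject_reduction(self, rng, fast_policy):
        a = make_series(rng.normal(size=(80, 3)), "a")
        b = make_series(rng.normal(size=(80, 3)), "b")
        study = GroupStudy([a, b], policy=fast_policy, max_parents=2)
        pred = predicted_network(study, 0, "iemn")
        indiv_b = search_network(study.tables(1))
        assert pred.parents == indiv_b.parents

    def test_predicted_close_to_estimated_on_homogeneous_study(self):
        spec = _preset(
            5, n=5, T=400, n_groups=1, subjects_per_group=5,
            n_mutations=2, min_shd=1, max_in_degree=2,
        )
        bundle = simulate_group(spec)
        study = GroupStudy.from_bundle(
            bundle, policy=PriorPolicy(delta_grid=(1.0,)), max_parents=2
        )
        from mdmgroup.evaluate import shd_networks
        from mdmgroup.search import dag_search_exact

        shds = [
            shd_networks(
                dag_search_exact(study.tables(i)),
                predicted_network(study, i, "iemn"),
            )
            for i in range(study.S)
        ]
        # close on average: a small fraction of the 20 possible directed pairs
        assert float(np.mean(shds)) <= 4.0

    def test_prediction_needs_two_subjects(self, rng, fast_policy):
        study = GroupStudy([make_series(rng.normal(size=(50, 2)), "a")],
                           policy=fast_policy)
        with pytest.raises(ValueError):
            predicted_network(study, 0)


class TestIemn:
    def test_single_subject_all_levels_identical(self, rng, fast_policy):
        study = GroupStudy([make_series(rng.normal(size=(60, 3)), "a")],
                           policy=fast_policy, max_parents=2)
        res = iemn(study, all_in_one(1))
        assert res.individual[0].parents == res.subgroup[0].parents
        assert res.individual[0].parents == res.group.parents

    def test_composition_matches_module_level_calls(self, tiny_study, tiny_bundle):
        labels = tiny_bundle.labels
        assignment = SubgroupAssignment(
            labels=labels, singleton=(False,) * len(labels)
        )
        res = iemn(tiny_study, assignment)
        from mdmgroup import individual_networks
        indiv = individual_networks(tiny_study)
        assert all(a == b for a, b in zip(res.individual, indiv))
        for g in range(1, assignment.G + 1):
            direct = search_network(cs_scores(tiny_study, assignment.members(g)))
            assert res.subgroup[g - 1].parents == direct.parents
        assert res.group.parents == search_network(cs_scores(tiny_study)).parents
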