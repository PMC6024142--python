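"""Term vocabulary, model enumeration and the five pruning checks."""

import numpy as np
import pytest

from fullsubsets.candidates import (ModelSpec, TermOptions, TermSpec,
                                    apply_checks, enumerate_models,
                                    enumerate_terms)
from fullsubsets.predictors import InclusionMatrix, PredictorSpec

from helpers import oracle_candidate_ids

C = lambda n, **kw: PredictorSpec(name=n, role="continuous", **kw)
F = lambda n: PredictorSpec(name=n, role="factor", levels=("l1", "l2"))

S = lambda v: TermSpec(kind="smooth", vars=(v,))
FM = lambda f: TermSpec(kind="factor_main", factors=(f,))
BY = lambda v, bf: TermSpec(kind="by_smooth", vars=(v,), by_factor=bf)
TE = lambda a, b: TermSpec(kind="tensor_smooth", vars=(a, b))


def _inclusion(names, disallowed=()):
    k = len(names)
    allowed = np.ones((k, k), bool)
    for a, b in disallowed:
        i, j = names.index(a), names.index(b)
        allowed[i, j] = allowed[j, i] = False
    return InclusionMatrix(names=list(names), allowed=allowed)


class TestEnumerateTerms:
    def test_two_continuous_no_interactions(self):
        terms = enumerate_terms([C("x1"), C("x2")])
        assert sorted(t.canonical() for t in terms) == ["s(x1)", "s(x2)"]

    def test_smooth_smooth_adds_tensor(self):
        terms = enumerate_terms([C("x1"), C("x2")],
                                TermOptions(smooth_smooth_interactions=True))
        assert sorted(t.canonical() for t in terms) == \
            ["s(x1)", "s(x2)", "te(x1,x2)"]

    def test_factor_switches_give_seven_terms(self):
        terms = enumerate_terms(
            [C("x"), F("fA"), F("fB")],
            TermOptions(factor_factor_interactions=True,
                        factor_smooth_interactions=True))
        assert sorted(t.canonical() for t in terms) == sorted([
            "s(x)", "fA", "fB", "fA:fB", "s(x,by=fA)", "s(x,by=fB)",
            "s(x,by=fA:fB)"])

    def test_linear_vars_get_no_by_or_tensor(self):
        terms = enumerate_terms(
            [C("x1", linear=True), C("x2"), F("fA")],
            TermOptions(factor_smooth_interactions=True,
                        smooth_smooth_interactions=True))
        canons = {t.canonical() for t in terms}
        assert "lin(x1)" in canons
        assert not any("x1" in c and c != "lin(x1)" for c in canons)

    def test_restriction_lists(self):
        terms = enumerate_terms(
            [C("x"), F("fA"), F("fB")],
            TermOptions(factor_smooth_interactions=True,
                        by_factor_restrict=["fA"]))
        canons = {t.canonical() for t in terms}
        assert "s(x,by=fA)" in canons and "s(x,by=fB)" not in canons
        with pytest.raises(ValueError, match="unknown"):
            enumerate_terms([C("x"), F("fA")],
                            TermOptions(factor_smooth_interactions=True,
                                        by_factor_restrict=["nope"]))


class TestEnumerateModels:
    @pytest.mark.parametrize("n_terms,max_p,expected", [
        (3, 3, 8),    # C(3,1)+C(3,2)+C(3,3)+null
        (1, 3, 2),    # the single-term model + null
        (4, 2, 11),   # 4+6+null
    ])
    def test_counts(self, n_terms, max_p, expected):
        terms = [S(f"x{i}") for i in range(n_terms)]
        assert len(enumerate_models(terms, max_p)) == expected

    def test_null_model_present_once_and_first_after_checks(self):
        models = enumerate_models([S("x1")], 3)
        cs = apply_checks(models, None, 3)
        assert cs.models[0].is_null
        assert sum(m.is_null for m in cs.models) == 1

    def test_closed_form_count_no_interactions(self):
        from math import comb
        for n_cont, max_p in [(3, 2), (4, 3), (5, 5)]:
            terms = [S(f"x{i}") for i in range(n_cont)]
            cs = apply_checks(enumerate_models(terms, max_p), None, max_p)
            expected = sum(comb(n_cont, i)
                           for i in range(1, min(max_p, n_cont) + 1)) + 1
            assert len(cs) == expected


class TestChecks:
    """Each check gets a minimal removed fixture and a surviving sibling."""

    fA, fB = FM("fA"), FM("fB")
    fAB = TermSpec(kind="factor_interaction", factors=("fA", "fB"))

    @pytest.mark.parametrize("terms,check", [
        # check 1: factor interaction pushes footprint past the maximum
        # (3 terms but 4 predictors at max_predictors=3)
        ((fAB, S("x1"), S("x2")), 1),
        # check 2: by-smooth without its factor main effect
        ((BY("x1", FM("fA")),), 2),
        # check 2: interaction by-variable missing a marginal main
        ((BY("x1", fAB), fAB, FM("fA")), 2),
        # check 3: by-smooth plus single smooth of the same variable
        ((BY("x1", FM("fA")), FM("fA"), S("x1")), 3),
        # check 4: tensor plus single smooth of a shared margin
        ((TE("x1", "x2"), S("x1")), 4),
    ])
    def test_removed_with_lowest_check(self, terms, check):
        max_p = 3
        cs = apply_checks([ModelSpec(terms=t) for t in [terms]], None, max_p)
        assert len(cs.models) == 0
        assert len(cs.removed) == 1
        assert cs.removed[0][1] == check

    @pytest.mark.parametrize("terms", [
        (BY("x1", fAB), fAB, FM("fA"), FM("fB")),  # fine at max_predictors=4
        (BY("x1", FM("fA")), FM("fA")),            # main effect present
        (BY("x1", FM("fA")), FM("fA"), S("x2")),   # different single var
        (TE("x1", "x2"), S("x3")),                 # tensor + disjoint smooth
        (S("x1"),),                                # single term, no conflicts
    ])
    def test_surviving_siblings(self, terms):
        cs = apply_checks([ModelSpec(terms=terms)], None, 4)
        assert len(cs.models) == 1 and not cs.removed

    def test_check5_collinear_pair_removed_and_single_kept(self):
        inc = _inclusion(["x1", "x2"], disallowed=[("x1", "x2")])
        both = ModelSpec(terms=(S("x1"), S("x2")))
        single = ModelSpec(terms=(S("x1"),))
        cs = apply_checks([both, single], inc, 3)
        assert cs.ids == ["s(x1)"]
        assert cs.removed[0][1] == 5

    def test_check5_counts_by_factor_names(self):
        inc = _inclusion(["x1", "fA"], disallowed=[("fA", "x1")])
        m = ModelSpec(terms=(BY("x1", FM("fA")), FM("fA")))
        cs = apply_checks([m], inc, 3)
        assert len(cs.models) == 0 and cs.removed[0][1] == 5

    def test_three_predictors_one_disallowed_pair(self):
        # 3 uncorrelated smooths, one pair too correlated: 3 singles +
        # 2 allowed pairs + null survive
        terms = [S("x1"), S("x2"), S("x3")]
        inc = _inclusion(["x1", "x2", "x3"], disallowed=[("x1", "x2")])
        cs = apply_checks(enumerate_models(terms, 3), inc, 3)
        assert len(cs) == 6
        assert "s(x1)+s(x2)" not in cs.ids
        assert "s(x1)+s(x2)+s(x3)" not in cs.ids


class TestOracleEquivalence:
    def test_pruning_matches_brute_force_small(self):
        preds = [C("x1"), C("x2"), F("fA"), F("fB")]
        opts = TermOptions(factor_factor_interactions=True,
                           factor_smooth_interactions=True,
                           smooth_smooth_interactions=True)
        terms = enumerate_terms(preds, opts)
        names = [p.name for p in preds]
        inc = _inclusion(names, disallowed=[("x1", "x2")])
        disallowed = {frozenset(("x1", "x2"))}
        cs = apply_checks(enumerate_models(terms, 3), inc, 3)
        keep, removed = oracle_candidate_ids(terms, 3, disallowed)
        assert set(cs.ids) == keep
        assert {mid: chk for mid, chk, _ in cs.removed} == removed

    def test_pruning_is_order_independent(self, rng):
        preds = [C("x1"), C("x2"), F("fA")]
        opts = TermOptions(factor_smooth_interactions=True,
                           smooth_smooth_interactions=True)
        terms = enumerate_terms(preds, opts)
        ref = apply_checks(enumerate_models(terms, 3), None, 3).ids
        for _ in range(5):
            perm = list(terms)
            rng.shuffle(perm)
            assert apply_checks(enumerate_models(perm, 3), None, 3).ids == ref
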