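"""State enumeration, weights, contributions and total-expression predictions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from thermosens import (
    BindingSite,
    Construct,
    FakhouriParams,
    ZinzenParams,
    ZinzenStructure,
    default_binning,
    enumerate_states,
    predict_expression_fakhouri,
    predict_expression_zinzen,
    state_expression_contribution,
    state_weight,
)
from thermosens.thermo_models import STATE_CAP, FakhouriEvaluator

from oracle import brute_fakhouri, brute_zinzen

BIN = default_binning()


def _params(R=1.0, Q=0.0, C1=1.0, C2=1.0, **over):
    q = {f"Q{i}": Q for i in range(1, 7)}
    q.update({k: v for k, v in over.items() if k.startswith("Q")})
    return FakhouriParams(R=R, Q=q, C1=C1, C2=C2)


def _c(*sites, length=200):
    return Construct("t", sites, length)


A100 = BindingSite("activator", "Dl", 100)


class TestEnumerateStates:
    @pytest.mark.parametrize(
        "sites, expected",
        [
            ((BindingSite("repressor", "Gt", 97), A100), 4),
            ((), 1),
            (
                (
                    BindingSite("repressor", "Gt", 60),
                    BindingSite("repressor", "Gt", 70),
                    BindingSite("repressor", "Gt", 80),
                    BindingSite("activator", "Dl", 100),
                    BindingSite("activator", "Dl", 110),
                ),
                32,
            ),
        ],
    )
    def test_state_counts(self, sites, expected):
        states = enumerate_states(_c(*sites))
        assert len(states) == expected
        assert len({s.bound for s in states}) == expected
        assert frozenset() in {s.bound for s in states}

    def test_cap_refused_by_name(self):
        sites = tuple(BindingSite("repressor", "Gt", 10 + i) for i in range(STATE_CAP + 1))
        with pytest.raises(ValueError, match=str(STATE_CAP)):
            enumerate_states(_c(*sites))

    def test_structure_states(self):
        assert len(enumerate_states(ZinzenStructure(1, 1, 1))) == 8


class TestStateWeight:
    def test_empty_state_is_unity(self):
        c = _c(BindingSite("repressor", "Gt", 97), A100)
        empty = next(s for s in enumerate_states(c) if not s.bound)
        assert state_weight(empty, _params(), {"Dl": 1.0, "Gt": 1.0}) == 1.0

    def test_single_repressor_product(self):
        c = _c(BindingSite("repressor", "Gt", 97), A100)
        st_ = next(s for s in enumerate_states(c) if s.bound == frozenset({0}))
        assert state_weight(st_, _params(R=2.0), {"Dl": 1.0, "Gt": 0.5}) == pytest.approx(1.0)

    def test_adjacent_pair_cooperativity(self):
        c = _c(BindingSite("repressor", "Gt", 94), BindingSite("repressor", "Gt", 97), A100)
        st_ = next(s for s in enumerate_states(c) if s.bound == frozenset({0, 1}))
        w = state_weight(st_, _params(R=1.0, C1=3.0), {"Dl": 1.0, "Gt": 1.0})
        assert w == pytest.approx(3.0)

    def test_activator_between_repressors_breaks_pair(self):
        c = _c(BindingSite("repressor", "Gt", 95), A100, BindingSite("repressor", "Gt", 130))
        st_ = next(s for s in enumerate_states(c) if s.bound == frozenset({0, 2}))
        w = state_weight(st_, _params(R=1.0, C1=3.0), {"Dl": 1.0, "Gt": 1.0})
        assert w == pytest.approx(1.0)

    def test_missing_concentration_names_factor(self):
        c = _c(BindingSite("repressor", "Gt", 97), A100)
        st_ = next(s for s in enumerate_states(c) if s.bound == frozenset({0}))
        with pytest.raises(KeyError, match="Gt"):
            state_weight(st_, _params(), {"Dl": 1.0})


class TestExpressionContribution:
    def test_lone_activator_full_contribution(self):
        c = _c(BindingSite("repressor", "Gt", 97), A100)
        st_ = next(s for s in enumerate_states(c) if s.bound == frozenset({1}))
        assert state_expression_contribution(st_, _params(), c, BIN) == pytest.approx(1.0)

    def test_quenched_activator(self):
        c = _c(BindingSite("repressor", "Gt", 97), A100)  # 3 bp apart: Q1
        st_ = next(s for s in enumerate_states(c) if s.bound == frozenset({0, 1}))
        val = state_expression_contribution(st_, _params(Q1=0.8), c, BIN)
        assert val == pytest.approx(0.2)

    def test_repressor_only_state_contributes_zero(self):
        c = _c(BindingSite("repressor", "Gt", 97), A100)
        st_ = next(s for s in enumerate_states(c) if s.bound == frozenset({0}))
        assert state_expression_contribution(st_, _params(Q1=0.8), c, BIN) == 0.0

    def test_unbinned_distance_raises(self):
        c = _c(BindingSite("repressor", "Gt", 10), A100)  # 90 bp: outside all bins
        st_ = next(s for s in enumerate_states(c) if s.bound == frozenset({0, 1}))
        with pytest.raises(ValueError, match="bins"):
            state_expression_contribution(st_, _params(), c, BIN)


class TestPredictFakhouri:
    def test_single_activator_half(self):
        c = _c(A100)
        assert predict_expression_fakhouri(c, _params(), {"Dl": 1.0}, BIN) == pytest.approx(0.5)

    def test_zero_repressor_reduces_to_activator_only(self):
        c2 = _c(BindingSite("repressor", "Gt", 97), A100)
        with_reps = predict_expression_fakhouri(
            c2, _params(R=3.0, Q1=0.9, C1=5.0), {"Dl": 1.0, "Gt": 0.0}, BIN
        )
        assert with_reps == pytest.approx(0.5)

    def test_hand_enumerated_four_state_case(self):
        # states: empty(1), A(1), R(1), AR(1 * (1-1)=0 contribution) -> E = 1/4
        c = _c(BindingSite("repressor", "Gt", 97), A100)
        val = predict_expression_fakhouri(c, _params(R=1.0, Q1=1.0), {"Dl": 1.0, "Gt": 1.0}, BIN)
        assert val == pytest.approx(0.25)

    @given(
        R=st.floats(0.0, 5.0),
        Q=st.floats(0.0, 1.0),
        g=st.floats(0.0, 1.0),
        C1=st.floats(0.0, 10.0),
    )
    def test_bounded_and_partition_of_unity(self, R, Q, g, C1):
        c = _c(BindingSite("repressor", "Gt", 94), BindingSite("repressor", "Gt", 97), A100)
        p = _params(R=R, Q1=Q, C1=C1)
        conc = {"Dl": 1.0, "Gt": g}
        e = predict_expression_fakhouri(c, p, conc, BIN)
        assert 0.0 <= e <= 1.0
        weights = [state_weight(s, p, conc) for s in enumerate_states(c)]
        probs = np.array(weights) / sum(weights)
        assert probs.sum() == pytest.approx(1.0)

    def test_monotone_in_quenching_and_scaling(self, rng):
        c = _c(BindingSite("repressor", "Gt", 70), BindingSite("repressor", "Gt", 97), A100)
        conc = {"Dl": 1.0, "Gt": 0.7}
        for _ in range(25):
            R, q1, q3, c1 = rng.uniform(0.1, 3), rng.random(), rng.random(), rng.uniform(1, 8)
            base = predict_expression_fakhouri(c, _params(R=R, Q1=q1, Q3=q3, C1=c1), conc, BIN)
            up_q = predict_expression_fakhouri(
                c, _params(R=R, Q1=min(q1 + 0.1, 1.0), Q3=q3, C1=c1), conc, BIN
            )
            up_r = predict_expression_fakhouri(c, _params(R=R * 1.5, Q1=q1, Q3=q3, C1=c1), conc, BIN)
            assert up_q <= base + 1e-12
            assert up_r <= base + 1e-12

    def test_zero_quenching_equals_activator_occupancy(self, rng):
        c = _c(BindingSite("repressor", "Gt", 70), A100, BindingSite("repressor", "Gt", 130))
        p = _params(R=2.0, Q=0.0, C1=4.0)
        conc = {"Dl": 1.0, "Gt": 0.8}
        e = predict_expression_fakhouri(c, p, conc, BIN)
        states = enumerate_states(c)
        weights = np.array([state_weight(s, p, conc) for s in states])
        act_bound = np.array([1 in s.bound for s in states])  # index 1 is the activator
        occupancy = float(weights[act_bound].sum() / weights.sum())
        assert e == pytest.approx(occupancy, rel=1e-12)


class TestOracleEquivalence:
    """The vectorized evaluator must match an independent brute-force loop."""

    @pytest.mark.parametrize("mode", ["binding", "post_binding"])
    @pytest.mark.parametrize("pairing", ["two_term", "single_term"])
    def test_panel_constructs(self, original_design, mode, pairing, rng):
        for c in original_design.constructs:
            for _ in range(5):
                p = FakhouriParams(
                    R=rng.uniform(0.1, 3),
                    Q={f"Q{i}": rng.random() for i in range(1, 7)},
                    C1=rng.uniform(1, 10),
                    C2=rng.uniform(1, 10),
                )
                conc = {"Dl": 1.0, "Gt": rng.random()}
                got = predict_expression_fakhouri(
                    c, p, conc, BIN, pairing=pairing, cooperativity_mode=mode
                )
                want = brute_fakhouri(c, p, conc, BIN, pairing=pairing, mode=mode)
                assert got == pytest.approx(want, rel=1e-12)

    def test_larger_random_construct(self, rng):
        sites = []
        pos = 40
        for _ in range(7):
            pos += int(rng.integers(3, 15))
            role = "repressor" if rng.random() < 0.6 else "activator"
            sites.append(BindingSite(role, "Gt" if role == "repressor" else "Dl", pos))
        if not any(s.role == "activator" for s in sites):
            sites[-1] = BindingSite("activator", "Dl", sites[-1].position)
        # keep every pair distance binnable: repressors beyond 56 bp of an
        # activator are only legal 3' of it, so clamp by construction
        c = Construct("rand", sites, 400)
        p = FakhouriParams(
            R=1.3, Q={f"Q{i}": 0.1 * i for i in range(1, 7)}, C1=2.0, C2=3.0
        )
        conc = {"Dl": 0.9, "Gt": 0.4}
        try:
            want = brute_fakhouri(c, p, conc, BIN)
        except ValueError:
            pytest.skip("random construct drew an unbinnable distance")
        got = predict_expression_fakhouri(c, p, conc, BIN)
        assert got == pytest.approx(want, rel=1e-12)


class TestPredictZinzen:
    ZP = dict(D=1.0, T=1.0, S=1.0, DTr=1.0, TTr=1.0, SSr=1.0, DTv=1.0, TTv=1.0, SSv=1.0)

    def test_three_of_four_states_activate(self):
        val = predict_expression_zinzen(
            ZinzenStructure(1, 1, 0), ZinzenParams(**self.ZP), "rho-like",
            {"Dl": 1.0, "Twi": 1.0, "Sna": 0.0},
        )
        assert val == pytest.approx(0.75)

    def test_no_snail_sites_means_snail_independence(self):
        s = ZinzenStructure(2, 1, 0)
        base = dict(self.ZP)
        a = predict_expression_zinzen(
            s, ZinzenParams(**base), "rho-like", {"Dl": 0.5, "Twi": 0.3, "Sna": 0.9}
        )
        base.update(S=7e3, SSr=55.0)
        b = predict_expression_zinzen(
            s, ZinzenParams(**base), "rho-like", {"Dl": 0.5, "Twi": 0.3, "Sna": 0.2}
        )
        assert a == pytest.approx(b, rel=1e-14)

    def test_zero_concentrations_silent(self):
        val = predict_expression_zinzen(
            ZinzenStructure(2, 2, 1), ZinzenParams(**self.ZP), "vnd-like",
            {"Dl": 0.0, "Twi": 0.0, "Sna": 0.0},
        )
        assert val == 0.0

    def test_unknown_class_tag(self):
        with pytest.raises(ValueError, match="class"):
            predict_expression_zinzen(
                ZinzenStructure(1, 0, 0), ZinzenParams(**self.ZP), "other",
                {"Dl": 1.0, "Twi": 0.0, "Sna": 0.0},
            )

    @pytest.mark.parametrize("counts", [(1, 1, 1), (2, 2, 1), (3, 2, 2), (0, 2, 1)])
    @pytest.mark.parametrize("tag", ["rho-like", "vnd-like"])
    def test_matches_site_level_brute_force(self, counts, tag, rng):
        s = ZinzenStructure(*counts)
        for _ in range(5):
            p = ZinzenParams(
                D=rng.uniform(1e8, 1e10), T=rng.uniform(1e8, 1e10), S=rng.uniform(1e8, 1e10),
                DTr=rng.uniform(1, 100), TTr=rng.uniform(1, 100), SSr=rng.uniform(1, 100),
                DTv=rng.uniform(1, 100), TTv=rng.uniform(1, 100), SSv=rng.uniform(1, 100),
            )
            dl, twi, sna = rng.random(3) * 1e-9
            got = predict_expression_zinzen(s, p, tag, {"Dl": dl, "Twi": twi, "Sna": sna})
            want = brute_zinzen(s, p, tag, dl, twi, sna)
            assert got == pytest.approx(want, rel=1e-12)

    def test_monotone_in_activator_scaling_without_snail(self, rng):
        s = ZinzenStructure(2, 2, 0)
        conc = {"Dl": 2e-10, "Twi": 1e-10, "Sna": 0.0}
        base = dict(self.ZP, D=1e9, T=1e9)
        lo = predict_expression_zinzen(s, ZinzenParams(**base), "rho-like", conc)
        base["D"] *= 3
        hi = predict_expression_zinzen(s, ZinzenParams(**base), "rho-like", conc)
        assert hi >= lo


class TestEvaluatorVectorization:
    def test_vector_conditions_match_scalar_calls(self, original_design):
        c = original_design.constructs[7]
        p = FakhouriParams(R=1.1, Q={f"Q{i}": 0.4 for i in range(1, 7)}, C1=2.0, C2=1.5)
        grid = np.linspace(0, 1, 7)
        ev = FakhouriEvaluator(c, BIN)
        vec = ev.expression(p, {"Dl": np.ones_like(grid), "Gt": grid})
        for g, v in zip(grid, vec):
            assert predict_expression_fakhouri(c, p, {"Dl": 1.0, "Gt": g}, BIN) == pytest.approx(v)
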