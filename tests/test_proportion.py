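import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgbesmart import proportion as pr
from cgbesmart.io_tables import EditPattern, OutcomeTable, ValidationError

from conftest import make_site

# ---------------------------------------------------------------------------
# Independent oracles (kept free of the package's closed-form path)
# ---------------------------------------------------------------------------


def oracle_p11(pa: float, pb: float, c: float, tol: float = 1e-14) -> float:
    """p11 with margins (pa, pb) and odds ratio c, by pure bisection on the
    monotone map p11 -> odds ratio within the Frechet bounds."""
    lo, hi = max(0.0, pa + pb - 1.0), min(pa, pb)

    def odds(x):
        return (x * (1 - pa - pb + x)) / ((pa - x) * (pb - x))

    a, b = lo, hi
    for _ in range(300):
        mid = 0.5 * (a + b)
        if odds(mid) < c:
            a = mid
        else:
            b = mid
        if b - a < tol:
            break
    return 0.5 * (a + b)


def oracle_proportions(positions, margs, cs):
    """Enumerate the chain joint by the *backward* factorization
    p(X_n) * prod p(X_{i} | X_{i+1}), re-deriving conditionals from the
    bisection pairwise joints."""
    import itertools

    n = len(positions)
    pairs = [oracle_p11(margs[i], margs[i + 1], cs[i]) for i in range(n - 1)]
    out = {}
    for bits in itertools.product((0, 1), repeat=n):
        p = margs[-1] if bits[-1] else 1 - margs[-1]
        for i in range(n - 2, -1, -1):
            p11 = pairs[i]
            pa, pb = margs[i], margs[i + 1]
            cells = {  # (x_i, x_{i+1}) -> joint
                (1, 1): p11, (1, 0): pa - p11,
                (0, 1): pb - p11, (0, 0): 1 - pa - pb + p11,
            }
            denom = pb if bits[i + 1] else 1 - pb
            p *= cells[(bits[i], bits[i + 1])] / denom
        pattern = EditPattern.from_positions(
            pos for pos, b in zip(positions, bits) if b
        )
        out[pattern] = p
    return out


# ---------------------------------------------------------------------------
# estimate_c
# ---------------------------------------------------------------------------


class TestEstimateC:
    def test_printed_formula(self):
        pair = pr.PairwiseCounts(p11=0.4, p10=0.1, p01=0.1, p00=0.4)
        assert pr.estimate_c(pair) == pytest.approx(16.0)

    def test_independent_pair_gives_one(self):
        pa, pb = 0.3, 0.2
        pair = pr.joint_from_marginals(pa, pb, 1.0)
        assert pr.estimate_c(pair) == pytest.approx(1.0)

    def test_small_counts(self):
        pair = pr.PairwiseCounts(p11=3 / 8, p10=1 / 8, p01=1 / 8, p00=3 / 8)
        assert pr.estimate_c(pair) == pytest.approx(9.0)

    def test_zero_cell_directs_to_smoothing(self):
        pair = pr.PairwiseCounts(p11=0.5, p10=0.5, p01=0.0, p00=0.0)
        with pytest.raises(pr.SmoothingError, match="smoothing"):
            pr.estimate_c(pair)


# ---------------------------------------------------------------------------
# joint_from_marginals
# ---------------------------------------------------------------------------


class TestJointFromMarginals:
    def test_independence_is_product(self):
        pair = pr.joint_from_marginals(0.3, 0.2, 1.0)
        assert pair.p11 == pytest.approx(0.06, abs=1e-15)

    def test_symmetric_closed_form(self):
        # pa = pb = 0.5, c = 9: p11 solves x = 3(0.5 - x) -> 0.375
        pair = pr.joint_from_marginals(0.5, 0.5, 9.0)
        assert pair.p11 == pytest.approx(0.375, abs=1e-12)

    def test_against_bisection_oracle_on_grid(self):
        for pa in (0.05, 0.3, 0.5, 0.9):
            for pb in (0.1, 0.45, 0.8):
                for c in (0.1, 0.5, 1.0, 2.0, 9.0, 100.0):
                    got = pr.joint_from_marginals(pa, pb, c).p11
                    assert got == pytest.approx(oracle_p11(pa, pb, c), abs=1e-9)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        pa=st.floats(0.01, 0.99),
        pb=st.floats(0.01, 0.99),
        logc=st.floats(-4, 4),
    )
    def test_margins_and_odds_ratio_round_trip(self, pa, pb, logc):
        c = 10.0**logc
        pair = pr.joint_from_marginals(pa, pb, c)
        assert pair.p_a == pytest.approx(pa, abs=1e-12)
        assert pair.p_b == pytest.approx(pb, abs=1e-12)
        assert max(0.0, pa + pb - 1.0) <= pair.p11 <= min(pa, pb)
        assert pr.estimate_c(pair) == pytest.approx(c, rel=1e-9)

    def test_p11_strictly_increasing_in_c(self):
        for pa, pb in ((0.3, 0.6), (0.5, 0.5), (0.1, 0.9)):
            p11s = [
                pr.joint_from_marginals(pa, pb, c).p11
                for c in np.logspace(-2, 2, 25)
            ]
            assert all(a < b for a, b in zip(p11s[:-1], p11s[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            pr.joint_from_marginals(0.0, 0.5, 2.0)
        with pytest.raises(ValidationError):
            pr.joint_from_marginals(0.5, 0.5, -1.0)


# ---------------------------------------------------------------------------
# build_chain / outcome_proportions
# ---------------------------------------------------------------------------


class TestChain:
    def test_single_bernoulli(self):
        chain = pr.build_chain([5], [0.3], [])
        props = pr.outcome_proportions(chain)
        assert props[EditPattern.ref()] == pytest.approx(0.7)
        assert props[EditPattern.parse("5G")] == pytest.approx(0.3)

    def test_all_independent_equals_product_model(self):
        margs = [0.2, 0.5, 0.7]
        chain = pr.build_chain([2, 5, 9], margs, [1.0, 1.0])
        props = pr.outcome_proportions(chain)
        expected = (1 - 0.2) * 0.5 * (1 - 0.7)
        assert props[EditPattern.parse("5G")] == pytest.approx(expected, abs=1e-12)

    def test_two_position_chain_matches_pairwise_joint(self):
        pair = pr.joint_from_marginals(0.5, 0.5, 9.0)
        chain = pr.build_chain([4, 6], [0.5, 0.5], [9.0])
        props = pr.outcome_proportions(chain)
        assert props[EditPattern.parse("4G+6G")] == pytest.approx(pair.p11, abs=1e-12)
        assert props[EditPattern.ref()] == pytest.approx(pair.p00, abs=1e-12)
        assert props[EditPattern.parse("4G")] == pytest.approx(0.125, abs=1e-12)
        assert props[EditPattern.parse("6G")] == pytest.approx(0.125, abs=1e-12)

    def test_degenerate_marginals_clip_to_ref(self):
        chain = pr.build_chain([3, 8], [0.0, 0.0], [2.0])
        props = pr.outcome_proportions(chain)
        assert props[EditPattern.ref()] == pytest.approx(1.0, abs=1e-6)

    def test_random_chains_match_oracle_and_preserve_structure(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 7))
            positions = sorted(rng.choice(range(1, 21), size=n, replace=False).tolist())
            margs = rng.uniform(0.05, 0.95, size=n).tolist()
            cs = (10.0 ** rng.uniform(-1, 1, size=max(n - 1, 0))).tolist()
            chain = pr.build_chain(positions, margs, cs)
            props = pr.outcome_proportions(chain)

            oracle = oracle_proportions(positions, margs, cs)
            dev = max(abs(props[k] - oracle[k]) for k in props)
            assert dev <= 1e-9
            assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)
            # marginal consistency
            for i, pos in enumerate(positions):
                marg = sum(
                    v for k, v in props.items()
                    if k.kind == "substitution" and pos in k.g_positions()
                )
                assert marg == pytest.approx(margs[i], abs=1e-9)
            # odds-ratio preservation on adjacent pairs
            for i in range(n - 1):
                a, b = positions[i], positions[i + 1]
                cells = np.zeros((2, 2))
                for k, v in props.items():
                    g = k.g_positions() if k.kind == "substitution" else frozenset()
                    cells[int(a in g), int(b in g)] += v
                c_back = cells[1, 1] * cells[0, 0] / (cells[0, 1] * cells[1, 0])
                assert c_back == pytest.approx(cs[i], rel=1e-6)

    def test_exact_enumeration_refuses_long_chains(self):
        n = 13
        chain = pr.build_chain(
            list(range(1, n + 1)), [0.2] * n, [1.0] * (n - 1)
        )
        with pytest.raises(ValidationError, match="sample"):
            pr.outcome_proportions(chain)

    def test_chain_sampler_marginals(self, rng):
        chain = pr.build_chain([4, 5, 6], [0.3, 0.5, 0.2], [4.0, 4.0])
        draws = chain.sample(200_000, rng)
        assert np.allclose(draws.mean(axis=0), [0.3, 0.5, 0.2], atol=0.01)


class TestPooledEstimation:
    TWO_C = "ACCTGATTGATTGATTGATG"  # substrate Cs at 2 and 3 only

    def test_pooled_counts_and_chain_fallback(self):
        site = make_site(self.TWO_C, "s1")
        table = OutcomeTable(
            "s1",
            {
                EditPattern.ref(): 30,
                EditPattern.parse("2G"): 10,
                EditPattern.parse("3G"): 10,
                EditPattern.parse("2G+3G"): 30,
            },
        )
        cs = pr.estimate_adjacent_correlations([table], {"s1": site})
        # pair (2,3): cells 00=30,10=10,01=10,11=30 -> c = 9
        assert cs == {(2, 3): pytest.approx(9.0)}
        # a pair unseen in training falls back to the pooled median c,
        # or to independence when explicitly requested
        wide = make_site("ACCTGACCTGATTGATTGTG", "s2")  # Cs at 2,3,7,8
        chain = pr.chain_for_site(wide, {2: 0.5, 3: 0.5, 7: 0.1}, cs, default_c=1.0)
        assert chain.positions == (2, 3, 7)
        assert chain.cond_given_prev[1] == (pytest.approx(0.1), pytest.approx(0.1))
        pooled_default = pr.chain_for_site(wide, {2: 0.5, 3: 0.5, 7: 0.1}, cs)
        q0, q1 = pooled_default.cond_given_prev[1]
        assert q1 > q0  # median c = 9 > 1 couples the unseen pair positively

    def test_zero_pooled_cell_raises_smoothing_error(self):
        site = make_site(self.TWO_C, "s1")
        table = OutcomeTable(
            "s1", {EditPattern.ref(): 50, EditPattern.parse("2G"): 10}
        )
        with pytest.raises(pr.SmoothingError):
            pr.estimate_adjacent_correlations([table], {"s1": site})

    def test_c_cap_applied(self):
        site = make_site(self.TWO_C, "s1")
        table = OutcomeTable(
            "s1",
            {
                EditPattern.ref(): 10**7,
                EditPattern.parse("2G"): 1,
                EditPattern.parse("3G"): 1,
                EditPattern.parse("2G+3G"): 10**7,
            },
        )
        cs = pr.estimate_adjacent_correlations([table], {"s1": site})
        assert cs[(2, 3)] == pytest.approx(1e4)
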