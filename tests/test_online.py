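"""Alpha-wealth accounting: gamma sequences, level updates, state ledger."""

import numpy as np
import pytest

from batchfdr import (
    BatchRecord,
    PValueVector,
    init_state,
    make_gamma,
    next_alpha,
    process_batch,
    state_from_json,
    state_to_json,
)
from batchfdr.online import _wealth_spend
from conftest import random_pvector


def extend(state, record_kwargs):
    from dataclasses import replace

    rec = BatchRecord(s=state.t + 1, **record_kwargs)
    return replace(state, history=state.history + (rec,))


class TestGamma:
    def test_default_power_law_closed_form(self):
        g = make_gamma()
        assert g(1) == pytest.approx(6 / np.pi**2, abs=1e-12)
        assert g(2) == pytest.approx(6 / np.pi**2 / 4, abs=1e-12)

    def test_power_law_sums_to_one(self):
        g = make_gamma(exponent=2.0)
        s = np.arange(1, 10**6 + 1, dtype=float)
        partial = (s**-2.0).sum() * 6 / np.pi**2
        assert abs(partial - 1.0) < 1e-4

    def test_custom_weights(self):
        g = make_gamma("custom", weights=[0.5, 0.5])
        assert (g(1), g(2), g(3)) == (0.5, 0.5, 0.0)

    def test_invalid_sequences(self):
        with pytest.raises(ValueError):
            make_gamma("custom", weights=[0.6, 0.6])
        with pytest.raises(ValueError):
            make_gamma("custom", weights=[-0.1, 0.5])
        with pytest.raises(ValueError):
            make_gamma(exponent=1.0)


class TestInitAndWorkedUpdates:
    def test_first_level_is_gamma1_alpha(self):
        for method in ("online_bh", "online_stbh", "online_prds"):
            st = init_state(method, 0.05, make_gamma("custom", weights=[0.5, 0.25]))
            assert st.t == 0 and st.history == ()
            assert next_alpha(st, 4) == pytest.approx(0.025, abs=1e-15)

    def test_degenerate_alpha_rejected(self):
        with pytest.raises(ValueError):
            init_state("online_bh", 0.0, make_gamma())
        with pytest.raises(ValueError):
            init_state("nope", 0.05, make_gamma())

    def test_online_bh_hand_worked_update(self):
        st = init_state("online_bh", 0.05, make_gamma("custom", weights=[0.5, 0.25]))
        st = extend(st, dict(N_s=4, alpha_s=0.025, R_s=2, R_plus_s=2))
        # [(0.75*0.05) - 0.025*(2/2)] * (4+2)/4
        assert next_alpha(st, 4) == pytest.approx(0.01875, abs=1e-12)

    def test_online_stbh_hand_worked_update(self):
        st = init_state("online_stbh", 0.05, make_gamma("custom", weights=[0.5, 0.25]))
        st = extend(st, dict(N_s=4, alpha_s=0.025, R_s=2, R_plus_s=2, k_s=0.5))
        # [0.0375 - 0.5*0.025] * 1.5
        assert next_alpha(st, 4) == pytest.approx(0.0375, abs=1e-12)

    def test_online_prds_closed_form_update(self):
        st = init_state("online_prds", 0.05, make_gamma("custom", weights=[0.5, 0.25]))
        st = extend(st, dict(N_s=100, alpha_s=0.025, R_s=10, R_plus_s=10))
        # 0.05 * 0.25 * 110/100
        assert next_alpha(st, 100) == pytest.approx(0.01375, abs=1e-12)

    def test_next_batch_must_be_nonempty(self):
        st = init_state("online_bh", 0.05, make_gamma())
        with pytest.raises(ValueError):
            next_alpha(st, 0)


class TestTelescopingAndWealth:
    @pytest.mark.parametrize("method", ["online_bh", "online_stbh", "online_prds"])
    def test_zero_rejections_telescopes_to_gamma_t_alpha(self, method):
        """With R_s = 0, R_s^+ = 1 (and k_s = 1), alpha_t = gamma_t * alpha exactly."""
        alpha, g = 0.05, make_gamma()
        st = init_state(method, alpha, g)
        for t in range(1, 21):
            level = next_alpha(st, 100)
            assert level == pytest.approx(g(t) * alpha, rel=1e-12)
            st = extend(st, dict(N_s=100, alpha_s=level, R_s=0, R_plus_s=1))

    def test_stbh_unit_k_spend_matches_bh_spend(self):
        """The stbh update differs from onlineBH only through the k_s factor."""
        alpha, g = 0.05, make_gamma()
        stb = init_state("online_bh", alpha, g)
        sts = init_state("online_stbh", alpha, g)
        for t in range(1, 10):
            lb, ls = next_alpha(stb, 50), next_alpha(sts, 50)
            assert ls == pytest.approx(lb, rel=1e-12)
            stb = extend(stb, dict(N_s=50, alpha_s=lb, R_s=1, R_plus_s=2))
            sts = extend(sts, dict(N_s=50, alpha_s=ls, R_s=1, R_plus_s=2, k_s=1.0))

    @pytest.mark.parametrize("method", ["online_bh", "online_stbh"])
    def test_wealth_never_overdrawn_on_random_histories(self, rng, method):
        alpha = 0.05
        for _ in range(50):
            st = init_state(method, alpha, make_gamma(), lam=0.5)
            for t in range(1, int(rng.integers(5, 21))):
                p = PValueVector(random_pvector(rng, n=40), batch_index=st.t + 1)
                _, st = process_batch(st, p)
                spend = _wealth_spend(st.history)
                budget = alpha * st.gamma.cumulative(st.t)
                assert spend <= budget + 1e-12

    def test_levels_clamped_to_unit_interval(self, rng):
        st = init_state("online_bh", 1.0, make_gamma("custom", weights=[1.0]))
        # all wealth at s=1, later batches have zero budget left or inflated
        p = PValueVector(np.full(5, 1e-9), batch_index=1)
        _, st = process_batch(st, p)
        level = next_alpha(st, 5)
        assert 0.0 <= level <= 1.0


class TestProcessBatch:
    def test_batch_index_must_follow_history(self):
        st = init_state("online_bh", 0.05, make_gamma())
        with pytest.raises(ValueError):
            process_batch(st, PValueVector(np.array([0.5]), batch_index=2))

    def test_all_ones_batch_under_prds(self):
        st = init_state("online_prds", 0.05, make_gamma())
        _, st = process_batch(st, PValueVector(np.ones(10), batch_index=1))
        rec = st.history[0]
        assert rec.R_s == 0 and rec.R_plus_s == 1
        assert next_alpha(st, 10) == pytest.approx(0.05 * st.gamma(2), rel=1e-12)

    def test_past_decisions_immutable(self, rng):
        st = init_state("online_stbh", 0.05, make_gamma())
        p1 = PValueVector(random_pvector(rng, n=30), batch_index=1)
        r1_alone, st1 = process_batch(st, p1)
        p2 = PValueVector(random_pvector(rng, n=30), batch_index=2)
        _, st2 = process_batch(st1, p2)
        assert st2.history[0] == st1.history[0]
        r1_again, _ = process_batch(st, p1)
        assert r1_again.rejected_indices == r1_alone.rejected_indices
        assert r1_again.level_used == r1_alone.level_used

    def test_stbh_with_unit_k_matches_online_bh_levels(self, rng):
        gb = init_state("online_bh", 0.05, make_gamma())
        gs = init_state("online_stbh", 0.05, make_gamma())
        for t in range(1, 8):
            # all-large p-values: pi0=1, Storey-BH == BH, R=0
            p = np.clip(rng.uniform(0.6, 1.0, size=20), 0, 1)
            rb, gb = process_batch(gb, PValueVector(p, batch_index=t))
            rs, gs = process_batch(gs, PValueVector(p, batch_index=t), k_fn=lambda p, lam: 1.0)
            assert gb.history[-1].alpha_s == pytest.approx(gs.history[-1].alpha_s, rel=1e-12)


class TestSerialization:
    def test_round_trip_bit_exact(self, rng):
        st = init_state("online_stbh", 0.05, make_gamma(exponent=2.0), lam=0.37)
        for t in range(1, 6):
            p = PValueVector(random_pvector(rng, n=25), batch_index=t)
            _, st = process_batch(st, p)
        st2 = state_from_json(state_to_json(st))
        assert st2 == st  # dataclass equality: every float bit-exact
        assert state_to_json(st2) == state_to_json(st)

    def test_schema_version_checked(self):
        st = init_state("online_bh", 0.05, make_gamma())
        doc = state_to_json(st).replace('"schema_version": "1"', '"schema_version": "0"')
        with pytest.raises(ValueError):
            state_from_json(doc)

    def test_corrupt_state_rejected(self):
        with pytest.raises(ValueError):
            state_from_json("{not json")
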