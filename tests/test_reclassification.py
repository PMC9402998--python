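"""NRI and IDI: hand-enumerated examples, oracle equivalence, symmetries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsofa_hbp.reclassification import (
    RiskCategories,
    categorical_nri,
    categorize,
    continuous_nri,
    idi,
)

# probabilities that land squarely in low / moderate / high
P_LOW, P_MOD, P_HIGH = 0.05, 0.25, 0.60
CAT_P = {"low": P_LOW, "moderate": P_MOD, "high": P_HIGH}


def patientwise_nri(p_old, p_new, y, cats=None):
    """Direct per-patient up/down counting (test oracle)."""
    y = np.asarray(y, dtype=bool)
    if cats is None:
        old_v, new_v = np.asarray(p_old), np.asarray(p_new)
    else:
        old_v, new_v = cats.index(p_old), cats.index(p_new)
    up = new_v > old_v
    down = new_v < old_v
    comp_e = up[y].mean() - down[y].mean()
    comp_ne = down[~y].mean() - up[~y].mean()
    return comp_e + comp_ne, comp_e, comp_ne


class TestCategorize:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.15, "moderate"), (0.35, "high"), (0.0, "low"), (0.1499, "low"),
         (0.3499, "moderate"), (1.0, "high")],
    )
    def test_half_open_boundaries(self, p, expected):
        assert categorize(p) == expected

    def test_vectorized(self):
        out = categorize(np.array([0.0, 0.2, 0.9]))
        assert list(out) == ["low", "moderate", "high"]

    def test_bad_cuts_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            RiskCategories(cuts=(0.4, 0.2))


class TestCategoricalNri:
    def test_hand_enumerated_eight_patients(self):
        # events: low->mod, low->low, mod->low, high->high
        # non-events: mod->low, mod->mod, low->low, high->mod
        moves = [
            ("low", "moderate", 1), ("low", "low", 1),
            ("moderate", "low", 1), ("high", "high", 1),
            ("moderate", "low", 0), ("moderate", "moderate", 0),
            ("low", "low", 0), ("high", "moderate", 0),
        ]
        p_old = np.array([CAT_P[a] for a, _, _ in moves])
        p_new = np.array([CAT_P[b] for _, b, _ in moves])
        y = np.array([e for _, _, e in moves])
        res, table = categorical_nri(p_old, p_new, y)
        assert res.event_component == pytest.approx(0.0)
        assert res.nonevent_component == pytest.approx(0.5)
        assert res.nri == pytest.approx(0.5)
        assert table.events.sum() == 4 and table.nonevents.sum() == 4
        assert table.movements("events") == (1, 1, 4)
        assert table.movements("nonevents") == (0, 2, 4)

    def test_identity_gives_zero_and_diagonal_table(self, rng):
        p = rng.random(60)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        res, table = categorical_nri(p, p, y)
        assert res.nri == 0.0
        assert np.all(np.triu(table.events, 1) == 0)
        assert np.all(np.tril(table.nonevents, -1) == 0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_table_equals_patientwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 40)
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            return
        p_old = rng.random(n)
        p_new = rng.random(n)
        res, table = categorical_nri(p_old, p_new, y)
        cats = RiskCategories()
        oracle, comp_e, comp_ne = patientwise_nri(p_old, p_new, y, cats)
        assert res.nri == pytest.approx(oracle, abs=1e-12)
        # the same statistic recomputed from the 3x3 tables
        up_e, down_e, n_e = table.movements("events")
        up_ne, down_ne, n_ne = table.movements("nonevents")
        from_table = (up_e - down_e) / n_e + (down_ne - up_ne) / n_ne
        assert res.nri == pytest.approx(from_table, abs=1e-12)
        assert res.event_component == pytest.approx(comp_e)
        assert res.nonevent_component == pytest.approx(comp_ne)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            categorical_nri([0.1, 0.2], [0.2, 0.1], [0, 0])


class TestContinuousNri:
    def test_enumerated_example(self):
        # events: 2 of 3 move up; non-events: 1 of 2 moves up (1 down)
        p_old = np.array([0.2, 0.3, 0.4, 0.1, 0.2])
        p_new = np.array([0.3, 0.2, 0.5, 0.05, 0.25])
        y = np.array([1, 1, 1, 0, 0])
        res = continuous_nri(p_old, p_new, y)
        assert res.nri == pytest.approx(1.0 / 3.0)
        assert res.event_component == pytest.approx(1.0 / 3.0)
        assert res.nonevent_component == pytest.approx(0.0)
        # doubled-difference form, valid tie-free
        assert res.nri == pytest.approx(2 * (2 / 3 - 1 / 2))

    def test_identity_zero(self, rng):
        p = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        assert continuous_nri(p, p, y).nri == 0.0

    def test_maximum_attained(self):
        p_old = np.array([0.4, 0.4, 0.6, 0.6])
        p_new = np.array([0.9, 0.9, 0.1, 0.1])
        y = np.array([1, 1, 0, 0])
        assert continuous_nri(p_old, p_new, y).nri == 2.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 40)
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            return
        p_old = rng.random(n)
        p_new = rng.random(n)
        base = continuous_nri(p_old, p_new, y).nri
        transformed = continuous_nri(p_old**2, p_new**2, y).nri
        assert transformed == pytest.approx(base, abs=1e-12)


class TestIdi:
    def test_group_mean_example(self):
        # events: mean p 0.3 -> 0.4; non-events: 0.2 -> 0.15
        p_old = np.array([0.2, 0.4, 0.1, 0.3])
        p_new = np.array([0.3, 0.5, 0.05, 0.25])
        y = np.array([1, 1, 0, 0])
        res = idi(p_old, p_new, y)
        assert res.idi == pytest.approx(0.15)
        assert res.discrimination_slope_old == pytest.approx(0.1)
        assert res.discrimination_slope_new == pytest.approx(0.25)

    def test_identity_zero(self, rng):
        p = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        assert idi(p, p, y).idi == 0.0

    def test_slope_oracle(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        p_old, p_new = rng.random(n), rng.random(n)
        res = idi(p_old, p_new, y)
        ev = y.astype(bool)
        slope = lambda p: p[ev].mean() - p[~ev].mean()  # noqa: E731
        assert res.idi == pytest.approx(slope(p_new) - slope(p_old), abs=1e-12)


class TestSymmetriesAndBounds:
    @given(st.integers(0, 10_000))
    @settings(max_examples=80, deadline=None)
    def test_antisymmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 40)
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            return
        p_old, p_new = rng.random(n), rng.random(n)
        for stat in (
            lambda a, b: categorical_nri(a, b, y)[0],
            lambda a, b: continuous_nri(a, b, y),
        ):
            fwd, rev = stat(p_old, p_new), stat(p_new, p_old)
            assert fwd.nri == pytest.approx(-rev.nri, abs=1e-12)
            assert -1 <= fwd.event_component <= 1
            assert -1 <= fwd.nonevent_component <= 1
            assert -2 <= fwd.nri <= 2
        assert idi(p_old, p_new, y).idi == pytest.approx(
            -idi(p_new, p_old, y).idi, abs=1e-12
        )

    def test_bootstrap_ci_brackets_estimate(self, rng):
        n = 300
        y = np.r_[np.ones(100), np.zeros(200)].astype(int)
        p_old = np.clip(rng.normal(0.3 + 0.1 * y, 0.1), 0.01, 0.99)
        p_new = np.clip(rng.normal(0.3 + 0.25 * y, 0.1), 0.01, 0.99)
        res = continuous_nri(p_old, p_new, y, bootstrap_reps=500, seed=0)
        lo, hi = res.bootstrap_ci
        assert lo < res.nri < hi
        ires = idi(p_old, p_new, y, bootstrap_reps=500, seed=0)
        lo, hi = ires.bootstrap_ci
        assert lo < ires.idi < hi
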