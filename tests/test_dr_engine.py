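import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txtime import (
    DynamicRange,
    EnergyLayer,
    LineSegment,
    MachineSpec,
    TreatmentField,
    adjust_layer,
    baseline_dose_rate,
    bot_floor,
    dr_dose_rate,
    elevate_mu,
    field_bot,
)

UNC = DynamicRange.unconstrained()


def random_layer(rng, n=None, uniform_length=True):
    n = n or int(rng.integers(2, 40))
    mus = rng.lognormal(-4.5, 1.2, size=n)
    lengths = np.full(n, 0.6) if uniform_length else rng.uniform(0.2, 2.0, size=n)
    return EnergyLayer(150.0, tuple(LineSegment(float(m), float(l)) for m, l in zip(mus, lengths)))


class TestDynamicRange:
    def test_constrained_below_one_rejected(self):
        with pytest.raises(ValueError):
            DynamicRange(0.5)
        with pytest.raises(ValueError):
            DynamicRange(float("nan"))
        assert DynamicRange(1.0).constrained
        assert not UNC.constrained

    def test_parse(self):
        assert DynamicRange.parse("unconstrained") == UNC
        assert DynamicRange.parse("10") == DynamicRange(10)
        assert DynamicRange.parse(None) == UNC


class TestBaselineDoseRate:
    def test_worked_layer(self, worked_layer, machine):
        """mu_min 0.0010 over 0.6 cm at 2000 cm/s pins the rate at 10/3 MU/s."""
        rate = baseline_dose_rate(worked_layer, machine)
        assert rate == pytest.approx(0.0010 / 0.6 * 2000, rel=1e-12)
        assert round(rate, 1) == 3.3  # the 2-significant-figure clinical value

    def test_single_segment_direct_formula(self, machine):
        layer = EnergyLayer(150.0, (LineSegment(0.5, 1.0),))
        assert baseline_dose_rate(layer, machine) == pytest.approx(1000.0)

    def test_mixed_lengths_brute_force(self, machine):
        rng = np.random.default_rng(21)
        layer = random_layer(rng, n=200, uniform_length=False)
        expected = min((s.mu / s.length) * machine.speed_max for s in layer.segments)
        assert baseline_dose_rate(layer, machine) == pytest.approx(expected, rel=1e-12)

    def test_machine_dose_rate_cap(self):
        layer = EnergyLayer(150.0, (LineSegment(0.5, 1.0),))
        capped = MachineSpec(speed_max=2000.0, max_dose_rate=100.0)
        assert baseline_dose_rate(layer, capped) == 100.0


class TestDrDoseRate:
    def test_worked_layer_dr10(self, worked_layer, machine):
        """(0.0198/0.6)*2000/10 = 6.6 MU/s, within 1% of the reported 6.592."""
        rate = dr_dose_rate(worked_layer, DynamicRange(10), machine)
        assert rate == pytest.approx(6.6, rel=1e-12)
        assert abs(rate - 6.592) / 6.592 < 0.01

    def test_direct_formula(self, machine):
        # mu_max 1.0 over 1.0 cm at 2000 cm/s, DR = 100 -> 20 MU/s (the low-MU
        # companion segment keeps the baseline below the DR-elevated rate)
        layer = EnergyLayer(150.0, (LineSegment(1.0, 1.0), LineSegment(0.001, 1.0)))
        assert dr_dose_rate(layer, DynamicRange(100), machine) == pytest.approx(20.0)

    def test_dr_equal_intrinsic_ratio_equals_baseline(self, machine):
        rng = np.random.default_rng(5)
        for _ in range(20):
            layer = random_layer(rng)
            intrinsic = layer.mu_max / layer.mu_min
            assert dr_dose_rate(layer, DynamicRange(intrinsic), machine) == pytest.approx(
                baseline_dose_rate(layer, machine), rel=1e-9
            )

    def test_loose_dr_never_slower_than_baseline(self, machine):
        rng = np.random.default_rng(6)
        for _ in range(20):
            layer = random_layer(rng)
            loose = 10 * layer.mu_max / layer.mu_min
            assert dr_dose_rate(layer, DynamicRange(loose), machine) >= baseline_dose_rate(
                layer, machine
            ) - 1e-15

    def test_unconstrained_delegates_to_baseline(self, worked_layer, machine):
        assert dr_dose_rate(worked_layer, UNC, machine) == baseline_dose_rate(
            worked_layer, machine
        )


class TestElevateMu:
    def test_worked_layer_dr10_clamps_two_segments(self, worked_layer):
        adjusted = elevate_mu(worked_layer, DynamicRange(10))
        floor = 0.0198 / 10
        assert adjusted[0] == pytest.approx(floor)  # 0.0013 -> 0.00198
        assert adjusted[4] == pytest.approx(floor)  # 0.0010 -> 0.00198
        assert adjusted[1:4] == [0.0198, 0.0178, 0.0056]  # untouched

    def test_loose_dr_is_identity(self, worked_layer):
        loose = DynamicRange(2 * 0.0198 / 0.0010)
        assert elevate_mu(worked_layer, loose) == [s.mu for s in worked_layer.segments]

    def test_dr_one_clamps_everything_to_mu_max(self, worked_layer):
        assert elevate_mu(worked_layer, DynamicRange(1)) == pytest.approx([0.0198] * 5)

    def test_mu_conservation_violated_only_upward(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            layer = random_layer(rng)
            adjusted = elevate_mu(layer, DynamicRange(10))
            assert all(a >= s.mu for a, s in zip(adjusted, layer.segments))
            assert sum(adjusted) >= sum(s.mu for s in layer.segments)


class TestAdjustLayer:
    def test_worked_layer_baseline_bot(self, worked_layer, machine):
        adj = adjust_layer(worked_layer, UNC, machine)
        assert adj.layer_bot == pytest.approx(0.01365, abs=5e-4)  # reported as 0.0138
        # per-segment beam-on times agree with the worked table at the 4th decimal
        expected = [0.0004, 0.0060, 0.0054, 0.0017, 0.0003]
        assert np.allclose(adj.segment_bot, expected, atol=1e-4)
        assert adj.n_elevated == 0
        assert adj.adjusted_mu == tuple(s.mu for s in worked_layer.segments)

    def test_worked_layer_dr10_bot(self, worked_layer, machine):
        adj = adjust_layer(worked_layer, DynamicRange(10), machine)
        assert adj.layer_bot == pytest.approx(0.0072, abs=5e-4)
        expected = [0.0003, 0.0030, 0.0027, 0.0009, 0.0003]
        assert np.allclose(adj.segment_bot, expected, atol=1e-4)
        assert adj.n_elevated == 2
        # the reduction lands at about half the baseline (0.0072/0.0138)
        base = adjust_layer(worked_layer, UNC, machine)
        assert 0.50 < adj.layer_bot / base.layer_bot < 0.55

    def test_layer_bot_is_sum_of_segment_bot(self, machine):
        rng = np.random.default_rng(9)
        layer = random_layer(rng, n=100)
        adj = adjust_layer(layer, DynamicRange(50), machine)
        assert adj.layer_bot == pytest.approx(sum(adj.segment_bot), rel=1e-12)

    def test_all_equal_mu_layer_is_pure_traversal(self, machine):
        """Equal MUs at any DR: BoT = N * length / speed_max (scan at full speed)."""
        layer = EnergyLayer(150.0, tuple(LineSegment(0.01, 0.6) for _ in range(7)))
        for dr in (UNC, DynamicRange(10), DynamicRange(1)):
            adj = adjust_layer(layer, dr, machine)
            assert adj.layer_bot == pytest.approx(7 * 0.6 / 2000.0, rel=1e-12)

    def test_implied_speed_never_exceeds_machine(self, machine):
        rng = np.random.default_rng(10)
        for uniform in (True, False):
            layer = random_layer(rng, n=50, uniform_length=uniform)
            for dr in (UNC, DynamicRange(100), DynamicRange(10), DynamicRange(1)):
                adj = adjust_layer(layer, dr, machine)
                for a, s in zip(adj.adjusted_mu, layer.segments):
                    speed = adj.dose_rate * s.length / a
                    assert speed <= machine.speed_max * (1 + 1e-9)

    @given(
        seed=st.integers(0, 10_000),
        dr_pair=st.tuples(st.floats(10, 200), st.floats(10, 200)),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotonicity_in_dr(self, seed, dr_pair):
        """Tighter DR never lengthens BoT, never lowers the dose rate."""
        machine = MachineSpec()
        layer = random_layer(np.random.default_rng(seed), n=20)
        lo, hi = sorted(dr_pair)
        a_lo = adjust_layer(layer, DynamicRange(lo), machine)
        a_hi = adjust_layer(layer, DynamicRange(hi), machine)
        assert a_lo.layer_bot <= a_hi.layer_bot + 1e-12
        assert a_lo.dose_rate >= a_hi.dose_rate - 1e-12

    @given(seed=st.integers(0, 10_000), dr=st.floats(1, 300))
    @settings(max_examples=60, deadline=None)
    def test_bot_floor_lower_bound(self, seed, dr):
        machine = MachineSpec()
        layer = random_layer(np.random.default_rng(seed), n=15)
        adj = adjust_layer(layer, DynamicRange(dr), machine)
        assert adj.layer_bot >= bot_floor(layer, machine) - 1e-15

    def test_dr_one_attains_the_floor(self, machine):
        rng = np.random.default_rng(14)
        layer = random_layer(rng, n=30)
        adj = adjust_layer(layer, DynamicRange(1), machine)
        assert adj.layer_bot == pytest.approx(bot_floor(layer, machine), rel=1e-9)


class TestFieldBot:
    def test_additivity_over_identical_layers(self, worked_layer, machine):
        field = TreatmentField("f", (worked_layer,) * 3)
        res = field_bot(field, DynamicRange(10), machine)
        single = adjust_layer(worked_layer, DynamicRange(10), machine).layer_bot
        assert res.total == pytest.approx(3 * single, rel=1e-12)
        assert list(res.per_layer) == pytest.approx([single] * 3)

    def test_huge_dr_equals_unconstrained(self, machine):
        rng = np.random.default_rng(15)
        field = TreatmentField("f", tuple(random_layer(rng) for _ in range(5)))
        assert field_bot(field, DynamicRange(1e6), machine).total == pytest.approx(
            field_bot(field, UNC, machine).total, rel=1e-12
        )

    def test_total_matches_independent_segment_loop(self, machine):
        """Brute-force oracle: recompute the field total segment by segment."""
        rng = np.random.default_rng(16)
        field = TreatmentField("f", tuple(random_layer(rng) for _ in range(30)))
        dr = DynamicRange(25)
        expected = 0.0
        for layer in field.layers:
            floor = layer.mu_max / dr.value
            rate = max(
                min(s.mu / s.length for s in layer.segments) * machine.speed_max,
                max(s.mu / s.length for s in layer.segments if s.mu == layer.mu_max)
                * machine.speed_max / dr.value,
            )
            for s in layer.segments:
                expected += max(s.mu, floor) / rate
        assert field_bot(field, dr, machine).total == pytest.approx(expected, rel=1e-9)
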