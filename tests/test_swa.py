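"""Cyclic learning-rate schedule and stochastic weight averaging."""

import numpy as np
import pytest

from plumvision.model import NetworkSpec, build_network, predict
from plumvision.swa import (
    CycleSchedule,
    SWAState,
    cycle_ends,
    cyclic_lr,
    finalize,
    swa_update,
)


class TestCyclicLR:
    def test_endpoint_of_cycle_hits_lower_rate(self):
        s = CycleSchedule(0.1, 0.05, c=7)
        assert cyclic_lr(s, 7) == pytest.approx(0.05)
        assert cyclic_lr(s, 14) == pytest.approx(0.05)

    def test_periodicity(self):
        s = CycleSchedule(0.1, 0.05, c=5)
        for i in range(1, 40):
            assert cyclic_lr(s, i + 5) == pytest.approx(cyclic_lr(s, i))

    def test_first_step_arithmetic(self):
        # t = 1/5 -> 0.8 * 0.1 + 0.2 * 0.05 = 0.09
        s = CycleSchedule(0.1, 0.05, c=5)
        assert cyclic_lr(s, 1) == pytest.approx(0.09)

    def test_rate_stays_in_band(self):
        s = CycleSchedule(0.3, 0.07, c=11)
        rates = [cyclic_lr(s, i) for i in range(1, 200)]
        assert min(rates) >= 0.07 - 1e-15
        assert max(rates) <= 0.3

    def test_cycle_end_marker(self):
        s = CycleSchedule(0.1, 0.05, c=4)
        assert [cycle_ends(s, i) for i in range(1, 9)] == \
            [False, False, False, True, False, False, False, True]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cyclic_lr(CycleSchedule(0.1, 0.05, 5), 0)
        with pytest.raises(ValueError):
            CycleSchedule(0.05, 0.1, 5)
        with pytest.raises(ValueError):
            CycleSchedule(0.1, 0.05, 0)


class TestSWAUpdate:
    def test_first_snapshot_becomes_average(self):
        st = SWAState()
        swa_update(st, {"w": np.array([3.0, 4.0])})
        assert st.n_models == 1
        assert np.allclose(st.w_swa["w"], [3.0, 4.0])

    def test_identical_snapshots_leave_average_unchanged(self):
        st = SWAState()
        for _ in range(5):
            swa_update(st, {"w": np.array([1.5])})
        assert st.w_swa["w"] == pytest.approx(1.5)

    def test_scalar_snapshots_average_arithmetically(self):
        st = SWAState()
        for v in (1.0, 2.0, 4.0):
            swa_update(st, {"w": np.array([v])})
        assert st.w_swa["w"] == pytest.approx(7.0 / 3.0)

    def test_running_mean_equals_batch_mean_oracle(self, rng):
        """Accumulate-then-divide oracle over many random snapshots."""
        st = SWAState()
        snaps = [rng.normal(size=(3, 4)) for _ in range(12)]
        for s in snaps:
            swa_update(st, {"w": s})
        assert np.abs(st.w_swa["w"] - np.mean(snaps, axis=0)).max() < 1e-12

    def test_shape_mismatch_rejected(self):
        st = SWAState()
        swa_update(st, {"w": np.zeros(3)})
        with pytest.raises(ValueError):
            swa_update(st, {"w": np.zeros(4)})


class TestFinalize:
    def _tiny_net(self, seed=0):
        return build_network(NetworkSpec(width_multiplier=0.125), seed=seed)

    def test_no_snapshots_raises(self):
        with pytest.raises(ValueError):
            finalize(self._tiny_net(), SWAState(), [])

    def test_finalize_then_predict_is_deterministic(self, rng):
        net = self._tiny_net()
        st = SWAState()
        swa_update(st, net.named_params())
        batch = rng.normal(size=(8, 3, 32, 32)).astype(np.float32)
        finalize(net, st, [batch])
        _, s1 = predict(net, batch)
        _, s2 = predict(net, batch)
        assert np.array_equal(s1, s2)

    def test_single_snapshot_average_equals_snapshot_model(self, rng):
        """Averaging one snapshot and recalibrating must reproduce the
        snapshot model under the same recalibration."""
        batch = rng.normal(size=(16, 3, 32, 32)).astype(np.float32)
        net_a = self._tiny_net(seed=9)
        st = SWAState()
        swa_update(st, net_a.named_params())
        finalize(net_a, st, [batch])
        _, sa = predict(net_a, batch)

        net_b = self._tiny_net(seed=9)
        st_b = SWAState()
        swa_update(st_b, net_b.named_params())
        finalize(net_b, st_b, [batch])
        _, sb = predict(net_b, batch)
        assert np.allclose(sa, sb, atol=1e-6)

    def test_opposite_weights_average_to_zero_logits(self, rng):
        """Snapshots w and -w average to zero weights: the classifier head
        then outputs identical (zero) scores for every input."""
        net = self._tiny_net(seed=2)
        w = {k: v.copy() for k, v in net.named_params().items()}
        st = SWAState()
        swa_update(st, w)
        swa_update(st, {k: -v for k, v in w.items()})
        batch = rng.normal(size=(8, 3, 32, 32)).astype(np.float32)
        finalize(net, st, [batch])
        assert all(np.allclose(v, 0) for v in net.named_params().values())
        _, scores = predict(net, batch)
        assert np.allclose(scores, 0.0, atol=1e-7)

    def test_finalize_clears_pending_flag(self, rng):
        net = self._tiny_net()
        net.swa_pending = True
        st = SWAState()
        swa_update(st, net.named_params())
        finalize(net, st, [rng.normal(size=(4, 3, 32, 32)).astype(np.float32)])
        assert not net.swa_pending
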