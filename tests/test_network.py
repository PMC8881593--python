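import numpy as np
import pytest

from cxcompass import network as net
from cxcompass._angles import wrap_rad
from cxcompass.encoding import AngularVelocityEncoder, pen_drive
from cxcompass.readout import decode_heading


class TestLayout:
    def test_population_counts(self, layout):
        assert layout.n_total == 141
        assert layout.counts == {
            "ring": 81, "epg": 18, "pen": 16, "peg": 16, "pintr": 10,
        }

    def test_pintr_count_is_remainder(self, layout):
        assert layout.counts["pintr"] == 141 - 81 - 18 - 16 - 16

    def test_preferred_angles_closed_ring(self, layout):
        """The ring has 8 distinct positions at 2*pi/8 spacing; the ninth
        glomerulus per hemisphere duplicates position 0 so both rotation
        directions are covered by the 8 P-EN/P-EG per hemisphere."""
        th = layout.preferred_angles
        assert th.shape == (18,)
        # identical across hemispheres
        np.testing.assert_allclose(th[:9], th[9:])
        distinct = np.unique(np.round(th[:8], 12))
        assert len(distinct) == 8
        assert wrap_rad(th[8] - th[0]) == pytest.approx(0.0)
        spacing = np.diff(np.sort(np.unique(wrap_rad(th) % (2 * np.pi))))
        np.testing.assert_allclose(spacing, 2 * np.pi / 8)


class TestConnectome:
    def test_block_values(self, layout, connectome):
        W = connectome.weights
        epg_to_pintr = W[layout.epg, layout.pintr]
        assert np.all(epg_to_pintr[epg_to_pintr != 0] == 20.0)
        assert np.any(epg_to_pintr != 0)
        pintr_to_pen = W[layout.pintr, layout.pen]
        assert np.all(pintr_to_pen[pintr_to_pen != 0] == -15.0)
        pintr_to_peg = W[layout.pintr, layout.peg]
        assert np.all(pintr_to_peg[pintr_to_peg != 0] == -15.0)
        pintr_to_pintr = W[layout.pintr, layout.pintr]
        off_diag = pintr_to_pintr[~np.eye(10, dtype=bool)]
        assert np.all(off_diag == -20.0)

    def test_pintr_never_inhibit_epg(self, layout, connectome):
        assert np.all(connectome.weights[layout.pintr, layout.epg] == 0.0)

    def test_sign_pattern(self, layout, connectome):
        W = connectome.weights
        # excitatory blocks are 0 or +20, never negative
        for pre, post in [
            (layout.epg, layout.pen), (layout.epg, layout.peg),
            (layout.epg, layout.pintr), (layout.pen, layout.epg),
            (layout.peg, layout.epg),
        ]:
            blk = W[pre, post]
            assert np.all((blk == 0.0) | (blk == 20.0))
        # ring rows and columns carry no fixed weights
        assert np.all(W[layout.ring, :] == 0.0)
        assert np.all(W[:, layout.ring] == 0.0)
        # no self-excitation of E-PG
        assert np.all(W[layout.epg, layout.epg] == 0.0)

    def test_even_pintr_coverage(self, layout, connectome):
        # every P-EN/P-EG receives the same number of PIntr inputs
        W = connectome.weights
        counts = (W[layout.pintr, layout.pen] != 0).sum(axis=0)
        assert len(set(counts)) == 1
        counts_g = (W[layout.pintr, layout.peg] != 0).sum(axis=0)
        assert len(set(counts_g)) == 1


class TestLIF:
    def test_subthreshold_decay(self, lif_params):
        state = net.NetworkState.zeros(1)
        state.v[:] = 0.5
        for _ in range(200):
            net.lif_step(state, np.zeros((1, net.N_TOTAL)), lif_params)
        assert not state.spikes.any()
        assert np.all(np.abs(state.v) < 1e-4)

    @pytest.mark.parametrize("current", [1.5, 3.0, 8.0])
    def test_rate_matches_closed_form(self, lif_params, current):
        state = net.NetworkState.zeros(1)
        I = np.full((1, net.N_TOTAL), current)
        n = 0
        steps = 4000
        for _ in range(steps):
            net.lif_step(state, I, lif_params)
            n += int(state.spikes[0, 0])
        empirical = n / (steps * lif_params.dt)
        # exact match to the discrete-time closed form ...
        assert empirical == pytest.approx(
            net.lif_rate_discrete(current, lif_params), rel=0.02
        )
        # ... and the continuous closed form where quantization is mild
        if current < 2.0:
            assert empirical == pytest.approx(
                net.lif_rate(current, lif_params), rel=0.02
            )

    def test_seeded_runs_identical(self, layout, connectome, lif_params):
        def raster(seed):
            rng = np.random.default_rng(seed)
            state = net.NetworkState.zeros(2)
            net.init_bump(state, 0.0, layout, connectome, lif_params, rng, epg_bias=0.3)
            rec = []
            for _ in range(200):
                net.step_network(
                    state, np.zeros((2, 81)), np.zeros((2, 16)), None, None,
                    connectome, layout, lif_params, rng, epg_bias=0.3,
                )
                rec.append(state.spikes.copy())
            return np.array(rec)

        np.testing.assert_array_equal(raster(3), raster(3))
        assert raster(3).any()  # and the network is actually active

    def test_nonfinite_current_rejected(self, lif_params):
        state = net.NetworkState.zeros(1)
        I = np.full((1, net.N_TOTAL), np.nan)
        with pytest.raises(ValueError):
            net.lif_step(state, I, lif_params)

    def test_inverse_rate_current(self, lif_params):
        for r in [50.0, 150.0, 300.0]:
            I = net.lif_current_for_rate(r, lif_params)
            assert net.lif_rate(I, lif_params) == pytest.approx(r, rel=1e-9)


def _run_free(layout, connectome, p, av, duration, seed=0, bias=0.3, B=4, init=0.0):
    rng = np.random.default_rng(seed)
    enc = AngularVelocityEncoder(lif=p)
    state = net.NetworkState.zeros(B)
    net.init_bump(state, init, layout, connectome, p, rng, epg_bias=bias)
    th = layout.preferred_angles
    T = int(duration / p.dt)
    hs = np.empty((B, T))
    rates = np.zeros(net.N_TOTAL)
    for i in range(T):
        avm = av + rng.standard_normal(B) * 0.1
        net.step_network(
            state, np.zeros((B, 81)), pen_drive(avm, enc), None, None,
            connectome, layout, p, rng, epg_bias=bias,
        )
        c = state.trace[:, layout.epg]
        hs[:, i] = np.arctan2(c @ np.sin(th), c @ np.cos(th))
        rates += state.spikes.mean(axis=0)
    return hs, rates / (T * p.dt)


class TestAttractor:
    def test_bump_initialization_and_persistence(self, layout, connectome, lif_params):
        """A seeded bump decodes near its target and survives 1 s of zero
        input with less than one ring position of drift."""
        rng = np.random.default_rng(11)
        state = net.NetworkState.zeros(4)
        target = np.pi / 2
        net.init_bump(state, target, layout, connectome, lif_params, rng, epg_bias=0.3)
        h0, _ = decode_heading(state.trace[:, layout.epg], layout.preferred_angles)
        assert np.all(np.abs(wrap_rad(h0 - target)) < 2 * np.pi / 8)
        hs, rates = _run_free(layout, connectome, lif_params, 0.0, 1.0, seed=11, init=target)
        drift = np.abs(wrap_rad(hs[:, -1] - h0))
        assert np.all(drift < 2 * np.pi / 8)
        assert rates[layout.epg].max() > 20.0  # bump alive, not silent

    def test_single_bump(self, layout, connectome, lif_params):
        # exactly one contiguous active region on the ring (positions of
        # trace above half its max form one circular run)
        rng = np.random.default_rng(2)
        state = net.NetworkState.zeros(1)
        net.init_bump(state, 0.0, layout, connectome, lif_params, rng, epg_bias=0.3)
        for _ in range(500):
            net.step_network(
                state, np.zeros((1, 81)), pen_drive(np.zeros(1), AngularVelocityEncoder(lif=lif_params)),
                None, None, connectome, layout, lif_params, rng, epg_bias=0.3,
            )
        tr = state.trace[0, layout.epg]
        by_pos = np.zeros(8)
        np.add.at(by_pos, layout.epg_position, tr)
        active = by_pos > 0.5 * by_pos.max()
        # count circular runs of active positions
        transitions = np.sum(active != np.roll(active, 1))
        assert transitions == 2

    def test_shift_direction_follows_hemisphere(self, layout, connectome, lif_params):
        """Positive angular velocity (right P-EN) moves the bump
        counter-clockwise; negative moves it clockwise."""
        hs_pos, _ = _run_free(layout, connectome, lif_params, 2.0, 2.0, seed=5)
        hs_neg, _ = _run_free(layout, connectome, lif_params, -2.0, 2.0, seed=5)
        disp_pos = wrap_rad(np.diff(hs_pos, axis=1)).sum(axis=1).mean()
        disp_neg = wrap_rad(np.diff(hs_neg, axis=1)).sum(axis=1).mean()
        assert disp_pos > 0.3
        assert disp_neg < -0.3

    def test_runaway_guard(self, layout, connectome, lif_params):
        # mean E-PG rate stays bounded: PIntr inhibition is functional
        _, rates = _run_free(layout, connectome, lif_params, 1.0, 3.0, seed=9)
        assert rates[layout.epg].mean() < 400.0
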